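"""Construction of the binary training tasks.

Labeling thresholds follow the screening convention: a compound is a
ligand of a target at Ki < 1 uM, a non-ligand at Ki > 10 uM, and
indeterminate in the 1-10 uM gap (excluded from training, so assay
noise near the cutoff cannot flip training labels).  Subtype-selective
means at least a 10-fold Ki ratio in favour of the first subtype;
multi-subtype means Ki < 1 uM on two or more subtypes.

Negative classes for the step-1 binding tasks combine known
non-ligands with *putative* non-ligands: representatives of compound
families (leader clustering under Tanimoto similarity) that contain no
known ligand of the target.  Step-2 binary-relevance selectivity tasks
use ligands of the target as positives and ligands of the other
subtypes as negatives.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .chem_io import CompoundRecord, DescriptorMatrix, FingerprintMatrix
from .errors import DatasetError
from .features import ScalerParams, apply_scaler, fit_scaler


class ActivityLabel(enum.Enum):
    LIGAND = "ligand"
    NON_LIGAND = "non_ligand"
    INDETERMINATE = "indeterminate"
    UNTESTED = "untested"


DEFAULT_LIGAND_THRESHOLD = 1.0  # uM
DEFAULT_NONLIGAND_THRESHOLD = 10.0  # uM
DEFAULT_SELECTIVITY_FOLD = 10.0


def assign_activity_label(
    ki: float | None,
    ligand_threshold: float = DEFAULT_LIGAND_THRESHOLD,
    nonligand_threshold: float = DEFAULT_NONLIGAND_THRESHOLD,
) -> ActivityLabel:
    """Map one Ki value (uM, or None for untested) to an activity label."""
    if ligand_threshold >= nonligand_threshold:
        raise DatasetError("ligand threshold must be below the non-ligand threshold")
    if ki is None:
        return ActivityLabel.UNTESTED
    if ki <= 0:
        raise DatasetError(f"non-positive Ki {ki}")
    if ki < ligand_threshold:
        return ActivityLabel.LIGAND
    if ki > nonligand_threshold:
        return ActivityLabel.NON_LIGAND
    return ActivityLabel.INDETERMINATE


def label_selective(
    record: CompoundRecord,
    target_a: str,
    target_b: str,
    fold_threshold: float = DEFAULT_SELECTIVITY_FOLD,
    ligand_threshold: float = DEFAULT_LIGAND_THRESHOLD,
) -> bool | None:
    """Is the compound a ``target_a``-selective ligand against ``target_b``?

    Returns ``None`` (not evaluable) if either Ki is missing or the
    compound does not qualify as a ligand of ``target_a``; otherwise the
    Ki ratio Ki_b / Ki_a is compared against the fold threshold.
    """
    ki_a = record.ki(target_a)
    ki_b = record.ki(target_b)
    if ki_a is None or ki_b is None:
        return None
    if assign_activity_label(ki_a, ligand_threshold) is not ActivityLabel.LIGAND:
        return None
    return ki_b / ki_a >= fold_threshold


def label_multi_subtype(
    record: CompoundRecord,
    targets: list[str],
    ligand_threshold: float = DEFAULT_LIGAND_THRESHOLD,
) -> set[str]:
    """Subtypes the compound binds as a ligand; multi-subtype iff >= 2."""
    return {
        t
        for t in targets
        if record.ki(t) is not None and record.ki(t) < ligand_threshold
    }


def tanimoto_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between binary row sets a (n x l) and b (m x l)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return sim


@dataclass
class FamilyClustering:
    """Leader clustering of compounds into families.

    Algorithm (deterministic given input order): scan compounds in
    order; join the existing leader of maximal Tanimoto similarity if
    that similarity >= threshold (ties -> earliest leader), else open a
    new family led by the compound.  The family representative is the
    member with maximal mean similarity to its family (ties -> smallest
    compound id).  All-zero fingerprints become flagged singletons.
    """

    family_of: dict[str, int]
    representatives: dict[int, str]
    threshold: float
    method: str = "tanimoto-leader"
    flagged: list[str] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return len(self.representatives)

    def members(self, family_id: int) -> list[str]:
        return [c for c, f in self.family_of.items() if f == family_id]


def cluster_families(fp: FingerprintMatrix, threshold: float = 0.7) -> FamilyClustering:
    if not 0 < threshold < 1:
        raise DatasetError("clustering threshold must be in (0, 1)")
    if fp.n == 0:
        raise DatasetError("cannot cluster an empty fingerprint set")
    bits = fp.bits.astype(np.float64)
    row_sums = bits.sum(axis=1)
    zero_rows = row_sums == 0

    leaders: list[int] = []
    family_of_idx = np.full(fp.n, -1, dtype=int)
    for i in range(fp.n):
        if zero_rows[i]:
            family_of_idx[i] = len(leaders)
            leaders.append(i)
            continue
        if leaders:
            lead_bits = bits[leaders]
            inter = lead_bits @ bits[i]
            union = row_sums[leaders] + row_sums[i] - inter
            sims = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
            # zero-fingerprint leaders can never admit members
            sims = np.where(row_sums[leaders] == 0, -1.0, sims)
            best = int(np.argmax(sims))
            if sims[best] >= threshold:
                family_of_idx[i] = best
                continue
        family_of_idx[i] = len(leaders)
        leaders.append(i)

    ids = fp.compound_ids
    family_of = {ids[i]: int(family_of_idx[i]) for i in range(fp.n)}
    representatives: dict[int, str] = {}
    for fam in range(len(leaders)):
        member_idx = np.nonzero(family_of_idx == fam)[0]
        if len(member_idx) == 1:
            representatives[fam] = ids[member_idx[0]]
            continue
        block = bits[member_idx]
        sims = tanimoto_matrix(block, block)
        mean_sim = sims.mean(axis=1)
        best_val = mean_sim.max()
        candidates = sorted(ids[j] for j in member_idx[np.isclose(mean_sim, best_val)])
        representatives[fam] = candidates[0]
    flagged = [ids[i] for i in np.nonzero(zero_rows)[0]]
    return FamilyClustering(family_of, representatives, threshold, flagged=flagged)


def generate_putative_negatives(
    families: FamilyClustering,
    known_ligands_of_target: set[str],
    max_per_family: int = 1,
) -> list[str]:
    """Representatives of families with no known ligand of the target.

    With ``max_per_family`` > 1, additional members are drawn in sorted
    id order after the representative.  The result is disjoint from the
    known ligand set by construction and sorted for determinism.
    """
    ligand_families = {families.family_of[c] for c in known_ligands_of_target if c in families.family_of}
    out: list[str] = []
    for fam, rep in families.representatives.items():
        if fam in ligand_families:
            continue
        picked = [rep]
        if max_per_family > 1:
            others = sorted(c for c in families.members(fam) if c != rep)
            picked.extend(others[: max_per_family - 1])
        out.extend(picked)
    if not out:
        warnings.warn("no ligand-free families; putative negative set is empty", stacklevel=2)
    return sorted(out)


@dataclass
class LabeledDataset:
    """Scaled descriptor matrix with +/-1 labels for one binary task."""

    X: np.ndarray
    y: np.ndarray
    compound_ids: list[str]
    task: str
    descriptor_names: list[str]
    scaler: ScalerParams

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.compound_ids):
            raise DatasetError("X, y, and compound_ids must align")
        if not np.isin(self.y, (-1, 1)).all():
            raise DatasetError("labels must be +/-1")
        if (self.y == 1).sum() == 0 or (self.y == -1).sum() == 0:
            raise DatasetError(f"task {self.task!r}: one class is empty")

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == -1).sum())


def _assemble(
    target: str,
    task: str,
    pos_ids: list[str],
    neg_ids: list[str],
    descriptors: DescriptorMatrix,
    scaling: str,
) -> LabeledDataset:
    if not pos_ids:
        raise DatasetError(f"task {task!r}: positive class is empty")
    if not neg_ids:
        raise DatasetError(f"task {task!r}: negative class is empty")
    ids = list(pos_ids) + list(neg_ids)
    raw = descriptors.subset(ids)
    scaler = fit_scaler(raw, method=scaling)
    X = apply_scaler(scaler, raw)
    y = np.concatenate([np.ones(len(pos_ids), dtype=int), -np.ones(len(neg_ids), dtype=int)])
    return LabeledDataset(X, y, ids, task, list(descriptors.descriptor_names), scaler)


def build_binding_dataset(
    target: str,
    records: list[CompoundRecord],
    descriptors: DescriptorMatrix,
    putative_negative_ids: list[str] | None = None,
    ligand_threshold: float = DEFAULT_LIGAND_THRESHOLD,
    nonligand_threshold: float = DEFAULT_NONLIGAND_THRESHOLD,
    scaling: str = "minmax",
) -> LabeledDataset:
    """Step-1 task: ligands of ``target`` vs known non-ligands plus
    putative negatives.  Gap (indeterminate) compounds appear in
    neither class; a compound labeled ligand is never kept as negative."""
    available = set(descriptors.compound_ids)
    pos, neg = [], []
    for rec in records:
        if rec.compound_id not in available:
            continue
        lab = assign_activity_label(rec.ki(target), ligand_threshold, nonligand_threshold)
        if lab is ActivityLabel.LIGAND:
            pos.append(rec.compound_id)
        elif lab is ActivityLabel.NON_LIGAND:
            neg.append(rec.compound_id)
    pos_set = set(pos)
    for cid in putative_negative_ids or []:
        if cid in available and cid not in pos_set:
            neg.append(cid)
    neg = sorted(set(neg) - pos_set)
    return _assemble(target, f"binding:{target}", pos, neg, descriptors, scaling)


def build_selectivity_dataset(
    target: str,
    records: list[CompoundRecord],
    targets: list[str],
    descriptors: DescriptorMatrix,
    ligand_threshold: float = DEFAULT_LIGAND_THRESHOLD,
    scaling: str = "minmax",
) -> LabeledDataset:
    """Step-2 binary-relevance task: ligands of ``target`` vs ligands of
    the other subtypes.  A compound that is a ligand of ``target`` and
    of another subtype is assigned once, to the positive class."""
    if len(targets) < 2:
        raise DatasetError("selectivity tasks require at least two targets")
    available = set(descriptors.compound_ids)
    pos, neg = [], []
    for rec in records:
        if rec.compound_id not in available:
            continue
        bound = label_multi_subtype(rec, targets, ligand_threshold)
        if target in bound:
            pos.append(rec.compound_id)
        elif bound:
            neg.append(rec.compound_id)
    return _assemble(target, f"selectivity:{target}", pos, neg, descriptors, scaling)


@dataclass
class FoldAssignment:
    """Stratified fold index per compound (per-class counts differ by <= 1)."""

    fold_of: np.ndarray
    k: int
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_of == fold
        return np.nonzero(~test)[0], np.nonzero(test)[0]


def stratified_kfold(dataset: LabeledDataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    if k < 2:
        raise DatasetError("k must be >= 2")
    if dataset.n_pos < k or dataset.n_neg < k:
        warnings.warn(
            f"task {dataset.task!r}: a class has fewer than {k} members; "
            "some folds will miss that class",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(dataset.y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(dataset.X, dataset.y)):
        fold_of[test_idx] = fold
    return FoldAssignment(fold_of, k, seed)
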