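"""Screening strategies: single-label SVM, Combi-SVM, and 2SBR-SVM.

All three strategies share the same per-subtype step-1 binding models
(ligands vs known + putative non-ligands).  They differ in how a
"subtype selective" call is made on a screened compound:

* ``single``  — per-subtype call = step-1 positive; selectivity is not
  assessed (the reference point for hit-rate comparisons).
* ``combi``   — per-subtype call = step-1 positive; a compound is
  selective iff exactly one subtype call is positive (parallel
  screening).
* ``2sbr``    — per-subtype call = step-1 positive AND step-2
  binary-relevance selectivity positive; selective iff exactly one
  composed call is positive.

Because the 2SBR call is a conjunction, its per-subtype hit set is a
subset of the single-label hit set on any library, and its virtual hit
rate can never exceed the single-label rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import CompoundRecord, DescriptorMatrix, FingerprintMatrix
from .datasets import (
    build_binding_dataset,
    build_selectivity_dataset,
    cluster_families,
    generate_putative_negatives,
    label_multi_subtype,
)
from .errors import DatasetError, ModelError
from .svm import CvReport, SvmModel, predict, select_sigma_cv, train_svm

STRATEGIES = ("single", "combi", "2sbr")


@dataclass
class TwoStepModel:
    """Per-subtype (binding, selectivity) model pair plus decision rule.

    ``step2_rule`` controls how the composed per-subtype call combines
    the two steps: ``"and"`` (default; step-2 refines the step-1
    putative ligands), ``"or"``, or ``"step2_only"`` for ablation.
    """

    targets: list[str]
    binding: dict[str, SvmModel]
    selectivity: dict[str, SvmModel]
    descriptor_names: list[str]
    step2_rule: str = "and"
    cv_reports: dict[str, CvReport] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.binding) != sorted(self.targets) or sorted(self.selectivity) != sorted(self.targets):
            raise ModelError("binding/selectivity models must cover every target")


@dataclass
class HitMatrix:
    """Per-compound, per-subtype boolean calls with decision values."""

    compound_ids: list[str]
    targets: list[str]
    calls: np.ndarray  # n x T bool
    strategy: str
    step1_decisions: np.ndarray
    step2_decisions: np.ndarray | None = None

    def call_counts(self) -> np.ndarray:
        return self.calls.sum(axis=1)


@dataclass
class ScreenSummary:
    """Per-subtype selective-hit counts and virtual hit rates."""

    strategy: str
    library_size: int
    n_invalid: int
    selective_counts: dict[str, int]
    multi_count: int
    virtual_hit_rate: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "library_size": self.library_size,
            "n_invalid": self.n_invalid,
            "selective_counts": dict(self.selective_counts),
            "multi_count": self.multi_count,
            "virtual_hit_rate": dict(self.virtual_hit_rate),
        }


def train_two_step(
    records: list[CompoundRecord],
    descriptors: DescriptorMatrix,
    fingerprints: FingerprintMatrix,
    targets: list[str],
    background_ids: list[str] | None = None,
    C: float = 100000.0,
    sigma_grid: tuple[float, ...] = (0.4, 0.5, 0.6),
    cv_folds: int = 5,
    cv_metric: str = "mcc",
    family_threshold: float = 0.7,
    putative_max_per_family: int = 1,
    ligand_threshold: float = 1.0,
    nonligand_threshold: float = 10.0,
    scaling: str = "minmax",
    seed: int = 0,
    step2_rule: str = "and",
) -> TwoStepModel:
    """Train 2T models: a binding and a selectivity SVM per subtype.

    ``background_ids`` optionally restricts the putative-negative
    candidate pool to an explicit screening-background set.  By default
    the pool is every fingerprinted compound that is not a known ligand
    of *any* modeled subtype: putative non-ligands stand in for the
    inactive chemical space, so known actives of sister subtypes are
    never drafted into a binding model's negative class (their absence
    from the negatives is precisely what limits per-subtype binding
    models' selectivity).  Sigma is selected per task by stratified CV;
    the final model is retrained on the full task dataset at the
    selected sigma.
    """
    if len(targets) < 2:
        raise DatasetError("two-step training requires at least two targets")
    families = cluster_families(fingerprints, threshold=family_threshold)
    if background_ids is not None:
        candidate_pool = set(background_ids)
    else:
        any_ligand = {
            r.compound_id
            for r in records
            if any(
                r.ki(t) is not None and r.ki(t) < ligand_threshold for t in targets
            )
        }
        candidate_pool = set(fingerprints.compound_ids) - any_ligand
    binding: dict[str, SvmModel] = {}
    selectivity: dict[str, SvmModel] = {}
    reports: dict[str, CvReport] = {}
    for target in targets:
        ligand_ids = {
            r.compound_id
            for r in records
            if r.ki(target) is not None and r.ki(target) < ligand_threshold
        }
        if not ligand_ids:
            raise DatasetError(f"target {target!r} has no ligands")
        putative = generate_putative_negatives(families, ligand_ids, putative_max_per_family)
        putative = [c for c in putative if c in candidate_pool]
        ds1 = build_binding_dataset(
            target, records, descriptors, putative,
            ligand_threshold, nonligand_threshold, scaling,
        )
        rep1 = select_sigma_cv(ds1, sigma_grid, k=cv_folds, seed=seed, criterion=cv_metric, C=C)
        binding[target] = train_svm(ds1, C=C, sigma=rep1.selected_sigma)
        reports[f"binding:{target}"] = rep1

        ds2 = build_selectivity_dataset(target, records, targets, descriptors, ligand_threshold, scaling)
        rep2 = select_sigma_cv(ds2, sigma_grid, k=cv_folds, seed=seed, criterion=cv_metric, C=C)
        selectivity[target] = train_svm(ds2, C=C, sigma=rep2.selected_sigma)
        reports[f"selectivity:{target}"] = rep2
    config = {
        "C": C,
        "sigma_grid": list(sigma_grid),
        "cv_folds": cv_folds,
        "cv_metric": cv_metric,
        "family_threshold": family_threshold,
        "putative_max_per_family": putative_max_per_family,
        "ligand_threshold": ligand_threshold,
        "nonligand_threshold": nonligand_threshold,
        "scaling": scaling,
        "seed": seed,
    }
    return TwoStepModel(
        list(targets), binding, selectivity, list(descriptors.descriptor_names),
        step2_rule, reports, config,
    )


def predict_subtype_calls(
    model: TwoStepModel,
    X: DescriptorMatrix,
    strategy: str = "2sbr",
) -> HitMatrix:
    """Per-subtype positive calls for a descriptor matrix under a strategy."""
    if strategy not in STRATEGIES:
        raise ModelError(f"unknown strategy {strategy!r} (use one of {STRATEGIES})")
    n = X.n
    T = len(model.targets)
    step1 = np.zeros((n, T))
    step2 = np.zeros((n, T))
    calls = np.zeros((n, T), dtype=bool)
    for j, target in enumerate(model.targets):
        _, f1 = predict(model.binding[target], X.values, X.descriptor_names)
        step1[:, j] = f1
        if strategy == "2sbr":
            _, f2 = predict(model.selectivity[target], X.values, X.descriptor_names)
            step2[:, j] = f2
            if model.step2_rule == "and":
                calls[:, j] = (f1 >= 0) & (f2 >= 0)
            elif model.step2_rule == "or":
                calls[:, j] = (f1 >= 0) | (f2 >= 0)
            elif model.step2_rule == "step2_only":
                calls[:, j] = f2 >= 0
            else:
                raise ModelError(f"unknown step2 rule {model.step2_rule!r}")
        else:
            calls[:, j] = f1 >= 0
    return HitMatrix(
        list(X.compound_ids), list(model.targets), calls, strategy,
        step1, step2 if strategy == "2sbr" else None,
    )


def call_selective(hits: HitMatrix) -> list[tuple[str, object]]:
    """Classify each screened compound from its per-subtype calls.

    Returns one ``(kind, detail)`` per compound: ``("selective", target)``
    if exactly one subtype call is positive, ``("multi_subtype",
    frozenset_of_targets)`` if two or more, ``("none", None)`` otherwise.
    """
    out: list[tuple[str, object]] = []
    for row in hits.calls:
        positives = [t for t, c in zip(hits.targets, row) if c]
        if len(positives) == 1:
            out.append(("selective", positives[0]))
        elif positives:
            out.append(("multi_subtype", frozenset(positives)))
        else:
            out.append(("none", None))
    return out


def screen_library(
    model: TwoStepModel,
    library: DescriptorMatrix,
    strategy: str = "2sbr",
    batch_size: int = 1024,
    n_invalid: int = 0,
) -> tuple[ScreenSummary, pd.DataFrame]:
    """Stream a descriptor library through a strategy in batches.

    Per-subtype hit semantics mirror the three reference strategies:
    under ``single`` a hit is any step-1 positive for that subtype
    (putative ligand regardless of other subtypes); under ``combi`` and
    ``2sbr`` a hit is a *selective* call (exactly one subtype positive).
    The virtual hit rate per subtype is that count divided by the valid
    library size, so the two-step rate can never exceed the
    single-label rate.  ``n_invalid`` reports structures excluded
    upstream (they never enter the denominator).  Results are
    independent of ``batch_size``.
    """
    if library.n == 0:
        raise DatasetError("cannot screen an empty library")
    if batch_size < 1:
        raise DatasetError("batch_size must be >= 1")
    sel_counts = {t: 0 for t in model.targets}
    multi_count = 0
    hit_rows: list[dict] = []
    for start in range(0, library.n, batch_size):
        stop = min(start + batch_size, library.n)
        batch = DescriptorMatrix(
            library.compound_ids[start:stop],
            list(library.descriptor_names),
            library.values[start:stop],
        )
        hits = predict_subtype_calls(model, batch, strategy)
        outcomes = call_selective(hits)
        for i, (kind, detail) in enumerate(outcomes):
            if kind == "none":
                continue
            positives = (
                [detail] if kind == "selective" else sorted(detail)
            )
            if strategy == "single":
                # every step-1 positive counts as a putative ligand hit
                for t in positives:
                    sel_counts[t] += 1
            elif kind == "selective":
                sel_counts[detail] += 1
            if kind == "multi_subtype":
                multi_count += 1
            hit_rows.append(
                {
                    "compound_id": batch.compound_ids[i],
                    "subtype_call": "|".join(positives),
                    "kind": "putative_ligand" if strategy == "single" else kind,
                    **{
                        f"step1_{t}": hits.step1_decisions[i, j]
                        for j, t in enumerate(hits.targets)
                    },
                }
            )
    rates = {t: sel_counts[t] / library.n for t in model.targets}
    summary = ScreenSummary(strategy, library.n, n_invalid, sel_counts, multi_count, rates)
    columns = ["compound_id", "subtype_call", "kind"] + [f"step1_{t}" for t in model.targets]
    hits_df = pd.DataFrame(hit_rows, columns=columns)
    return summary, hits_df


def records_bound_subtypes(
    records: list[CompoundRecord], targets: list[str], ligand_threshold: float = 1.0
) -> dict[str, set[str]]:
    """Ground-truth bound-subtype sets from activity data (Ki < threshold)."""
    return {r.compound_id: label_multi_subtype(r, targets, ligand_threshold) for r in records}
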