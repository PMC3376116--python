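"""Synthetic multi-subtype ligand corpora with known ground truth.

The generator emulates the statistical structure of a curated
multi-subtype receptor ligand corpus in descriptor space (the screening
method operates entirely on descriptor vectors, so generating
descriptors directly keeps the ground truth exact).  Its central
organising unit is the *chemotype family*:

* Compounds come in families — tight clusters in descriptor space
  (family centre drawn once, members scattered around it with a small
  within-family spread).  Real ligand corpora are organised the same
  way, and test ligands overwhelmingly fall inside training chemotypes.
* Each ligand family is associated with a subtype subset S — the
  subtypes its scaffold can bind.  Single-subtype families carry plain
  ligands; shared families (|S| >= 2) carry a mixture of true
  multi-subtype binders and subtype-selective members whose small
  structural changes abolish binding to the other subtypes.  Shared
  chemotypes are what make per-subtype binding models cross-react —
  the phenomenon the two-step method exists to fix.
* Each compound has a latent *bound set* B ⊆ S — the subtypes it truly
  binds.  Training ligands are annotated with a single measured Ki
  ("unspecified selectivity toward other subtypes"), so a training
  ligand of one subtype may secretly bind another, exactly like the
  multi-subtype noise groups retained in real training corpora.

Descriptor dimensions:

* binding-informative dims (``d_shared`` per subtype): family-level;
  +delta for subtypes in the family's S, ``cross_reactivity * delta``
  for the rest of a ligand family, 0 for background families;
* selectivity-informative dims (``d_select`` per subtype):
  compound-level; +delta for subtypes in B, -delta for other subtypes
  (ligand compounds only) — the fine signal that only
  ligand-vs-other-ligand training exposes;
* noise dims: mean 0.

All dims receive the family-centre jitter (sd 1) plus member noise
(``within_family_spread``); ``delta`` is an effect size in units of the
family-centre spread.

Ki values are drawn consistently with the latent truth: ligands
log-uniform in [0.01, 0.9] uM, non-ligands in [11, 100] uM, selective
pairs enforce a >= 10-fold Ki ratio, and multi-subtype compounds have
Ki < 1 uM on every bound subtype.

Fingerprints are block-structured and aligned with the same families:
each family shares a 40-bit signature with small per-member
perturbations, so leader clustering at the default 0.7 Tanimoto
threshold recovers the planted families and putative-negative
generation is exactly checkable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import CompoundRecord, DescriptorMatrix, FingerprintMatrix
from .datasets import LabeledDataset
from .errors import DatasetError
from .features import FINGERPRINT_BITS, apply_scaler, fit_scaler


@dataclass
class SyntheticSpec:
    """Study conditions for a generated corpus."""

    n_subtypes: int = 4
    n_ligand: int = 200  # training ligands per subtype
    n_selective: int = 40  # test ligands per ordered subtype pair
    n_multi: int = 40  # test ligands per tested subtype subset
    n_background: int = 2000
    n_families: int = 400  # background families
    n_known_nonligand: int = 50  # per subtype
    d_shared: int = 2  # binding-informative dims per subtype
    d_select: int = 1  # selectivity-informative dims per subtype
    d_noise: int = 4
    delta: float = 1.5  # effect size in family-centre sd units
    cross_reactivity: float = 0.9  # binding-dim shift outside a ligand family's S
    # fraction of each subtype's training ligands drawn from shared
    # (multi-subtype) chemotype families: half known multi-subtype
    # binders (measured on every chemotype subtype), half cryptic
    # selective siblings with a single Ki.  Real corpora retain
    # multi-subtype groups at comparable rates (roughly half the
    # training ligands of the closely related subtypes).
    hidden_multi_fraction: float = 0.5
    ligand_family_size: int = 5
    within_family_spread: float = 0.3
    multi_subsets: tuple[tuple[int, ...], ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise DatasetError("need at least two subtypes")
        if self.delta <= 0:
            raise DatasetError("delta must be positive")
        if not 0 <= self.cross_reactivity <= 1:
            raise DatasetError("cross_reactivity must be in [0, 1]")
        if not 0 <= self.hidden_multi_fraction <= 1:
            raise DatasetError("hidden_multi_fraction must be in [0, 1]")
        if self.ligand_family_size < 1:
            raise DatasetError("ligand_family_size must be >= 1")
        if self.within_family_spread <= 0:
            raise DatasetError("within_family_spread must be positive")
        for name in (
            "n_ligand",
            "n_selective",
            "n_multi",
            "n_background",
            "n_families",
            "n_known_nonligand",
            "d_shared",
            "d_select",
            "d_noise",
        ):
            if getattr(self, name) < 0:
                raise DatasetError(f"{name} must be >= 0")
        if self.n_background > 0 and self.n_families == 0:
            raise DatasetError("background compounds require families")
        for subset in self.multi_subsets or ():
            if len(subset) < 2 or len(set(subset)) != len(subset):
                raise DatasetError(f"invalid multi subset {subset}")
            if any(not 0 <= t < self.n_subtypes for t in subset):
                raise DatasetError(f"multi subset {subset} names unknown subtypes")

    @property
    def targets(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_subtypes)]

    def tested_multi_subsets(self) -> tuple[tuple[int, ...], ...]:
        if self.multi_subsets is not None:
            return tuple(tuple(sorted(s)) for s in self.multi_subsets)
        t = self.n_subtypes
        if t == 2:
            return ((0, 1),)
        if t == 3:
            return ((0, 1), (1, 2), (0, 1, 2))
        # dual, dual, triple, quadruple — the canonical test panel
        return ((0, 1), (2, 3), (0, 1, 2), tuple(range(4)))


@dataclass
class SyntheticCorpus:
    """Generated corpus plus exact ground-truth tables."""

    spec: SyntheticSpec
    records: list[CompoundRecord]
    descriptors: DescriptorMatrix
    fingerprints: FingerprintMatrix
    truth: pd.DataFrame  # compound_id, role, subtypes (true bound set), family_id
    targets: list[str] = field(default_factory=list)

    def ids_with_role(self, role: str) -> list[str]:
        return self.truth.loc[self.truth["role"] == role, "compound_id"].tolist()

    def selective_ids(self, a: str, b: str) -> list[str]:
        mask = (
            (self.truth["role"] == "selective")
            & (self.truth["first_subtype"] == a)
            & (self.truth["second_subtype"] == b)
        )
        return self.truth.loc[mask, "compound_id"].tolist()

    def multi_ids(self, subtypes: tuple[str, ...]) -> list[str]:
        key = "|".join(subtypes)
        mask = (self.truth["role"] == "multi") & (self.truth["subtypes"] == key)
        return self.truth.loc[mask, "compound_id"].tolist()

    @property
    def training_records(self) -> list[CompoundRecord]:
        """Records entering model training: annotated ligands and known
        non-ligands.  Selective and multi-subtype test compounds stay
        out."""
        keep = set(
            self.truth.loc[
                self.truth["role"].isin(("ligand", "non_ligand")), "compound_id"
            ]
        )
        return [r for r in self.records if r.compound_id in keep]


def _descriptor_names(spec: SyntheticSpec) -> list[str]:
    names = []
    for t in spec.targets:
        names.extend(f"bind_{t}_{k}" for k in range(spec.d_shared))
    for t in spec.targets:
        names.extend(f"sel_{t}_{k}" for k in range(spec.d_select))
    names.extend(f"noise_{k}" for k in range(spec.d_noise))
    return names


def _profile_mean(spec: SyntheticSpec, family_subset: set[int], bound: set[int]) -> np.ndarray:
    """Family-level binding shifts plus compound-level selectivity shifts."""
    d = spec.n_subtypes * (spec.d_shared + spec.d_select) + spec.d_noise
    mu = np.zeros(d)
    pos = 0
    if family_subset:
        for t in range(spec.n_subtypes):
            shift = spec.delta if t in family_subset else spec.cross_reactivity * spec.delta
            mu[pos : pos + spec.d_shared] = shift
            pos += spec.d_shared
    else:
        pos += spec.n_subtypes * spec.d_shared
    if bound:
        for t in range(spec.n_subtypes):
            shift = spec.delta if t in bound else -spec.delta
            mu[pos : pos + spec.d_select] = shift
            pos += spec.d_select
    return mu


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _family_fingerprint(rng: np.random.Generator, signature: np.ndarray, n_flip: int = 2) -> np.ndarray:
    bits = signature.copy()
    on = np.nonzero(bits)[0]
    off = np.nonzero(bits == 0)[0]
    drop = rng.choice(on, size=min(n_flip, len(on)), replace=False)
    add = rng.choice(off, size=min(n_flip, len(off)), replace=False)
    bits[drop] = 0
    bits[add] = 1
    return bits


class _FamilyPool:
    """Allocates family ids within a chemotype class round-robin."""

    def __init__(self, label: str, n_members: int, family_size: int):
        self.label = label
        self.n_fam = max(1, -(-n_members // family_size)) if n_members else 0
        self._next = 0

    def take(self) -> tuple[str, int]:
        fam = self._next % self.n_fam
        self._next += 1
        return (self.label, fam)


def generate_corpus(spec: SyntheticSpec | None = None) -> SyntheticCorpus:
    """Generate a corpus with exact ground truth; deterministic per seed."""
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    targets = spec.targets
    T = spec.n_subtypes
    names = _descriptor_names(spec)
    d = len(names)

    # ------------------------------------------------------------------
    # plan chemotype classes and their member counts
    pairs = [tuple(p) for p in itertools.combinations(range(T), 2)]
    tested = list(spec.tested_multi_subsets())
    shared_subsets = sorted(set(pairs) | set(tested))
    # hidden (shared-chemotype) training ligands of subtype t, split
    # equally over the shared subsets containing t
    n_hidden = int(round(spec.hidden_multi_fraction * spec.n_ligand))
    hidden_alloc: dict[tuple[int, ...], dict[int, int]] = {s: {} for s in shared_subsets}
    for t in range(T):
        subsets_t = [s for s in shared_subsets if t in s]
        base, rem = divmod(n_hidden, len(subsets_t)) if subsets_t else (0, 0)
        for k, s in enumerate(subsets_t):
            hidden_alloc[s][t] = base + (1 if k < rem else 0)

    pools: dict[object, _FamilyPool] = {}
    for t in range(T):
        n_plain = spec.n_ligand - n_hidden
        pools[("single", t)] = _FamilyPool(f"single_{t}", n_plain, spec.ligand_family_size)
    for s in shared_subsets:
        n_members = sum(hidden_alloc[s].values())
        if len(s) == 2:
            n_members += 2 * spec.n_selective  # both ordered directions
        if s in tested:
            n_members += spec.n_multi
        pools[("shared", s)] = _FamilyPool(
            "shared_" + "".join(targets[t] for t in s), n_members, spec.ligand_family_size
        )

    # ------------------------------------------------------------------
    # emit compounds
    ids: list[str] = []
    mean_rows: list[np.ndarray] = []
    rows: list[dict] = []
    records: list[CompoundRecord] = []
    fam_keys: list[tuple] = []
    centre_dims: list[tuple] = []  # family key per compound (same as fam_keys)

    def add(cid, family_subset, bound, role, activities, fam_key, extra=None):
        ids.append(cid)
        mean_rows.append(_profile_mean(spec, family_subset, bound))
        records.append(CompoundRecord(cid, activities=activities))
        row = {
            "compound_id": cid,
            "role": role,
            "subtypes": "|".join(targets[t] for t in sorted(bound)),
            "first_subtype": "",
            "second_subtype": "",
        }
        if extra:
            row.update(extra)
        rows.append(row)
        fam_keys.append(fam_key)

    # training ligands of each subtype: plain members of single-subtype
    # families, plus shared-chemotype members (half true multi-subtype
    # binders, half selective chemotype siblings), all with one Ki
    for t in range(T):
        n_plain = spec.n_ligand - n_hidden
        kis = _log_uniform(rng, 0.01, 0.9, spec.n_ligand)
        j = 0
        for _ in range(n_plain):
            add(
                f"lig_{targets[t]}_{j:04d}",
                {t},
                {t},
                "ligand",
                {targets[t]: float(kis[j])},
                pools[("single", t)].take(),
            )
            j += 1
        for s in shared_subsets:
            for k in range(hidden_alloc[s].get(t, 0)):
                if k % 2 == 0:
                    # known multi-subtype binder: measured sub-uM on every
                    # subtype of the chemotype (a retained noise group)
                    bound = set(s)
                    acts = {
                        targets[u]: float(_log_uniform(rng, 0.01, 0.9)) for u in s
                    }
                else:
                    # cryptic selective sibling: binds t only, single Ki
                    bound = {t}
                    acts = {targets[t]: float(kis[j])}
                add(
                    f"lig_{targets[t]}_{j:04d}",
                    set(s),
                    bound,
                    "ligand",
                    acts,
                    pools[("shared", s)].take(),
                )
                j += 1

    # selective test ligands: members of the shared {a, b} chemotype
    # that truly bind only a; measured on both subtypes
    for a, b in itertools.permutations(range(T), 2):
        s = tuple(sorted((a, b)))
        ki_b = _log_uniform(rng, 11.0, 1000.0, spec.n_selective)
        for j in range(spec.n_selective):
            hi = min(0.9, ki_b[j] / 10.0)
            ki_a = float(_log_uniform(rng, 0.01, hi))
            add(
                f"sel_{targets[a]}_{targets[b]}_{j:04d}",
                set(s),
                {a},
                "selective",
                {targets[a]: ki_a, targets[b]: float(ki_b[j])},
                pools[("shared", s)].take(),
                {"first_subtype": targets[a], "second_subtype": targets[b]},
            )

    # multi-subtype test ligands: members of the shared chemotype that
    # bind every subtype of the subset
    for s in tested:
        kis = _log_uniform(rng, 0.01, 0.9, (spec.n_multi, len(s)))
        for j in range(spec.n_multi):
            acts = {targets[t]: float(kis[j, i]) for i, t in enumerate(s)}
            add(
                f"multi_{''.join(targets[t] for t in s)}_{j:04d}",
                set(s),
                set(s),
                "multi",
                acts,
                pools[("shared", s)].take(),
            )

    # known non-ligands: background chemotypes, measured inactive
    for t in range(T):
        kis = _log_uniform(rng, 11.0, 100.0, spec.n_known_nonligand)
        for j in range(spec.n_known_nonligand):
            fam = int(rng.integers(spec.n_families)) if spec.n_families else 0
            add(
                f"nonlig_{targets[t]}_{j:04d}",
                set(),
                set(),
                "non_ligand",
                {targets[t]: float(kis[j])},
                ("bg", fam),
            )

    # background screening library
    for j in range(spec.n_background):
        add(f"bg_{j:05d}", set(), set(), "background", {}, ("bg", j % spec.n_families))

    # ------------------------------------------------------------------
    # descriptors: profile mean + family-centre jitter + member noise
    n = len(ids)
    unique_keys = sorted(set(fam_keys), key=repr)
    centres = {key: rng.standard_normal(d) for key in unique_keys}
    X = np.empty((n, d))
    for i, key in enumerate(fam_keys):
        X[i] = (
            mean_rows[i]
            + centres[key]
            + spec.within_family_spread * rng.standard_normal(d)
        )
    descriptors = DescriptorMatrix(ids, names, X)

    # fingerprints: block structure aligned with the same families
    signatures: dict[tuple, np.ndarray] = {}
    for key in unique_keys:
        sig = np.zeros(FINGERPRINT_BITS, dtype=np.uint8)
        sig[rng.choice(FINGERPRINT_BITS, size=40, replace=False)] = 1
        signatures[key] = sig
    bits = np.zeros((n, FINGERPRINT_BITS), dtype=np.uint8)
    for i, key in enumerate(fam_keys):
        bits[i] = _family_fingerprint(rng, signatures[key])
    fingerprints = FingerprintMatrix(ids, [f"bit_{j}" for j in range(FINGERPRINT_BITS)], bits)

    key_index = {key: i for i, key in enumerate(unique_keys)}
    truth = pd.DataFrame(rows)
    truth["family_id"] = [key_index[k] for k in fam_keys]
    return SyntheticCorpus(spec, records, descriptors, fingerprints, truth, targets)


def make_feature_selection_instance(
    n_per_class: int = 100,
    d_informative: int = 5,
    d_total: int = 30,
    delta: float = 1.5,
    seed: int = 0,
    scaling: str = "minmax",
) -> LabeledDataset:
    """A planted-feature selectivity task for feature-ranking studies.

    The informative dimensions (named ``inf_*``) separate the classes
    at +/- delta; the remaining ``noise_*`` dimensions are pure noise.
    Mirrors a step-2 selectivity dataset: ligands of one subtype versus
    ligands of the others.
    """
    if d_informative > d_total:
        raise DatasetError("d_informative cannot exceed d_total")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, d_total))
    y = np.concatenate([np.ones(n_per_class, dtype=int), -np.ones(n_per_class, dtype=int)])
    X[:n_per_class, :d_informative] += delta
    X[n_per_class:, :d_informative] -= delta
    names = [f"inf_{i}" for i in range(d_informative)] + [
        f"noise_{i}" for i in range(d_total - d_informative)
    ]
    scaler = fit_scaler(X, method=scaling, descriptor_names=names)
    Xs = apply_scaler(scaler, X)
    ids = [f"c{i:04d}" for i in range(n)]
    return LabeledDataset(Xs, y, ids, "selectivity:planted", names, scaler)


# ~30 drug-like structures (common CNS-active and reference drugs) with
# synthetic Ki annotations covering every labeling case: ligands,
# non-ligands, the 1-10 uM indeterminate gap, a >= 10-fold selective
# pair, and multi-subtype binders.  The Ki values are invented fixture
# data, not measurements.
_FIXTURE_ROWS: list[tuple[str, str, float | None, float | None]] = [
    # (id, smiles, Ki_S1 uM, Ki_S2 uM)
    ("fx_dopamine", "NCCc1ccc(O)c(O)c1", 0.5, 0.6),
    ("fx_serotonin", "NCCc1c[nH]c2ccc(O)cc12", 0.8, 0.05),
    ("fx_haloperidol", "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1", 0.02, 0.4),
    ("fx_clozapine", "CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1", 0.09, 0.11),
    ("fx_quetiapine", "OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1", 0.3, None),
    ("fx_risperidone", "CC1=C(CCN2CCC(c3noc4cc(F)ccc34)CC2)C(=O)N2CCCCC2=N1", 0.05, 0.9),
    ("fx_aripiprazole", "O=C1CCc2ccc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)cc2N1", 0.04, 0.5),
    ("fx_sulpiride", "CCN1CCCC1CNC(=O)c1cc(S(N)(=O)=O)ccc1OC", 0.06, 45.0),
    ("fx_amisulpride", "CCN1CCCC1CNC(=O)c1cc(S(=O)(=O)CC)c(N)cc1OC", 0.03, 30.0),
    ("fx_spiperone", "O=C(CCCN1CCC2(CC1)C(=O)NCN2c1ccccc1)c1ccc(F)cc1", 0.01, 0.2),
    ("fx_apomorphine", "CN1CCc2cccc3c2C1Cc1ccc(O)c(O)c1-3", 0.7, 0.08),
    ("fx_pramipexole", "CCCNC1CCc2nc(N)sc2C1", 0.4, 0.009),
    ("fx_ropinirole", "CCCN(CCC)CCc1cccc2c1CC(=O)N2", 0.6, 0.03),
    ("fx_bromocriptine_frag", "CC(C)CC1NC(=O)C2CCCN2C1=O", 2.5, None),
    ("fx_caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O", 50.0, 80.0),
    ("fx_theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O", 90.0, None),
    ("fx_aspirin", "CC(=O)Oc1ccccc1C(=O)O", None, 60.0),
    ("fx_ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1", 70.0, 95.0),
    ("fx_paracetamol", "CC(=O)Nc1ccc(O)cc1", 40.0, 55.0),
    ("fx_naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1", 85.0, None),
    ("fx_amantadine", "NC12CC3CC(CC(C3)C1)C2", 5.0, 12.0),
    ("fx_memantine", "CC12CC3CC(C)(CC(N)(C3)C1)C2", 3.0, 8.0),
    ("fx_benzamide", "NC(=O)c1ccccc1", 8.0, 20.0),
    ("fx_phenylpiperazine", "c1ccc(N2CCNCC2)cc1", 6.0, 2.0),
    ("fx_quinpirole", "CCCN1CCCC2Cc3[nH]ncc3CC21", 0.07, None),
    ("fx_raclopride", "CCN1CCCC1CNC(=O)c1cc(Cl)c(O)c(Cl)c1OC", 0.005, 0.09),
    ("fx_domperidone", "O=C1Nc2ccccc2N1CCCN1CCC(n2c(=O)[nH]c3cc(Cl)ccc32)CC1", 0.03, None),
    ("fx_fluphenazine", "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(C(F)(F)F)cc32)CC1", 0.008, 0.1),
    ("fx_chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21", 0.09, 0.02),
    ("fx_tetrabenazine", "COc1cc2c(cc1OC)C1CC(CC(C)C)C(=O)CN1CC2", 15.0, 25.0),
]


def fixture_smiles() -> list[CompoundRecord]:
    """~30 embedded drug-like compounds with synthetic Ki annotations.

    Parseable by the default descriptor provider; spans ligands, the
    1-10 uM gap, non-ligands, a >= 10-fold selective pair (e.g.
    fx_sulpiride: 0.06 vs 45 uM), and multi-subtype binders.
    """
    return [
        CompoundRecord(
            cid,
            smiles,
            {t: ki for t, ki in (("S1", ki1), ("S2", ki2)) if ki is not None},
        )
        for cid, smiles, ki1, ki2 in _FIXTURE_ROWS
    ]
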