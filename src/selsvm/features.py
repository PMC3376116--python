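"""Descriptor and fingerprint providers, plus train-set-fitted scaling.

The default descriptor provider computes a fixed, ordered panel of 2D
physicochemical, topological, and E-state descriptors with RDKit —
comparable in size and character to the descriptor panels typically
used for SVM screening models.  Descriptor names and the provider
version are recorded so a model bundle can refuse mismatched inputs.

Scaling is fitted on training data only and applied to everything
downstream.  The default is min-max to [0, 1] (the classical
``svm-scale`` convention): with an RBF kernel at widths sigma ~ 0.5 the
squared distances must stay of order one, which bounded feature ranges
guarantee and per-column unit-variance scaling does not.  Z-score
scaling is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.EState import EState_VSA

from .chem_io import CompoundRecord, DescriptorMatrix, FingerprintMatrix
from .errors import SchemaError

PROVIDER_VERSION = "rdkit2d-1"
FINGERPRINT_BITS = 882  # 882-bit convention for Tanimoto similarity profiling


def _descriptor_panel() -> list[tuple[str, object]]:
    panel = [
        ("MolWt", Descriptors.MolWt),
        ("MolLogP", Crippen.MolLogP),
        ("MolMR", Crippen.MolMR),
        ("TPSA", rdMolDescriptors.CalcTPSA),
        ("NumHAcceptors", Lipinski.NumHAcceptors),
        ("NumHDonors", Lipinski.NumHDonors),
        ("NumRotatableBonds", Lipinski.NumRotatableBonds),
        ("NumAromaticRings", rdMolDescriptors.CalcNumAromaticRings),
        ("NumAliphaticRings", rdMolDescriptors.CalcNumAliphaticRings),
        ("NumSaturatedRings", rdMolDescriptors.CalcNumSaturatedRings),
        ("RingCount", Descriptors.RingCount),
        ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
        ("HeavyAtomCount", Descriptors.HeavyAtomCount),
        ("NumHeteroatoms", Descriptors.NumHeteroatoms),
        ("NumOAtoms", lambda m: sum(1 for a in m.GetAtoms() if a.GetSymbol() == "O")),
        ("NumNAtoms", lambda m: sum(1 for a in m.GetAtoms() if a.GetSymbol() == "N")),
        ("NumSAtoms", lambda m: sum(1 for a in m.GetAtoms() if a.GetSymbol() == "S")),
        ("NumHalogen", lambda m: sum(1 for a in m.GetAtoms() if a.GetSymbol() in ("F", "Cl", "Br", "I"))),
        ("BalabanJ", GraphDescriptors.BalabanJ),
        ("BertzCT", GraphDescriptors.BertzCT),
        ("Chi0v", GraphDescriptors.Chi0v),
        ("Chi1v", GraphDescriptors.Chi1v),
        ("Chi2v", GraphDescriptors.Chi2v),
        ("Chi3v", GraphDescriptors.Chi3v),
        ("Chi4v", GraphDescriptors.Chi4v),
        ("Kappa1", GraphDescriptors.Kappa1),
        ("Kappa2", GraphDescriptors.Kappa2),
        ("Kappa3", GraphDescriptors.Kappa3),
        ("HallKierAlpha", GraphDescriptors.HallKierAlpha),
        ("MaxEStateIndex", Descriptors.MaxEStateIndex),
        ("MinEStateIndex", Descriptors.MinEStateIndex),
        ("MaxAbsEStateIndex", Descriptors.MaxAbsEStateIndex),
        ("LabuteASA", rdMolDescriptors.CalcLabuteASA),
        ("NumAmideBonds", rdMolDescriptors.CalcNumAmideBonds),
        ("NumSpiroAtoms", rdMolDescriptors.CalcNumSpiroAtoms),
        ("NumBridgeheadAtoms", rdMolDescriptors.CalcNumBridgeheadAtoms),
    ]
    for i in range(1, 11):
        name = f"EState_VSA{i}"
        panel.append((name, getattr(EState_VSA, name)))
    return panel


_PANEL = _descriptor_panel()
DESCRIPTOR_NAMES = [name for name, _ in _PANEL]


@dataclass
class ProviderConfig:
    """Descriptor/fingerprint provider selection.

    ``provider`` is ``"rdkit2d"`` / ``"rdkit_morgan"`` (structure-based)
    or ``"precomputed"`` with ``path`` pointing at a CSV whose first
    column is ``compound_id``.
    """

    provider: str = "rdkit2d"
    path: str | None = None
    morgan_radius: int = 2
    n_bits: int = FINGERPRINT_BITS


def _mols(compounds: list[CompoundRecord]) -> tuple[list[str], list[Chem.Mol], list[str]]:
    ids, mols, failed = [], [], []
    for rec in compounds:
        mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        if mol is None:
            failed.append(rec.compound_id)
        else:
            ids.append(rec.compound_id)
            mols.append(mol)
    return ids, mols, failed


def _read_precomputed(path: str, ids: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    missing = [c for c in ids if c not in df.index]
    if missing:
        raise SchemaError(f"precomputed matrix missing compounds: {missing[:10]}")
    return df.loc[ids]


def compute_descriptors(
    compounds: list[CompoundRecord], provider_config: ProviderConfig | None = None
) -> tuple[DescriptorMatrix, list[str]]:
    """Compute (or load) the descriptor matrix for ``compounds``.

    Returns the matrix plus the list of compound ids whose descriptor
    computation failed; those compounds are excluded, never imputed.
    """
    cfg = provider_config or ProviderConfig()
    if cfg.provider == "precomputed":
        if not cfg.path:
            raise SchemaError("precomputed provider requires a path")
        ids = [r.compound_id for r in compounds]
        df = _read_precomputed(cfg.path, ids)
        return DescriptorMatrix(ids, [str(c) for c in df.columns], df.to_numpy(dtype=float)), []
    if cfg.provider != "rdkit2d":
        raise SchemaError(f"unknown descriptor provider {cfg.provider!r}")
    ids, mols, failed = _mols(compounds)
    values = np.empty((len(mols), len(_PANEL)), dtype=float)
    keep = []
    for i, mol in enumerate(mols):
        try:
            values[i] = [fn(mol) for _, fn in _PANEL]
            if not np.isfinite(values[i]).all():
                raise ValueError("non-finite descriptor")
            keep.append(i)
        except Exception:
            failed.append(ids[i])
    keep_idx = np.asarray(keep, dtype=int)
    kept_ids = [ids[i] for i in keep]
    return DescriptorMatrix(kept_ids, list(DESCRIPTOR_NAMES), values[keep_idx]), failed


def compute_fingerprints(
    compounds: list[CompoundRecord], provider_config: ProviderConfig | None = None
) -> tuple[FingerprintMatrix, list[str]]:
    """Compute (or load) the binary fingerprint matrix for ``compounds``."""
    cfg = provider_config or ProviderConfig(provider="rdkit_morgan")
    if cfg.provider == "precomputed":
        if not cfg.path:
            raise SchemaError("precomputed provider requires a path")
        ids = [r.compound_id for r in compounds]
        df = _read_precomputed(cfg.path, ids)
        return FingerprintMatrix(ids, [str(c) for c in df.columns], df.to_numpy(dtype=np.uint8)), []
    if cfg.provider not in ("rdkit_morgan", "rdkit2d"):
        raise SchemaError(f"unknown fingerprint provider {cfg.provider!r}")
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.morgan_radius, fpSize=cfg.n_bits)
    ids, mols, failed = _mols(compounds)
    bits = np.zeros((len(mols), cfg.n_bits), dtype=np.uint8)
    for i, mol in enumerate(mols):
        fp = gen.GetFingerprint(mol)
        bits[i, list(fp.GetOnBits())] = 1
    names = [f"bit_{j}" for j in range(cfg.n_bits)]
    return FingerprintMatrix(ids, names, bits), failed


@dataclass
class ScalerParams:
    """Per-descriptor location/spread fitted on a training matrix.

    ``method`` is ``"minmax"`` (location = column minimum, spread =
    range) or ``"zscore"`` (mean, standard deviation).  Constant columns
    get spread 1 and are flagged, so they map to exactly 0.
    """

    method: str
    descriptor_names: list[str]
    location: np.ndarray
    spread: np.ndarray
    constant_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if np.any(self.spread <= 0):
            raise SchemaError("scaler spread values must be positive")


def fit_scaler(train: DescriptorMatrix | np.ndarray, method: str = "minmax",
               descriptor_names: list[str] | None = None) -> ScalerParams:
    """Fit scaling statistics on a training matrix (and only there)."""
    if isinstance(train, DescriptorMatrix):
        X = train.values
        names = list(train.descriptor_names)
    else:
        X = np.asarray(train, dtype=float)
        names = descriptor_names or [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] == 0:
        raise SchemaError("cannot fit a scaler on an empty matrix")
    if method == "zscore":
        loc = X.mean(axis=0)
        spread = X.std(axis=0, ddof=0)
    elif method == "minmax":
        loc = X.min(axis=0)
        spread = X.max(axis=0) - loc
    else:
        raise SchemaError(f"unknown scaling method {method!r}")
    const = spread <= 0
    spread = np.where(const, 1.0, spread)
    return ScalerParams(method, names, loc, spread, [names[i] for i in np.nonzero(const)[0]])


def apply_scaler(params: ScalerParams, X: DescriptorMatrix | np.ndarray) -> np.ndarray:
    """Apply fitted scaling; fails on dimension mismatch."""
    if isinstance(X, DescriptorMatrix):
        if list(X.descriptor_names) != list(params.descriptor_names):
            raise SchemaError("descriptor names do not match scaler")
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.location.shape[0]:
        raise SchemaError(
            f"matrix with {X.shape[-1] if X.ndim else 0} columns does not match "
            f"scaler of dimension {params.location.shape[0]}"
        )
    return (X - params.location) / params.spread
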