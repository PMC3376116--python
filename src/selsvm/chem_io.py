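"""Compound, activity-table, matrix, and model I/O.

Activity tables are CSV files with one row per compound:
``compound_id,smiles,<target>_ki_um,...``.  An empty Ki cell means the
compound was not tested against that target.  Binding affinities are
held internally in micromolar (uM); nanomolar input is converted on
read via the schema.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import ModelError, SchemaError

RDLogger.DisableLog("rdApp.*")

_FORMAT_VERSION = "selsvm-bundle-1"

_KI_COL_RE = re.compile(r"^(?P<target>.+)_ki_(?P<unit>um|nm)$", re.IGNORECASE)

_UNIT_TO_UM = {"um": 1.0, "nm": 1e-3}


@dataclass
class CompoundRecord:
    """One compound: identifier, optional structure, per-target Ki map (uM)."""

    compound_id: str
    smiles: str | None = None
    activities: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def ki(self, target: str) -> float | None:
        return self.activities.get(target)


@dataclass
class DescriptorMatrix:
    """Real-valued n x d descriptor block aligned to compound ids."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise SchemaError(
                f"descriptor matrix shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} ids x {len(self.descriptor_names)} names"
            )

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    def index_of(self, ids: list[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise SchemaError(f"compounds missing from matrix: {missing[:10]}")
        return np.asarray([pos[c] for c in ids], dtype=int)

    def subset(self, ids: list[str]) -> "DescriptorMatrix":
        idx = self.index_of(ids)
        return DescriptorMatrix(list(ids), list(self.descriptor_names), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "compound_id", self.compound_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        ids = df.iloc[:, 0].astype(str).tolist()
        names = [str(c) for c in df.columns[1:]]
        return cls(ids, names, df.iloc[:, 1:].to_numpy(dtype=float))


@dataclass
class FingerprintMatrix:
    """Binary n x l fingerprint block (entries in {0, 1})."""

    compound_ids: list[str]
    bit_names: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.compound_ids), len(self.bit_names)):
            raise SchemaError("fingerprint matrix shape mismatch")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise SchemaError("fingerprint entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    def index_of(self, ids: list[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise SchemaError(f"compounds missing from fingerprints: {missing[:10]}")
        return np.asarray([pos[c] for c in ids], dtype=int)

    def subset(self, ids: list[str]) -> "FingerprintMatrix":
        idx = self.index_of(ids)
        return FingerprintMatrix(list(ids), list(self.bit_names), self.bits[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bits.astype(int), columns=self.bit_names)
        df.insert(0, "compound_id", self.compound_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FingerprintMatrix":
        ids = df.iloc[:, 0].astype(str).tolist()
        names = [str(c) for c in df.columns[1:]]
        return cls(ids, names, df.iloc[:, 1:].to_numpy(dtype=np.uint8))


@dataclass
class ActivitySchema:
    """Column mapping for activity CSV files.

    ``target_cols`` maps target id -> column name.  When ``None`` the
    targets are auto-detected from columns named ``<target>_ki_um`` or
    ``<target>_ki_nm`` (the suffix fixes the unit per column,
    overriding ``unit``).

    ``on_duplicate`` controls rows sharing a compound_id: ``"error"``
    (default, duplicate ids are rejected) or one of
    ``{"geometric_mean", "mean", "min", "max"}`` to merge the per-target
    Ki values of the duplicate assay records.
    """

    id_col: str = "compound_id"
    smiles_col: str | None = "smiles"
    target_cols: dict[str, str] | None = None
    unit: str = "um"
    on_duplicate: str = "error"


def _merge_kis(values: list[float], how: str) -> float:
    arr = np.asarray(values, dtype=float)
    if how == "geometric_mean":
        return float(np.exp(np.mean(np.log(arr))))
    if how == "mean":
        return float(arr.mean())
    if how == "min":
        return float(arr.min())
    if how == "max":
        return float(arr.max())
    raise SchemaError(f"unknown duplicate policy {how!r}")


def _detect_target_cols(columns: list[str], schema: ActivitySchema) -> dict[str, tuple[str, float]]:
    """Return target -> (column, factor-to-uM)."""
    out: dict[str, tuple[str, float]] = {}
    if schema.target_cols is not None:
        unit = schema.unit.lower()
        if unit not in _UNIT_TO_UM:
            raise SchemaError(f"unknown Ki unit {schema.unit!r}")
        for target, col in schema.target_cols.items():
            if col not in columns:
                raise SchemaError(f"activity column {col!r} not in table")
            out[str(target)] = (col, _UNIT_TO_UM[unit])
        return out
    for col in columns:
        m = _KI_COL_RE.match(str(col))
        if m:
            out[m.group("target")] = (col, _UNIT_TO_UM[m.group("unit").lower()])
    if not out:
        raise SchemaError("no Ki columns found (expected '<target>_ki_um' or '<target>_ki_nm')")
    return out


def read_activity_table(path: str | Path, schema: ActivitySchema | None = None) -> list[CompoundRecord]:
    """Read an activity CSV into compound records.

    Blank Ki cells become absent activities.  Unparsable SMILES emit a
    per-row warning and flag the record (it is kept, not dropped).
    Duplicate compound ids raise unless the schema selects a merge
    policy; non-positive Ki values always raise.
    """
    schema = schema or ActivitySchema()
    df = pd.read_csv(path, dtype=str)
    if schema.id_col not in df.columns:
        raise SchemaError(f"id column {schema.id_col!r} not in table")
    targets = _detect_target_cols(list(df.columns), schema)

    rows: dict[str, list[CompoundRecord]] = {}
    for i, row in df.iterrows():
        cid = str(row[schema.id_col])
        smiles = None
        if schema.smiles_col and schema.smiles_col in df.columns:
            raw = row[schema.smiles_col]
            if isinstance(raw, str) and raw.strip():
                smiles = raw.strip()
        rec = CompoundRecord(cid, smiles)
        if smiles is not None and Chem.MolFromSmiles(smiles) is None:
            warnings.warn(f"row {i}: unparsable SMILES for compound {cid!r}", stacklevel=2)
            rec.flags.append("invalid_smiles")
        for target, (col, factor) in targets.items():
            cell = row[col]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                continue
            try:
                ki = float(cell) * factor
            except ValueError as exc:
                raise SchemaError(f"row {i}: non-numeric Ki {cell!r} for {target}") from exc
            if not ki > 0:
                raise SchemaError(f"row {i}: non-positive Ki {ki} for {target}")
            rec.activities[target] = ki
        rows.setdefault(cid, []).append(rec)

    records: list[CompoundRecord] = []
    for cid, group in rows.items():
        if len(group) == 1:
            records.append(group[0])
            continue
        if schema.on_duplicate == "error":
            raise SchemaError(f"duplicate compound id {cid!r}")
        merged = CompoundRecord(cid, group[0].smiles)
        merged.flags = sorted({f for g in group for f in g.flags})
        per_target: dict[str, list[float]] = {}
        for g in group:
            for t, ki in g.activities.items():
                per_target.setdefault(t, []).append(ki)
        merged.activities = {t: _merge_kis(v, schema.on_duplicate) for t, v in per_target.items()}
        records.append(merged)
    return records


def write_activity_table(records: list[CompoundRecord], path: str | Path) -> None:
    """Write records back to the canonical activity CSV layout."""
    targets = sorted({t for r in records for t in r.activities})
    data = {
        "compound_id": [r.compound_id for r in records],
        "smiles": [r.smiles or "" for r in records],
    }
    for t in targets:
        data[f"{t}_ki_um"] = [
            ("" if r.activities.get(t) is None else repr(r.activities[t])) for r in records
        ]
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class LibraryLoad:
    """Result of reading a screening library: valid records plus a
    report of structures that failed to parse (quarantined, not dropped
    silently)."""

    records: list[CompoundRecord]
    invalid: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_invalid(self) -> int:
        return len(self.invalid)


def read_library(path: str | Path) -> LibraryLoad:
    """Read a SMILES (.smi, whitespace-separated ``smiles id``) or SDF library.

    Records carry empty activity maps.  Invalid structures are counted
    and reported in the returned ``LibraryLoad.invalid`` list.
    """
    path = Path(path)
    records: list[CompoundRecord] = []
    invalid: list[tuple[str, str]] = []
    if path.suffix.lower() in {".sdf", ".sd"}:
        with open(path, "rb") as fh:
            supplier = Chem.ForwardSDMolSupplier(fh, sanitize=True)
            for i, mol in enumerate(supplier):
                if mol is None:
                    invalid.append((f"sdf_record_{i}", "unparsable SDF block"))
                    continue
                name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_record_{i}"
                records.append(CompoundRecord(name, Chem.MolToSmiles(mol)))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                smiles = parts[0]
                cid = parts[1] if len(parts) > 1 else f"smi_record_{i}"
                if Chem.MolFromSmiles(smiles) is None:
                    invalid.append((cid, f"unparsable SMILES {smiles!r}"))
                    continue
                records.append(CompoundRecord(cid, smiles))
    if not records:
        warnings.warn(f"library {path} contains no valid structures", stacklevel=2)
    return LibraryLoad(records, invalid)


def save_model(bundle: object, path: str | Path, meta: dict | None = None) -> None:
    """Persist a trained model bundle to a single archive file."""
    payload = {"format_version": _FORMAT_VERSION, "meta": dict(meta or {}), "bundle": bundle}
    joblib.dump(payload, path)


def load_model(path: str | Path) -> object:
    """Load a bundle written by :func:`save_model`; version-checked."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated / foreign file
        raise ModelError(f"cannot read model bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelError(f"{path} is not a selsvm model bundle")
    if payload["format_version"] != _FORMAT_VERSION:
        raise ModelError(
            f"bundle version {payload['format_version']!r} != expected {_FORMAT_VERSION!r}"
        )
    return payload["bundle"]
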