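"""Layered run configuration and reproducibility manifests.

Every tunable of the screening method is collected in :class:`RunConfig`
with its conventional default: ligand/non-ligand Ki thresholds 1 and
10 uM, 10-fold selectivity ratio, hard margin C = 100000, sigma grid
{0.4, 0.5, 0.6}, 5 CV folds, RFE batch m = 4, and family-clustering
Tanimoto threshold 0.7.  Configs load from YAML, accept dotted-path
overrides (``svm.sigma_grid=0.5``), are validated before any
computation, and are serialised in full into every run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class SvmConfig:
    C: float = 100000.0
    sigma_grid: tuple[float, ...] = (0.4, 0.5, 0.6)
    cv_folds: int = 5
    cv_metric: str = "mcc"


@dataclass(frozen=True)
class RunConfig:
    ligand_threshold: float = 1.0  # uM
    nonligand_threshold: float = 10.0  # uM
    selectivity_fold: float = 10.0
    family_threshold: float = 0.7
    putative_max_per_family: int = 1
    scaling: str = "minmax"
    rfe_m: int = 4
    step2_rule: str = "and"
    seed: int = 0
    svm: SvmConfig = field(default_factory=SvmConfig)

    def validate(self) -> "RunConfig":
        if not 0 < self.ligand_threshold < self.nonligand_threshold:
            raise ConfigError("need 0 < ligand_threshold < nonligand_threshold")
        if self.selectivity_fold <= 1:
            raise ConfigError("selectivity_fold must exceed 1")
        if not 0 < self.family_threshold < 1:
            raise ConfigError("family_threshold must be in (0, 1)")
        if self.putative_max_per_family < 1:
            raise ConfigError("putative_max_per_family must be >= 1")
        if self.scaling not in ("minmax", "zscore"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")
        if self.rfe_m < 1:
            raise ConfigError("rfe_m must be >= 1")
        if self.step2_rule not in ("and", "or", "step2_only"):
            raise ConfigError(f"unknown step2_rule {self.step2_rule!r}")
        if self.svm.C <= 0:
            raise ConfigError("svm.C must be positive")
        if not self.svm.sigma_grid or any(s <= 0 for s in self.svm.sigma_grid):
            raise ConfigError("svm.sigma_grid must contain positive widths")
        if self.svm.cv_folds < 2:
            raise ConfigError("svm.cv_folds must be >= 2")
        if self.svm.cv_metric not in ("mcc", "q"):
            raise ConfigError(f"unknown svm.cv_metric {self.svm.cv_metric!r}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["svm"]["sigma_grid"] = list(self.svm.sigma_grid)
        return d


def _coerce(value: str):
    try:
        return yaml.safe_load(value)
    except yaml.YAMLError:
        return value


def load_config(path: str | Path | None = None, overrides: list[str] | None = None) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus
    dotted ``key=value`` overrides (e.g. ``svm.sigma_grid=[0.5]``)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    for item in overrides or []:
        if "=" not in item:
            raise ConfigError(f"override {item!r} must look like key=value")
        key, value = item.split("=", 1)
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot override through scalar at {part!r}")
        node[parts[-1]] = _coerce(value)
    svm_data = dict(data.pop("svm", {}))
    if "sigma_grid" in svm_data:
        grid = svm_data["sigma_grid"]
        svm_data["sigma_grid"] = tuple(grid) if isinstance(grid, (list, tuple)) else (float(grid),)
    known = set(RunConfig.__dataclass_fields__) - {"svm"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    unknown_svm = set(svm_data) - set(SvmConfig.__dataclass_fields__)
    if unknown_svm:
        raise ConfigError(f"unknown svm config keys: {sorted(unknown_svm)}")
    try:
        cfg = RunConfig(svm=SvmConfig(**svm_data), **data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg.validate()


def with_seed(cfg: RunConfig, seed: int) -> RunConfig:
    return replace(cfg, seed=seed)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    cfg: RunConfig,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a reproducibility manifest: config snapshot, input hashes,
    package version, and seed.  File references are recorded by
    basename + SHA-256 so two runs in different directories produce
    byte-identical manifests."""
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "inputs": {
            name: {"file": Path(p).name, "sha256": file_sha256(p)}
            for name, p in sorted((inputs or {}).items())
        },
        "outputs": {
            name: {"file": Path(p).name, "sha256": file_sha256(p)}
            for name, p in sorted((outputs or {}).items())
        },
    }
    if extra:
        manifest["extra"] = extra
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
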