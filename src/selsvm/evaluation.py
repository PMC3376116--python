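"""Performance statistics and the three evaluation protocols.

Classification quality uses the standard screening indicators derived
from the confusion counts: sensitivity SE = TP/(TP+FN), specificity
SP = TN/(TN+FP), overall accuracy Q = (TP+TN)/n, and the Matthews
correlation coefficient.  In library screening the yield is TP/(TP+FN)
and the false-hit rate FP/(TP+FP).

Protocols:

* selective set — for ligands selective for subtype a over subtype b,
  the fraction selected by the model of a but not by the model of b;
* multi-subtype set — for ligands binding two or more subtypes, the
  fraction selected by the models of more than one subtype;
* applicability-domain profile — a library binned by maximal Tanimoto
  similarity to the reference ligands (ten bins over [0, 1]) with the
  per-bin percentage of model hits; a flat profile indicates the model
  behaves uniformly across the similarity range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem_io import DescriptorMatrix, FingerprintMatrix
from .datasets import tanimoto_matrix
from .errors import DatasetError
from .screening import HitMatrix, TwoStepModel, predict_subtype_calls


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DatasetError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts from +/-1 prediction and truth vectors."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise DatasetError("prediction and truth vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((predicted == 1) & (truth == 1))),
        tn=int(np.sum((predicted == -1) & (truth == -1))),
        fp=int(np.sum((predicted == 1) & (truth == -1))),
        fn=int(np.sum((predicted == -1) & (truth == 1))),
    )


@dataclass
class MetricsReport:
    """SE/SP/Q/MCC plus screening yield and false-hit rate.

    Ratios with a zero denominator are reported as ``nan`` and named in
    ``undefined`` (except MCC, whose zero-denominator convention is 0,
    flagged) so degenerate tables never propagate silently.
    """

    counts: ConfusionCounts
    se: float
    sp: float
    q: float
    mcc: float
    yield_: float
    false_hit_rate: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "SE": self.se,
            "SP": self.sp,
            "Q": self.q,
            "MCC": self.mcc,
            "yield": self.yield_,
            "false_hit_rate": self.false_hit_rate,
            "undefined": list(self.undefined),
        }


def metrics(counts: ConfusionCounts) -> MetricsReport:
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    se = ratio(tp, tp + fn, "SE")
    sp = ratio(tn, tn + fp, "SP")
    q = ratio(tp + tn, counts.n, "Q")
    y = ratio(tp, tp + fn, "yield")
    fh = ratio(fp, tp + fp, "false_hit_rate")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.append("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(counts, se, sp, q, mcc, y, fh, undefined)


def evaluate_selective_set(
    model: TwoStepModel,
    X: DescriptorMatrix,
    target_a: str,
    target_b: str,
    strategy: str = "2sbr",
) -> tuple[float, np.ndarray]:
    """Fraction of a-selective test ligands called by the model of
    ``target_a`` but not by the model of ``target_b`` (pairwise
    first-not-second protocol), plus the per-compound breakdown.

    For the 2SBR strategy the per-subtype call is the composed
    step-1 AND step-2 decision; for combi/single it is the step-1 call.
    """
    if X.n == 0:
        raise DatasetError("selective test set is empty")
    hits = predict_subtype_calls(model, X, strategy)
    ja = hits.targets.index(target_a)
    jb = hits.targets.index(target_b)
    ok = hits.calls[:, ja] & ~hits.calls[:, jb]
    return float(ok.mean()), ok


def evaluate_multisubtype_set(
    model: TwoStepModel,
    X: DescriptorMatrix,
    strategy: str = "2sbr",
) -> tuple[float, np.ndarray]:
    """Fraction of multi-subtype test ligands selected by the models of
    more than one subtype (predicted non-selective), plus breakdown."""
    if X.n == 0:
        raise DatasetError("multi-subtype test set is empty")
    hits = predict_subtype_calls(model, X, strategy)
    multi = hits.call_counts() >= 2
    return float(multi.mean()), multi


def max_similarity(
    compound_fp: np.ndarray, reference: FingerprintMatrix
) -> tuple[float, str]:
    """Maximal Tanimoto similarity of one fingerprint to a reference
    ligand set, with the id of the most similar reference (ties ->
    smallest id).  An all-zero query has similarity 0 by convention."""
    if reference.n == 0:
        raise DatasetError("reference fingerprint set is empty")
    q = np.asarray(compound_fp, dtype=np.uint8).reshape(1, -1)
    sims = tanimoto_matrix(q, reference.bits)[0]
    best = sims.max()
    tied = sorted(
        reference.compound_ids[i] for i in np.nonzero(np.isclose(sims, best))[0]
    )
    return float(best), tied[0]


def max_similarity_many(
    library: FingerprintMatrix, reference: FingerprintMatrix
) -> np.ndarray:
    """Vectorised maximal Tanimoto similarity for every library row."""
    if reference.n == 0:
        raise DatasetError("reference fingerprint set is empty")
    return tanimoto_matrix(library.bits, reference.bits).max(axis=1)


SIMILARITY_BIN_EDGES = tuple(np.round(np.arange(0.0, 1.1, 0.1), 1))


@dataclass
class SimilarityProfile:
    """Ten similarity bins over [0, 1] with per-bin hit percentages.

    Bins are left-closed: [0, 0.1), ..., [0.8, 0.9), [0.9, 1.0].
    Percentages of empty bins are ``nan`` (undefined, not zero).
    """

    bin_edges: tuple[float, ...]
    counts: np.ndarray
    hit_counts: np.ndarray

    @property
    def percent_hits(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, 100.0 * self.hit_counts / np.maximum(self.counts, 1), np.nan)

    def bin_labels(self) -> list[str]:
        e = self.bin_edges
        return [f"{e[i]:.1f}-{e[i + 1]:.1f}" for i in range(len(e) - 1)]


def bin_index(sim: float | np.ndarray) -> np.ndarray:
    """Left-closed decile bin index for similarity values in [0, 1]."""
    idx = np.floor(np.asarray(sim, dtype=float) * 10).astype(int)
    return np.clip(idx, 0, 9)


def similarity_profile(
    library: FingerprintMatrix,
    reference: FingerprintMatrix,
    hit_flags: np.ndarray,
) -> SimilarityProfile:
    """Similarity-binned hit-rate profile of a screened library."""
    hit_flags = np.asarray(hit_flags, dtype=bool)
    if hit_flags.shape[0] != library.n:
        raise DatasetError("hit flags must align with the library")
    sims = max_similarity_many(library, reference)
    idx = bin_index(sims)
    counts = np.bincount(idx, minlength=10)
    hits = np.bincount(idx[hit_flags], minlength=10)
    return SimilarityProfile(SIMILARITY_BIN_EDGES, counts, hits)
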