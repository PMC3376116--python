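"""End-to-end synthetic benchmark of the screening strategies.

Runs the full study on a generated corpus: train the two-step models
on the training ligands, known non-ligands, and putative negatives
drawn from the background families; then

* selective-set protocol — for every ordered subtype pair, the
  fraction of held-out selective ligands selected by the first
  subtype's model but not the second's, per strategy;
* multi-subtype protocol — for every tested subtype subset, the
  fraction of held-out multi-subtype ligands selected by more than one
  subtype model, per strategy;
* null-library screen — virtual hit rates of each strategy on the
  inactive background library;
* cross-validation metrics of every trained task at its selected
  kernel width.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .evaluation import ConfusionCounts, evaluate_multisubtype_set, evaluate_selective_set, metrics
from .rfe import rfe_rank
from .screening import STRATEGIES, TwoStepModel, screen_library, train_two_step
from .synthetic import SyntheticCorpus, SyntheticSpec, generate_corpus, make_feature_selection_instance


@dataclass
class StudyResult:
    corpus: SyntheticCorpus
    model: TwoStepModel
    selective_fractions: dict[str, dict[tuple[str, str], float]]  # strategy -> pair -> frac
    multi_fractions: dict[str, dict[tuple[str, ...], float]]  # strategy -> subset -> frac
    null_hit_rates: dict[str, float]  # strategy -> mean selective rate on background
    cv_metrics: dict[str, dict] = field(default_factory=dict)  # task -> SE/SP/Q/MCC

    def mean_selective(self, strategy: str) -> float:
        return float(np.mean(list(self.selective_fractions[strategy].values())))

    def mean_multi(self, strategy: str) -> float:
        return float(np.mean(list(self.multi_fractions[strategy].values())))

    def mean_cv(self, step: str, key: str) -> float:
        vals = [m[key] for task, m in self.cv_metrics.items() if task.startswith(step)]
        return float(np.mean(vals))


def train_study_model(corpus: SyntheticCorpus, seed: int, **train_kwargs) -> TwoStepModel:
    """Train the two-step model under the held-out protocol: the
    clustering/putative-negative input is the training compounds plus
    the screening background; test compounds never enter training."""
    train_records = corpus.training_records
    fp_ids = [r.compound_id for r in train_records] + corpus.ids_with_role("background")
    fingerprints = corpus.fingerprints.subset(fp_ids)
    return train_two_step(
        train_records, corpus.descriptors, fingerprints, corpus.targets,
        seed=seed, **train_kwargs,
    )


def run_study(
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    strategies: tuple[str, ...] = ("single", "combi", "2sbr"),
    **train_kwargs,
) -> StudyResult:
    """Generate a corpus, train, and run every evaluation protocol."""
    spec = spec or SyntheticSpec(seed=seed)
    if spec.seed != seed:
        spec = SyntheticSpec(**{**vars(spec), "seed": seed})
    corpus = generate_corpus(spec)
    model = train_study_model(corpus, seed, **train_kwargs)
    targets = corpus.targets

    selective: dict[str, dict[tuple[str, str], float]] = {s: {} for s in strategies}
    for a, b in itertools.permutations(targets, 2):
        ids = corpus.selective_ids(a, b)
        if not ids:
            continue
        X = corpus.descriptors.subset(ids)
        for strat in strategies:
            frac, _ = evaluate_selective_set(model, X, a, b, strat)
            selective[strat][(a, b)] = frac

    multi: dict[str, dict[tuple[str, ...], float]] = {s: {} for s in strategies}
    for subset in spec.tested_multi_subsets():
        names = tuple(targets[t] for t in subset)
        ids = corpus.multi_ids(names)
        if not ids:
            continue
        X = corpus.descriptors.subset(ids)
        for strat in strategies:
            frac, _ = evaluate_multisubtype_set(model, X, strat)
            multi[strat][names] = frac

    null_rates: dict[str, float] = {}
    bg_ids = corpus.ids_with_role("background")
    if bg_ids:
        lib = corpus.descriptors.subset(bg_ids)
        for strat in strategies:
            summary, _ = screen_library(model, lib, strat)
            null_rates[strat] = float(np.mean(list(summary.virtual_hit_rate.values())))

    cv_metrics: dict[str, dict] = {}
    for task, rep in model.cv_reports.items():
        counts = rep.per_sigma[rep.selected_sigma]["fold_confusions"]
        total = ConfusionCounts(
            tp=sum(c[0] for c in counts),
            tn=sum(c[1] for c in counts),
            fp=sum(c[2] for c in counts),
            fn=sum(c[3] for c in counts),
        )
        m = metrics(total)
        cv_metrics[task] = {"SE": m.se, "SP": m.sp, "Q": m.q, "MCC": m.mcc}

    return StudyResult(corpus, model, selective, multi, null_rates, cv_metrics)


def rfe_recovery(
    seed: int,
    n_informative: int = 5,
    d_total: int = 30,
    n_per_class: int = 100,
    delta: float = 1.5,
    sigma_grid: tuple[float, ...] = (0.4, 0.5, 0.6),
    m: int = 4,
) -> int:
    """Planted-feature recovery: how many of the informative descriptors
    survive into the top ``n_informative`` of the RFE ranking."""
    ds = make_feature_selection_instance(
        n_per_class=n_per_class, d_informative=n_informative, d_total=d_total,
        delta=delta, seed=seed,
    )
    results, best = rfe_rank(ds, sigma_grid=sigma_grid, m=m, k=5, seed=seed)
    top = set(results[best].elimination_order[-n_informative:])
    planted = {n for n in ds.descriptor_names if n.startswith("inf_")}
    return len(top & planted)
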