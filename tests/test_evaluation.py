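import math

import numpy as np
import pytest

from selsvm.chem_io import FingerprintMatrix
from selsvm.errors import DatasetError
from selsvm.evaluation import (
    ConfusionCounts,
    bin_index,
    confusion,
    evaluate_multisubtype_set,
    evaluate_selective_set,
    max_similarity,
    max_similarity_many,
    metrics,
    similarity_profile,
)
from selsvm.screening import predict_subtype_calls


def _oracle_metrics(tp, tn, fp, fn):
    """First-principles recomputation of every indicator."""
    def ratio(a, b):
        return a / b if b else math.nan

    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    q = ratio(tp + tn, tp + tn + fp + fn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    y = ratio(tp, tp + fn)
    fh = ratio(fp, tp + fp)
    return se, sp, q, mcc, y, fh


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion(np.array([1, 1, -1, -1]), np.array([1, 1, -1, -1]))
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        c = confusion(np.array([1, 1, 1, 1]), np.array([1, -1, 1, -1]))
        assert (c.tp, c.fp) == (2, 2)

    def test_empty_vectors(self):
        c = confusion(np.array([]), np.array([]))
        assert c.n == 0

    def test_length_mismatch_fails(self):
        with pytest.raises(DatasetError):
            confusion(np.array([1]), np.array([1, -1]))


class TestMetrics:
    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(5, 5, 0, 0))
        assert rep.se == rep.sp == rep.q == 1.0
        assert rep.mcc == 1.0

    def test_overall_accuracy_arithmetic(self):
        rep = metrics(ConfusionCounts(3, 7, 1, 1))
        assert rep.q == pytest.approx(10 / 12)

    def test_matches_first_principles_oracle_on_small_tables(self):
        for tp in range(0, 7):
            for tn in range(0, 7):
                for fp in range(0, 7):
                    for fn in range(0, 7):
                        rep = metrics(ConfusionCounts(tp, tn, fp, fn))
                        exp = _oracle_metrics(tp, tn, fp, fn)
                        got = (rep.se, rep.sp, rep.q, rep.mcc, rep.yield_, rep.false_hit_rate)
                        for g, e in zip(got, exp):
                            if math.isnan(e):
                                assert math.isnan(g)
                            else:
                                assert g == pytest.approx(e, abs=1e-12)

    def test_degenerate_denominators_flagged_not_thrown(self):
        rep = metrics(ConfusionCounts(3, 0, 0, 0))
        assert math.isnan(rep.sp)
        assert "SP" in rep.undefined
        assert rep.mcc == 0.0 and "MCC" in rep.undefined


class TestSimilarity:
    def _ref(self, rows, ids=None):
        rows = np.asarray(rows, dtype=np.uint8)
        ids = ids or [f"r{i}" for i in range(len(rows))]
        return FingerprintMatrix(ids, [f"b{j}" for j in range(rows.shape[1])], rows)

    def test_identical_fingerprint_scores_one(self):
        ref = self._ref([[1, 0, 1, 0]])
        sim, who = max_similarity(np.array([1, 0, 1, 0]), ref)
        assert sim == 1.0 and who == "r0"

    def test_disjoint_bits_score_zero(self):
        sim, _ = max_similarity(np.array([1, 1, 0, 0]), self._ref([[0, 0, 1, 1]]))
        assert sim == 0.0

    def test_set_formula(self):
        # bits {0,1,2} vs {1,2,3}: 2 shared of 4 total
        sim, _ = max_similarity(np.array([1, 1, 1, 0]), self._ref([[0, 1, 1, 1]]))
        assert sim == pytest.approx(0.5)

    def test_tie_broken_to_smallest_reference_id(self):
        ref = self._ref([[1, 1, 0, 0], [1, 1, 0, 0]], ids=["zz", "aa"])
        _, who = max_similarity(np.array([1, 1, 0, 0]), ref)
        assert who == "aa"

    def test_all_zero_query_defined_as_zero(self):
        sim, _ = max_similarity(np.zeros(4, dtype=np.uint8), self._ref([[1, 0, 1, 0]]))
        assert sim == 0.0

    def test_reference_order_invariance(self, rng):
        bits = (rng.random((30, 40)) < 0.2).astype(np.uint8)
        ref_a = self._ref(bits[10:])
        perm = rng.permutation(20)
        ref_b = FingerprintMatrix(
            [ref_a.compound_ids[i] for i in perm], ref_a.bit_names, ref_a.bits[perm]
        )
        sims_a = max_similarity_many(self._ref(bits[:10]), ref_a)
        sims_b = max_similarity_many(self._ref(bits[:10]), ref_b)
        np.testing.assert_allclose(sims_a, sims_b)


class TestSimilarityProfile:
    def _ref(self):
        bits = np.zeros((1, 20), dtype=np.uint8)
        bits[0, :10] = 1
        return FingerprintMatrix(["ref"], [f"b{j}" for j in range(20)], bits)

    def test_bin_placement_of_known_similarities(self):
        assert list(bin_index(np.array([0.95, 0.55, 0.05]))) == [9, 5, 0]

    def test_boundary_value_belongs_to_left_closed_bin(self):
        assert bin_index(0.8) == 8
        assert bin_index(1.0) == 9  # top bin is closed above

    def test_counts_partition_library_and_empty_bins_are_nan(self, rng):
        lib_bits = (rng.random((50, 20)) < 0.3).astype(np.uint8)
        lib = FingerprintMatrix([f"c{i}" for i in range(50)], [f"b{j}" for j in range(20)], lib_bits)
        prof = similarity_profile(lib, self._ref(), np.zeros(50, dtype=bool))
        assert prof.counts.sum() == 50
        pct = prof.percent_hits
        assert np.isnan(pct[prof.counts == 0]).all()

    def test_hit_percentages(self):
        lib = self._ref()  # identical to reference: similarity 1.0, bin 9
        prof = similarity_profile(lib, self._ref(), np.array([True]))
        assert prof.counts[9] == 1
        assert prof.percent_hits[9] == pytest.approx(100.0)


class TestProtocols:
    def test_selective_fraction_is_first_not_second(self, small_corpus, trained_model):
        a, b = small_corpus.targets[0], small_corpus.targets[1]
        ids = small_corpus.selective_ids(a, b)
        X = small_corpus.descriptors.subset(ids)
        frac, ok = evaluate_selective_set(trained_model, X, a, b, "2sbr")
        hits = predict_subtype_calls(trained_model, X, "2sbr")
        ja, jb = hits.targets.index(a), hits.targets.index(b)
        manual = hits.calls[:, ja] & ~hits.calls[:, jb]
        assert frac == pytest.approx(manual.mean())
        np.testing.assert_array_equal(ok, manual)
        assert 0.0 <= frac <= 1.0

    def test_multisubtype_fraction_counts_two_or_more_calls(self, small_corpus, trained_model):
        subset = small_corpus.spec.tested_multi_subsets()[0]
        names = tuple(small_corpus.targets[t] for t in subset)
        X = small_corpus.descriptors.subset(small_corpus.multi_ids(names))
        frac, flags = evaluate_multisubtype_set(trained_model, X, "combi")
        hits = predict_subtype_calls(trained_model, X, "combi")
        np.testing.assert_array_equal(flags, hits.call_counts() >= 2)
        assert frac == pytest.approx(flags.mean())

    def test_empty_test_set_rejected(self, small_corpus, trained_model):
        X = small_corpus.descriptors.subset([])
        with pytest.raises(DatasetError):
            evaluate_selective_set(trained_model, X, *small_corpus.targets[:2])
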