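import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selsvm.chem_io import CompoundRecord, FingerprintMatrix
from selsvm.datasets import (
    ActivityLabel,
    FamilyClustering,
    assign_activity_label,
    build_binding_dataset,
    build_selectivity_dataset,
    cluster_families,
    generate_putative_negatives,
    label_multi_subtype,
    label_selective,
    stratified_kfold,
    tanimoto_matrix,
)
from selsvm.errors import DatasetError


class TestActivityLabeling:
    @pytest.mark.parametrize(
        "ki,expected",
        [
            (0.5, ActivityLabel.LIGAND),
            (5.0, ActivityLabel.INDETERMINATE),
            (20.0, ActivityLabel.NON_LIGAND),
            (None, ActivityLabel.UNTESTED),
            (1.0, ActivityLabel.INDETERMINATE),  # boundary values fall in the gap
            (10.0, ActivityLabel.INDETERMINATE),
        ],
    )
    def test_threshold_labeling(self, ki, expected):
        assert assign_activity_label(ki) is expected

    def test_non_positive_ki_fails(self):
        with pytest.raises(DatasetError):
            assign_activity_label(0.0)

    def test_inverted_thresholds_fail(self):
        with pytest.raises(DatasetError):
            assign_activity_label(0.5, ligand_threshold=10, nonligand_threshold=1)

    @given(st.one_of(st.none(), st.floats(min_value=1e-6, max_value=1e4)))
    @settings(deadline=None, max_examples=200)
    def test_labels_partition_all_ki_values(self, ki):
        label = assign_activity_label(ki)
        if ki is None:
            assert label is ActivityLabel.UNTESTED
        elif ki < 1:
            assert label is ActivityLabel.LIGAND
        elif ki > 10:
            assert label is ActivityLabel.NON_LIGAND
        else:
            assert label is ActivityLabel.INDETERMINATE


class TestSelectivityLabeling:
    def test_tenfold_ratio_is_selective(self):
        rec = CompoundRecord("c", activities={"A": 0.1, "B": 1.2})
        assert label_selective(rec, "A", "B") is True

    def test_fivefold_ratio_is_not_selective(self):
        rec = CompoundRecord("c", activities={"A": 0.1, "B": 0.5})
        assert label_selective(rec, "A", "B") is False

    def test_non_ligand_of_first_target_not_evaluable(self):
        rec = CompoundRecord("c", activities={"A": 2.0, "B": 40.0})
        assert label_selective(rec, "A", "B") is None

    def test_missing_ki_not_evaluable(self):
        rec = CompoundRecord("c", activities={"A": 0.1})
        assert label_selective(rec, "A", "B") is None

    @pytest.mark.parametrize(
        "acts,expected",
        [
            ({"A": 0.2, "B": 0.8, "C": 30.0}, {"A", "B"}),
            ({"A": 0.2}, {"A"}),
            ({}, set()),
        ],
    )
    def test_multi_subtype_subset(self, acts, expected):
        rec = CompoundRecord("c", activities=acts)
        assert label_multi_subtype(rec, ["A", "B", "C"]) == expected


def _leader_oracle(bits, threshold):
    """Straightforward re-implementation of the documented leader rule."""
    leaders = []
    assignment = []
    for i, row in enumerate(bits):
        best, best_sim = None, -1.0
        for fam, lead in enumerate(leaders):
            lead_row = bits[lead]
            if lead_row.sum() == 0:
                continue
            inter = np.minimum(row, lead_row).sum()
            union = np.maximum(row, lead_row).sum()
            sim = inter / union if union else 0.0
            if sim > best_sim:
                best, best_sim = fam, sim
        if row.sum() and best is not None and best_sim >= threshold:
            assignment.append(best)
        else:
            assignment.append(len(leaders))
            leaders.append(i)
    return assignment


class TestFamilyClustering:
    def _fp(self, bits):
        bits = np.asarray(bits, dtype=np.uint8)
        return FingerprintMatrix(
            [f"c{i}" for i in range(len(bits))],
            [f"b{j}" for j in range(bits.shape[1])],
            bits,
        )

    def test_identical_fingerprints_share_a_family(self):
        fp = self._fp([[1, 1, 0, 0], [1, 1, 0, 0]])
        fam = cluster_families(fp, 0.7)
        assert fam.family_of["c0"] == fam.family_of["c1"]
        assert fam.n_families == 1

    def test_disjoint_fingerprints_split(self):
        fp = self._fp([[1, 1, 0, 0], [0, 0, 1, 1]])
        fam = cluster_families(fp, 0.7)
        assert fam.n_families == 2

    def test_matches_brute_force_leader_oracle_on_random_fingerprints(self, rng):
        bits = (rng.random((100, 64)) < 0.15).astype(np.uint8)
        fp = self._fp(bits)
        fam = cluster_families(fp, 0.35)
        expected = _leader_oracle(bits, 0.35)
        got = [fam.family_of[c] for c in fp.compound_ids]
        assert got == expected

    def test_zero_fingerprint_rows_become_flagged_singletons(self):
        fp = self._fp([[0, 0, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0]])
        fam = cluster_families(fp, 0.5)
        assert fam.family_of["c0"] != fam.family_of["c2"]
        assert set(fam.flagged) == {"c0", "c2"}

    def test_representative_is_a_member(self, small_corpus):
        fam = cluster_families(small_corpus.fingerprints, 0.7)
        for fid, rep in fam.representatives.items():
            assert fam.family_of[rep] == fid

    def test_threshold_bounds_enforced(self):
        fp = self._fp([[1, 0]])
        with pytest.raises(DatasetError):
            cluster_families(fp, 1.5)


class TestPutativeNegatives:
    def _families(self):
        return FamilyClustering(
            family_of={"l1": 0, "x1": 0, "x2": 1, "x3": 1, "x4": 2},
            representatives={0: "l1", 1: "x2", 2: "x4"},
            threshold=0.7,
        )

    def test_only_ligand_free_family_representatives_returned(self):
        out = generate_putative_negatives(self._families(), {"l1"})
        assert out == ["x2", "x4"]

    def test_all_families_contaminated_gives_empty_set(self):
        with pytest.warns(UserWarning, match="empty"):
            out = generate_putative_negatives(self._families(), {"l1", "x2", "x4"})
        assert out == []

    def test_max_per_family_draws_extra_sorted_members(self):
        out = generate_putative_negatives(self._families(), {"l1"}, max_per_family=2)
        assert out == ["x2", "x3", "x4"]

    def test_never_shares_family_with_a_target_ligand(self, small_corpus, training_fingerprints):
        fam = cluster_families(training_fingerprints, 0.7)
        target = small_corpus.targets[0]
        ligands = {
            r.compound_id
            for r in small_corpus.training_records
            if r.ki(target) is not None and r.ki(target) < 1.0
        }
        out = generate_putative_negatives(fam, ligands)
        ligand_families = {fam.family_of[c] for c in ligands}
        assert out
        for cid in out:
            assert fam.family_of[cid] not in ligand_families
            assert cid not in ligands


class TestTaskConstruction:
    def _records(self):
        return [
            CompoundRecord("lig1", activities={"A": 0.5}),
            CompoundRecord("lig2", activities={"A": 0.2, "B": 0.4}),
            CompoundRecord("gap1", activities={"A": 5.0}),
            CompoundRecord("non1", activities={"A": 20.0}),
            CompoundRecord("ligB", activities={"B": 0.3}),
            CompoundRecord("ligC", activities={"C": 0.1}),
        ]

    def _descriptors(self, ids):
        from selsvm.chem_io import DescriptorMatrix

        rng = np.random.default_rng(0)
        return DescriptorMatrix(ids, ["x", "y"], rng.normal(size=(len(ids), 2)))

    def test_binding_dataset_composition(self):
        recs = self._records()
        ids = [r.compound_id for r in recs] + ["put1", "put2"]
        ds = build_binding_dataset("A", recs, self._descriptors(ids), ["put1", "put2"])
        pos = {c for c, y in zip(ds.compound_ids, ds.y) if y == 1}
        neg = {c for c, y in zip(ds.compound_ids, ds.y) if y == -1}
        assert pos == {"lig1", "lig2"}
        assert neg == {"non1", "put1", "put2"}
        assert "gap1" not in pos | neg  # indeterminate excluded

    def test_ligand_never_enters_negative_class(self):
        recs = self._records()
        ids = [r.compound_id for r in recs]
        ds = build_binding_dataset("A", recs, self._descriptors(ids), ["lig1", "non1"])
        neg = {c for c, y in zip(ds.compound_ids, ds.y) if y == -1}
        assert "lig1" not in neg

    def test_empty_class_fails_with_class_name(self):
        recs = [CompoundRecord("lig1", activities={"A": 0.5})]
        with pytest.raises(DatasetError, match="negative"):
            build_binding_dataset("A", recs, self._descriptors(["lig1"]), [])

    def test_selectivity_dataset_binary_relevance_transform(self):
        recs = self._records()
        ids = [r.compound_id for r in recs]
        targets = ["A", "B", "C"]
        per_target = {
            t: build_selectivity_dataset(t, recs, targets, self._descriptors(ids))
            for t in targets
        }
        # dual ligand lig2 is positive for both A and B, never negative
        for t in ("A", "B"):
            ds = per_target[t]
            assert dict(zip(ds.compound_ids, ds.y))["lig2"] == 1
        assert dict(zip(per_target["C"].compound_ids, per_target["C"].y))["lig2"] == -1
        # union of positives over tasks == union of all ligands
        all_pos = {
            c for ds in per_target.values() for c, y in zip(ds.compound_ids, ds.y) if y == 1
        }
        assert all_pos == {"lig1", "lig2", "ligB", "ligC"}
        # negatives of A = ligands of B or C that are not ligands of A
        neg_a = {c for c, y in zip(per_target["A"].compound_ids, per_target["A"].y) if y == -1}
        assert neg_a == {"ligB", "ligC"}

    def test_selectivity_requires_multiple_targets(self):
        recs = self._records()
        with pytest.raises(DatasetError):
            build_selectivity_dataset("A", recs, ["A"], self._descriptors([r.compound_id for r in recs]))


class TestStratifiedKFold:
    def _dataset(self, n_pos, n_neg, seed=0):
        from selsvm.chem_io import DescriptorMatrix
        from selsvm.datasets import LabeledDataset
        from selsvm.features import fit_scaler

        rng = np.random.default_rng(seed)
        n = n_pos + n_neg
        X = rng.normal(size=(n, 3))
        y = np.r_[np.ones(n_pos, int), -np.ones(n_neg, int)]
        return LabeledDataset(
            X, y, [f"c{i}" for i in range(n)], "t", ["a", "b", "c"], fit_scaler(X)
        )

    def test_balanced_case_exact_fold_sizes(self):
        folds = stratified_kfold(self._dataset(10, 10), k=5, seed=0)
        ds_y = np.r_[np.ones(10, int), -np.ones(10, int)]
        for f in range(5):
            assert (ds_y[folds.fold_of == f] == 1).sum() == 2
            assert (ds_y[folds.fold_of == f] == -1).sum() == 2

    def test_uneven_positives_differ_by_at_most_one(self):
        folds = stratified_kfold(self._dataset(11, 20), k=5, seed=0)
        y = np.r_[np.ones(11, int), -np.ones(20, int)]
        pos_counts = sorted((y[folds.fold_of == f] == 1).sum() for f in range(5))
        assert pos_counts == [2, 2, 2, 2, 3]

    def test_same_seed_reproduces_assignment(self):
        ds = self._dataset(13, 29)
        a = stratified_kfold(ds, k=5, seed=42).fold_of
        b = stratified_kfold(ds, k=5, seed=42).fold_of
        np.testing.assert_array_equal(a, b)

    @given(
        n_pos=st.integers(min_value=6, max_value=60),
        n_neg=st.integers(min_value=6, max_value=60),
        k=st.integers(min_value=2, max_value=6),
    )
    @settings(deadline=None, max_examples=40)
    def test_per_class_fold_counts_differ_by_at_most_one(self, n_pos, n_neg, k):
        k = min(k, n_pos, n_neg)
        ds = self._dataset(n_pos, n_neg)
        folds = stratified_kfold(ds, k=k, seed=3)
        y = ds.y
        for cls in (1, -1):
            counts = [(y[folds.fold_of == f] == cls).sum() for f in range(k)]
            assert max(counts) - min(counts) <= 1


def test_tanimoto_matrix_set_formula():
    a = np.array([[1, 1, 1, 0]], dtype=np.uint8)  # bits {0,1,2}
    b = np.array([[0, 1, 1, 1]], dtype=np.uint8)  # bits {1,2,3}
    assert tanimoto_matrix(a, b)[0, 0] == pytest.approx(0.5)
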