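import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdakrls.data_model import AssociationDataset
from mdakrls.evaluation import (
    case_study_rank,
    fold_split,
    global_loocv,
    kfold_cv,
    parameter_sweep,
    rank_auc,
    roc_auc,
)
from mdakrls.kron_rls import ModelParams, kronecker_similarity, krls_solve_direct
from mdakrls.similarity import gip_similarity, hip_similarity


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half credit for ties (independent oracle)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1], [1, 1, 0]).auc == 1.0

    def test_total_ties_give_half(self):
        assert roc_auc([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0]).auc == 0.5

    def test_hand_counted_mixed_case(self):
        # pairs: (0.8 vs 0.6), (0.8 vs 0.4), (0.2 vs 0.6), (0.2 vs 0.4) -> 2/4
        assert roc_auc([0.8, 0.6, 0.4, 0.2], [1, 0, 0, 1]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            roc_auc([0.5, 0.6], [1, 1])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 51))
            scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert rank_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_roc_points_form_a_valid_curve(self):
        pts = roc_auc([0.9, 0.7, 0.7, 0.2, 0.1], [1, 1, 0, 0, 1]).roc_points
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-20, 20), min_size=4, max_size=30), st.data())
    def test_invariant_under_monotone_transform(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if sum(labels) in (0, len(labels)):
            labels[0] = 1 - labels[0]
        # quarter-integer grid keeps exp() injective in floating point,
        # so ties are preserved exactly under the transform
        scores = np.array(scores) / 4.0
        assert rank_auc(scores, labels) == pytest.approx(
            rank_auc(np.exp(scores) + 3, labels), abs=1e-12
        )


def brute_force_loocv_ranks(dataset, params):
    """LOOCV per-round ranks via the explicit-Kronecker direct solve."""
    A = np.asarray(dataset.A)
    candidate_mask = A == 0
    ranks = []
    for i, j in dataset.positives():
        Y = np.array(A, dtype=float)
        Y[i, j] = 0
        out = {}
        for tag, (maker, sigma) in {
            "G": (gip_similarity, params.sigma_G),
            "H": (hip_similarity, params.sigma_H),
        }.items():
            Sm, Sd = maker(Y, "microbe"), maker(Y, "disease")
            K = kronecker_similarity(Sm, Sd)
            out[tag] = krls_solve_direct(K, Y, sigma).values
        F = params.w * out["G"] + (1 - params.w) * out["H"]
        ranks.append(1 + int(np.sum(F[candidate_mask] > F[i, j])))
    return ranks


class TestGlobalLoocv:
    def test_single_association_is_the_coin_flip_case(self):
        ds = AssociationDataset(("d1", "d2"), ("m1", "m2"),
                                np.array([[1, 0], [0, 0]]))
        result = global_loocv(ds)
        assert result.auc == 0.5
        assert result.per_round_ranks == [((0, 0), 1, 3)]

    def test_ranks_match_brute_force_direct_solver(self, identity_dataset):
        params = ModelParams()
        result = global_loocv(identity_dataset, params)
        expected = brute_force_loocv_ranks(identity_dataset, params)
        assert [r for _, r, _ in result.per_round_ranks] == expected
        assert len(result.per_round_ranks) == 2

    def test_structure_beats_permuted_entries(self, small_structured):
        ds = small_structured.observed
        structured_auc = global_loocv(ds).auc
        rng = np.random.default_rng(9)
        null_aucs = []
        for _ in range(3):
            flat = rng.permutation(np.asarray(ds.A).ravel())
            null_aucs.append(global_loocv(ds.with_matrix(flat.reshape(ds.A.shape))).auc)
        assert structured_auc > np.mean(null_aucs)
        assert structured_auc > 0.6

    def test_pooled_aggregation_also_detects_structure(self, small_structured):
        ds = small_structured.observed
        assert global_loocv(ds, aggregation="pooled").auc > 0.6

    def test_deterministic(self, small_structured):
        ds = small_structured.observed
        assert global_loocv(ds).auc == global_loocv(ds).auc


class TestKfoldCv:
    def test_seeded_runs_are_identical(self, small_structured):
        ds = small_structured.observed
        a = kfold_cv(ds, k=5, repeats=2, seed=3)
        b = kfold_cv(ds, k=5, repeats=2, seed=3)
        assert (a.auc, a.auc_std) == (b.auc, b.auc_std)

    def test_different_seeds_differ(self, small_structured):
        ds = small_structured.observed
        assert kfold_cv(ds, k=5, repeats=1, seed=0).auc != pytest.approx(
            kfold_cv(ds, k=5, repeats=1, seed=104729).auc, abs=1e-12
        )

    def test_fold_split_partitions_exactly(self):
        for n, k, seed in [(23, 5, 0), (10, 2, 7), (450, 5, 1)]:
            folds = fold_split(n, k, seed)
            assert len(folds) == k
            combined = np.sort(np.concatenate(folds))
            np.testing.assert_array_equal(combined, np.arange(n))

    def test_structure_beats_shuffled_labels(self, small_structured):
        ds = small_structured.observed
        structured = kfold_cv(ds, k=5, repeats=3, seed=0).auc
        rng = np.random.default_rng(13)
        flat = rng.permutation(np.asarray(ds.A).ravel()).reshape(ds.A.shape)
        null = kfold_cv(ds.with_matrix(flat), k=5, repeats=3, seed=0).auc
        assert structured > null
        assert abs(null - 0.5) < 0.1

    def test_k_larger_than_positive_count_rejected(self):
        ds = AssociationDataset(("d1", "d2"), ("m1", "m2"),
                                np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValueError, match="at least k"):
            kfold_cv(ds, k=5, repeats=1, seed=0)


class TestCaseStudy:
    def test_full_ranking_is_a_permutation(self, small_structured):
        ds = small_structured.observed
        rows = case_study_rank(ds, ds.disease_ids[0], top_n=ds.nm)
        assert sorted(m for _, m, _ in rows) == sorted(ds.microbe_ids)

    def test_zeroing_an_empty_row_is_idempotent(self):
        from mdakrls.kron_rls import predict

        A = np.array([[0, 0, 0], [1, 0, 1]])
        ds = AssociationDataset(("d1", "d2"), ("m1", "m2", "m3"), A)
        rows = case_study_rank(ds, "d1", top_n=3)
        F = predict(ds).values
        expected = sorted(range(3), key=lambda j: (-F[0, j], ds.microbe_ids[j]))
        assert [m for _, m, _ in rows] == [ds.microbe_ids[j] for j in expected]

    def test_true_microbes_outrank_others(self, small_structured):
        ds = small_structured.observed
        truth = small_structured.truth_matrix()
        # pick the disease with the most true associations
        target = int(truth.sum(axis=1).argmax())
        rows = case_study_rank(ds, ds.disease_ids[target], top_n=ds.nm)
        pos_ids = {ds.microbe_ids[j] for j in np.nonzero(truth[target])[0]}
        pos_ranks = [r for r, m, _ in rows if m in pos_ids]
        neg_ranks = [r for r, m, _ in rows if m not in pos_ids]
        assert np.mean(pos_ranks) < np.mean(neg_ranks)

    def test_unknown_disease_rejected(self, identity_dataset):
        with pytest.raises(KeyError, match="nosuch"):
            case_study_rank(identity_dataset, "nosuch")


class TestParameterSweep:
    def test_single_point_grid_matches_direct_run(self, small_structured):
        ds = small_structured.observed
        sweep = parameter_sweep(ds, [30.0], [0.8], protocol="kfold",
                                k=5, repeats=2, seed=0)
        direct = kfold_cv(ds, ModelParams(), k=5, repeats=2, seed=0).auc
        assert sweep.sigma_auc[0] == pytest.approx(direct, abs=1e-12)

    def test_w_extremes_match_single_branch_models(self, small_structured):
        ds = small_structured.observed
        sweep = parameter_sweep(ds, [30.0], [0.0, 1.0], protocol="kfold",
                                k=5, repeats=1, seed=0)
        only_h = kfold_cv(ds, ModelParams(w=0.0), k=5, repeats=1, seed=0).auc
        only_g = kfold_cv(ds, ModelParams(w=1.0), k=5, repeats=1, seed=0).auc
        assert sweep.w_auc[0] == pytest.approx(only_h, abs=1e-12)
        assert sweep.w_auc[1] == pytest.approx(only_g, abs=1e-12)

    def test_tsv_output_has_one_row_per_cell(self, small_structured, tmp_path):
        ds = small_structured.observed
        sweep = parameter_sweep(ds, [1.0, 30.0], [0.5], protocol="kfold",
                                k=5, repeats=1, seed=0)
        out = tmp_path / "sweep.tsv"
        with open(out, "w") as fh:
            sweep.write_tsv(fh)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 + 2 + 1  # header + sigma cells + w cells

    def test_empty_grid_rejected(self, small_structured):
        with pytest.raises(ValueError):
            parameter_sweep(small_structured.observed, [], [0.5])
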