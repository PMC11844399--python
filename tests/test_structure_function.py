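import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commutefc import (
    PairwiseMatrix,
    add_homotopic_tracts,
    add_random_tracts,
    all_offdiag_mask,
    commute_time,
    generate_connectome,
    hemisphere_mask,
    homotopic_tract_sweep,
    shuffled_connectome,
    spearman_compare,
    top_mode_reconstruction,
    validate_connectome,
)
from commutefc.synthetic import ConnectomeRecipe


def _pm(values, labels=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    labels = labels or tuple(f"r{i}" for i in range(n))
    return PairwiseMatrix(values=(values + values.T) / 2, metric_name="fc",
                          labels=tuple(labels))


def _random_sym(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, n))
    return (x + x.T) / 2


class TestSpearmanCompare:
    def test_perfect_and_inverted_agreement(self):
        x = _pm(_random_sym(6, 0))
        y_same = _pm(x.values.copy())
        y_neg = _pm(-x.values)
        assert spearman_compare(x, y_same).rho == pytest.approx(1.0)
        assert spearman_compare(x, y_neg).rho == pytest.approx(-1.0)

    def test_independent_matrices_near_zero(self):
        n = 84  # 3486 pairs
        res = spearman_compare(_pm(_random_sym(n, 1)), _pm(_random_sym(n, 2)))
        assert res.n_pairs == 3486
        assert abs(res.rho) < 0.05

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 300), a=st.floats(0.1, 5), b=st.floats(-2, 2))
    def test_invariant_under_monotone_transform(self, seed, a, b):
        x = _pm(np.abs(_random_sym(7, seed)) + 0.1)
        y = _pm(_random_sym(7, seed + 1))
        transformed = _pm(a * np.exp(x.values) + b)
        r1 = spearman_compare(x, y).rho
        r2 = spearman_compare(transformed, y).rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_label_mismatch_rejected(self):
        x = _pm(_random_sym(4, 3))
        y = _pm(_random_sym(4, 4), labels=("a", "b", "c", "d"))
        with pytest.raises(ValueError, match="label"):
            spearman_compare(x, y)


class TestTopModeReconstruction:
    def test_rank_one_input_reproduced(self):
        v = np.linspace(1, 2, 8)
        m = _pm(3.0 * np.outer(v, v))
        rec = top_mode_reconstruction(m, 1)
        assert np.allclose(rec.values, m.values, atol=1e-10)

    def test_full_rank_reconstruction_is_identity(self):
        m = _pm(_random_sym(6, 5))
        assert np.allclose(top_mode_reconstruction(m, 6).values, m.values,
                           atol=1e-10)

    def test_matches_best_rank_k_approximation(self):
        # Eckart–Young via an independent eigendecomposition
        m = _pm(_random_sym(10, 6))
        rec = top_mode_reconstruction(m, 2)
        evals, evecs = np.linalg.eigh(m.values)
        idx = np.argsort(np.abs(evals))[::-1][:2]
        best = (evecs[:, idx] * evals[idx]) @ evecs[:, idx].T
        assert np.allclose(rec.values, best, atol=1e-10)
        assert np.linalg.norm(m.values - rec.values) <= min(
            np.linalg.norm(m.values - best) + 1e-10,
            np.linalg.norm(m.values),
        )

    def test_error_monotone_in_k(self):
        m = _pm(_random_sym(9, 7))
        errs = [np.linalg.norm(m.values - top_mode_reconstruction(m, k).values)
                for k in range(1, 10)]
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            top_mode_reconstruction(_pm(_random_sym(4, 8)), 0)


class TestShuffle:
    def test_weight_multiset_preserved(self, make_connectome):
        c = make_connectome(12, seed=9)
        s = shuffled_connectome(c, seed=1)
        iu = np.triu_indices(12, 1)
        assert sorted(c.weights[iu]) == sorted(s.weights[iu])
        assert np.array_equal(s.weights, s.weights.T)
        assert np.allclose(np.diag(s.weights), 0)

    def test_seed_reproducibility(self, make_connectome):
        c = make_connectome(10, seed=10)
        assert np.array_equal(shuffled_connectome(c, 3).weights,
                              shuffled_connectome(c, 3).weights)


class TestPerturbations:
    def test_homotopic_addition_fills_pairs(self):
        c = validate_connectome(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]])
        out = add_homotopic_tracts(c, 100.0)
        assert out.weights[0, 2] == 100.0
        assert out.weights[1, 3] == 100.0
        assert np.array_equal(out.weights, out.weights.T)

    def test_homotopic_commute_time_strictly_decreases(self):
        c = generate_connectome(ConnectomeRecipe(n_regions=40, seed=3))
        before = commute_time(c).values
        after = commute_time(add_homotopic_tracts(c, 100.0)).values
        for i, j in c.homotopic_pairs():
            assert after[i, j] < before[i, j]

    def test_sweep_returns_one_connectome_per_weight(self, make_connectome):
        c = make_connectome(8, seed=12)
        out = homotopic_tract_sweep(c, [10, 100, 1000])
        assert len(out) == 3
        assert out[2].weights[0, 4] > out[0].weights[0, 4]

    def test_random_addition_bookkeeping(self, make_connectome):
        c = make_connectome(10, seed=13)
        assert add_random_tracts(c, 5.0, 0) is c
        out = add_random_tracts(c, 5.0, 7, seed=1)
        assert out.weights.sum() == pytest.approx(c.weights.sum() + 2 * 7 * 5.0)

    def test_random_addition_too_many_pairs(self, make_connectome):
        c = make_connectome(4, seed=14)
        with pytest.raises(ValueError, match="exceeds"):
            add_random_tracts(c, 1.0, 1000, seed=0)


class TestMasks:
    def test_desikan_killiany_pair_counts(self):
        c = generate_connectome(ConnectomeRecipe(n_regions=84, seed=1))
        assert hemisphere_mask(c, "all_offdiag").n_pairs == 3486  # 84·83/2
        assert hemisphere_mask(c, "intra_left").n_pairs == 861  # 42·41/2

    def test_masks_partition_all_pairs(self):
        c = generate_connectome(ConnectomeRecipe(n_regions=12, seed=2))
        kinds = ["intra_left", "intra_right", "inter_hemisphere"]
        parts = [hemisphere_mask(c, k) for k in kinds]
        combined = {tuple(p) for m in parts for p in m.pairs.tolist()}
        everything = {tuple(p) for p in all_offdiag_mask(12).pairs.tolist()}
        assert combined == everything
        assert sum(m.n_pairs for m in parts) == len(everything)

    def test_unknown_kind(self):
        c = generate_connectome(ConnectomeRecipe(n_regions=8, seed=3))
        with pytest.raises(ValueError):
            hemisphere_mask(c, "frontal")
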