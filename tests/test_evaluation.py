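import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tensorparc as tp
from tensorparc.embedding import Parcellation


# ----------------------------------------------------------- brute oracles
def homogeneity_oracle(z, labels):
    ids = np.unique(labels[labels >= 0])
    total = (labels >= 0).sum()
    rho = 0.0
    for i in ids:
        idx = np.flatnonzero(labels == i)
        if len(idx) < 2:
            continue
        acc, cnt = 0.0, 0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += z[idx[a], idx[b]]
                cnt += 1
        rho += (acc / cnt) * len(idx) / total
    return rho


def variance_oracle(c, labels):
    total = (labels >= 0).sum()
    out = 0.0
    for i in np.unique(labels[labels >= 0]):
        vals = c[labels == i]
        mu = sum(vals) / len(vals)
        var = sum((v - mu) ** 2 for v in vals) / len(vals)
        out += var * len(vals) / total
    return out


def ari_oracle(l1, l2):
    """Pair-counting ARI with the closed-form expected index."""
    n = len(l1)
    pairs = list(itertools.combinations(range(n), 2))
    a = sum(1 for i, j in pairs if l1[i] == l1[j] and l2[i] == l2[j])
    b1 = sum(1 for i, j in pairs if l1[i] == l1[j])
    b2 = sum(1 for i, j in pairs if l2[i] == l2[j])
    total = len(pairs)
    expected = b1 * b2 / total
    maximum = (b1 + b2) / 2
    if maximum == expected:
        return 0.0 if a != maximum else 1.0
    return (a - expected) / (maximum - expected)


def dice_total_oracle(l1, l2, n_parcels):
    """Exhaustive-permutation maximum total Dice."""
    sizes1 = [np.sum(l1 == i) for i in range(n_parcels)]
    sizes2 = [np.sum(l2 == i) for i in range(n_parcels)]
    inter = [[np.sum((l1 == i) & (l2 == j)) for j in range(n_parcels)]
             for i in range(n_parcels)]
    best = -np.inf
    for perm in itertools.permutations(range(n_parcels)):
        tot = sum(2 * inter[i][perm[i]] / (sizes1[i] + sizes2[perm[i]])
                  for i in range(n_parcels))
        best = max(best, tot)
    return best


# ------------------------------------------------------------------ rsfc_z
class TestRsfcZ:
    def test_closed_forms(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        z, valid = tp.rsfc_z(X)
        r = np.corrcoef(X.T)
        assert z[0, 1] == pytest.approx(np.arctanh(r[0, 1]), abs=1e-10)

    def test_perfect_correlation_clipped_finite(self):
        x = np.arange(10.0)
        X = np.column_stack([x, x])
        z, _ = tp.rsfc_z(X, clip_epsilon=1e-7)
        assert np.isfinite(z[0, 1])
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_constant_series_flagged(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        z, valid = tp.rsfc_z(X)
        assert not valid[0]
        assert np.all(z[0] == 0)

    def test_needs_three_timepoints(self):
        with pytest.raises(ValueError):
            tp.rsfc_z(np.zeros((2, 4)))


# -------------------------------------------------------------- homogeneity
class TestHomogeneity:
    def test_uniform_z_single_parcel(self):
        z = np.full((4, 4), 0.5)
        np.fill_diagonal(z, 9.9)  # diagonal must be excluded
        rep = tp.homogeneity(z, Parcellation(np.zeros(4, int), 1))
        assert rep.weighted_average == pytest.approx(0.5)

    def test_weighted_average_with_singleton(self):
        z = np.full((4, 4), 0.4)
        labels = np.array([0, 0, 0, 1])
        with pytest.warns(UserWarning, match="singleton"):
            rep = tp.homogeneity(z, Parcellation(labels, 2))
        assert rep.weighted_average == pytest.approx(0.4 * 3 / 4)
        np.testing.assert_array_equal(rep.parcel_sizes, [3, 1])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((50, 50))
        z = (z + z.T) / 2
        labels = rng.integers(0, 6, 50).astype(np.int32)
        rep = tp.homogeneity(z, Parcellation(labels, 6))
        assert rep.weighted_average == pytest.approx(
            homogeneity_oracle(z, labels), abs=1e-12)

    def test_weights_form_convex_combination(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((30, 30))
        labels = rng.integers(0, 4, 30).astype(np.int32)
        labels[:5] = -1  # invalid vertices excluded from |V|
        rep = tp.homogeneity(z, Parcellation(labels, 4))
        assert rep.total_vertices == 25
        assert rep.parcel_sizes.sum() == 25


# ------------------------------------------------------------ task variance
class TestTaskVariance:
    def test_constant_contrast_zero(self):
        rep = tp.task_variance(np.full(10, 3.3), Parcellation(np.zeros(10, int), 1))
        assert rep.weighted_average == pytest.approx(0.0)

    def test_population_variance_convention(self):
        rep = tp.task_variance(np.array([0.0, 2.0]), Parcellation(np.zeros(2, int), 1))
        assert rep.per_parcel[0] == pytest.approx(1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal(50)
        labels = rng.integers(0, 7, 50).astype(np.int32)
        rep = tp.task_variance(c, Parcellation(labels, 7))
        assert rep.weighted_average == pytest.approx(
            variance_oracle(c, labels), abs=1e-12)


class TestAggregation:
    def test_two_level_mean(self):
        assert tp.aggregate_task_variance({"A": [2, 4], "B": [6]}) == pytest.approx(4.5)

    def test_single_value_passthrough(self):
        assert tp.aggregate_task_variance({"A": [7.5]}) == pytest.approx(7.5)

    def test_order_of_aggregation_not_flat_mean(self):
        assert tp.aggregate_task_variance({"A": [0, 0], "B": [6]}) == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tp.aggregate_task_variance({})
        with pytest.raises(ValueError):
            tp.aggregate_task_variance({"A": []})


# --------------------------------------------------------------------- ARI
class TestARI:
    def test_identical_labelings(self):
        labels = np.array([0, 0, 1, 1, 2])
        assert tp.adjusted_rand_index(labels, labels) == pytest.approx(1.0)

    def test_one_cluster_vs_singletons(self):
        assert tp.adjusted_rand_index(np.zeros(6, int), np.arange(6)) == pytest.approx(0.0)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(4)
        l1 = rng.integers(0, 5, 40)
        l2 = rng.integers(0, 4, 40)
        assert tp.adjusted_rand_index(l1, l2) == pytest.approx(
            ari_oracle(l1, l2), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.lists(st.integers(0, 4), min_size=5, max_size=30),
           st.integers(0, 1000))
    def test_symmetric_and_permutation_invariant(self, l1, seed):
        rng = np.random.default_rng(seed)
        l1 = np.array(l1)
        l2 = rng.integers(0, 3, len(l1))
        a = tp.adjusted_rand_index(l1, l2)
        assert a == pytest.approx(tp.adjusted_rand_index(l2, l1), abs=1e-12)
        perm = rng.permutation(5)
        assert a == pytest.approx(tp.adjusted_rand_index(perm[l1], l2), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tp.adjusted_rand_index(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------- matching
class TestMatchParcels:
    def test_self_match_perfect_dice(self):
        labels = np.random.default_rng(5).integers(0, 5, 60).astype(np.int32)
        p = Parcellation(labels, 5)
        pairs, dice, unmatched = tp.match_parcels(p, p)
        np.testing.assert_allclose(dice, 1.0)
        assert unmatched == []

    def test_label_permutation_invariance(self):
        labels = np.random.default_rng(6).integers(0, 5, 60).astype(np.int32)
        perm = np.array([3, 0, 4, 1, 2])
        p1 = Parcellation(labels, 5)
        p2 = Parcellation(perm[labels], 5)
        _, dice, _ = tp.match_parcels(p1, p2)
        np.testing.assert_allclose(dice, 1.0)

    def test_hungarian_equals_exhaustive_permutation_optimum(self):
        rng = np.random.default_rng(7)
        l1 = rng.integers(0, 8, 100).astype(np.int32)
        l2 = rng.integers(0, 8, 100).astype(np.int32)
        pairs, dice, _ = tp.match_parcels(Parcellation(l1, 8), Parcellation(l2, 8))
        assert dice.sum() == pytest.approx(dice_total_oracle(l1, l2, 8), abs=1e-12)

    def test_surplus_parcels_flagged(self):
        l1 = np.array([0, 0, 1, 1, 2, 2], dtype=np.int32)
        l2 = np.array([0, 0, 0, 1, 1, 1], dtype=np.int32)
        pairs, dice, unmatched = tp.match_parcels(Parcellation(l1, 3), Parcellation(l2, 2))
        assert len(pairs) == 2 and len(unmatched) == 1


# ------------------------------------------------------ random parcellation
class TestRandomParcellation:
    def test_each_vertex_own_parcel(self, ico2):
        parc = tp.random_parcellation(ico2, ico2.n_vertices, seed=0)
        assert parc.n_parcels == ico2.n_vertices
        assert (parc.parcel_sizes == 1).all()

    def test_single_parcel(self, ico2):
        parc = tp.random_parcellation(ico2, 1, seed=0)
        assert parc.n_parcels == 1
        assert (parc.labels == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coverage_count_and_connectivity(self, ico3, seed):
        from scipy.sparse import csgraph

        parc = tp.random_parcellation(ico3, 20, seed=seed)
        assert parc.n_parcels == 20
        assert (parc.labels >= 0).all()
        assert np.all(parc.parcel_sizes > 0)
        adj = ico3.adjacency()
        for i in range(20):
            idx = np.flatnonzero(parc.labels == i)
            n_comp, _ = csgraph.connected_components(adj[idx, :][:, idx],
                                                     directed=False)
            assert n_comp == 1

    def test_deterministic(self, ico2):
        a = tp.random_parcellation(ico2, 7, seed=9)
        b = tp.random_parcellation(ico2, 7, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_validation(self, ico2):
        with pytest.raises(ValueError):
            tp.random_parcellation(ico2, 0)


# --------------------------------------------------------------- ratio curve
class TestRatioCurve:
    def test_scale_invariance_of_homogeneity_ratio(self, ico2):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((ico2.n_vertices, ico2.n_vertices))
        z = np.abs(z + z.T)
        parc = tp.random_parcellation(ico2, 6, seed=1)
        r1 = tp.ratio_curve({6: parc}, ico2, z_matrices=[z], null_draws=5, seed=0)
        r2 = tp.ratio_curve({6: parc}, ico2, z_matrices=[3.7 * z], null_draws=5, seed=0)
        assert r1[6] == pytest.approx(r2[6], rel=1e-12)

    def test_planted_truth_beats_random(self, ico3, standard_fixture):
        zs = [tp.rsfc_z(s)[0] for s in standard_fixture["subjects"][:3]]
        truth_parc = standard_fixture["truth"].parcellation
        ratios = tp.ratio_curve({10: truth_parc}, ico3, z_matrices=zs,
                                null_draws=10, seed=0)
        assert ratios[10] > 1.0


# ------------------------------------------------------------ parcel networks
class TestParcelNetworks:
    @staticmethod
    def block_series(seed, T=300, per_block=6, noise=0.15):
        rng = np.random.default_rng(seed)
        s1, s2 = rng.standard_normal((2, T))
        X = np.empty((T, 2 * per_block))
        for p in range(per_block):
            X[:, p] = s1 + noise * rng.standard_normal(T)
            X[:, per_block + p] = s2 + noise * rng.standard_normal(T)
        return X, np.array([0] * per_block + [1] * per_block)

    def test_two_block_recovery(self):
        X, truth = self.block_series(0)
        labels = tp.parcel_networks(X, 2, seed=0)
        assert tp.adjusted_rand_index(labels, truth) == 1.0

    def test_identity_when_networks_equal_parcels(self):
        X, _ = self.block_series(1)
        labels = tp.parcel_networks(X, X.shape[1], seed=0)
        np.testing.assert_array_equal(labels, np.arange(X.shape[1]))

    def test_global_signal_regression_reduces_common_coupling(self):
        X, truth = self.block_series(2)
        g = np.random.default_rng(3).standard_normal(X.shape[0])
        Xc = X + 5.0 * g[:, None]  # strong shared component
        labels = tp.parcel_networks(Xc, 2, global_signal_regression=True, seed=0)
        assert tp.adjusted_rand_index(labels, truth) == 1.0
        # between-block correlation drops once the global signal is removed
        raw_between = np.corrcoef(Xc.T)[0, 7]
        resid = Xc - np.outer(Xc.mean(1), Xc.mean(1) @ Xc) / (Xc.mean(1) @ Xc.mean(1))
        reg_between = np.corrcoef(resid.T)[0, 7]
        assert reg_between < raw_between

    def test_validation(self):
        with pytest.raises(ValueError):
            tp.parcel_networks(np.zeros((10, 3)), 4)


# ----------------------------------------------------------------- degree map
class TestDegreeMap:
    def test_constant_degree_warns_zeros(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.warns(UserWarning):
            out = tp.degree_map(A)
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_minmax_arithmetic(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        A[1, 2] = A[2, 1] = 1.0
        A[0, 2] = A[2, 0] = 0.0
        A[1, 2] += 0.0
        # off-diagonal row sums: 1, 2, 1 -> normalized 0, 1, 0
        out = tp.degree_map(A)
        np.testing.assert_allclose(out, [0.0, 1.0, 0.0])

    def test_matches_loop_oracle_with_negative_clipping(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(-1, 1, (30, 30))
        A = (A + A.T) / 2
        out = tp.degree_map(A)
        deg = np.array([sum(max(A[i, j], 0.0) for j in range(30) if j != i)
                        for i in range(30)])
        expect = (deg - deg.min()) / (deg.max() - deg.min())
        np.testing.assert_allclose(out, expect, atol=1e-12)


# ---------------------------------------------------------- paired comparison
class TestPairedComparison:
    def test_identical_samples_degenerate(self):
        v = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            res = tp.paired_comparison(v, v)
        assert res.degenerate and np.isnan(res.d)

    def test_cohens_d_hand_arithmetic(self):
        v1 = np.array([1.0, 1.0, 1.0, 3.0])
        res = tp.paired_comparison(v1, np.zeros(4))
        assert res.d == pytest.approx(1.5)

    def test_t_matches_closed_form(self):
        rng = np.random.default_rng(10)
        v1, v2 = rng.standard_normal((2, 12))
        res = tp.paired_comparison(v1, v2)
        diff = v1 - v2
        expect = diff.mean() * np.sqrt(12) / diff.std(ddof=1)
        assert res.t == pytest.approx(expect, abs=1e-12)
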