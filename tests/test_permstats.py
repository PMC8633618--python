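"""Cluster-based permutation statistics: oracles and invariants.

Independent oracles used here:

* a brute-force flood-fill clusterer (recursive, no shared code) for
  cluster membership and mass;
* exhaustive sign-flip enumeration (2^n) for permutation p values;
* scipy's paired t for the t maps; MNE's cluster permutation machinery as
  a library cross-check.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hepsleep.montage import channel_adjacency
from hepsleep.permstats import (
    ClusterPermutationTest,
    StatsError,
    bh_fdr,
    cluster_permutation_test,
    form_clusters,
    paired_t_map,
    pointwise_permutation_test,
    t_critical,
)

CHAIN5 = np.zeros((5, 5), dtype=bool)
for _i in range(4):
    CHAIN5[_i, _i + 1] = CHAIN5[_i + 1, _i] = True


# ---------------------------------------------------------------------------
# brute-force oracle: flood fill over (channel, time) grid
# ---------------------------------------------------------------------------


def _oracle_clusters(tmap, adjacency, tcrit, min_neighbors=0):
    """Recursive flood fill; returns a set of (frozenset(members), mass)."""
    n_ch, n_t = tmap.shape
    out = []
    for sign in (1, -1):
        mask = sign * tmap > tcrit
        if min_neighbors > 0:
            pruned = mask.copy()
            for c in range(n_ch):
                for t in range(n_t):
                    if mask[c, t]:
                        nb = sum(
                            mask[c2, t]
                            for c2 in range(n_ch)
                            if adjacency[c, c2]
                        )
                        if nb < min_neighbors:
                            pruned[c, t] = False
            mask = pruned
        seen = np.zeros_like(mask)
        for c in range(n_ch):
            for t in range(n_t):
                if mask[c, t] and not seen[c, t]:
                    stack, members = [(c, t)], []
                    seen[c, t] = True
                    while stack:
                        ci, ti = stack.pop()
                        members.append((ci, ti))
                        cands = [(ci, ti - 1), (ci, ti + 1)] + [
                            (c2, ti) for c2 in range(n_ch)
                            if adjacency[ci, c2]
                        ]
                        for cj, tj in cands:
                            if (
                                0 <= tj < n_t
                                and mask[cj, tj]
                                and not seen[cj, tj]
                            ):
                                seen[cj, tj] = True
                                stack.append((cj, tj))
                    mass = sum(tmap[ci, ti] for ci, ti in members)
                    out.append((frozenset(members), mass))
    return out


def _oracle_max_mass(tmap, adjacency, tcrit, min_neighbors=0):
    cl = _oracle_clusters(tmap, adjacency, tcrit, min_neighbors)
    return max((abs(m) for _, m in cl), default=0.0)


class TestPairedTMap:
    def test_identical_conditions_give_zero_map(self, rng):
        a = rng.normal(size=(6, 3, 10))
        assert np.allclose(paired_t_map(a, a.copy()), 0.0)

    def test_matches_scipy_paired_t(self, rng):
        a = rng.normal(size=(8, 4, 12))
        b = rng.normal(size=(8, 4, 12))
        t = paired_t_map(a, b)
        ref = stats.ttest_rel(a, b, axis=0).statistic
        assert np.allclose(t, ref, atol=1e-12)

    def test_four_subject_textbook_point(self):
        # hand-computed: d = [1, 2, 3, 6], mean 3, sd sqrt(14/3)
        a = np.array([5.0, 7.0, 9.0, 14.0])[:, None, None]
        b = np.array([4.0, 5.0, 6.0, 8.0])[:, None, None]
        expected = 3.0 / (np.sqrt(14.0 / 3.0) / 2.0)
        assert paired_t_map(a, b)[0, 0] == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_shift_scales_like_sqrt_n(self, rng):
        n = 20
        a = rng.normal(1.0, 1.0, size=(n, 2, 200))
        b = rng.normal(0.0, 1.0, size=(n, 2, 200))
        t = paired_t_map(a, b)
        # E[t] ~ sqrt(n) * delta / sd(d), sd(d) = sqrt(2)
        assert t.mean() == pytest.approx(np.sqrt(n) / np.sqrt(2), rel=0.15)

    def test_zero_variance_points_get_zero(self):
        a = np.ones((5, 1, 3))
        b = np.zeros((5, 1, 3))
        assert np.allclose(paired_t_map(a, b), 0.0)


class TestClusterFormation:
    def test_single_channel_mass_arithmetic(self):
        tmap = np.array([[0.0, 3.0, 3.0, 0.0]])
        adj = np.zeros((1, 1), dtype=bool)
        # critical value 2.1 ~ df=18 at alpha=0.05 (2.1009)
        clusters = form_clusters(tmap, adj, df=18, min_neighbors=0)
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(6.0)
        assert clusters[0].sign == 1

    def test_non_neighbor_channels_form_separate_clusters(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = True  # 2 is isolated from 0
        tmap = np.array([[5.0], [0.0], [5.0]])
        clusters = form_clusters(tmap, adj, df=10, min_neighbors=0)
        assert len(clusters) == 2

    def test_negative_excursions_cluster_separately(self):
        adj = np.zeros((2, 2), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        tmap = np.array([[4.0, -4.0], [4.0, -4.0]])
        clusters = form_clusters(tmap, adj, df=12, min_neighbors=0)
        signs = sorted(c.sign for c in clusters)
        assert signs == [-1, 1]

    @pytest.mark.parametrize("min_neighbors", [0, 2])
    def test_matches_flood_fill_oracle_on_random_maps(self, min_neighbors):
        rng = np.random.default_rng(99)
        tcrit = t_critical(9)
        for _ in range(20):
            tmap = rng.normal(0, 2.0, size=(5, 20))
            ours = form_clusters(
                tmap, CHAIN5, df=9, min_neighbors=min_neighbors
            )
            oracle = _oracle_clusters(tmap, CHAIN5, tcrit, min_neighbors)
            ours_set = {
                (frozenset(zip(c.channels.tolist(), c.times.tolist())),
                 round(c.mass, 9))
                for c in ours
            }
            oracle_set = {(m, round(mass, 9)) for m, mass in oracle}
            assert ours_set == oracle_set

    def test_min_neighbors_pruning_requires_spatial_support(self):
        # lone suprathreshold channel dies under the 2-neighbor rule
        tmap = np.zeros((5, 4))
        tmap[2, 1] = 5.0
        assert form_clusters(tmap, CHAIN5, df=9, min_neighbors=2) == []
        # whole chain suprathreshold: the single-pass rule keeps the
        # interior channels (two supported neighbors) and drops the ends
        tmap[:, 1] = 5.0
        got = form_clusters(tmap, CHAIN5, df=9, min_neighbors=2)
        assert len(got) == 1
        assert sorted(got[0].channels.tolist()) == [1, 2, 3]
        assert got[0].mass == pytest.approx(15.0)


class TestPermutationTest:
    def test_identical_conditions_find_no_clusters(self, rng):
        a = rng.normal(size=(8, 5, 20))
        res = cluster_permutation_test(
            a, a.copy(), adjacency=CHAIN5, window_ms=None,
            n_permutations=200, seed=0,
        )
        assert res.clusters == []

    def test_monte_carlo_p_matches_exhaustive_enumeration(self, rng):
        # n=6 subjects: all 64 sign flips enumerable
        n = 6
        d = rng.normal(0.6, 1.0, size=(n, 5, 50))
        a = d.copy()
        b = np.zeros_like(d)
        res = cluster_permutation_test(
            a, b, adjacency=CHAIN5, window_ms=None,
            n_permutations=5000, seed=3, min_neighbors=0,
        )
        assert res.clusters, "effect should form at least one cluster"
        tcrit = t_critical(n - 1)

        null = []
        for bits in range(64):
            signs = np.array([1 if bits >> k & 1 else -1
                              for k in range(n)], dtype=float)
            flipped = d * signs[:, None, None]
            tmap = stats.ttest_rel(
                flipped, np.zeros_like(flipped), axis=0
            ).statistic
            null.append(_oracle_max_mass(tmap, CHAIN5, tcrit))
        null = np.asarray(null)
        for c in res.clusters:
            exact_p = np.mean(null >= abs(c.mass))
            assert c.p_value == pytest.approx(exact_p, abs=0.02)

    def test_subject_order_invariance(self, rng):
        a = rng.normal(size=(7, 5, 12))
        b = rng.normal(size=(7, 5, 12))
        perm = np.random.default_rng(1).permutation(7)
        r1 = cluster_permutation_test(
            a, b, adjacency=CHAIN5, window_ms=None, n_permutations=300,
            seed=5,
        )
        r2 = cluster_permutation_test(
            a[perm], b[perm], adjacency=CHAIN5, window_ms=None,
            n_permutations=300, seed=5,
        )
        m1 = sorted(round(c.mass, 9) for c in r1.clusters)
        m2 = sorted(round(c.mass, 9) for c in r2.clusters)
        assert m1 == m2

    def test_enlarging_effect_never_shrinks_cluster_mass(self, rng):
        noise = rng.normal(size=(10, 5, 30))
        bump = np.zeros((5, 30))
        bump[1:4, 10:20] = 1.0
        masses = []
        for amp in (0.5, 1.0, 1.5, 2.0):
            a = noise + amp * bump
            res = cluster_permutation_test(
                a, np.zeros_like(a), adjacency=CHAIN5, window_ms=None,
                n_permutations=100, seed=2, min_neighbors=0,
            )
            masses.append(res.max_mass)
        assert all(x <= y + 1e-9 for x, y in zip(masses, masses[1:]))

    def test_determinism_same_seed(self, rng):
        a = rng.normal(size=(6, 5, 15))
        b = rng.normal(size=(6, 5, 15))
        r1 = cluster_permutation_test(a, b, adjacency=CHAIN5,
                                      window_ms=None, n_permutations=500,
                                      seed=11)
        r2 = cluster_permutation_test(a, b, adjacency=CHAIN5,
                                      window_ms=None, n_permutations=500,
                                      seed=11)
        assert np.array_equal(r1.null_distribution, r2.null_distribution)

    def test_cross_check_against_mne_cluster_masses(self, rng):
        mne = pytest.importorskip("mne")
        from scipy import sparse

        n = 10
        d = rng.normal(0.0, 1.0, size=(n, 6, 40))
        d[:, 2:5, 10:25] += 0.9
        labels = ["Fp1", "F3", "Fz", "F4", "C3", "Cz"]
        adj = channel_adjacency(labels)
        ours = cluster_permutation_test(
            d, np.zeros_like(d), adjacency=adj, window_ms=None,
            n_permutations=200, seed=0, min_neighbors=0,
        )
        thresh = t_critical(n - 1)
        t_obs, clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
            d.transpose(0, 2, 1),  # obs x time x space
            threshold=thresh,
            adjacency=sparse.coo_matrix(adj),
            n_permutations=50,
            tail=0,
            out_type="mask",
            seed=1,
            verbose="error",
        )
        mne_masses = sorted(
            round(float(t_obs[m].sum()), 6) for m in clusters
        )
        our_masses = sorted(round(c.mass, 6) for c in ours.clusters)
        assert our_masses == mne_masses

    def test_window_outside_epoch_rejected(self, rng):
        a = rng.normal(size=(5, 5, 10))
        with pytest.raises(StatsError):
            ClusterPermutationTest(
                a, a, adjacency=CHAIN5,
                times_ms=np.linspace(0, 100, 10), window_ms=(350, 650),
            )


class TestPointwise:
    def test_identical_waveforms_give_maximal_p(self, rng):
        a = rng.normal(size=(6, 30))
        t, p = pointwise_permutation_test(a, a.copy(),
                                          n_permutations=200, seed=0)
        assert np.allclose(t, 0.0)
        assert (p == 1.0).all()

    def test_single_time_point_matches_exhaustive_p(self, rng):
        n = 6
        d = rng.normal(0.8, 1.0, size=(n, 1))
        t_obs, p = pointwise_permutation_test(
            d, np.zeros_like(d), n_permutations=5000, seed=1
        )
        null = []
        for bits in range(64):
            signs = np.array([1 if bits >> k & 1 else -1
                              for k in range(n)], dtype=float)
            null.append(
                stats.ttest_rel(d[:, 0] * signs,
                                np.zeros(n)).statistic
            )
        exact = np.mean(np.abs(null) >= abs(t_obs[0]))
        assert p[0] == pytest.approx(exact, abs=0.02)

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(40):
            a = rng.normal(size=(10, 25))
            b = rng.normal(size=(10, 25))
            _, p = pointwise_permutation_test(a, b, n_permutations=400,
                                              seed=int(rng.integers(1e6)))
            rates.append(np.mean(p < 0.05))
        assert 0.02 <= np.mean(rates) <= 0.10


class TestFDR:
    def _oracle(self, p, q):
        # textbook step-up: largest k with p_(k) <= k q / m
        m = len(p)
        order = np.argsort(p)
        sorted_p = np.asarray(p)[order]
        k = 0
        for i in range(1, m + 1):
            if sorted_p[i - 1] <= i * q / m:
                k = i
        mask = np.zeros(m, dtype=bool)
        mask[order[:k]] = True
        return mask

    def test_textbook_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        assert bh_fdr(p, q=0.05).tolist() == [True, True, True, False]

    def test_all_ones_reject_nothing(self):
        assert not bh_fdr(np.ones(10)).any()

    def test_single_small_p_rejected(self):
        assert bh_fdr(np.array([0.01]), q=0.05).all()

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
            assert np.array_equal(bh_fdr(p, 0.05), self._oracle(p, 0.05))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_oracle_agreement_property(self, p):
        p = np.asarray(p)
        assert np.array_equal(bh_fdr(p, 0.05), self._oracle(p, 0.05))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(StatsError):
            bh_fdr(np.array([0.5, 1.2]))
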