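import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import cohesionnet as cn
from cohesionnet.expression import ExpressionMatrix
from cohesionnet.network import (
    communities_from_assignment,
    scale_free_fit,
    UNASSIGNED,
)


# ----------------------------------------------------------------------
# adjacency
# ----------------------------------------------------------------------
class TestAdjacency:
    def test_known_correlation_is_exponentiated(self):
        # two genes with r = 0.8 exactly, power 6 -> 0.8^6
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        e = rng.standard_normal(2000)
        # construct y with sample correlation exactly 0.8 via residual orthogonalization
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        y = 0.8 * x + math.sqrt(1 - 0.64) * e
        z = rng.standard_normal(2000)
        em = ExpressionMatrix(["a", "b", "c"], [f"s{i}" for i in range(2000)], np.vstack([x, y, z]))
        adj = cn.compute_adjacency(em, power=6)
        assert adj[0, 1] == pytest.approx(0.8**6, abs=1e-12)
        assert adj[0, 1] == pytest.approx(0.262144, abs=1e-6)

    def test_perfect_and_zero_correlation(self):
        x = np.arange(10.0)
        em = ExpressionMatrix(
            ["a", "b", "c"],
            [f"s{i}" for i in range(10)],
            np.vstack([x, 2 * x + 1, np.ones(10)]),
        )
        adj = cn.compute_adjacency(em, power=7)
        assert adj[0, 1] == pytest.approx(1.0)  # |r| = 1 fixed point at any power
        assert adj[0, 2] == 0.0  # constant gene -> correlation defined as 0
        assert np.all(np.diag(adj) == 0)
        np.testing.assert_allclose(adj, adj.T)

    def test_power_must_be_positive(self, tiny_controls):
        with pytest.raises(ValueError):
            cn.compute_adjacency(tiny_controls, power=0)


# ----------------------------------------------------------------------
# soft power
# ----------------------------------------------------------------------
class TestPickSoftPower:
    def test_single_candidate_is_returned(self, tiny_controls):
        assert cn.pick_soft_power(tiny_controls, [6]) == 6

    def test_fallback_matches_independent_fit_oracle(self, tiny_controls):
        # cutoff 1.0 is unreachable -> argmax-fit power, verified against an
        # independent recomputation of the signed R^2 with scipy.linregress
        candidates = [1, 2, 4, 6]
        chosen = cn.pick_soft_power(tiny_controls, candidates, r2_cutoff=1.0)

        def oracle_fit(power):
            adj = cn.compute_adjacency(tiny_controls, power)
            k = adj.sum(axis=1)
            k = k[k > 0]
            hist, edges = np.histogram(k, bins=10)
            centers = []
            freqs = []
            for b in range(10):
                sel = (k >= edges[b]) & (k <= edges[b + 1] if b == 9 else k < edges[b + 1])
                if hist[b] > 0:
                    centers.append(k[sel].mean())
                    freqs.append(hist[b] / k.size)
            res = stats.linregress(np.log10(centers), np.log10(freqs))
            return -np.sign(res.slope) * res.rvalue**2

        oracle_choice = candidates[int(np.argmax([oracle_fit(p) for p in candidates]))]
        assert chosen == oracle_choice

    def test_smallest_qualifying_power_wins(self, tiny_controls):
        # with a cutoff below every fit, the first candidate qualifies
        fits = [scale_free_fit(cn.compute_adjacency(tiny_controls, p)) for p in [2, 4]]
        assert cn.pick_soft_power(tiny_controls, [2, 4], r2_cutoff=min(fits) - 1) == 2

    def test_degenerate_connectivity_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(np.zeros((5, 5)))


# ----------------------------------------------------------------------
# TOM
# ----------------------------------------------------------------------
def _tom_oracle(a):
    """Loop-based brute-force TOM for cross-checking the vectorized form."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_zero_adjacency_gives_zero_overlap(self):
        tom = cn.compute_tom(np.zeros((4, 4)))
        assert np.all(tom[~np.eye(4, dtype=bool)] == 0)
        assert np.all(np.diag(tom) == 1)

    def test_triangle_of_unit_weights(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = cn.compute_tom(a)
        # (shared + a) / (min(k) + 1 - a) = (1 + 1) / (2 + 1 - 1)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.uniform(0, 1, (6, 6))
            a = np.triu(a, 1)
            a = a + a.T
            np.testing.assert_allclose(cn.compute_tom(a), _tom_oracle(a), atol=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        arrays(
            float,
            (5, 5),
            elements=st.floats(0, 1, allow_nan=False, allow_infinity=False),
        )
    )
    def test_output_always_valid(self, raw):
        a = np.triu(raw, 1)
        a = a + a.T
        tom = cn.compute_tom(a)
        np.testing.assert_allclose(tom, tom.T)
        assert np.all(np.diag(tom) == 1)
        assert np.all((tom >= 0) & (tom <= 1))


# ----------------------------------------------------------------------
# community detection
# ----------------------------------------------------------------------
class TestDetectCommunities:
    def test_two_planted_blocks_recovered_exactly(self):
        config = cn.SimulationConfig(
            n_genes=40,
            n_controls=300,
            n_cases=1,
            communities=(cn.CommunitySpec(20, 0.9), cn.CommunitySpec(20, 0.9)),
            seed=8,
        )
        controls = cn.generate_controls(config)
        tom = cn.compute_tom(cn.compute_adjacency(controls, 6))
        assignment = cn.detect_communities(tom, controls.gene_ids, min_size=5)
        planted = [0] * 20 + [1] * 20
        found = [assignment[g] for g in controls.gene_ids]
        assert UNASSIGNED not in found
        assert adjusted_rand_score(planted, found) == 1.0

    def test_min_size_too_large_leaves_all_unassigned(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 0.3, (12, 12))
        a = np.triu(a, 1)
        a = a + a.T
        tom = cn.compute_tom(a)
        assignment = cn.detect_communities(tom, [f"g{i}" for i in range(12)], min_size=13)
        assert set(assignment.values()) == {UNASSIGNED}
        assert communities_from_assignment(assignment) == {}

    def test_identical_tom_rows_share_a_community(self):
        # zero dissimilarity merges first, so duplicates can never split
        config = cn.SimulationConfig(
            n_genes=30,
            n_controls=200,
            n_cases=1,
            communities=(cn.CommunitySpec(15, 0.9), cn.CommunitySpec(15, 0.9)),
            seed=9,
        )
        controls = cn.generate_controls(config)
        tom = cn.compute_tom(cn.compute_adjacency(controls, 6))
        tom[1] = tom[0]
        tom[:, 1] = tom[:, 0]
        tom[0, 1] = tom[1, 0] = 1.0
        np.fill_diagonal(tom, 1.0)
        assignment = cn.detect_communities(tom, controls.gene_ids, min_size=5)
        g0, g1 = controls.gene_ids[0], controls.gene_ids[1]
        assert assignment[g0] == assignment[g1]


# ----------------------------------------------------------------------
# preservation
# ----------------------------------------------------------------------
def _block_tom(n, blocks, low, rng):
    """Background TOM with hub-graded blocks: within-block w_ij = lam_i*lam_j."""
    tom = rng.uniform(0, low, (n, n))
    for members in blocks:
        lam = np.linspace(0.95, 0.6, len(members))
        for a, i in enumerate(members):
            for b, j in enumerate(members):
                if i != j:
                    tom[i, j] = lam[a] * lam[b] + rng.uniform(-0.02, 0.02)
    tom = (tom + tom.T) / 2
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0, 1)


@pytest.fixture(scope="module")
def toms():
    rng = np.random.default_rng(21)
    n = 80
    genes = [f"g{i:02d}" for i in range(n)]
    preserved = list(range(12))
    noise = list(range(12, 24))
    train = _block_tom(n, [preserved, noise], 0.1, rng)
    test = _block_tom(n, [preserved], 0.1, rng)  # noise block vanishes
    return train, test, genes


class TestPreservation:

    def test_planted_block_kept_noise_block_dropped(self, toms):
        train, test, genes = toms
        communities = {
            "kept_block": frozenset(genes[:12]),
            "noise_block": frozenset(genes[12:24]),
        }
        report = cn.preservation_filter(
            train, test, genes, communities, n_permutations=100, seed=4
        )
        assert report.kept == ["kept_block"]
        assert report.dropped == ["noise_block"]

    def test_vacuous_cutoff_keeps_everything(self, toms):
        train, test, genes = toms
        communities = {
            "a": frozenset(genes[:12]),
            "b": frozenset(genes[12:24]),
        }
        report = cn.preservation_filter(
            train, test, genes, communities, n_permutations=50,
            z_cutoff=-math.inf, seed=4,
        )
        assert set(report.kept) == {"a", "b"}

    def test_zsummary_invariant_to_gene_renaming(self, toms):
        train, test, genes = toms
        communities = {"blk": frozenset(genes[:12])}
        z1 = cn.preservation_filter(
            train, test, genes, communities, n_permutations=50, seed=4
        ).table["zsummary"].iloc[0]
        renamed = [f"x_{g}" for g in genes]
        z2 = cn.preservation_filter(
            train, test, renamed,
            {"blk": frozenset(renamed[:12])}, n_permutations=50, seed=4,
        ).table["zsummary"].iloc[0]
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_too_few_permutations_rejected(self, toms):
        train, test, genes = toms
        with pytest.raises(ValueError):
            cn.preservation_filter(
                train, test, genes, {"a": frozenset(genes[:12])}, n_permutations=10
            )


# ----------------------------------------------------------------------
# edge retention
# ----------------------------------------------------------------------
class TestRetainTopEdges:
    def _tom(self, n, seed=0):
        rng = np.random.default_rng(seed)
        tom = rng.uniform(0.1, 0.9, (n, n))
        tom = (tom + tom.T) / 2
        np.fill_diagonal(tom, 1.0)
        return tom

    def test_fraction_one_keeps_every_pair(self):
        genes = [f"g{i}" for i in range(5)]
        net = cn.retain_top_edges(self._tom(5), genes, {"c": frozenset(genes)}, 1.0)
        assert net.n_edges() == 10

    def test_fraction_point_one_keeps_single_max_pair(self):
        genes = [f"g{i}" for i in range(5)]
        tom = self._tom(5, seed=1)
        net = cn.retain_top_edges(tom, genes, {"c": frozenset(genes)}, 0.1)
        assert net.n_edges() == 1
        pos = {g: i for i, g in enumerate(genes)}
        # enumeration oracle over all 10 pairs
        best = max(
            ((genes[i], genes[j]) for i in range(5) for j in range(i + 1, 5)),
            key=lambda e: tom[pos[e[0]], pos[e[1]]],
        )
        assert set(net.edges) == {best}

    def test_boundary_tie_breaks_lexicographically(self):
        genes = ["a", "b", "c", "d"]
        tom = np.full((4, 4), 0.5)
        np.fill_diagonal(tom, 1.0)
        net = cn.retain_top_edges(tom, genes, {"c": frozenset(genes)}, 0.5)
        # 6 pairs, keep ceil(3) = 3; all tied -> first three in pair order
        assert sorted(net.edges) == [("a", "b"), ("a", "c"), ("a", "d")]

    def test_edge_counts_and_no_intercommunity_edges(self):
        genes = [f"g{i}" for i in range(12)]
        communities = {
            "c1": frozenset(genes[:7]),
            "c2": frozenset(genes[7:]),
        }
        fraction = 0.3
        net = cn.retain_top_edges(self._tom(12, 2), genes, communities, fraction)
        for label, members in communities.items():
            n_pairs = len(members) * (len(members) - 1) // 2
            expected = math.ceil(fraction * n_pairs)
            assert len(net.community_edges(label)) == expected
        for a, b in net.edges:
            assert net.community_of[a] == net.community_of[b]

    def test_tiny_community_gets_no_edges(self):
        genes = ["a", "b", "c"]
        net = cn.retain_top_edges(
            self._tom(3), genes, {"solo": frozenset(["a"])}, 0.5
        )
        assert net.n_edges() == 0
        assert set(net.nodes) == set(genes)


# ----------------------------------------------------------------------
# train/test split
# ----------------------------------------------------------------------
def test_split_is_seeded_and_disjoint(tiny_controls):
    train1, test1 = cn.split_controls(tiny_controls, 0.2, seed=17)
    train2, test2 = cn.split_controls(tiny_controls, 0.2, seed=17)
    assert train1.sample_ids == train2.sample_ids
    assert not set(train1.sample_ids) & set(test1.sample_ids)
    assert len(test1.sample_ids) == round(0.2 * tiny_controls.n_samples)
    train3, _ = cn.split_controls(tiny_controls, 0.2, seed=18)
    assert train3.sample_ids != train1.sample_ids
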