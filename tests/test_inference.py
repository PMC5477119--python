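"""The nine network constructors and their search-space machinery."""

import itertools
import warnings

import numpy as np
import pytest

from rlowpc import inference as inf
from rlowpc.association import mi_from_correlation, shrinkage_correlation
from rlowpc.netio import WeightedAdjacency, rank_edges

from .conftest import (
    chain_motif_expr,
    data_with_exact_correlation,
    make_expr,
    random_correlation_matrix,
)


class TestInferPC:
    def test_two_genes_equals_shrunk_marginal(self, rng):
        expr = make_expr(rng.standard_normal((2, 30)))
        est = shrinkage_correlation(expr)
        w = inf.infer_pc(expr).weights
        assert w[0, 1] == pytest.approx(est.shrunk_correlation[0, 1], abs=1e-12)

    def test_equicorrelated_closed_form(self, rng):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        X = data_with_exact_correlation(R, 40, rng)
        w = inf.infer_pc(make_expr(X), lambda_override=0.0).weights
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(w[iu], 1.0 / 3.0, atol=1e-10)

    def test_independent_data_gives_small_weights(self, rng):
        w = inf.infer_pc(make_expr(rng.standard_normal((10, 200)))).weights
        assert np.abs(w).max() < 0.3


class TestSearchSpace:
    def _adj_from_scores(self, n, scores):
        genes = [f"X{i + 1}" for i in range(n)]
        idx = {g: i for i, g in enumerate(genes)}
        w = np.zeros((n, n))
        for (a, b), s in scores.items():
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = s
        return WeightedAdjacency(gene_ids=genes, weights=w)

    def test_top_six_of_ten_retained(self, rng):
        """5 genes give 10 pairs; a search space of 6 keeps exactly the 6
        highest-|score| edges."""
        w = rng.standard_normal((5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        adj = WeightedAdjacency(gene_ids=[f"X{i + 1}" for i in range(5)], weights=w)
        trimmed = inf.trim_search_space(adj, 6)
        assert len(trimmed.retained_edges) == 6
        ranked = rank_edges(adj)
        assert trimmed.retained_edges == list(zip(ranked.gene_a, ranked.gene_b))[:6]

    def test_large_N_retains_everything_and_N1_the_top_edge(self, rng):
        w = rng.standard_normal((4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        adj = WeightedAdjacency(gene_ids=list("ABCD"), weights=w)
        assert len(inf.trim_search_space(adj, 99).retained_edges) == 6
        top = inf.trim_search_space(adj, 1).retained_edges
        assert top == [rank_edges(adj).pairs()[0]]

    def test_neighbour_set_motif(self):
        """The worked 5-gene example: retained edges 12,13,15,23,25,34 make
        X3 and X5 the neighbours of the pair (X1, X2) in either mode."""
        edges = [("X1", "X2"), ("X1", "X3"), ("X1", "X5"), ("X2", "X3"),
                 ("X2", "X5"), ("X3", "X4")]
        trimmed = inf.TrimmedNetwork(
            retained_edges=edges, source_scores={e: 1.0 for e in edges}, N=6
        )
        for mode in ("union", "shared"):
            assert inf.neighbour_set(trimmed, "X1", "X2", mode) == {"X3", "X5"}

    def test_neighbour_set_isolated_pair_and_star(self):
        lone = inf.TrimmedNetwork(
            retained_edges=[("A", "B")], source_scores={("A", "B"): 1.0}, N=1
        )
        assert inf.neighbour_set(lone, "A", "B", "union") == set()
        star_edges = [("C", "L1"), ("C", "L2"), ("C", "L3")]
        star = inf.TrimmedNetwork(
            retained_edges=star_edges, source_scores={e: 1.0 for e in star_edges}, N=3
        )
        assert inf.neighbour_set(star, "L1", "L2", "union") == {"C"}
        assert inf.neighbour_set(star, "L1", "L2", "shared") == {"C"}

    def test_suggested_sizes_follow_published_mapping(self):
        assert inf.suggested_search_space(100) == 1500
        assert inf.suggested_search_space(500) == 2000
        assert inf.suggested_search_space(1000) == 3000
        assert inf.suggested_search_space(2000) == 5000
        assert inf.suggested_search_space(3000) == 8000
        # linear interpolation between table entries: halfway 500 -> 1000
        assert inf.suggested_search_space(750) == 2500
        # small networks keep the 100-gene retained fraction of pairs
        assert inf.suggested_search_space(45) == round(1500 / 4950 * 990)


class TestRLowPC:
    def test_indirect_edge_demoted_exactly(self, rng):
        R = np.array([[1.0, 0.64, 0.8], [0.64, 1.0, 0.8], [0.8, 0.8, 1.0]])
        X = data_with_exact_correlation(R, 63, rng)
        expr = make_expr(X, gene_ids=["X1", "X2", "X3"])
        adj, signed = inf.infer_rlowpc(
            expr, N=3, lambda_override=0.0, return_signed=True
        )
        assert adj.weights[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert adj.weights[0, 2] > 0.1 and adj.weights[1, 2] > 0.1
        assert signed[("X1", "X2")] == pytest.approx(0.0, abs=1e-10)

    def test_empty_conditioning_keeps_marginal(self, rng):
        """A retained edge whose endpoints have no other retained edges is
        conditioned on nothing: the refined score is the shrunk marginal."""
        expr = make_expr(rng.standard_normal((4, 30)))
        est = shrinkage_correlation(expr)
        adj = inf.infer_rlowpc(expr, N=1)
        ranked_pc = rank_edges(inf.infer_pc(expr))
        a, b = ranked_pc.pairs()[0]
        ia, ib = expr.gene_ids.index(a), expr.gene_ids.index(b)
        assert adj.weights[ia, ib] == pytest.approx(
            abs(est.shrunk_correlation[ia, ib]), abs=1e-12
        )

    def test_two_genes_degenerates_to_pc(self, rng):
        expr = make_expr(rng.standard_normal((2, 25)))
        np.testing.assert_allclose(
            inf.infer_rlowpc(expr, N=5).weights, np.abs(inf.infer_pc(expr).weights),
            atol=1e-12,
        )

    def test_non_retained_edges_never_outrank_retained(self, rng):
        expr = make_expr(rng.standard_normal((8, 40)))
        N = 5
        adj = inf.infer_rlowpc(expr, N=N)
        ranked = rank_edges(adj)
        trimmed = inf.trim_search_space(inf.infer_pc(expr), N)
        retained = set(trimmed.retained_edges)
        head = set(ranked.pairs()[:N])
        assert head == retained

    def test_motif_demotion_beats_plain_correlation(self):
        """Across 20 simulated motif datasets the refinement sends the
        spurious pair's score to near zero, while plain correlation leaves
        it high; the spurious pair also ranks last at least as often."""
        rl_rank_ok = cor_rank_ok = 0
        rl_scores, cor_scores = [], []
        for s in range(20):
            expr = chain_motif_expr(1000 + s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rl = inf.infer_rlowpc(expr, N=3)
                co = inf.infer_cor(expr)
            rl_rank_ok += rank_edges(rl).pairs().index(("X1", "X2")) == 2
            cor_rank_ok += rank_edges(co).pairs().index(("X1", "X2")) == 2
            rl_scores.append(rl.weights[0, 1])
            cor_scores.append(abs(co.weights[0, 1]))
        assert rl_rank_ok >= cor_rank_ok
        assert np.mean(rl_scores) < 0.2
        assert np.mean(cor_scores) > 0.5


class TestPCIT:
    def test_two_genes_keep_absolute_correlation(self, rng):
        expr = make_expr(rng.standard_normal((2, 20)))
        w = inf.infer_pcit(expr).weights
        r = np.corrcoef(expr.values)[0, 1]
        assert w[0, 1] == pytest.approx(abs(r), abs=1e-12)

    def test_matches_exhaustive_triplet_oracle(self, rng):
        """Keep-flags agree with a literal three-nested-loop enumeration
        using the first-order recursion formula."""
        expr = make_expr(rng.standard_normal((6, 40)))
        r = np.corrcoef(expr.values)
        flags = inf.pcit_keep_flags(r)

        def pcor(i, j, k):
            den = np.sqrt((1 - r[i, k] ** 2) * (1 - r[j, k] ** 2))
            return 0.0 if den < 1e-12 else (r[i, j] - r[i, k] * r[j, k]) / den

        n = 6
        expected = np.ones((n, n)) - np.eye(n)
        for x, y, z in itertools.permutations(range(n), 3):
            if x > y:
                continue
            ratios = []
            for (i, j, k) in [(x, y, z), (x, z, y), (y, z, x)]:
                ratios.append(0.0 if abs(r[i, j]) < 1e-12 else pcor(i, j, k) / r[i, j])
            eps = np.mean(ratios)
            if abs(r[x, y]) < abs(eps * r[x, z]) and abs(r[x, y]) < abs(eps * r[y, z]):
                expected[x, y] = expected[y, x] = 0.0
        np.testing.assert_array_equal(flags, expected)

    def test_support_within_correlation_support(self, rng):
        expr = make_expr(rng.standard_normal((7, 30)))
        w = inf.infer_pcit(expr).weights
        r = np.abs(np.corrcoef(expr.values))
        np.fill_diagonal(r, 0)
        assert np.all(w <= r + 1e-12)


class TestARACNE:
    def test_weakest_triplet_edge_removed(self):
        mi = np.array([[0, 0.5, 0.4], [0.5, 0, 0.3], [0.4, 0.3, 0]], dtype=float)
        out = inf.dpi_prune(mi)
        assert out[1, 2] == 0.0
        assert out[0, 1] == 0.5 and out[0, 2] == 0.4

    def test_equal_mi_triangle_survives(self):
        mi = np.full((3, 3), 0.4)
        np.fill_diagonal(mi, 0)
        np.testing.assert_array_equal(inf.dpi_prune(mi), mi)

    def test_matches_brute_force_triplet_oracle(self, rng):
        expr = make_expr(rng.standard_normal((7, 35)))
        mi = np.asarray(mi_from_correlation(np.corrcoef(expr.values)))
        np.fill_diagonal(mi, 0)
        got = inf.infer_aracne(expr).weights
        expected = mi.copy()
        n = 7
        for i, j in itertools.combinations(range(n), 2):
            for k in range(n):
                if k in (i, j):
                    continue
                if mi[i, j] < min(mi[i, k], mi[j, k]):
                    expected[i, j] = expected[j, i] = 0.0
                    break
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_support_within_mi_support(self, rng):
        expr = make_expr(rng.standard_normal((6, 30)))
        w = inf.infer_aracne(expr).weights
        mi = np.asarray(mi_from_correlation(np.corrcoef(expr.values)))
        np.fill_diagonal(mi, 0)
        assert np.all((w > 0) <= (mi > 0))


class TestCLR:
    def test_hand_computed_example(self):
        """MI off-diagonals {12: 0.9, 13: 0.1, 23: 0.1}: both endpoints of
        (1,2) have background mean 0.5 and sample SD 0.5657, so z = 0.7071
        each side and the combined weight is exactly 1."""
        mi = np.array([[0, 0.9, 0.1], [0.9, 0, 0.1], [0.1, 0.1, 0]], dtype=float)
        w = inf.clr_weights(mi)
        assert w[0, 1] == pytest.approx(1.0, abs=5e-5)

    def test_constant_mi_gives_all_zero(self):
        mi = np.where(np.eye(4, dtype=bool), 0.0, 0.3)
        assert np.abs(inf.clr_weights(mi)).max() == 0

    def test_weights_nonnegative(self, rng):
        expr = make_expr(rng.standard_normal((6, 25)))
        assert inf.infer_clr(expr).weights.min() >= 0


class TestMRNET:
    def test_hand_executed_selection(self):
        """Target 3 with MI {13: .5, 23: .4, 12: .3} selects gene 1 at score
        0.5, then gene 2 at 0.4 - 0.3 = 0.1; other passes give (1,3) -> 0.5
        and (2,3) -> 0.4 after max-symmetrisation."""
        mi = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]], dtype=float)
        w = inf.mrnet_weights(mi)
        assert w[0, 2] == pytest.approx(0.5)
        assert w[1, 2] == pytest.approx(0.4)
        assert w[0, 1] == 0.0

    def test_two_genes_weight_is_mi(self, rng):
        expr = make_expr(rng.standard_normal((2, 20)))
        mi = mi_from_correlation(np.corrcoef(expr.values)[0, 1])
        assert inf.infer_mrnet(expr).weights[0, 1] == pytest.approx(mi, abs=1e-12)

    def test_matches_independent_greedy_oracle(self, rng):
        """Re-derive the greedy forward pass with plain loops and compare."""
        mi = np.abs(random_correlation_matrix(6, rng))
        np.fill_diagonal(mi, 0)
        got = inf.mrnet_weights(mi)
        n = 6
        expected = np.zeros((n, n))
        for t in range(n):
            selected = []
            candidates = [j for j in range(n) if j != t]
            while candidates:
                scores = {
                    j: mi[t, j]
                    - (np.mean([mi[j, s] for s in selected]) if selected else 0.0)
                    for j in candidates
                }
                best = max(scores, key=lambda j: (scores[j], -j))
                if scores[best] <= 0:
                    break
                expected[t, best] = max(expected[t, best], scores[best])
                selected.append(best)
                candidates.remove(best)
        expected = np.maximum(expected, expected.T)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestMRNETB:
    def test_two_genes_weight_is_mi(self, rng):
        expr = make_expr(rng.standard_normal((2, 20)))
        mi = mi_from_correlation(np.corrcoef(expr.values)[0, 1])
        assert inf.infer_mrnetb(expr).weights[0, 1] == pytest.approx(mi, abs=1e-12)

    def test_backward_objective_at_least_forward(self, rng):
        """The backward-selected set's objective (mean relevance minus mean
        redundancy) is never below the forward-greedy set's objective."""

        def objective(mi, t, S):
            if not S:
                return 0.0
            rel = np.mean([mi[t, j] for j in S])
            if len(S) < 2:
                return rel
            red = np.mean([mi[i, j] for i, j in itertools.combinations(S, 2)])
            return rel - red

        for seed in range(5):
            r = np.random.default_rng(seed)
            mi = np.abs(random_correlation_matrix(6, r))
            np.fill_diagonal(mi, 0)
            for t in range(6):
                backward = inf._mrnetb_select(mi, t, 6)
                # forward set per the greedy rule
                selected, candidates = [], [j for j in range(6) if j != t]
                while candidates:
                    scores = {
                        j: mi[t, j]
                        - (np.mean([mi[j, s] for s in selected]) if selected else 0.0)
                        for j in candidates
                    }
                    best = max(scores, key=lambda j: (scores[j], -j))
                    if scores[best] <= 0:
                        break
                    selected.append(best)
                    candidates.remove(best)
                assert objective(mi, t, backward) >= objective(mi, t, selected) - 1e-10


class TestRandomBaseline:
    def test_seed_determinism(self):
        a = inf.infer_random(6, seed=7)
        b = inf.infer_random(6, seed=7)
        c = inf.infer_random(6, seed=8)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert not np.array_equal(a.weights, c.weights)


@pytest.mark.parametrize(
    "method", ["cor", "pc", "rlowpc", "pcit", "aracne", "clr", "mrnet", "mrnetb"]
)
class TestMethodContracts:
    def test_output_is_valid_adjacency(self, method, rng):
        expr = make_expr(rng.standard_normal((8, 30)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj = inf.infer(expr, method)
        w = adj.weights
        assert w.shape == (8, 8)
        np.testing.assert_allclose(w, w.T)
        assert np.abs(np.diag(w)).max() == 0
        assert np.isfinite(w).all()

    def test_gene_permutation_equivariance(self, method, rng):
        expr = make_expr(rng.standard_normal((7, 40)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = inf.infer(expr, method).weights
            perm = rng.permutation(7)
            permuted = make_expr(
                expr.values[perm], gene_ids=[expr.gene_ids[p] for p in perm]
            )
            wp = inf.infer(permuted, method).weights
        np.testing.assert_allclose(wp, w[np.ix_(perm, perm)], atol=1e-9)


def test_unknown_method_lists_valid_names(rng):
    expr = make_expr(rng.standard_normal((3, 10)))
    with pytest.raises(ValueError, match="rlowpc"):
        inf.infer(expr, "wavelets")
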