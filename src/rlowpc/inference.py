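"""The benchmarked network constructors.

Nine methods share one contract — :class:`~rlowpc.netio.ExpressionMatrix` in,
:class:`~rlowpc.netio.WeightedAdjacency` out:

========  ==========================================================
rlowpc    relevance low-order partial correlation (two-step refinement)
pc        full-order shrinkage partial correlation
pcit      first-order partial correlation + information-theory trimming
aracne    MI network pruned by the data-processing inequality
clr       MI z-scored against each gene's background distribution
mrnet     forward minimum-redundancy maximum-relevance selection
mrnetb    backward MRMR selection with a replacement sweep
cor       plain Pearson correlation
random    seeded uniform weights (baseline)
========  ==========================================================

MI matrices are the Gaussian surrogate ``-1/2 ln(1 - r^2)`` of the Pearson
correlation, the convention for continuous time-series input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import (
    low_order_pcor,
    mi_from_correlation,
    partial_correlation_matrix,
    pearson_matrix,
    shrinkage_correlation,
)
from .netio import (
    ExpressionMatrix,
    WeightedAdjacency,
    canonical_pair,
    rank_edges,
)

__all__ = [
    "TrimmedNetwork",
    "infer_pc",
    "trim_search_space",
    "neighbour_set",
    "infer_rlowpc",
    "infer_pcit",
    "infer_aracne",
    "infer_clr",
    "infer_mrnet",
    "infer_mrnetb",
    "infer_cor",
    "infer_random",
    "infer",
    "suggested_search_space",
    "METHODS",
]

_TOL = 1e-12


@dataclass
class TrimmedNetwork:
    """The confined search space: the top-N edges of a pre-inferred network.

    ``retained_edges`` are exactly the first ``min(N, n(n-1)/2)`` entries of
    the ranked edge list of the source adjacency; ``source_scores`` maps each
    retained pair to its pre-inference (signed) score.
    """

    retained_edges: list[tuple[str, str]]
    source_scores: dict[tuple[str, str], float]
    N: int


def infer_pc(
    expr: ExpressionMatrix, lambda_override: float | None = None
) -> WeightedAdjacency:
    """Full-order partial correlation network via shrinkage estimation."""
    est = shrinkage_correlation(expr, lambda_override=lambda_override)
    return partial_correlation_matrix(est)


def trim_search_space(pc_adj: WeightedAdjacency, N: int) -> TrimmedNetwork:
    """Keep the top-N ranked edges of ``pc_adj`` as the confined search space."""
    if N < 1:
        raise ValueError("search-space size N must be >= 1")
    ranked = rank_edges(pc_adj)
    head = ranked.head(min(N, len(ranked)))
    edges = list(zip(head.gene_a, head.gene_b))
    return TrimmedNetwork(
        retained_edges=edges,
        source_scores={e: float(s) for e, s in zip(edges, head.score)},
        N=N,
    )


def _trimmed_neighbours(trimmed: TrimmedNetwork) -> dict[str, set[str]]:
    nbrs: dict[str, set[str]] = {}
    for a, b in trimmed.retained_edges:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)
    return nbrs


def neighbour_set(
    trimmed: TrimmedNetwork, i: str, j: str, mode: str = "union"
) -> set[str]:
    """Immediate neighbours of the pair (i, j) within the trimmed graph.

    ``union`` mode returns ``(N(i) | N(j)) \\ {i, j}``; ``shared`` mode
    returns ``(N(i) & N(j)) \\ {i, j}``. The edge (i, j) itself never
    contributes (so j is not a neighbour of i through it).
    """
    if mode not in ("union", "shared"):
        raise ValueError(f"mode must be 'union' or 'shared', got {mode!r}")
    nbrs = _trimmed_neighbours(trimmed)
    ni = nbrs.get(i, set()) - {i, j}
    nj = nbrs.get(j, set()) - {i, j}
    return (ni | nj) if mode == "union" else (ni & nj)


def infer_rlowpc(
    expr: ExpressionMatrix,
    N: int | None = None,
    mode: str = "shared",
    max_q: int | None = None,
    lambda_override: float | None = None,
    return_signed: bool = False,
) -> WeightedAdjacency | tuple[WeightedAdjacency, dict[tuple[str, str], float]]:
    """Relevance low-order partial correlation network.

    The two-step refinement: (1) infer a full shrinkage partial-correlation
    network; (2) keep only its top-N edges as the search space; (3) for each
    retained edge (i, j) recompute the partial correlation conditioning only
    on the pair's immediate neighbours inside the trimmed graph (capped at
    the ``max_q`` strongest); (4) carry ``|refined score|`` on retained edges
    and scale the original scores of non-retained edges strictly below every
    retained weight, so the refinement re-orders the head of the ranking
    without discarding the tail.

    Parameters
    ----------
    N
        Search-space size (number of retained edges). Defaults to
        :func:`suggested_search_space` of the gene count.
    mode
        ``shared`` (default) conditions on the pair's common neighbours
        only — the set the method is named for; ``union`` conditions on
        neighbours of either endpoint.
    max_q
        Cap on the conditioning-set size; defaults to ``n_samples - 4`` so
        the conditioned submatrix stays well-posed. Neighbours are dropped
        weakest-first by the pre-inference |score| of their retained edges
        incident to the pair.
    return_signed
        Also return the signed refined scores of the retained edges.
    """
    if N is None:
        N = suggested_search_space(expr.n_genes)
    if max_q is None:
        max_q = max(1, expr.n_samples - 4)
    if max_q < 1:
        raise ValueError("max_q must be >= 1")

    est = shrinkage_correlation(expr, lambda_override=lambda_override)
    pc = partial_correlation_matrix(est)
    trimmed = trim_search_space(pc, N)
    R = est.shrunk_correlation
    pos = {g: k for k, g in enumerate(est.gene_ids)}
    nbrs = _trimmed_neighbours(trimmed)

    n = expr.n_genes
    refined = np.zeros((n, n))
    signed: dict[tuple[str, str], float] = {}
    retained_mask = np.zeros((n, n), dtype=bool)

    def _edge_strength(q: str, i: str, j: str) -> float:
        s = 0.0
        for other in (i, j):
            e = canonical_pair(q, other)
            if e in trimmed.source_scores:
                s = max(s, abs(trimmed.source_scores[e]))
        return s

    for a, b in trimmed.retained_edges:
        Q = neighbour_set(trimmed, a, b, mode=mode)
        if len(Q) > max_q:
            Q = set(sorted(Q, key=lambda q: (-_edge_strength(q, a, b), q))[:max_q])
        val = low_order_pcor(R, pos[a], pos[b], [pos[q] for q in sorted(Q)])
        ia, ib = pos[a], pos[b]
        refined[ia, ib] = refined[ib, ia] = abs(val)
        retained_mask[ia, ib] = retained_mask[ib, ia] = True
        signed[(a, b)] = val
    del nbrs

    # non-retained edges: keep original PC scores, scaled strictly below the
    # retained block so the tail order is preserved but never outranks the head
    non_mask = ~retained_mask
    np.fill_diagonal(non_mask, False)
    if non_mask.any():
        abs_pc = np.abs(pc.weights)
        max_non = abs_pc[non_mask].max()
        retained_vals = refined[retained_mask]
        min_ret = retained_vals.min() if retained_vals.size else 0.0
        if max_non <= _TOL or min_ret <= _TOL:
            eps = 0.0
        else:
            eps = min_ret / (2.0 * max_non)
        refined[non_mask] = eps * abs_pc[non_mask]

    adj = WeightedAdjacency(gene_ids=list(expr.gene_ids), weights=refined)
    return (adj, signed) if return_signed else adj


def infer_pcit(expr: ExpressionMatrix) -> WeightedAdjacency:
    """Partial correlation with information theory (PCIT).

    For every gene triplet (x, y, z) the three first-order partial
    correlations are computed; the trio tolerance is the mean of the three
    ratios (first-order partial / corresponding marginal). An edge (x, y) is
    eliminated if for some third gene z both ``|r_xy| < |eps * r_xz|`` and
    ``|r_xy| < |eps * r_yz|``. Surviving edges carry ``|r|`` (the Boolean
    keep-flag weighting the Pearson correlation network).
    """
    if expr.n_genes < 3:
        adj = pearson_matrix(expr)
        adj.weights = np.abs(adj.weights)
        np.fill_diagonal(adj.weights, 0.0)
        return WeightedAdjacency(gene_ids=adj.gene_ids, weights=adj.weights)
    r = pearson_matrix(expr).weights
    np.fill_diagonal(r, 1.0)
    keep = pcit_keep_flags(r)
    w = keep * np.abs(r)
    np.fill_diagonal(w, 0.0)
    return WeightedAdjacency(gene_ids=list(expr.gene_ids), weights=w)


def _first_order_pcor_cube(r: np.ndarray) -> np.ndarray:
    """``P[x, y, z]`` = partial correlation of (x, y) given z, broadcast."""
    rxz = r[:, None, :]
    rzy = r[None, :, :]
    denom2 = (1.0 - rxz**2) * (1.0 - rzy**2)
    denom = np.sqrt(np.clip(denom2, 0.0, None))
    num = r[:, :, None] - rxz * rzy
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(denom > _TOL, num / np.where(denom > _TOL, denom, 1.0), 0.0)
    return P


def pcit_keep_flags(r: np.ndarray) -> np.ndarray:
    n = len(r)
    P = _first_order_pcor_cube(r)  # P[x,y,z]
    absr = np.abs(r)

    # ratio[x,y,z] = pcor(x,y|z) / r_xy, guarded at tiny denominators
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            absr[:, :, None] > _TOL, P / np.where(np.abs(r) > _TOL, r, 1.0)[:, :, None], 0.0
        )
    # eps[x,y,z] = mean of the trio's three ratios
    eps = (ratio + np.transpose(ratio, (0, 2, 1)) + np.transpose(ratio, (2, 1, 0))) / 3.0

    keep = np.ones((n, n), dtype=bool)
    idx = np.arange(n)
    # eliminate (x,y) if exists z (distinct) with |r_xy| < |eps*r_xz| and |r_xy| < |eps*r_yz|
    cond = (absr[:, :, None] < np.abs(eps * r[:, None, :])) & (
        absr[:, :, None] < np.abs(eps * r.T[None, :, :])
    )
    cond[idx, :, idx] = False
    cond[:, idx, idx] = False
    cond[idx, idx, :] = False
    eliminated = cond.any(axis=2)
    keep &= ~(eliminated | eliminated.T)
    np.fill_diagonal(keep, False)
    return keep.astype(float)


def infer_aracne(expr: ExpressionMatrix, dpi_eps: float = 0.0) -> WeightedAdjacency:
    """ARACNE: mutual-information network pruned by the data-processing
    inequality.

    For every triplet the weakest association is presumed indirect: edge
    (i, j) is zeroed when some third gene k satisfies
    ``MI_ij < min(MI_ik, MI_jk) - dpi_eps`` (strict inequality, so equal-MI
    triangles survive at ``dpi_eps = 0``). Triplets are evaluated
    simultaneously on the unpruned matrix.
    """
    if dpi_eps < 0:
        raise ValueError("dpi_eps must be non-negative")
    r = pearson_matrix(expr).weights
    mi = np.asarray(mi_from_correlation(r))
    np.fill_diagonal(mi, 0.0)
    return WeightedAdjacency(
        gene_ids=list(expr.gene_ids), weights=dpi_prune(mi, dpi_eps)
    )


def dpi_prune(mi: np.ndarray, dpi_eps: float = 0.0) -> np.ndarray:
    """Apply the data-processing inequality to an MI matrix.

    Edge (i, j) is zeroed when ``MI_ij < min(MI_ik, MI_jk) - dpi_eps`` for
    some k; all triplets are judged on the unpruned input simultaneously.
    """
    mi = np.array(mi, dtype=float)
    np.fill_diagonal(mi, 0.0)
    n = len(mi)
    if n >= 3:
        weakest = np.minimum(mi[:, None, :], mi[None, :, :])  # [i,j,k]
        cond = mi[:, :, None] < (weakest - dpi_eps)
        idx = np.arange(n)
        cond[idx, :, idx] = False
        cond[:, idx, idx] = False
        cond[idx, idx, :] = False
        removed = cond.any(axis=2)
        mi = np.where(removed | removed.T, 0.0, mi)
    np.fill_diagonal(mi, 0.0)
    return mi


def infer_clr(expr: ExpressionMatrix) -> WeightedAdjacency:
    """Context likelihood of relatedness.

    Each MI value is z-scored against the background distribution (mean and
    sample standard deviation) of both genes' off-diagonal MI values, with
    negative z clipped to 0; the edge weight is the Stouffer-like combination
    ``sqrt(z_i^2 + z_j^2)``. A zero background SD yields z = 0.
    """
    r = pearson_matrix(expr).weights
    mi = np.asarray(mi_from_correlation(r))
    np.fill_diagonal(mi, 0.0)
    return WeightedAdjacency(gene_ids=list(expr.gene_ids), weights=clr_weights(mi))


def clr_weights(mi: np.ndarray) -> np.ndarray:
    """CLR z-score combination of an MI matrix.

    Per-gene background mean and sample SD are taken over the off-diagonal
    MI values; negative z clip to 0; a zero SD yields z = 0.
    """
    mi = np.array(mi, dtype=float)
    np.fill_diagonal(mi, 0.0)
    n = len(mi)
    off = ~np.eye(n, dtype=bool)
    mu = np.array([mi[i, off[i]].mean() for i in range(n)])
    sd = np.array([mi[i, off[i]].std(ddof=1) if n > 2 else 0.0 for i in range(n)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            sd[:, None] > _TOL,
            (mi - mu[:, None]) / np.where(sd[:, None] > _TOL, sd[:, None], 1.0),
            0.0,
        )
    z = np.clip(z, 0.0, None)
    w = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(w, 0.0)
    return w


def infer_mrnet(expr: ExpressionMatrix) -> WeightedAdjacency:
    """MRNET: greedy forward minimum-redundancy maximum-relevance selection.

    For each target gene t, genes are added one at a time maximising
    ``s_j = MI(t, j) - mean MI(j, selected)`` until the best score drops to
    0 or below; the pair weight is the score at selection, symmetrised by
    the maximum over the two target passes.
    """
    r = pearson_matrix(expr).weights
    mi = np.asarray(mi_from_correlation(r))
    np.fill_diagonal(mi, 0.0)
    return WeightedAdjacency(gene_ids=list(expr.gene_ids), weights=mrnet_weights(mi))


def mrnet_weights(mi: np.ndarray) -> np.ndarray:
    """Forward-MRMR pair weights from an MI matrix (see :func:`infer_mrnet`)."""
    mi = np.array(mi, dtype=float)
    np.fill_diagonal(mi, 0.0)
    n = len(mi)
    w = np.zeros((n, n))
    for t in range(n):
        candidates = np.array([j for j in range(n) if j != t])
        rel = mi[t, candidates]
        red_sum = np.zeros(len(candidates))
        selected_mask = np.zeros(len(candidates), dtype=bool)
        n_sel = 0
        while not selected_mask.all():
            scores = rel - np.where(n_sel > 0, red_sum / max(n_sel, 1), 0.0)
            scores = np.where(selected_mask, -np.inf, scores)
            best = int(np.argmax(scores))
            if scores[best] <= 0.0:
                break
            j = int(candidates[best])
            w[t, j] = max(w[t, j], scores[best])
            selected_mask[best] = True
            n_sel += 1
            red_sum += mi[candidates, j]
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return w


def _mrmr_objective(mi: np.ndarray, target: int, selected: list[int]) -> float:
    """Mean relevance to the target minus mean pairwise redundancy within."""
    if not selected:
        return 0.0
    rel = float(mi[target, selected].mean())
    if len(selected) < 2:
        return rel
    sub = mi[np.ix_(selected, selected)]
    m = len(selected)
    red = float((sub.sum() - np.trace(sub)) / (m * (m - 1)))
    return rel - red


def _mrnetb_select(mi: np.ndarray, t: int, n: int) -> list[int]:
    """Backward MRMR selection for one target, with one replacement sweep.

    Sums are maintained incrementally (relevance sum, within-set redundancy
    sum, and per-gene column sums against the selected set) so each
    elimination or swap evaluation is O(n).
    """
    in_set = np.ones(n, dtype=bool)
    in_set[t] = False
    m = int(in_set.sum())
    rel_sum = float(mi[t, in_set].sum())
    colsum = mi[:, in_set].sum(axis=1)  # sum of MI to the selected set
    red_sum = float(colsum[in_set].sum()) / 2.0

    def objective(m_: int, rel_: float, red_: float) -> float:
        if m_ == 0:
            return 0.0
        rel_mean = rel_ / m_
        if m_ < 2:
            return rel_mean
        return rel_mean - red_ / (m_ * (m_ - 1) / 2.0)

    obj = objective(m, rel_sum, red_sum)

    # backward elimination: remove the gene whose removal best improves
    while m > 1:
        sel = np.flatnonzero(in_set)
        rel_rm = rel_sum - mi[t, sel]
        red_rm = red_sum - colsum[sel]
        m_rm = m - 1
        rel_mean = rel_rm / m_rm
        if m_rm >= 2:
            objs = rel_mean - red_rm / (m_rm * (m_rm - 1) / 2.0)
        else:
            objs = rel_mean
        best = int(np.argmax(objs))
        if objs[best] <= obj + _TOL:
            break
        j = int(sel[best])
        in_set[j] = False
        rel_sum = float(rel_rm[best])
        red_sum = float(red_rm[best])
        colsum = colsum - mi[:, j]
        m -= 1
        obj = float(objs[best])

    # one sequential replacement sweep
    for j in list(np.flatnonzero(in_set)):
        if not in_set[j]:
            continue
        out = np.flatnonzero(~in_set)
        out = out[out != t]
        if len(out) == 0:
            break
        rel_sw = rel_sum - mi[t, j] + mi[t, out]
        red_sw = red_sum - colsum[j] + (colsum[out] - mi[out, j])
        if m >= 2:
            objs = rel_sw / m - red_sw / (m * (m - 1) / 2.0)
        else:
            objs = rel_sw / m
        best = int(np.argmax(objs))
        if objs[best] > obj + _TOL:
            k = int(out[best])
            in_set[j] = False
            in_set[k] = True
            rel_sum = float(rel_sw[best])
            red_sum = float(red_sw[best])
            colsum = colsum - mi[:, j] + mi[:, k]
            obj = float(objs[best])
    return list(np.flatnonzero(in_set))


def infer_mrnetb(expr: ExpressionMatrix) -> WeightedAdjacency:
    """MRNETB: backward MRMR selection with one sequential-replacement sweep.

    Per target, all other genes start selected; the gene whose removal most
    improves the objective (mean relevance minus mean redundancy) is removed
    while improvement exceeds 1e-12; a single replacement sweep then tries
    swapping each selected gene with each unselected one. Weights are the
    final within-set MRMR scores, symmetrised by max.
    """
    r = pearson_matrix(expr).weights
    mi = np.asarray(mi_from_correlation(r))
    np.fill_diagonal(mi, 0.0)
    return WeightedAdjacency(gene_ids=list(expr.gene_ids), weights=mrnetb_weights(mi))


def mrnetb_weights(mi: np.ndarray) -> np.ndarray:
    """Backward-MRMR pair weights from an MI matrix (see :func:`infer_mrnetb`)."""
    mi = np.array(mi, dtype=float)
    np.fill_diagonal(mi, 0.0)
    n = len(mi)
    w = np.zeros((n, n))
    for t in range(n):
        sel = sorted(_mrnetb_select(mi, t, n))
        for j in sel:
            others = [k for k in sel if k != j]
            score = mi[t, j] - (mi[j, others].mean() if others else 0.0)
            w[t, j] = max(w[t, j], score)
    w = np.maximum(w, w.T)
    # MRMR scores can be negative for weak members; clip for a ranking weight
    w = np.clip(w, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return w


def infer_cor(expr: ExpressionMatrix) -> WeightedAdjacency:
    """Plain Pearson correlation network."""
    return pearson_matrix(expr)


def infer_random(n_genes: int, seed: int, gene_ids: list[str] | None = None) -> WeightedAdjacency:
    """Random baseline: i.i.d. uniform(0, 1) weights on the upper triangle."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n_genes, n_genes))
    iu = np.triu_indices(n_genes, k=1)
    w[iu] = rng.uniform(size=len(iu[0]))
    w = w + w.T
    if gene_ids is None:
        gene_ids = [f"G{i + 1}" for i in range(n_genes)]
    return WeightedAdjacency(gene_ids=list(gene_ids), weights=w)


_SIZE_MAP_X = np.array([100.0, 500.0, 1000.0, 2000.0, 3000.0])
_SIZE_MAP_Y = np.array([1500.0, 2000.0, 3000.0, 5000.0, 8000.0])


def suggested_search_space(n_genes: int) -> int:
    """Suggested RLowPC search-space size for a given network size.

    Follows the mapping {100: 1500, 500: 2000, 1000: 3000, 2000: 5000,
    3000: 8000}, interpolating linearly in between and clamping above;
    below 100 genes the retained *fraction* of pairs is held at the
    100-gene ratio (1500/4950), so small networks are trimmed
    proportionally instead of keeping every pair. Never exceeds the total
    number of pairs.
    """
    pairs = n_genes * (n_genes - 1) // 2
    if n_genes < 100:
        N = int(round(1500.0 / 4950.0 * pairs))
    else:
        N = int(round(float(np.interp(n_genes, _SIZE_MAP_X, _SIZE_MAP_Y))))
    return max(1, min(N, pairs))


METHODS = (
    "cor",
    "pc",
    "rlowpc",
    "pcit",
    "aracne",
    "clr",
    "mrnet",
    "mrnetb",
    "random",
)


def infer(
    expr: ExpressionMatrix,
    method: str,
    seed: int = 0,
    **kwargs,
) -> WeightedAdjacency:
    """Dispatch to a method by name (see :data:`METHODS`)."""
    if method == "cor":
        return infer_cor(expr)
    if method == "pc":
        return infer_pc(expr, **kwargs)
    if method == "rlowpc":
        return infer_rlowpc(expr, **kwargs)
    if method == "pcit":
        return infer_pcit(expr)
    if method == "aracne":
        return infer_aracne(expr, **kwargs)
    if method == "clr":
        return infer_clr(expr)
    if method == "mrnet":
        return infer_mrnet(expr)
    if method == "mrnetb":
        return infer_mrnetb(expr)
    if method == "random":
        return infer_random(expr.n_genes, seed=seed, gene_ids=list(expr.gene_ids))
    raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
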