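"""Scoring ranked edge predictions against a gold standard.

All evaluation is over undirected, self-loop-free gene pairs. The central
quantities are confusion counts at a rank cutoff k, precision within rank
windows (default 1-100, 101-500, 501-1000), and the partial areas under the
precision-recall and ROC curves restricted to the top-K predictions
(default K = 1000) — in sparse networks the full-curve areas are dominated
by the uninformative tail, so only the head of the ranking is scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import cluster, spatial, stats

from .association import pearson_matrix
from .netio import (
    ExpressionMatrix,
    RankedEdgeList,
    ReferenceNetwork,
    canonical_pair,
    rank_edges,
)

__all__ = [
    "ConfusionAtK",
    "PRCurve",
    "confusion_at_k",
    "precision_groups",
    "paupr",
    "pauroc",
    "compare_methods",
    "cluster_modules",
    "modulewise_evaluate",
    "GREY",
]

#: reserved label for genes unassigned to any co-expression module
GREY = "grey"


@dataclass
class ConfusionAtK:
    """Confusion counts over the pair universe at rank cutoff k.

    Invariants: ``TP + FP = k``; ``TP + FN`` equals the number of true
    undirected edges; the four counts sum to ``n(n-1)/2``.
    """

    k: int
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / self.k if self.k else 0.0

    @property
    def recall(self) -> float:
        pos = self.TP + self.FN
        return self.TP / pos if pos else 0.0


@dataclass
class PRCurve:
    """Per-rank precision/recall points and the partial area under them."""

    k: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    paupr: float


def _true_mask(ranked: RankedEdgeList, ref: ReferenceNetwork) -> np.ndarray:
    """Boolean mask over the ranking marking true undirected edges.

    Errors if the gene universes differ (evaluation is only meaningful on a
    shared universe).
    """
    ranked_genes = ranked.genes
    ref_genes = set(ref.nodes)
    if ranked_genes != ref_genes:
        only_ranked = sorted(ranked_genes - ref_genes)[:10]
        only_ref = sorted(ref_genes - ranked_genes)[:10]
        raise ValueError(
            "gene universes differ between ranking and reference "
            f"(ranking-only: {only_ranked}; reference-only: {only_ref})"
        )
    truth = {canonical_pair(a, b) for a, b in ref.undirected_edges}
    return np.fromiter(
        (canonical_pair(a, b) in truth for a, b in zip(ranked.gene_a, ranked.gene_b)),
        dtype=bool,
        count=len(ranked),
    )


def confusion_at_k(
    ranked: RankedEdgeList, ref: ReferenceNetwork, k: int
) -> ConfusionAtK:
    """Confusion counts comparing the top-k ranked pairs with the reference."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k = {k} out of range 1..{len(ranked)}")
    mask = _true_mask(ranked, ref)
    total = len(ranked)
    n_true = int(mask.sum())
    tp = int(mask[:k].sum())
    fp = k - tp
    fn = n_true - tp
    tn = total - k - fn
    return ConfusionAtK(k=k, TP=tp, FP=fp, TN=tn, FN=fn)


def precision_groups(
    ranked: RankedEdgeList,
    ref: ReferenceNetwork,
    bounds: list[tuple[int, int]] = ((1, 100), (101, 500), (501, 1000)),
) -> dict[tuple[int, int], float]:
    """Precision within disjoint rank windows (1-based, inclusive).

    Windows extending past the ranking are truncated with a warning;
    precision is TPs in the window divided by the (truncated) window width.
    """
    prev_end = 0
    for lo, hi in bounds:
        if lo <= prev_end or hi < lo:
            raise ValueError("rank intervals must be disjoint and ordered")
        prev_end = hi
    mask = _true_mask(ranked, ref)
    out: dict[tuple[int, int], float] = {}
    for lo, hi in bounds:
        hi_eff = min(hi, len(ranked))
        if hi_eff < hi:
            warnings.warn(
                f"window ({lo}, {hi}) truncated to ({lo}, {hi_eff}): "
                "ranking is shorter",
                stacklevel=2,
            )
        if lo > len(ranked):
            out[(lo, hi)] = float("nan")
            continue
        width = hi_eff - lo + 1
        out[(lo, hi)] = float(mask[lo - 1 : hi_eff].sum()) / width
    return out


def paupr(ranked: RankedEdgeList, ref: ReferenceNetwork, K: int = 1000) -> PRCurve:
    """Partial area under the precision-recall curve over ranks 1..K.

    Step integration: each true positive at rank k contributes
    ``precision(k) * delta_recall``; the curve starts at recall 0 with no
    anchor precision point. K is clipped to the ranking length.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n_true = len(ref.undirected_edges)
    if n_true == 0:
        raise ValueError("reference network has no true edges; recall is undefined")
    K = min(K, len(ranked))
    mask = _true_mask(ranked, ref)[:K]
    ks = np.arange(1, K + 1)
    tps = np.cumsum(mask)
    precision = tps / ks
    recall = tps / n_true
    area = float(np.sum(precision[mask]) / n_true)
    return PRCurve(k=ks, precision=precision, recall=recall, paupr=area)


def pauroc(ranked: RankedEdgeList, ref: ReferenceNetwork, K: int = 1000) -> float:
    """Partial area under the ROC curve over ranks 1..K (trapezoidal).

    FPR uses the total negatives of the full pair universe as denominator.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n_true = len(ref.undirected_edges)
    if n_true == 0:
        raise ValueError("reference network has no true edges; TPR is undefined")
    K = min(K, len(ranked))
    mask = _true_mask(ranked, ref)
    negatives = len(ranked) - int(mask.sum())
    if negatives == 0:
        raise ValueError("reference network has no negatives; FPR is undefined")
    mask = mask[:K]
    tpr = np.concatenate([[0.0], np.cumsum(mask) / n_true])
    fpr = np.concatenate([[0.0], np.cumsum(~mask) / negatives])
    return float(np.trapezoid(tpr, fpr))


def compare_methods(
    pauprs_a: list[float], pauprs_b: list[float]
) -> tuple[float, float]:
    """Two-sided paired Student t-test across repeated simulation runs.

    Returns ``(t, p)``. Identical vectors (all differences zero) return
    ``(0.0, 1.0)`` exactly; a constant non-zero difference has no variance
    to test against and raises.
    """
    a = np.asarray(pauprs_a, dtype=float)
    b = np.asarray(pauprs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(float(np.abs(d).max()), 1.0):
        if d.mean() == 0.0:
            return 0.0, 1.0
        raise ValueError(
            "paired differences are constant and non-zero; the t statistic "
            "is undefined (zero variance)"
        )
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def cluster_modules(
    expr: ExpressionMatrix, min_size: int = 10
) -> tuple[dict[str, str], set[str]]:
    """Partition genes into co-expressed modules by hierarchical clustering.

    Average-linkage clustering on the distance ``1 - |r|`` (Pearson), with
    the tree cut at the height that maximises the number of modules of size
    at least ``min_size`` (smallest such height on ties). Genes falling in
    clusters below ``min_size`` are left unassigned and labelled ``grey``.

    Returns
    -------
    (assignment, grey)
        ``assignment`` maps gene -> module label (``"M1"``, ``"M2"``, ...,
        or ``"grey"``); ``grey`` is the set of unassigned genes.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    genes = list(expr.gene_ids)
    n = len(genes)
    if n < 2:
        return {g: GREY for g in genes}, set(genes)
    r = pearson_matrix(expr).weights
    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    condensed = spatial.distance.squareform(dist, checks=False)
    Z = cluster.hierarchy.linkage(condensed, method="average")
    heights = np.unique(Z[:, 2])
    cuts = np.unique(np.concatenate([[0.0], heights + 1e-12]))
    # choose the cut maximising the number of modules of size >= min_size,
    # breaking ties by how many genes those modules cover (fewest grey)
    best_labels, best_score = None, (-1, -1)
    for h in cuts:
        labels = cluster.hierarchy.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)
        big = sizes[1:] >= min_size
        score = (int(big.sum()), int(sizes[1:][big].sum()))
        if score > best_score:
            best_labels, best_score = labels, score
    labels = best_labels
    sizes = np.bincount(labels)
    assignment: dict[str, str] = {}
    grey: set[str] = set()
    relabel: dict[int, str] = {}
    for g, lab in zip(genes, labels):
        if sizes[lab] < min_size:
            assignment[g] = GREY
            grey.add(g)
        else:
            if lab not in relabel:
                relabel[lab] = f"M{len(relabel) + 1}"
            assignment[g] = relabel[lab]
    return assignment, grey


def modulewise_evaluate(
    expr: ExpressionMatrix,
    ref: ReferenceNetwork,
    method: str = "cor",
    K: int = 1000,
    min_size: int = 10,
    partition: dict[str, str] | None = None,
    seed: int = 0,
    **method_kwargs,
) -> float:
    """Average pAUPR across co-expressed modules (grey genes excluded).

    Inference runs independently inside each module against the reference
    sub-network induced on the module's genes; modules without a true edge
    are excluded from the average. A precomputed ``partition`` (gene ->
    label, ``grey`` reserved) may be supplied instead of clustering.
    """
    from . import inference as _inf  # local import to avoid a cycle

    if partition is None:
        partition, _ = cluster_modules(expr, min_size=min_size)
    modules: dict[str, list[str]] = {}
    for g in expr.gene_ids:
        lab = partition.get(g, GREY)
        if lab != GREY:
            modules.setdefault(lab, []).append(g)
    values = []
    for lab, genes in sorted(modules.items()):
        if len(genes) < 2:
            continue
        sub_ref = ref.subnetwork(genes)
        if not sub_ref.undirected_edges:
            continue
        sub_expr = expr.subset(genes)
        adj = _inf.infer(sub_expr, method, seed=seed, **method_kwargs)
        ranked = rank_edges(adj)
        k_eff = min(K, len(ranked))
        values.append(paupr(ranked, sub_ref, K=k_eff).paupr)
    if not values:
        raise ValueError("no module contains a true edge; nothing to average")
    return float(np.mean(values))
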