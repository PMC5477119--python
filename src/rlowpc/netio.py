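"""Core data containers and text I/O.

Expression matrices travel as tab-separated text (genes as rows, first column
``gene_id``, one column per sample); reference networks as 2- or 3-column
edge lists in the DREAM gold-standard convention (``regulator<TAB>target<TAB>1``).
Every inference method in :mod:`rlowpc.inference` consumes an
:class:`ExpressionMatrix` and returns a :class:`WeightedAdjacency`; evaluation
consumes the deterministic :class:`RankedEdgeList` derived from it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ReferenceNetwork",
    "WeightedAdjacency",
    "RankedEdgeList",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "write_ranked_edges",
    "network_density",
    "rank_edges",
    "embed_adjacency",
    "canonical_pair",
]

_SAMPLE_RE = re.compile(r"^t(\d+)_r(\d+)$")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered gene pair in canonical (lexicographic) order."""
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix.

    Parameters
    ----------
    gene_ids
        Unique, ordered gene identifiers (one per row of ``values``).
    values
        Array of shape ``(n_genes, n_samples)``; all entries finite.
    sample_ids
        Column labels. For simulator output these follow the ``t<k>_r<j>``
        dialect, from which per-sample time point and replicate metadata is
        parsed automatically.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str] | None = None
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        dup = pd.Index(self.gene_ids).duplicated()
        if dup.any():
            bad = sorted({g for g, d in zip(self.gene_ids, dup) if d})
            raise ValueError(f"duplicate gene ids: {', '.join(bad)}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.n_samples < 3:
            raise ValueError("at least 3 samples are required")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample id count does not match column count")
        if self.sample_meta is None:
            self.sample_meta = _parse_sample_meta(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_time_metadata(self) -> bool:
        return self.sample_meta is not None

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        """Row-subset keeping the given genes in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing)}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            values=self.values[rows],
            sample_ids=list(self.sample_ids),
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _parse_sample_meta(sample_ids: list[str]) -> pd.DataFrame | None:
    """Parse ``t<k>_r<j>`` sample labels into (time_point, replicate) metadata.

    Any label outside the dialect leaves metadata absent (inference never
    needs it; only the ANOVA prefilter does).
    """
    rows = []
    for sid in sample_ids:
        m = _SAMPLE_RE.match(sid)
        if m is None:
            return None
        rows.append((int(m.group(1)), int(m.group(2))))
    return pd.DataFrame(rows, columns=["time_point", "replicate"], index=sample_ids)


@dataclass
class ReferenceNetwork:
    """Directed gold-standard edge set with a derived undirected view.

    Self-loops are removed at construction and the undirected view collapses
    reciprocal directed edges, matching the evaluation convention in which all
    scoring is over undirected, self-loop-free gene pairs.
    """

    nodes: list[str]
    directed_edges: set[tuple[str, str]]
    undirected_edges: set[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = list(dict.fromkeys(self.nodes))
        node_set = set(self.nodes)
        for a, b in self.directed_edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
        self.directed_edges = {(a, b) for a, b in self.directed_edges if a != b}
        self.undirected_edges = {canonical_pair(a, b) for a, b in self.directed_edges}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def density(self) -> float:
        return network_density(self.n_nodes, len(self.undirected_edges))

    def subnetwork(self, genes: list[str]) -> "ReferenceNetwork":
        """Induced sub-network on the given genes."""
        keep = set(genes)
        return ReferenceNetwork(
            nodes=[g for g in genes if g in keep],
            directed_edges={
                (a, b) for a, b in self.directed_edges if a in keep and b in keep
            },
        )


@dataclass
class WeightedAdjacency:
    """Symmetric, zero-diagonal gene x gene score matrix.

    The common output contract of every inference method: ``weights[i, j]``
    scores the unordered pair, the diagonal is identically zero, and all
    entries are finite.
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape} != ({n}, {n})")
        if not np.isfinite(self.weights).all():
            raise ValueError("adjacency contains non-finite weights")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("adjacency is not symmetric")
        if np.abs(np.diag(self.weights)).max(initial=0.0) > 1e-12:
            raise ValueError("adjacency diagonal is not zero")
        # exact symmetry/zero-diagonal after validation
        self.weights = (self.weights + self.weights.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class RankedEdgeList:
    """Deterministic descending ordering of all unordered gene pairs.

    Pairs are stored canonically (``gene_a < gene_b``), ordered by descending
    ``|score|`` with lexicographic (gene_a, gene_b) tie-break; the signed
    score is preserved.
    """

    gene_a: np.ndarray
    gene_b: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.gene_a) == len(self.gene_b) == len(self.score)):
            raise ValueError("ragged ranked edge list")

    def __len__(self) -> int:
        return len(self.score)

    def __iter__(self):
        return iter(zip(self.gene_a, self.gene_b, self.score))

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.gene_a, self.gene_b))

    @property
    def genes(self) -> set[str]:
        return set(self.gene_a) | set(self.gene_b)

    def head(self, k: int) -> "RankedEdgeList":
        return RankedEdgeList(self.gene_a[:k], self.gene_b[:k], self.score[:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": self.gene_a,
                "gene_b": self.gene_b,
                "score": self.score,
                "abs_score": np.abs(self.score),
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    The file must have a header row; the first column holds gene identifiers.
    Duplicate gene ids or non-numeric cells are hard errors (the offending
    gene / cell is named).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene ids in {path.name}: {', '.join(map(str, dup))}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric value in {path.name} at gene {gene!r}, column {col!r}"
            ) from None
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        values=values,
        sample_ids=[str(c) for c in df.columns],
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV (first column header ``gene_id``)."""
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_edge_list(path: str | Path) -> ReferenceNetwork:
    """Read a DREAM-convention edge list (regulator, target[, 0/1]).

    Rows whose third column is 0 are dropped; self-loops are removed; the
    undirected view is derived at load. Malformed rows raise with the line
    number.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path.name}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise ValueError(f"{path.name}:{lineno}: empty gene identifier")
            if len(parts) == 3:
                flag = parts[2].strip()
                if flag not in ("0", "1"):
                    raise ValueError(
                        f"{path.name}:{lineno}: third column must be 0 or 1, got {flag!r}"
                    )
                if flag == "0":
                    continue
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    nodes.append(g)
            edges.add((a, b))
    return ReferenceNetwork(nodes=nodes, directed_edges=edges)


def write_edge_list(net: ReferenceNetwork, path: str | Path) -> None:
    """Write the directed edges as a 3-column TSV with indicator 1."""
    with open(path, "w") as fh:
        for a, b in sorted(net.directed_edges):
            fh.write(f"{a}\t{b}\t1\n")


def write_ranked_edges(ranked: RankedEdgeList, path: str | Path) -> None:
    """Write a ranked edge list as TSV with signed and absolute score columns."""
    ranked.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# elementary network arithmetic
# ---------------------------------------------------------------------------


def network_density(n_genes: int, n_undirected_edges: int) -> float:
    """True edges divided by all possible undirected edges, n(n-1)/2."""
    if n_genes < 2:
        raise ValueError("density needs at least 2 genes")
    if n_undirected_edges < 0:
        raise ValueError("negative edge count")
    max_edges = n_genes * (n_genes - 1) // 2
    if n_undirected_edges > max_edges:
        raise ValueError(
            f"{n_undirected_edges} edges exceed the maximum {max_edges} "
            f"for {n_genes} genes"
        )
    return n_undirected_edges / max_edges


def embed_adjacency(adj: WeightedAdjacency, gene_ids: list[str]) -> WeightedAdjacency:
    """Zero-pad an adjacency into a larger gene universe.

    Genes absent from ``adj`` get all-zero scores, so after ranking they sit
    at the bottom of the list. Used to score a network inferred on a
    filtered gene subset against a full-size reference.
    """
    missing = set(adj.gene_ids) - set(gene_ids)
    if missing:
        raise ValueError(f"adjacency genes not in target universe: {sorted(missing)[:5]}")
    n = len(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    W = np.zeros((n, n))
    idx = [pos[g] for g in adj.gene_ids]
    W[np.ix_(idx, idx)] = adj.weights
    return WeightedAdjacency(gene_ids=list(gene_ids), weights=W)


def rank_edges(adj: WeightedAdjacency) -> RankedEdgeList:
    """Rank all unordered gene pairs by descending ``|score|``.

    Ties are broken lexicographically on the canonical (gene_a, gene_b) pair,
    making the ordering strictly deterministic for a fixed input matrix.
    """
    n = adj.n_genes
    iu, ju = np.triu_indices(n, k=1)
    genes = np.asarray(adj.gene_ids, dtype=object)
    a = genes[iu]
    b = genes[ju]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    scores = adj.weights[iu, ju]
    # lexsort: last key is primary
    order = np.lexsort((b2, a2, -np.abs(scores)))
    return RankedEdgeList(gene_a=a2[order], gene_b=b2[order], score=scores[order])
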