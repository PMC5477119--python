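"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from rlowpc.netio import ExpressionMatrix, ReferenceNetwork


def make_expr(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"G{i + 1}" for i in range(values.shape[0])]
    return ExpressionMatrix(gene_ids=list(gene_ids), values=values, sample_ids=sample_ids)


def data_with_exact_correlation(R: np.ndarray, n_samples: int, rng) -> np.ndarray:
    """Rows whose *sample* correlation matrix equals R exactly.

    Raw Gaussian rows are whitened against their own sample covariance and
    recoloured with the Cholesky factor of R, so the empirical (ddof=1)
    correlations match R to machine precision.
    """
    p = len(R)
    X = rng.standard_normal((p, n_samples))
    X = X - X.mean(axis=1, keepdims=True)
    S = X @ X.T / (n_samples - 1)
    Z = np.linalg.solve(np.linalg.cholesky(S), X)
    return np.linalg.cholesky(R) @ Z


def random_correlation_matrix(p: int, rng) -> np.ndarray:
    """Random well-conditioned correlation matrix (Gram of random vectors)."""
    A = rng.standard_normal((p, p + 5))
    S = A @ A.T / (p + 5)
    d = 1.0 / np.sqrt(np.diag(S))
    return d[:, None] * S * d[None, :]


def residual_pcor_oracle(values: np.ndarray, i: int, j: int, Q: list[int]) -> float:
    """Partial correlation by explicit regression residuals.

    Regress genes i and j on the conditioning genes (with intercept) and
    correlate the residuals — an independent route to the same quantity as
    submatrix inversion.
    """
    n = values.shape[1]
    if not Q:
        x, y = values[i], values[j]
        return float(np.corrcoef(x, y)[0, 1])
    design = np.column_stack([np.ones(n), values[Q].T])
    res = []
    for g in (i, j):
        beta, *_ = np.linalg.lstsq(design, values[g], rcond=None)
        res.append(values[g] - design @ beta)
    return float(np.corrcoef(res[0], res[1])[0, 1])


def chain_motif_expr(seed, a=0.9, b=0.65, n=63) -> ExpressionMatrix:
    """Indirect-edge motif: X3 drives X1 and X2; no direct X1-X2 edge."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    x1 = a * z + np.sqrt(1 - a * a) * rng.standard_normal(n)
    x2 = b * z + np.sqrt(1 - b * b) * rng.standard_normal(n)
    return make_expr(np.vstack([x1, x2, z]), gene_ids=["X1", "X2", "X3"])


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


@pytest.fixture
def toy_ranking():
    """4 genes, 6 pairs; ranking head TP, FP, TP against 2 true edges.

    Scores are chosen so the deterministic ranking is exactly
    (G1,G2), (G1,G3), (G3,G4), (G1,G4), (G2,G3), (G2,G4).
    """
    from rlowpc.netio import WeightedAdjacency, rank_edges

    genes = ["G1", "G2", "G3", "G4"]
    w = np.zeros((4, 4))
    pairs = {(0, 1): 0.9, (0, 2): 0.8, (2, 3): 0.7, (0, 3): 0.6, (1, 2): 0.5, (1, 3): 0.4}
    for (i, j), s in pairs.items():
        w[i, j] = w[j, i] = s
    ranked = rank_edges(WeightedAdjacency(gene_ids=genes, weights=w))
    ref = ReferenceNetwork(nodes=genes, directed_edges={("G1", "G2"), ("G3", "G4")})
    return ranked, ref


@pytest.fixture(scope="session")
def benchmark_result():
    """Reduced benchmark design shared by the directional tests.

    5 network structures x 2 time series at 100 genes and 63 samples, all
    nine methods, the default protocol (ANOVA prefilter, shared-neighbour
    RLowPC with the suggested search space, top-1000 evaluation).
    """
    from rlowpc.benchmark import run_benchmark
    from rlowpc.gnw_lite import SimulationConfig

    return run_benchmark(
        SimulationConfig(n_genes=100, seed=11), n_structures=5, n_series=2
    )
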