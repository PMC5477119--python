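"""Pairwise association measures.

Everything downstream is built from four primitives: the Pearson correlation
matrix, the Schafer-Strimmer shrinkage correlation estimate (identity target),
partial correlations of arbitrary conditioning order obtained by submatrix
inversion, and the Gaussian mutual-information surrogate
``MI = -1/2 ln(1 - r^2)`` used by the MI-based methods when applied to
continuous time-series data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .netio import ExpressionMatrix, WeightedAdjacency

__all__ = [
    "ShrinkageEstimate",
    "pearson_matrix",
    "shrinkage_correlation",
    "partial_correlation_matrix",
    "low_order_pcor",
    "mi_from_correlation",
]

#: |r| is clamped below 1 by this margin before the MI transform so that
#: collinear simulated genes never produce infinities.
_R_CLAMP = 1.0 - 1e-12

#: condition-number threshold above which a conditioning submatrix is
#: re-shrunk before inversion in :func:`low_order_pcor`.
_COND_LIMIT = 1e8


@dataclass
class ShrinkageEstimate:
    """Regularised correlation matrix ``R* = lambda*I + (1-lambda)*R``.

    ``lambda_`` is the analytic shrinkage intensity toward the identity
    target, clamped to [0, 1]; ``R*`` has unit diagonal and is positive
    definite whenever ``lambda_ > 0``.
    """

    gene_ids: list[str]
    lambda_: float
    shrunk_correlation: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("shrinkage intensity must lie in [0, 1]")
        R = np.asarray(self.shrunk_correlation, dtype=float)
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("shrunk correlation must have unit diagonal")
        self.shrunk_correlation = R


def _flat_rows(values: np.ndarray) -> np.ndarray:
    """Rows with (numerically) zero variance across samples."""
    sd = values.std(axis=1, ddof=1)
    scale = np.maximum(np.abs(values).max(axis=1), 1.0)
    return sd <= 1e-12 * scale


def _correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation of the rows, with zero-variance rows mapped to 0."""
    sd = values.std(axis=1, ddof=1)
    flat = _flat_rows(values)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their correlations are set to 0",
            stacklevel=3,
        )
    centred = values - values.mean(axis=1, keepdims=True)
    safe_sd = np.where(flat, 1.0, sd)
    z = centred / safe_sd[:, None]
    n = values.shape[1]
    r = (z @ z.T) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def pearson_matrix(expr: ExpressionMatrix) -> WeightedAdjacency:
    """Pairwise Pearson correlations with the diagonal zeroed.

    Zero-variance genes get correlation 0 against everything (with a warning)
    rather than NaN, so a flat simulated gene never poisons a whole matrix.
    """
    r = _correlation(expr.values)
    np.fill_diagonal(r, 0.0)
    return WeightedAdjacency(gene_ids=list(expr.gene_ids), weights=r)


def shrinkage_correlation(
    expr: ExpressionMatrix, lambda_override: float | None = None
) -> ShrinkageEstimate:
    """Schafer-Strimmer shrinkage of the sample correlation toward identity.

    The analytic intensity is

    .. math:: \\lambda^* = \\frac{\\sum_{i<j} \\widehat{Var}(r_{ij})}
                                 {\\sum_{i<j} r_{ij}^2}

    clamped to [0, 1], with the unbiased variance estimate of each sample
    correlation computed from the standardized data products
    (``Var(r_ij) = n/(n-1)^3 * sum_k (w_kij - mean_k w_kij)^2`` where
    ``w_kij = z_ki z_kj``). The shrunk matrix is
    ``lambda*I + (1-lambda)*R`` and is positive definite for ``lambda > 0``.

    Parameters
    ----------
    lambda_override
        If given, skip the analytic estimate and use this intensity
        (useful for forcing ``lambda = 0`` in exact closed-form tests).
    """
    n = expr.n_samples
    if n < 3:
        raise ValueError("shrinkage estimation needs at least 3 samples")
    values = expr.values
    r = _correlation(values)

    if lambda_override is not None:
        lam = float(np.clip(lambda_override, 0.0, 1.0))
    else:
        sd = values.std(axis=1, ddof=1)
        flat = _flat_rows(values)
        centred = values - values.mean(axis=1, keepdims=True)
        z = centred / np.where(flat, 1.0, sd)[:, None]
        # w_bar[i,j] = mean_k z_ki z_kj = (n-1)/n * r_ij
        w_bar = (z @ z.T) / n
        # sum_k w_kij^2 via squared data products
        z2 = z**2
        sum_w2 = z2 @ z2.T
        var_r = n / (n - 1) ** 3 * (sum_w2 - n * w_bar**2)
        iu = np.triu_indices_from(r, k=1)
        denom = float(np.sum(r[iu] ** 2))
        numer = float(np.sum(var_r[iu]))
        lam = 1.0 if denom <= 0 else float(np.clip(numer / denom, 0.0, 1.0))

    shrunk = lam * np.eye(len(r)) + (1.0 - lam) * r
    return ShrinkageEstimate(
        gene_ids=list(expr.gene_ids), lambda_=lam, shrunk_correlation=shrunk
    )


def partial_correlation_matrix(est: ShrinkageEstimate) -> WeightedAdjacency:
    """Full-order partial correlations from the shrunk correlation matrix.

    With ``Omega`` the inverse of the shrunk correlation,
    ``pcor[i, j] = -Omega_ij / sqrt(Omega_ii * Omega_jj)``; the result is
    symmetric with zero diagonal.
    """
    R = est.shrunk_correlation
    try:
        omega = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "shrunk correlation matrix is singular; use a positive shrinkage "
            "intensity (lambda > 0 guarantees invertibility)"
        ) from exc
    d = np.sqrt(np.abs(np.diag(omega)))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor = (pcor + pcor.T) / 2.0
    return WeightedAdjacency(gene_ids=list(est.gene_ids), weights=pcor)


def low_order_pcor(
    R: np.ndarray, i: int, j: int, Q: list[int] | tuple[int, ...]
) -> float:
    """Partial correlation of genes ``i`` and ``j`` given exactly the set ``Q``.

    Computed by inverting the ``{i, j} | Q`` submatrix of the correlation
    matrix ``R`` (indices are positions into ``R``). ``Q = []`` returns the
    marginal correlation unchanged. If the submatrix is ill-conditioned
    (condition number above 1e8) it is re-shrunk toward identity with
    intensity 0.01 and a warning is issued.
    """
    Q = list(Q)
    if i == j:
        raise ValueError("i and j must differ")
    if i in Q or j in Q:
        raise ValueError("conditioning set overlaps the gene pair")
    if not Q:
        return float(R[i, j])
    idx = [i, j] + Q
    sub = np.asarray(R, dtype=float)[np.ix_(idx, idx)]
    if np.linalg.cond(sub) > _COND_LIMIT:
        warnings.warn(
            "ill-conditioned conditioning submatrix; re-shrinking with lambda=0.01",
            stacklevel=2,
        )
        sub = 0.01 * np.eye(len(sub)) + 0.99 * sub
    omega = np.linalg.inv(sub)
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


def mi_from_correlation(r: float | np.ndarray) -> float | np.ndarray:
    """Gaussian mutual-information surrogate ``-1/2 ln(1 - r^2)``.

    Applied elementwise; ``|r|`` is clamped just below 1 so collinear inputs
    map to a large finite value instead of infinity.
    """
    r = np.clip(np.asarray(r, dtype=float), -_R_CLAMP, _R_CLAMP)
    out = -0.5 * np.log1p(-(r**2))
    return float(out) if out.ndim == 0 else out
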