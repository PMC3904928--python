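"""Confounder handling: principal-component projection and covariate residuals.

Population stratification is removed by projecting phenotype, genotype and
covariates off the top principal components R of the standardized genotype
matrix (X -> X - R R'X), after which covariates are regressed out of the
adjusted phenotypes by ordinary least squares.  The resulting residuals are
what the region tests consume; dichotomous phenotypes go through the same
linear operations and their residuals are treated as quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .score_core import GenotypeMatrix, InvalidInputError

__all__ = ["AdjustedData", "compute_pcs", "project_out", "residualize", "adjust_pipeline"]


def compute_pcs(G, k: int = 10) -> np.ndarray:
    """Top-k orthonormal principal components of the genotype matrix.

    Each variant is standardized by its allele frequency p: centered at 2p
    and scaled by sqrt(2p(1-p)) (the usual convention for genotype PCA),
    then the leading left singular vectors are returned as an N x k matrix
    with orthonormal columns.
    """
    g = np.asarray(G.values if isinstance(G, GenotypeMatrix) else G, dtype=float)
    n, l = g.shape
    if k < 0 or k >= min(n, l):
        if k == 0:
            return np.empty((n, 0))
        raise InvalidInputError(f"k={k} must satisfy 0 <= k < min(N, L) = {min(n, l)}")
    p = g.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    x = (g[:, ok] - 2.0 * p[ok]) / scale[ok]
    u, _, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k]


def project_out(X, R: np.ndarray):
    """Remove the span of the principal components: X - R R'X.

    Accepts a vector or a matrix whose rows are samples; the operation is
    an orthogonal projection, hence idempotent, and with an empty R it is
    the identity.
    """
    X = np.asarray(X, dtype=float)
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        return X.copy()
    if X.shape[0] != R.shape[0]:
        raise InvalidInputError("sample counts of X and R differ")
    return X - R @ (R.T @ X)


def residualize(phenotype: np.ndarray, covariates: Optional[np.ndarray] = None) -> np.ndarray:
    """OLS residuals of the phenotype on an intercept plus covariates.

    With no covariates this is mean-centering.  A rank-deficient design is
    rejected with the indices of the collinear columns.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if covariates is None or np.asarray(covariates).size == 0:
        return y - y.mean()
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise InvalidInputError("covariate and phenotype sample counts differ")
    X = np.column_stack([np.ones(n), C])
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    small = diag < 1e-10 * max(diag.max(), 1.0)
    if small.any():
        bad = [i - 1 for i in np.flatnonzero(small)]  # shift past the intercept
        raise InvalidInputError(f"collinear covariate column(s): {bad}")
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return y - X @ beta


@dataclass
class AdjustedData:
    """Stratification- and covariate-adjusted inputs ready for testing."""

    genotype: np.ndarray  # N x L, projected off R
    residuals: dict[str, np.ndarray]  # phenotype name -> residual vector
    covariates_adj: Optional[np.ndarray]
    R: np.ndarray


def adjust_pipeline(
    G,
    phenotypes: dict[str, np.ndarray],
    covariates: Optional[np.ndarray] = None,
    R: Optional[np.ndarray] = None,
    n_pcs: int = 10,
) -> AdjustedData:
    """Full confounder pipeline.

    Project genotype, phenotypes and covariates off the principal components
    (computed from the genotype when ``R`` is not supplied), then regress
    covariates out of each adjusted phenotype and return the residuals.
    """
    g = np.asarray(G.values if isinstance(G, GenotypeMatrix) else G, dtype=float)
    if R is None:
        R = compute_pcs(g, k=n_pcs)
    g_adj = project_out(g, R)
    cov_adj = None if covariates is None else project_out(covariates, R)
    residuals = {
        name: residualize(project_out(np.asarray(y, dtype=float), R), cov_adj)
        for name, y in phenotypes.items()
    }
    return AdjustedData(genotype=g_adj, residuals=residuals, covariates_adj=cov_adj, R=R)
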