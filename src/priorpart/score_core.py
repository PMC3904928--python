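"""Region-based score statistic and its decorrelation.

For a genomic region with genotype matrix ``G`` (N samples x L variants,
minor-allele counts) and phenotype ``Y``, the score test of no association
under a generalized linear model is the quadratic form

    T0 = U' V^+ U,

where ``U_l = sum_n (y_n - ybar)(g_nl - gbar_l)`` is the vector of scores and
``V = Cov(G) * sum_n (y_n - ybar)^2`` its covariance.  Under the null, T0 is
asymptotically chi-squared with rank(V) degrees of freedom.

This module also provides the decorrelation used by the partitioned test:
with an upper-triangular factor ``A`` such that ``A'A = V`` (a generalized
Cholesky factor, defined for singular positive semi-definite V), the vector
``S`` solving ``A'S = U`` is asymptotically standard multivariate normal
under the null, and ``S'S = T0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "ScoreDecomposition",
    "prepare_genotypes",
    "compute_score_vector",
    "compute_score_covariance",
    "generalized_cholesky",
    "pseudoinverse",
    "decorrelate",
    "score_statistic",
]

#: relative pivot threshold for rank detection in the generalized Cholesky
PSD_TOL = 1e-10


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class GenotypeMatrix:
    """Genotype matrix of minor-allele counts with per-variant metadata.

    ``values`` has shape (N, L) with entries in {0, 1, 2}.  Variants are
    expected in ascending genomic position (ties broken by variant id);
    :func:`prepare_genotypes` establishes that ordering together with
    minor-allele recoding and monomorphic-site removal.
    """

    values: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    annotations: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.variant_ids = list(self.variant_ids)
        n, l = self.values.shape
        if l < 1 or n < 2:
            raise InvalidInputError(
                f"genotype matrix needs N >= 2 samples and L >= 1 variants, got {n} x {l}"
            )
        if len(self.variant_ids) != l or len(self.positions) != l:
            raise InvalidInputError("variant metadata length does not match matrix width")
        if self.annotations is not None and len(self.annotations) != l:
            raise InvalidInputError("annotation length does not match matrix width")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise InvalidInputError("genotype entries must be minor-allele counts in {0, 1, 2}")
        if np.any(self.positions < 0):
            raise InvalidInputError("variant positions must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Sample frequency of the counted allele at each variant."""
        return self.values.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Observed minor allele frequency at each variant."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[:, idx],
            variant_ids=[self.variant_ids[i] for i in idx],
            positions=self.positions[idx],
            annotations=None
            if self.annotations is None
            else [self.annotations[i] for i in idx],
        )


@dataclass
class PhenotypeVector:
    """Phenotype values, dichotomous (0/1) or quantitative."""

    values: np.ndarray
    kind: Literal["dichotomous", "quantitative"] = "quantitative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("phenotype must be a one-dimensional vector")
        if not np.isfinite(self.values).all():
            raise InvalidInputError("phenotype contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _phenotype_array(Y) -> np.ndarray:
    y = Y.values if isinstance(Y, PhenotypeVector) else np.asarray(Y, dtype=float)
    if np.ptp(y) == 0:
        raise InvalidInputError("phenotype is constant: the score is identically zero")
    return y


def _genotype_array(G) -> np.ndarray:
    return np.asarray(G.values if isinstance(G, GenotypeMatrix) else G, dtype=float)


def prepare_genotypes(G: GenotypeMatrix) -> GenotypeMatrix:
    """Canonicalize a genotype matrix for analysis.

    Recode each variant so the counted allele has sample frequency <= 0.5
    (an exact 0.5 keeps the input coding), drop monomorphic variants with a
    warning, and sort ascending by position with ties broken by variant id.
    """
    values = G.values.copy()
    p = values.mean(axis=0) / 2.0
    flip = p > 0.5
    if flip.any():
        values[:, flip] = 2 - values[:, flip]
    poly = values.std(axis=0) > 0
    if not poly.all():
        dropped = [G.variant_ids[i] for i in np.flatnonzero(~poly)]
        logger.warning("dropping %d monomorphic variant(s): %s", len(dropped), dropped)
    if not poly.any():
        raise InvalidInputError("no polymorphic variants remain after filtering")
    gm = GenotypeMatrix(
        values=values,
        variant_ids=G.variant_ids,
        positions=G.positions,
        annotations=G.annotations,
    ).subset(np.flatnonzero(poly))
    order = sorted(
        range(gm.n_variants), key=lambda i: (gm.positions[i], gm.variant_ids[i])
    )
    return gm.subset(np.asarray(order))


def compute_score_vector(G, Y) -> np.ndarray:
    """Score vector U_l = sum_n (y_n - ybar)(g_nl - gbar_l)."""
    g = _genotype_array(G)
    y = _phenotype_array(Y)
    if g.shape[0] != y.shape[0]:
        raise InvalidInputError("genotype and phenotype sample counts differ")
    if g.shape[0] < 2:
        raise InvalidInputError("need at least two samples")
    yc = y - y.mean()
    gc = g - g.mean(axis=0)
    return gc.T @ yc


def compute_score_covariance(G, Y, divisor: Literal["n", "n-1"] = "n") -> np.ndarray:
    """Score covariance V = Cov(G) * sum_n (y_n - ybar)^2.

    The genotype covariance uses the maximum-likelihood divisor 1/N by
    default; ``divisor="n-1"`` selects the unbiased sample estimate.
    """
    g = _genotype_array(G)
    y = _phenotype_array(Y)
    if g.shape[0] != y.shape[0]:
        raise InvalidInputError("genotype and phenotype sample counts differ")
    n = g.shape[0]
    ddof = 0 if divisor == "n" else 1
    gc = g - g.mean(axis=0)
    cov = gc.T @ gc / (n - ddof)
    ssy = float(((y - y.mean()) ** 2).sum())
    return cov * ssy


def generalized_cholesky(V: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Upper-triangular factor A with A'A = V for symmetric PSD V.

    Extends the classical Cholesky factorization to singular matrices by
    zeroing rows whose pivot falls below ``tol * max(diag(V))``; on a
    positive-definite input it coincides with the classical factor.
    Raises on matrices indefinite beyond that tolerance.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise InvalidInputError("V must be square")
    if not np.allclose(V, V.T, atol=1e-8 * (1 + np.abs(V).max())):
        raise InvalidInputError("V must be symmetric")
    L = V.shape[0]
    scale = max(V.diagonal().max(initial=0.0), 0.0)
    thresh = tol * scale if scale > 0 else tol
    A = np.zeros_like(V)
    for j in range(L):
        r = V[j, j:] - A[:j, j] @ A[:j, j:]
        d = r[0]
        if d > thresh:
            A[j, j:] = r / np.sqrt(d)
        elif d < -thresh:
            lam = float(np.linalg.eigvalsh(V).min())
            raise np.linalg.LinAlgError(
                f"matrix is indefinite beyond tolerance: smallest eigenvalue {lam:.3e}"
            )
        # pivot within [-thresh, thresh]: numerically zero row, rank deficit
    return A


def pseudoinverse(V: np.ndarray) -> np.ndarray:
    """Moore-Penrose pseudoinverse of a symmetric matrix.

    Coincides with the ordinary inverse on nonsingular input and replaces
    it when the score covariance is (numerically) singular, e.g. under
    perfect LD between variants.
    """
    V = np.asarray(V, dtype=float)
    return np.linalg.pinv(V, hermitian=True)


def decorrelate(U: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Solve A'S = U for the decorrelated score vector S.

    Uses forward substitution on the triangular factor; when A carries
    zero pivot rows (singular V) the minimum-norm least-squares solution is
    taken, preserving S'S = U' V^+ U.
    """
    U = np.asarray(U, dtype=float)
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or A.shape[0] != U.shape[0]:
        raise InvalidInputError(
            f"dimension mismatch: A is {A.shape}, U has length {U.shape[0]}"
        )
    if np.all(A.diagonal() > 0):
        return scipy.linalg.solve_triangular(A, U, trans="T", lower=False)
    return np.linalg.lstsq(A.T, U, rcond=None)[0]


def score_statistic(U: np.ndarray, V: np.ndarray) -> float:
    """Classical region score statistic T0 = U' V^+ U (>= 0)."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if V.shape != (U.shape[0], U.shape[0]):
        raise InvalidInputError("U and V shapes do not match")
    return max(float(U @ pseudoinverse(V) @ U), 0.0)


@dataclass
class ScoreDecomposition:
    """Score vector, covariance, triangular factor and decorrelated scores."""

    U: np.ndarray
    V: np.ndarray
    A: np.ndarray
    S: np.ndarray
    T0: float
    rank_V: int

    @classmethod
    def from_data(cls, G, Y, divisor: Literal["n", "n-1"] = "n") -> "ScoreDecomposition":
        """Full decomposition for one region; T0 is computed as S'S."""
        U = compute_score_vector(G, Y)
        V = compute_score_covariance(G, Y, divisor=divisor)
        A = generalized_cholesky(V)
        S = decorrelate(U, A)
        return cls(U=U, V=V, A=A, S=S, T0=float(S @ S), rank_V=int((A.diagonal() > 0).sum()))
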