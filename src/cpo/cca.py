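"""Constrained correspondence analysis (CCA) core.

The machinery follows the classical chi-square-residual formulation.
Write ``P = Y / y··`` for the relative frequency table of the count matrix
``Y`` with row weights ``r`` (row sums of P) and column weights ``c``.
The standardized residual matrix is

    Q_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)

whose total sum of squares equals the table's Pearson chi-square divided
by the grand total — the *total inertia* partitioned by every analysis in
this package.  Constraining on a design matrix X means projecting the
rows of Q (in the sqrt(r)-weighted species space) onto the column space
of the weighted-centered, sqrt(r)-scaled X; covariates Z are projected
out first.  Canonical eigenvalues are the squared singular values of the
projected residual matrix and satisfy

    covariate inertia + constrained inertia + residual inertia = total.

The pseudo-F statistics assessed by Monte Carlo permutation are ratios of
constrained to residual mean inertia with residual degrees of freedom
``n - p - q - 1`` (p covariate rank, q constraint rank, 1 for the
weighted intercept implicit in the centering).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import DietMatrix, ValidationError

#: relative singular-value cutoff for numerical rank of projectors; binary
#: clade matrices over few species are often exactly collinear (nested clades)
RANK_TOL = 1e-10


@dataclass
class ChiSquareDecomposition:
    """Standardized chi-square residuals of a count table with its weights."""

    Q: np.ndarray
    row_weights: np.ndarray
    col_weights: np.ndarray
    total_inertia: float


def chi_square_residuals(Y: DietMatrix | np.ndarray) -> ChiSquareDecomposition:
    """Chi-square residual transform of a count matrix.

    Accepts a :class:`~cpo.datamodel.DietMatrix` or a raw nonnegative
    array with nonzero row and column sums.
    """
    counts = Y.counts if isinstance(Y, DietMatrix) else np.asarray(Y, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("count matrix has zero grand total")
    P = counts / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValidationError("zero row or column sum; filter before analysis")
    expected = np.outer(r, c)
    Q = (P - expected) / np.sqrt(expected)
    return ChiSquareDecomposition(
        Q=Q, row_weights=r, col_weights=c, total_inertia=float((Q ** 2).sum())
    )


def weighted_center(M: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Weighted-center the columns of M and scale rows by sqrt(r).

    After this transform, ordinary (unweighted) projections in the output
    space are r-weighted projections in the original species space, which
    is the metric correspondence analysis works in.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    means = r @ M
    return np.sqrt(r)[:, None] * (M - means)


def _orthonormal_basis(A: np.ndarray, tol: float = RANK_TOL,
                       ref_scale: float | None = None) -> np.ndarray:
    """Orthonormal basis (n × rank) of the column space of A, rank decided
    by a relative singular-value threshold.

    ``ref_scale`` anchors the threshold to an external magnitude (e.g. the
    norm of a matrix before residualization) so that a column space that is
    pure cancellation noise is recognized as empty.
    """
    if A.size == 0 or A.shape[1] == 0:
        return np.zeros((A.shape[0], 0))
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((A.shape[0], 0))
    scale = max(s[0], ref_scale or 0.0)
    rank = int(np.sum(s > tol * scale))
    return U[:, :rank]


def partial_out(Q: np.ndarray, Z_scaled: np.ndarray) -> tuple[np.ndarray, float]:
    """Project out the covariate space from the residual matrix.

    ``Z_scaled`` must already be weighted-centered and sqrt(r)-scaled.
    Returns the residualized matrix and the inertia absorbed by Z; by
    Pythagoras the two inertias sum to the input's sum of squares.
    """
    basis = _orthonormal_basis(Z_scaled)
    if basis.shape[1] == 0:
        return Q, 0.0
    fitted = basis @ (basis.T @ Q)
    Q_res = Q - fitted
    return Q_res, float((fitted ** 2).sum())


@dataclass
class OrdinationResult:
    """Eigen-solution and inertia decomposition of a (partial) CCA."""

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    covariate_inertia: float
    residual_inertia: float
    rank_constraints: int
    rank_covariates: int
    n_rows: int
    row_scores: np.ndarray = field(default=None, repr=False)
    column_scores: np.ndarray = field(default=None, repr=False)
    biplot_scores: np.ndarray = field(default=None, repr=False)
    species_ids: list = field(default_factory=list, repr=False)
    prey_categories: list = field(default_factory=list, repr=False)
    constraint_names: list = field(default_factory=list, repr=False)

    @property
    def axis_percent_of_constrained(self) -> np.ndarray:
        if self.constrained_inertia <= 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / self.constrained_inertia

    @property
    def axis_percent_of_total(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.total_inertia

    def to_dict(self) -> dict:
        return {
            "eigenvalues": list(map(float, self.eigenvalues)),
            "total_inertia": self.total_inertia,
            "constrained_inertia": self.constrained_inertia,
            "covariate_inertia": self.covariate_inertia,
            "residual_inertia": self.residual_inertia,
            "rank_constraints": self.rank_constraints,
            "rank_covariates": self.rank_covariates,
            "n_rows": self.n_rows,
            "axis_percent_of_constrained": list(map(float, self.axis_percent_of_constrained)),
            "axis_percent_of_total": list(map(float, self.axis_percent_of_total)),
        }


def _as_values(X) -> tuple[np.ndarray, list]:
    """Accept a CladeMatrix, a (names, values) pair, or a raw array."""
    if X is None:
        return np.zeros((0, 0)), []
    if hasattr(X, "membership"):
        return np.asarray(X.membership, dtype=float), list(X.clade_names)
    if isinstance(X, tuple) and len(X) == 2:
        names, values = X
        return np.asarray(values, dtype=float), list(names)
    return np.asarray(X, dtype=float), []


def constrained_ordination(
    Y: DietMatrix | np.ndarray,
    X,
    Z=None,
    compute_scores: bool = True,
) -> OrdinationResult:
    """Canonical (optionally partial) correspondence analysis.

    Parameters
    ----------
    Y :
        Count matrix (DietMatrix or array).
    X :
        Constraints: CladeMatrix, (names, values) pair, or array.
    Z :
        Optional covariates in the same accepted forms; their inertia is
        removed before constraining (partial CCA).
    """
    chi = chi_square_residuals(Y)
    Q, r = chi.Q, chi.row_weights
    n = Q.shape[0]

    X_values, x_names = _as_values(X)
    Z_values, _ = _as_values(Z)
    if X_values.ndim == 1:
        X_values = X_values[:, None]
    if X_values.shape[0] != n:
        raise ValidationError("X row count does not match Y")
    if Z_values.size and Z_values.shape[0] != n:
        raise ValidationError("Z row count does not match Y")

    Z_scaled = weighted_center(Z_values, r) if Z_values.size else np.zeros((n, 0))
    Z_basis = _orthonormal_basis(Z_scaled)
    p = Z_basis.shape[1]
    Q_res, covariate_inertia = partial_out(Q, Z_scaled)

    X_scaled = weighted_center(X_values, r)
    x_scale = float(np.linalg.norm(X_scaled, 2)) if X_scaled.size else 0.0
    if p:
        X_scaled = X_scaled - Z_basis @ (Z_basis.T @ X_scaled)
    X_basis = _orthonormal_basis(X_scaled, ref_scale=x_scale)
    q = X_basis.shape[1]
    if q == 0:
        raise ValidationError(
            "no testable constraint: X is constant or fully collinear with covariates"
        )

    fitted = X_basis @ (X_basis.T @ Q_res)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eigenvalues = s ** 2
    n_axes = min(q, Q.shape[1] - 1, n - 1)
    eigenvalues = eigenvalues[:n_axes]
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    constrained_inertia = float(eigenvalues.sum())
    residual_inertia = float((Q_res ** 2).sum() - constrained_inertia)

    res = OrdinationResult(
        eigenvalues=eigenvalues,
        total_inertia=chi.total_inertia,
        constrained_inertia=constrained_inertia,
        covariate_inertia=covariate_inertia,
        residual_inertia=residual_inertia,
        rank_constraints=q,
        rank_covariates=p,
        n_rows=n,
        species_ids=list(getattr(Y, "species_ids", [])),
        prey_categories=list(getattr(Y, "prey_categories", [])),
        constraint_names=x_names,
    )
    if compute_scores and eigenvalues.size and eigenvalues[0] > 0:
        _attach_scores(res, chi, U, s, Vt, X_values)
    return res


def _attach_scores(res, chi, U, s, Vt, X_values) -> None:
    """Symmetric-biplot scores: both row and column scores carry the
    singular value split evenly (factor s**0.5 each)."""
    keep = s > RANK_TOL * max(s[0], 1.0)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    sqrt_r = np.sqrt(chi.row_weights)[:, None]
    sqrt_c = np.sqrt(chi.col_weights)[:, None]
    half = np.sqrt(s)
    res.row_scores = (U / sqrt_r) * half
    res.column_scores = (Vt.T / sqrt_c) * half
    # biplot arrows: r-weighted correlation of each constraint with the
    # linear-combination species axes (U / sqrt(r))
    lc = U / sqrt_r
    r = chi.row_weights
    Xc = X_values - r @ X_values
    denom = np.sqrt((r[:, None] * Xc ** 2).sum(axis=0))
    denom[denom == 0] = 1.0
    lc_norm = np.sqrt((r[:, None] * lc ** 2).sum(axis=0))
    lc_norm[lc_norm == 0] = 1.0
    res.biplot_scores = (Xc.T * r) @ lc / np.outer(denom, lc_norm)


def pseudo_F(res: OrdinationResult, mode: str = "global",
             term_inertia: float | None = None, term_rank: int | None = None) -> float:
    """Pseudo-F statistic of a fitted ordination.

    ``global``: all constrained inertia over residual mean inertia;
    ``first_axis``: first canonical eigenvalue over residual mean inertia;
    ``term``: a single term's added inertia (supply ``term_inertia`` and
    ``term_rank``) over residual mean inertia.  Residual degrees of
    freedom are ``n - p - q - 1``.
    """
    n, p, q = res.n_rows, res.rank_covariates, res.rank_constraints
    df_resid = n - p - q - 1
    if df_resid <= 0:
        raise ValidationError(f"no residual degrees of freedom (n={n}, p={p}, q={q})")
    if res.residual_inertia <= RANK_TOL * res.total_inertia:
        warnings.warn("residual inertia is numerically zero; F is infinite", stacklevel=2)
        return float("inf")
    denom = res.residual_inertia / df_resid
    if mode == "global":
        return (res.constrained_inertia / q) / denom
    if mode == "first_axis":
        return float(res.eigenvalues[0]) / denom
    if mode == "term":
        if term_inertia is None or term_rank is None:
            raise ValidationError("term mode needs term_inertia and term_rank")
        return (term_inertia / term_rank) / denom
    raise ValidationError(f"unknown pseudo-F mode {mode!r}")


def unconstrained_ca_eigenvalues(Y) -> np.ndarray:
    """Eigenvalues of plain correspondence analysis (SVD of Q), the
    unconstrained limit that a full-rank constrained analysis must match."""
    chi = chi_square_residuals(Y)
    s = np.linalg.svd(chi.Q, compute_uv=False)
    n_axes = min(chi.Q.shape[0] - 1, chi.Q.shape[1] - 1)
    return (s ** 2)[:n_axes]
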