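"""Monte Carlo permutation tests for constrained ordination.

Significance of a pseudo-F statistic is assessed against its permutation
null distribution with the add-one estimator

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations),

so the smallest attainable p with B permutations is 1/(B+1) and ties
count as exceedances (conservative).

Two permutation schemes are available:

* ``raw`` — whole rows of the count matrix are permuted against the
  fixed design ("unrestricted" permutation units: every species row is
  exchangeable).  This is the only scheme when there are no covariates.
* ``residual`` — with covariates Z, rows of the covariate-residualized
  chi-square residual matrix are permuted while the covariate structure
  is held fixed (reduced-model scheme).

Every test draws its permutations from a :class:`numpy.random.Generator`
seeded through ``numpy.random.SeedSequence``; nested procedures (forward
selection) split the stream deterministically per step and candidate, so
a whole analysis is reproducible end to end from one integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cca import (
    RANK_TOL,
    chi_square_residuals,
    constrained_ordination,
    pseudo_F,
    weighted_center,
    _as_values,
    _orthonormal_basis,
)
from .datamodel import AnalysisConfig, DietMatrix, ValidationError

_CHUNK = 2048  # permutations handled per vectorized block


def rng_for(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child generator for a (seed, *keys) address."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def empirical_p(F_obs: float, F_perm: np.ndarray) -> float:
    """Add-one Monte Carlo p-value; permuted values within 1e-12 of the
    observed statistic count as exceedances."""
    F_perm = np.asarray(F_perm, dtype=float)
    if F_perm.size == 0:
        raise ValidationError("empty permutation distribution")
    exceed = int(np.sum(F_perm >= F_obs - 1e-12))
    return (1 + exceed) / (1 + F_perm.size)


@dataclass
class PermutationTestResult:
    F_observed: float
    F_permuted: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    mode: str
    term_name: str | None = None
    scheme: str = "raw"

    def to_dict(self) -> dict:
        return {
            "F_observed": float(self.F_observed),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
            "mode": self.mode,
            "term_name": self.term_name,
            "scheme": self.scheme,
        }


def _batched_F_no_covariates(Q, r, X, perms, mode):
    """Null pseudo-F values when rows of Y are permuted and there are no
    covariates.  Permuting Y's rows permutes Q's rows and the row weights
    jointly while the column weights are unchanged, so the statistics can
    be recomputed from the fixed Q without rebuilding the table."""
    n = Q.shape[0]
    total = float((Q ** 2).sum())
    out = np.empty(perms.shape[0])
    for lo in range(0, perms.shape[0], _CHUNK):
        block = perms[lo:lo + _CHUNK]
        B = block.shape[0]
        Rp = r[block]                                 # (B, n)
        Qp = Q[block]                                 # (B, n, m)
        means = Rp @ X                                # (B, k)
        Xt = np.sqrt(Rp)[:, :, None] * (X[None, :, :] - means[:, None, :])
        Ub, sb, _ = np.linalg.svd(Xt, full_matrices=False)
        smax = sb[:, :1]
        mask = sb > RANK_TOL * np.maximum(smax, 1e-300)  # (B, k')
        q_b = mask.sum(axis=1)
        proj = np.matmul(np.swapaxes(Ub, 1, 2), Qp)   # (B, k', m)
        proj = proj * mask[:, :, None]
        constrained = (proj ** 2).sum(axis=(1, 2))
        residual = total - constrained
        df = n - q_b - 1
        denom = np.where(residual > RANK_TOL * max(total, 1e-300),
                         residual / np.maximum(df, 1), np.inf)
        if mode in ("global", "term"):
            F = np.where(np.isfinite(denom), (constrained / np.maximum(q_b, 1)) / denom, np.inf)
        else:  # first_axis
            s1 = np.linalg.svd(proj, compute_uv=False)[:, 0]
            F = np.where(np.isfinite(denom), (s1 ** 2) / denom, np.inf)
        out[lo:lo + B] = F
    return out


def _batched_F_residual_scheme(Q_res, Z_basis, X_basis, perms, mode, n):
    """Null pseudo-F values under the reduced-model scheme: rows of the
    covariate-residualized Q are permuted, covariates and constraints held
    fixed.  After permutation the rows are re-residualized on Z (only the
    residual term changes: the constraint basis is already orthogonal to
    the covariate space)."""
    p = Z_basis.shape[1]
    q = X_basis.shape[1]
    total_res = float((Q_res ** 2).sum())
    df = n - p - q - 1
    out = np.empty(perms.shape[0])
    for lo in range(0, perms.shape[0], _CHUNK):
        block = perms[lo:lo + _CHUNK]
        B = block.shape[0]
        Qp = Q_res[block]                              # (B, n, m)
        projX = np.matmul(X_basis.T[None, :, :], Qp)   # (B, q, m)
        constrained = (projX ** 2).sum(axis=(1, 2))
        if p:
            projZ = np.matmul(Z_basis.T[None, :, :], Qp)
            absorbed = (projZ ** 2).sum(axis=(1, 2))
        else:
            absorbed = np.zeros(B)
        residual = total_res - absorbed - constrained
        denom = np.where(residual > RANK_TOL * max(total_res, 1e-300),
                         residual / df, np.inf)
        if mode in ("global", "term"):
            F = np.where(np.isfinite(denom), (constrained / q) / denom, np.inf)
        else:
            s1 = np.linalg.svd(projX, compute_uv=False)[:, 0]
            F = np.where(np.isfinite(denom), (s1 ** 2) / denom, np.inf)
        out[lo:lo + B] = F
    return out


def _loop_F_raw_with_covariates(counts, X, Z, perms, mode):
    """Raw scheme with covariates: permute whole rows of Y and recompute
    the full partial analysis each time."""
    out = np.empty(perms.shape[0])
    for b, perm in enumerate(perms):
        Yp = counts[perm]
        try:
            res = constrained_ordination(Yp, X, Z, compute_scores=False)
            out[b] = pseudo_F(res, "global" if mode == "term" else mode)
        except ValidationError:
            out[b] = np.inf
    return out


def permutation_test(
    Y: DietMatrix,
    X,
    Z=None,
    mode: str = "global",
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    term_name: str | None = None,
) -> PermutationTestResult:
    """Monte Carlo permutation test of a (partial) constrained ordination.

    ``mode`` is ``global`` (all canonical axes), ``first_axis`` (first
    canonical eigenvalue) or ``term`` (X is a single tested term; same
    statistic as ``global`` but labeled with ``term_name``).
    """
    config = config or AnalysisConfig()
    if mode not in ("global", "first_axis", "term"):
        raise ValidationError(f"unknown test mode {mode!r}")
    if rng is None:
        rng = rng_for(config.seed)

    counts = Y.counts if isinstance(Y, DietMatrix) else np.asarray(Y, dtype=float)
    X_values, _ = _as_values(X)
    Z_values, _ = _as_values(Z)
    if X_values.ndim == 1:
        X_values = X_values[:, None]
    has_Z = Z_values.size > 0 and Z_values.shape[1] > 0

    obs = constrained_ordination(counts, X_values, Z_values if has_Z else None,
                                 compute_scores=False)
    F_obs = pseudo_F(obs, "global" if mode == "term" else mode)

    n = counts.shape[0]
    B = config.n_permutations
    perms = np.argsort(rng.random((B, n)), axis=1)

    if not has_Z:
        chi = chi_square_residuals(counts)
        F_perm = _batched_F_no_covariates(chi.Q, chi.row_weights, X_values, perms, mode)
        scheme = "raw"
    elif config.perm_scheme == "residual":
        chi = chi_square_residuals(counts)
        r = chi.row_weights
        Z_basis = _orthonormal_basis(weighted_center(Z_values, r))
        Q_res = chi.Q - Z_basis @ (Z_basis.T @ chi.Q)
        X_scaled = weighted_center(X_values, r)
        x_scale = float(np.linalg.norm(X_scaled, 2)) if X_scaled.size else 0.0
        X_scaled -= Z_basis @ (Z_basis.T @ X_scaled)
        X_basis = _orthonormal_basis(X_scaled, ref_scale=x_scale)
        if X_basis.shape[1] == 0:
            raise ValidationError("no testable constraint after removing covariates")
        F_perm = _batched_F_residual_scheme(Q_res, Z_basis, X_basis, perms, mode, n)
        scheme = "residual"
    else:
        F_perm = _loop_F_raw_with_covariates(counts, X_values, Z_values, perms, mode)
        scheme = "raw"

    return PermutationTestResult(
        F_observed=float(F_obs),
        F_permuted=F_perm,
        p_value=empirical_p(F_obs, F_perm),
        n_permutations=B,
        seed=config.seed,
        mode=mode,
        term_name=term_name,
        scheme=scheme,
    )
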