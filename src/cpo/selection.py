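"""Stepwise ("manual") selection of clades in canonical phylogenetic
ordination, marginal per-clade effects, and variance partitioning.

The forward procedure mirrors how clade sets are assembled in this
analysis family: at every step each not-yet-selected clade is evaluated
as a single term conditioned on the covariates plus the clades already in
the model; the candidate adding the most inertia is admitted if its
permutation p-value clears alpha, and the procedure stops at the first
failure.  Each admitted step records the clade's added inertia, its share
of the reference denominator, pseudo-F and Monte Carlo p — the shape of a
published clade-selection table.
"""
from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np

from .cca import constrained_ordination, pseudo_F
from .datamodel import AnalysisConfig, CladeMatrix, DietMatrix, ValidationError
from .permutation import permutation_test, rng_for

ExplainedFraction = namedtuple(
    "ExplainedFraction", ["phylogeny", "covariates", "unexplained"]
)


@dataclass
class SelectionTrace:
    """Ordered record of admitted clades with their conditional effects."""

    steps: list[dict] = field(default_factory=list)
    reference_inertia: float = 0.0
    reference_kind: str = "total"
    conditioned_covariates: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def selected(self) -> list[str]:
        return [s["clade_name"] for s in self.steps]

    @property
    def final_explained_fraction(self) -> float:
        if self.reference_inertia <= 0:
            return 0.0
        return sum(s["added_inertia"] for s in self.steps) / self.reference_inertia

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "reference_inertia": self.reference_inertia,
            "reference_kind": self.reference_kind,
            "conditioned_covariates": self.conditioned_covariates,
            "alpha": self.alpha,
            "final_explained_fraction": self.final_explained_fraction,
        }


def _added_inertia(Y, x_col, Z_aug):
    """Constrained inertia of a single term conditioned on Z_aug, or None
    when the term is collinear with the conditioning set."""
    try:
        res = constrained_ordination(Y, x_col, Z_aug if Z_aug.shape[1] else None,
                                     compute_scores=False)
    except ValidationError:
        return None
    return res


def _augmented_Z(Z_values, X, selected_idx):
    cols = [Z_values] if Z_values.shape[1] else []
    if selected_idx:
        cols.append(X.membership[:, selected_idx])
    if not cols:
        return np.zeros((X.membership.shape[0], 0))
    return np.column_stack(cols)


def _reference_inertia(Y, Z_values, denominator: str):
    from .cca import chi_square_residuals, partial_out, weighted_center

    chi = chi_square_residuals(Y)
    total = chi.total_inertia
    if denominator == "total" or Z_values.shape[1] == 0:
        return total, "total"
    _, cov = partial_out(chi.Q, weighted_center(Z_values, chi.row_weights))
    return total - cov, "total-minus-covariates"


def forward_select(
    Y: DietMatrix,
    X: CladeMatrix,
    Z=None,
    config: AnalysisConfig | None = None,
) -> SelectionTrace:
    """Forward stepwise clade selection with permutation gating.

    At each step candidates are ranked by added inertia (ties broken
    lexicographically by clade name); only the top-ranked candidate is
    permutation-tested and admitted if ``p < alpha``.  With
    ``config.fallback_to_next_significant`` the next-ranked candidates
    are tested in turn when the leader fails.  Permutation streams are
    split deterministically per (step, candidate) from the config seed.
    """
    config = config or AnalysisConfig()
    from .cca import _as_values

    Z_values, z_names = _as_values(Z)
    if Z_values.ndim == 1:
        Z_values = Z_values[:, None]
    n = len(Y.species_ids)
    if Z_values.size == 0:
        Z_values = np.zeros((n, 0))

    reference, ref_kind = _reference_inertia(Y, Z_values, config.percent_denominator)
    trace = SelectionTrace(
        reference_inertia=reference,
        reference_kind=ref_kind,
        conditioned_covariates=list(z_names),
        alpha=config.alpha,
    )
    if X.n_clades == 0:
        warnings.warn("empty clade matrix; nothing to select", stacklevel=2)
        return trace

    selected: list[int] = []
    step = 0
    while len(selected) < X.n_clades:
        Z_aug = _augmented_Z(Z_values, X, selected)
        candidates = []
        for j in range(X.n_clades):
            if j in selected:
                continue
            res = _added_inertia(Y, X.membership[:, [j]], Z_aug)
            if res is None or res.constrained_inertia <= 1e-12:
                continue
            candidates.append((j, res.constrained_inertia))
        if not candidates:
            break
        # rank by added inertia, ties broken by clade name for determinism
        candidates.sort(key=lambda t: (-t[1], X.clade_names[t[0]]))

        admitted = False
        for j, added in candidates:
            test = permutation_test(
                Y, X.membership[:, [j]], Z_aug if Z_aug.shape[1] else None,
                mode="term", config=config,
                rng=rng_for(config.seed, 101, step, j),
                term_name=X.clade_names[j],
            )
            if test.p_value < config.alpha:
                trace.steps.append({
                    "clade_name": X.clade_names[j],
                    "added_inertia": float(added),
                    "percent_of_reference": 100.0 * added / reference,
                    "F": test.F_observed,
                    "p_value": test.p_value,
                    "n_permutations": test.n_permutations,
                })
                selected.append(j)
                admitted = True
                break
            if not config.fallback_to_next_significant:
                break
        if not admitted:
            break
        step += 1
    return trace


def marginal_effects(
    Y: DietMatrix,
    X: CladeMatrix,
    Z=None,
    config: AnalysisConfig | None = None,
) -> list[dict]:
    """Each clade tested alone against the covariates only (no
    conditioning on other clades).  Returns one record per clade with its
    standalone inertia, percent of the reference denominator, pseudo-F
    and permutation p, ordered by decreasing inertia."""
    config = config or AnalysisConfig()
    from .cca import _as_values

    Z_values, _ = _as_values(Z)
    if Z_values.ndim == 1:
        Z_values = Z_values[:, None]
    n = len(Y.species_ids)
    if Z_values.size == 0:
        Z_values = np.zeros((n, 0))
    reference, ref_kind = _reference_inertia(Y, Z_values, config.percent_denominator)

    rows = []
    for j in range(X.n_clades):
        res = _added_inertia(Y, X.membership[:, [j]], Z_values)
        if res is None:
            continue
        test = permutation_test(
            Y, X.membership[:, [j]], Z_values if Z_values.shape[1] else None,
            mode="term", config=config,
            rng=rng_for(config.seed, 202, j),
            term_name=X.clade_names[j],
        )
        rows.append({
            "clade_name": X.clade_names[j],
            "inertia_alone": float(res.constrained_inertia),
            "percent_of_reference": 100.0 * res.constrained_inertia / reference,
            "F": test.F_observed,
            "p_value": test.p_value,
            "reference_kind": ref_kind,
        })
    rows.sort(key=lambda d: (-d["inertia_alone"], d["clade_name"]))
    return rows


def explained_fraction(Y: DietMatrix, X, Z=None) -> ExplainedFraction:
    """Partition total inertia into the fractions explained by the clade
    constraints, by the covariates, and left unexplained; the three sum
    to one."""
    res = constrained_ordination(Y, X, Z, compute_scores=False)
    t = res.total_inertia
    return ExplainedFraction(
        phylogeny=res.constrained_inertia / t,
        covariates=res.covariate_inertia / t,
        unexplained=res.residual_inertia / t,
    )
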