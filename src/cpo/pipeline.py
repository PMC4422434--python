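"""End-to-end canonical phylogenetic ordination pipeline.

``run_cpo`` reproduces the full analysis sequence from input files or
in-memory objects: global permutation test, first-axis test, variance
partitioning, forward clade selection, and symmetric-biplot axis
summaries — optionally repeated for each covariate set (none / habitat /
SVL / both).  Every report echoes the configuration (seed, permutation
count and scheme, percentage denominator) completely enough to re-run
bit-identically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clade_encoding
from .cca import constrained_ordination
from .datamodel import (
    AnalysisConfig,
    CladeMatrix,
    CovariateTable,
    DietMatrix,
    ValidationError,
    read_clade_table,
    read_covariates,
    read_diet_matrix,
)
from .diet import profile_table
from .pca import PCAResult, pca_standardized
from .permutation import permutation_test
from .selection import SelectionTrace, explained_fraction, forward_select


@dataclass
class PipelineReport:
    """One covariate-variant's worth of results plus shared summaries."""

    config: dict
    variants: dict = field(default_factory=dict)
    pca: dict | None = None
    diet_profiles: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "variants": self.variants,
            "pca": self.pca,
            "diet_profiles": self.diet_profiles,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _check_alignment(Y: DietMatrix, X: CladeMatrix, cov: CovariateTable | None):
    if list(X.species_ids) != list(Y.species_ids):
        missing = sorted(set(Y.species_ids) ^ set(X.species_ids))
        raise ValidationError(f"species mismatch between diet and clade matrices: {missing}")
    if cov is not None and list(cov.species_ids) != list(Y.species_ids):
        missing = sorted(set(Y.species_ids) ^ set(cov.species_ids))
        raise ValidationError(f"species mismatch between diet and covariates: {missing}")


def _variant_Z(cov: CovariateTable | None, which: str):
    if which == "none" or cov is None:
        return None
    names, values = clade_encoding.covariate_design(cov, which=which)
    if not names:
        return None
    return (names, values)


def analyse_variant(Y: DietMatrix, X: CladeMatrix, Z, config: AnalysisConfig) -> dict:
    """Global test, first-axis test, variance partition, forward selection
    and axis percentages for one covariate design."""
    g = permutation_test(Y, X, Z, mode="global", config=config)
    fa = permutation_test(Y, X, Z, mode="first_axis", config=config)
    frac = explained_fraction(Y, X, Z)
    trace: SelectionTrace = forward_select(Y, X, Z, config=config)
    ord_full = constrained_ordination(Y, X, Z)
    return {
        "global_test": g.to_dict(),
        "first_axis_test": fa.to_dict(),
        "explained_fraction": {
            "phylogeny": frac.phylogeny,
            "covariates": frac.covariates,
            "unexplained": frac.unexplained,
        },
        "selection": trace.to_dict(),
        "eigenvalues": list(map(float, ord_full.eigenvalues)),
        "axis_percent_of_constrained": list(map(float, ord_full.axis_percent_of_constrained)),
        "axis_percent_of_total": list(map(float, ord_full.axis_percent_of_total)),
        "first_two_axes_percent_of_constrained": float(
            ord_full.axis_percent_of_constrained[:2].sum()
        ),
    }


def run_cpo(
    Y: DietMatrix,
    X: CladeMatrix,
    covariates: CovariateTable | None = None,
    covariate_sets: tuple[str, ...] = ("none",),
    config: AnalysisConfig | None = None,
) -> PipelineReport:
    """Run the constrained-ordination pipeline for each covariate set.

    ``covariate_sets`` entries are ``none``, ``habitat``, ``svl`` or
    ``both``; sets needing covariates are skipped (with a warning) when
    no covariate table is supplied.
    """
    config = config or AnalysisConfig()
    _check_alignment(Y, X, covariates)
    report = PipelineReport(config={
        "n_permutations": config.n_permutations,
        "seed": config.seed,
        "alpha": config.alpha,
        "perm_scheme": config.perm_scheme,
        "percent_denominator": config.percent_denominator,
        "scaling": config.scaling,
        "covariate_sets": list(covariate_sets),
    })
    if Y.dropped_categories:
        report.warnings.append(f"dropped all-zero prey categories: {Y.dropped_categories}")
    if X.aliases:
        report.warnings.append(f"collapsed duplicate clades: {X.aliases}")
    for which in covariate_sets:
        if which != "none" and covariates is None:
            report.warnings.append(f"covariate set {which!r} skipped: no covariate table")
            continue
        Z = _variant_Z(covariates, which)
        report.variants[which] = analyse_variant(Y, X, Z, config)
    report.pca = pca_standardized(Y).to_dict()
    report.diet_profiles = [p.to_dict() for p in profile_table(Y)]
    return report


def run_cpo_files(
    diet_path: str,
    tree_path: str | None = None,
    clades_path: str | None = None,
    covariates_path: str | None = None,
    covariate_sets: tuple[str, ...] = ("none",),
    config: AnalysisConfig | None = None,
) -> PipelineReport:
    """File-based front end: diet CSV/TSV + (Newick tree | clade table)
    + optional covariate CSV."""
    Y = read_diet_matrix(diet_path)
    if tree_path:
        tree = clade_encoding.load_tree(tree_path)
        X = clade_encoding.clade_matrix_from_tree(tree, species_ids=Y.species_ids)
    elif clades_path:
        pairs = read_clade_table(clades_path)
        X = clade_encoding.clade_matrix_from_table(pairs, species_ids=Y.species_ids)
    else:
        raise ValidationError("need either a tree or a clade-assignment table")
    cov = read_covariates(covariates_path, species_order=Y.species_ids) \
        if covariates_path else None
    return run_cpo(Y, X, cov, covariate_sets=covariate_sets, config=config)


def run_pca(diet_path: str, as_proportions: bool = True) -> PCAResult:
    return pca_standardized(read_diet_matrix(diet_path), as_proportions=as_proportions)
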