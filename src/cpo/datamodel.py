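"""Core data containers, file readers/writers and validation.

The three matrices of a canonical phylogenetic ordination:

* ``DietMatrix`` — the response matrix Y, species × prey-category counts
  (frequencies of consumed prey items per category);
* ``CladeMatrix`` — the constraint matrix X, species × clade binary
  membership indicators;
* ``CovariateTable`` — the covariate table E, per-species body size
  (snout–vent length) and habitat category.

All containers keep species in an explicit order; alignment between Y, X
and E is by exact species label (whitespace-trimmed, case-sensitive).
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: closed vocabulary of habitat-use categories
HABITAT_LEVELS = ("aquatic", "arboreal", "fossorial", "semi-aquatic", "terrestrial")


class ValidationError(ValueError):
    """Raised when an input matrix or table violates a structural invariant."""


@dataclass
class DietMatrix:
    """Species × prey-category frequency matrix (the response matrix Y).

    Parameters
    ----------
    species_ids :
        Ordered row labels; must be unique.
    prey_categories :
        Ordered column labels; must be unique.
    counts :
        Nonnegative ``(n, m)`` array of prey frequencies.  Columns whose
        sum is zero are dropped (with a warning); a zero row is an error
        because a species without prey records cannot enter a
        correspondence analysis.
    """

    species_ids: list[str]
    prey_categories: list[str]
    counts: np.ndarray
    dropped_categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if len(self.species_ids) != n or len(self.prey_categories) != m:
            raise ValidationError("label lengths do not match count matrix shape")
        if len(set(self.species_ids)) != n:
            dupes = sorted({s for s in self.species_ids if self.species_ids.count(s) > 1})
            raise ValidationError(f"duplicate species labels: {dupes}")
        if len(set(self.prey_categories)) != m:
            raise ValidationError("duplicate prey-category labels")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            bad = np.argwhere((self.counts < 0) | ~np.isfinite(self.counts))[0]
            raise ValidationError(
                f"negative or non-finite count at row {self.species_ids[bad[0]]!r}, "
                f"column {self.prey_categories[bad[1]]!r}"
            )
        row_sums = self.counts.sum(axis=1)
        if np.any(row_sums == 0):
            zero = [s for s, t in zip(self.species_ids, row_sums) if t == 0]
            raise ValidationError(f"species with no prey records: {zero}")
        col_sums = self.counts.sum(axis=0)
        if np.any(col_sums == 0):
            keep = col_sums > 0
            dropped = [c for c, k in zip(self.prey_categories, keep) if not k]
            warnings.warn(f"dropping all-zero prey categories: {dropped}", stacklevel=2)
            logger.warning("dropping all-zero prey categories: %s", dropped)
            self.dropped_categories = self.dropped_categories + dropped
            self.prey_categories = [c for c, k in zip(self.prey_categories, keep) if k]
            self.counts = self.counts[:, keep]
        n, m = self.counts.shape
        if n < 3:
            raise ValidationError(f"need at least 3 species, got {n}")
        if m < 2:
            raise ValidationError(f"need at least 2 prey categories, got {m}")

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.species_ids, columns=self.prey_categories)

    def row_proportions(self) -> np.ndarray:
        """Per-species diet composition (rows sum to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)


@dataclass
class CladeMatrix:
    """Species × clade binary membership matrix (the constraint matrix X).

    Columns that are all-0 or all-1 carry no contrast against the weighted
    intercept and are dropped with a warning; duplicate membership vectors
    are collapsed to a single column whose aliases are logged.
    """

    species_ids: list[str]
    clade_names: list[str]
    membership: np.ndarray
    aliases: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        n, k = self.membership.shape
        if len(self.species_ids) != n or len(self.clade_names) != k:
            raise ValidationError("label lengths do not match membership shape")
        if not np.all(np.isin(self.membership, (0.0, 1.0))):
            raise ValidationError("clade membership entries must be exactly 0 or 1")
        # drop constant columns (all-1 is collinear with the intercept)
        sums = self.membership.sum(axis=0)
        keep = (sums > 0) & (sums < n)
        if not np.all(keep):
            dropped = [c for c, k_ in zip(self.clade_names, keep) if not k_]
            warnings.warn(f"dropping constant clade columns: {dropped}", stacklevel=2)
            self.clade_names = [c for c, k_ in zip(self.clade_names, keep) if k_]
            self.membership = self.membership[:, keep]
        # collapse duplicate membership vectors, keeping first name
        seen: dict[tuple, int] = {}
        keep_idx: list[int] = []
        for j, col in enumerate(self.membership.T):
            key = tuple(col.astype(int))
            if key in seen:
                canon = self.clade_names[keep_idx[seen[key]]]
                self.aliases.setdefault(canon, []).append(self.clade_names[j])
                logger.warning("clade %r duplicates %r; collapsed", self.clade_names[j], canon)
            else:
                seen[key] = len(keep_idx)
                keep_idx.append(j)
        if len(keep_idx) < self.membership.shape[1]:
            self.clade_names = [self.clade_names[j] for j in keep_idx]
            self.membership = self.membership[:, keep_idx]

    @property
    def n_clades(self) -> int:
        return self.membership.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.membership, index=self.species_ids, columns=self.clade_names)

    def subset(self, names: Sequence[str]) -> "CladeMatrix":
        idx = [self.clade_names.index(nm) for nm in names]
        return CladeMatrix(
            species_ids=list(self.species_ids),
            clade_names=[self.clade_names[i] for i in idx],
            membership=self.membership[:, idx].copy(),
        )


@dataclass
class CovariateTable:
    """Per-species covariates: adult snout–vent length (mm) and habitat use."""

    species_ids: list[str]
    svl_mm: np.ndarray
    habitat: list[str]

    def __post_init__(self) -> None:
        self.svl_mm = np.asarray(self.svl_mm, dtype=float)
        n = len(self.species_ids)
        if len(set(self.species_ids)) != n:
            raise ValidationError("duplicate species in covariate table")
        if self.svl_mm.shape != (n,) or len(self.habitat) != n:
            raise ValidationError("covariate lengths do not match species list")
        if np.any(self.svl_mm <= 0) or not np.all(np.isfinite(self.svl_mm)):
            raise ValidationError("svl_mm must be positive and finite")
        bad = sorted({h for h in self.habitat if h not in HABITAT_LEVELS})
        if bad:
            raise ValidationError(
                f"unknown habitat categories {bad}; legal levels are {list(HABITAT_LEVELS)}"
            )

    def reorder(self, species_order: Sequence[str]) -> "CovariateTable":
        """Align records to a caller-supplied species order."""
        missing = [s for s in species_order if s not in self.species_ids]
        if missing:
            raise ValidationError(f"covariate table missing species: {missing}")
        idx = [self.species_ids.index(s) for s in species_order]
        return CovariateTable(
            species_ids=list(species_order),
            svl_mm=self.svl_mm[idx],
            habitat=[self.habitat[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"svl": self.svl_mm, "habitat": self.habitat}, index=self.species_ids
        )


@dataclass
class AnalysisConfig:
    """Settings shared by the permutation tests and the stepwise selection.

    Defaults are the conventional ones for this analysis family:
    9,999 Monte Carlo permutations, alpha = 0.05, unrestricted (whole-row)
    permutation units, reduced-model residual permutation when covariates
    are present.
    """

    n_permutations: int = 9999
    seed: int = 0
    alpha: float = 0.05
    selection_mode: str = "conditional"  # {conditional, marginal}
    scaling: str = "symmetric_biplot"
    perm_scheme: str = "residual"  # {residual, raw}: scheme used when covariates present
    percent_denominator: str = "total"  # {total, total-minus-covariates}
    fallback_to_next_significant: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.selection_mode not in ("conditional", "marginal"):
            raise ValidationError("selection_mode must be 'conditional' or 'marginal'")
        if self.perm_scheme not in ("residual", "raw"):
            raise ValidationError("perm_scheme must be 'residual' or 'raw'")
        if self.percent_denominator not in ("total", "total-minus-covariates"):
            raise ValidationError(
                "percent_denominator must be 'total' or 'total-minus-covariates'"
            )


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    header = Path(path).open().readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_diet_matrix(path: str | Path, sep: str | None = None) -> DietMatrix:
    """Read a species × prey-category count matrix from delimited text.

    First row holds prey-category headers, first column species labels.
    The delimiter is auto-detected (comma or tab) unless ``sep`` is given.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    species = [str(s).strip() for s in df.index]
    cats = [str(c).strip() for c in df.columns]
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path.name}: {exc}") from exc
    bad = np.argwhere(~np.isfinite(counts) | (counts < 0))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"negative or non-numeric value at species {species[i]!r}, category {cats[j]!r}"
        )
    return DietMatrix(species_ids=species, prey_categories=cats, counts=counts)


def read_covariates(path: str | Path, species_order: Sequence[str] | None = None,
                    sep: str | None = None) -> CovariateTable:
    """Read a covariate table with columns ``species``, ``svl``, ``habitat``.

    If ``species_order`` is given the records are reordered to match it;
    species present in the order but absent from the file are a hard error.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"species", "svl", "habitat"}
    if not required.issubset(df.columns):
        raise ValidationError(f"covariate file needs columns {sorted(required)}")
    table = CovariateTable(
        species_ids=[str(s).strip() for s in df["species"]],
        svl_mm=df["svl"].astype(float).to_numpy(),
        habitat=[str(h).strip() for h in df["habitat"]],
    )
    if species_order is not None:
        table = table.reorder(species_order)
    return table


def read_clade_table(path: str | Path, sep: str | None = None) -> list[tuple[str, str]]:
    """Read a two-column (species, clade) assignment table."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if not {"species", "clade"}.issubset(cols):
        raise ValidationError("clade table needs columns 'species' and 'clade'")
    return [(str(s).strip(), str(c).strip()) for s, c in zip(df["species"], df["clade"])]


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

def _format_row(step: dict) -> dict:
    """Render one selection-trace row with the conventional table precision:
    inertia to 4 decimals, percentage both integer-rounded and raw,
    F to 2 decimals, P to 4 decimals."""
    return {
        "Taxa": step["clade_name"],
        "Variation": f"{step['added_inertia']:.4f}",
        "Variation %": str(int(round(step["percent_of_reference"]))),
        "Variation % (raw)": f"{step['percent_of_reference']:.4f}",
        "F": f"{step['F']:.2f}",
        "P": f"{step['p_value']:.4f}",
    }


def write_report(result, path: str | Path, format: str = "json") -> None:
    """Serialize a result object (``SelectionTrace``, ``OrdinationResult`` or
    ``PermutationTestResult``) to JSON or, for selection traces, TSV shaped
    like a published clade-selection table (columns Taxa / Variation /
    Variation % / F / P)."""
    path = Path(path)
    if format == "json":
        payload = result.to_dict() if hasattr(result, "to_dict") else result
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
        return
    if format == "tsv":
        steps = getattr(result, "steps", None)
        if steps is None:
            raise ValidationError("TSV output is only defined for selection traces")
        cols = ["Taxa", "Variation", "Variation %", "F", "P"]
        lines = ["\t".join(cols)]
        for step in steps:
            row = _format_row(step if isinstance(step, dict) else step.to_dict())
            lines.append("\t".join(row[c] for c in cols))
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValidationError(f"unknown report format {format!r}")


def write_diet_matrix(Y: DietMatrix, path: str | Path, sep: str = ",") -> None:
    Y.to_frame().to_csv(path, sep=sep, index_label="species")


def write_covariates(cov: CovariateTable, path: str | Path, sep: str = ",") -> None:
    cov.to_frame().to_csv(path, sep=sep, index_label="species")
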