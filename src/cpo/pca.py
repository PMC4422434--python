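"""Indirect ordination: PCA of standardized diet variables.

Complements the constrained analysis: an unconstrained PCA of the
z-scored diet composition shows how much dietary variation the leading
axes summarize when no explanatory structure is imposed.  By default the
input counts are first converted to per-species proportions (removing
sample-size differences between species) before standardization; a flag
switches to raw counts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import DietMatrix, ValidationError


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: np.ndarray       # variables × axes
    scores: np.ndarray         # species × axes
    variable_names: list = field(default_factory=list)
    species_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "eigenvalues": list(map(float, self.eigenvalues)),
            "percent_variance": list(map(float, self.percent_variance)),
            "variable_names": self.variable_names,
        }


def pca_standardized(Y: DietMatrix, as_proportions: bool = True) -> PCAResult:
    """Correlation-matrix PCA of the diet variables.

    Columns are standardized to mean 0, unit variance (n-1 divisor);
    eigenvalues of the correlation matrix sum to the number of retained
    variables, so each axis's share of variance is eigenvalue / m.
    Zero-variance columns are dropped with a warning.  Loading signs
    follow the convention that each axis's largest-magnitude loading is
    positive.
    """
    data = Y.row_proportions() if as_proportions else Y.counts.astype(float)
    names = list(Y.prey_categories)
    n = data.shape[0]
    if n < 3:
        raise ValidationError("PCA needs at least 3 species")
    sd = data.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = [nm for nm, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance diet variables: {dropped}", stacklevel=2)
        data, names = data[:, keep], [nm for nm, k in zip(names, keep) if k]
        sd = sd[keep]
    m = data.shape[1]
    if m < 2:
        raise ValidationError("PCA needs at least 2 variable columns with variance")
    Zs = (data - data.mean(axis=0)) / sd
    corr = (Zs.T @ Zs) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: dominant loading of each axis is positive
    for a in range(m):
        j = np.argmax(np.abs(eigvec[:, a]))
        if eigvec[j, a] < 0:
            eigvec[:, a] = -eigvec[:, a]
    scores = Zs @ eigvec
    return PCAResult(
        eigenvalues=eigval,
        percent_variance=100.0 * eigval / m,
        loadings=eigvec,
        scores=scores,
        variable_names=names,
        species_ids=list(Y.species_ids),
    )
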