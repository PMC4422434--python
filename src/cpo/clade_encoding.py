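"""Build binary clade design matrices from a phylogeny or a taxonomy table,
and dummy-encode habitat covariates.

The constraint matrix X of a canonical phylogenetic ordination has one
binary column per clade (monophyletic group): 1 where the species belongs
to the clade, 0 elsewhere.  The root (all species) and singleton tips are
excluded by default — both are either collinear with the weighted
intercept or uninformative at the community level — and clades with
identical membership (nested nodes subtending the same analysed species)
are collapsed to one column.
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .datamodel import CladeMatrix, CovariateTable, ValidationError

logger = logging.getLogger(__name__)


def load_tree(path_or_newick: str, taxon_namespace=None) -> dendropy.Tree:
    """Load a rooted Newick tree from a file path or a Newick string."""
    src = str(path_or_newick)
    kwargs = dict(schema="newick", preserve_underscores=True)
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, **kwargs)
    return dendropy.Tree.get(path=src, **kwargs)


def _tip_labels(node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def clade_matrix_from_tree(
    tree: dendropy.Tree,
    species_ids: Sequence[str] | None = None,
    min_size: int = 2,
) -> CladeMatrix:
    """One binary column per internal node of the (rooted) tree.

    Parameters
    ----------
    tree :
        Rooted phylogeny whose tip labels cover the analysis species.
    species_ids :
        Analysis species (row order of the diet matrix).  Defaults to all
        tips of the tree in their tree order.
    min_size :
        Minimum number of analysis species a node must subtend to be
        emitted (default 2: singletons excluded).  Nodes subtending every
        analysis species (the root clade) are always excluded.

    Columns are named by the internal node label where present, else by a
    short memo of the member species.  Duplicate membership vectors are
    collapsed by the :class:`~cpo.datamodel.CladeMatrix` constructor.
    """
    all_tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if species_ids is None:
        species_ids = all_tips
    species_ids = [str(s).strip() for s in species_ids]
    missing = [s for s in species_ids if s not in all_tips]
    if missing:
        raise ValidationError(f"species absent from tree: {missing}")
    n = len(species_ids)
    index = {s: i for i, s in enumerate(species_ids)}

    names: list[str] = []
    cols: list[np.ndarray] = []
    for node in tree.preorder_internal_node_iter():
        members = [t for t in _tip_labels(node) if t in index]
        if len(members) < min_size or len(members) >= n:
            continue  # skip singletons (below min_size) and the root clade
        col = np.zeros(n)
        for m in members:
            col[index[m]] = 1.0
        label = None
        if node.label:
            label = str(node.label)
        elif node.taxon is not None and node.taxon.label:
            label = str(node.taxon.label)
        if not label:
            memo = sorted(members)
            label = "+".join(memo[:2]) + (f"+{len(memo) - 2}more" if len(memo) > 2 else "")
        names.append(label)
        cols.append(col)
    membership = np.column_stack(cols) if cols else np.zeros((n, 0))
    return CladeMatrix(species_ids=list(species_ids), clade_names=names, membership=membership)


def clade_matrix_from_table(
    assignments: Iterable[tuple[str, str]],
    species_ids: Sequence[str],
    min_size: int = 1,
) -> CladeMatrix:
    """Binary clade matrix from (species, clade) pairs.

    This curated path allows singleton clades (``min_size=1``) so that
    named monotypic groups from a published analysis can be coded even
    when a tree-derived matrix would exclude them.
    """
    species_ids = [str(s).strip() for s in species_ids]
    index = {s: i for i, s in enumerate(species_ids)}
    n = len(species_ids)
    cols: dict[str, np.ndarray] = {}
    for sp, clade in assignments:
        sp, clade = str(sp).strip(), str(clade).strip()
        if not clade:
            raise ValidationError("empty clade name in assignment table")
        if sp not in index:
            raise ValidationError(f"species {sp!r} not in analysis species list")
        cols.setdefault(clade, np.zeros(n))[index[sp]] = 1.0
    names, mats = [], []
    for name, col in cols.items():
        size = int(col.sum())
        if size < min_size:
            warnings.warn(f"clade {name!r} has {size} members < min_size; dropped", stacklevel=2)
            continue
        if size == n:
            warnings.warn(f"clade {name!r} contains every species; dropped", stacklevel=2)
            continue
        names.append(name)
        mats.append(col)
    membership = np.column_stack(mats) if mats else np.zeros((n, 0))
    return CladeMatrix(species_ids=species_ids, clade_names=names, membership=membership)


def encode_habitat(cov: CovariateTable, drop_level: str = "terrestrial"):
    """Dummy-encode habitat: one 0/1 column per observed non-reference level.

    The reference (dropped) level defaults to ``terrestrial`` — the
    generalized snake morphology — so the dummies measure departures from
    it.  Levels observed in no species yield no column; if every species
    shares one habitat the design is empty (a constant covariate carries
    no information).

    Returns
    -------
    (column_names, values) :
        Lexicographically ordered level names and the ``(n, p)`` 0/1 array.
    """
    observed = sorted(set(cov.habitat))
    if drop_level not in observed:
        raise ValidationError(
            f"drop_level {drop_level!r} not among observed habitats {observed}"
        )
    levels = [lv for lv in observed if lv != drop_level]
    if not levels:
        warnings.warn("all species share one habitat; empty habitat design", stacklevel=2)
        return [], np.zeros((len(cov.species_ids), 0))
    values = np.column_stack([
        np.asarray([1.0 if h == lv else 0.0 for h in cov.habitat]) for lv in levels
    ])
    return [f"habitat[{lv}]" for lv in levels], values


def covariate_design(
    cov: CovariateTable,
    which: str = "both",
    drop_level: str = "terrestrial",
):
    """Assemble the covariate design Z: SVL and/or habitat dummies.

    ``which`` is one of ``{"none", "svl", "habitat", "both"}``.
    """
    names: list[str] = []
    cols: list[np.ndarray] = []
    if which in ("svl", "both"):
        names.append("svl")
        cols.append(cov.svl_mm.astype(float))
    if which in ("habitat", "both"):
        hn, hv = encode_habitat(cov, drop_level=drop_level)
        names.extend(hn)
        if hv.shape[1]:
            cols.append(hv)
    if which == "none" or not cols:
        return [], np.zeros((len(cov.species_ids), 0))
    values = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return names, values
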