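"""Synthetic snake-community generator with known ground truth.

Every inference stage of the package is testable against data whose
generating process is known exactly.  The generator produces:

* a pure-birth (Yule) topology with unit branch lengths and labeled
  internal nodes;
* a diet count matrix from a softmax-multinomial model: species i's
  prey-category probabilities are ``softmax(base + Σ clade effects +
  habitat effect + ε_i)`` where ε is Brownian motion on the tree, and the
  counts are multinomial with Poisson-distributed per-species totals;
* tree-correlated covariates: Brownian log snout–vent length, and
  habitat as either a Markov walk on the tree or i.i.d. labels.

Additive effects on the log-preference scale compose transparently, so a
"planted" clade effect has a directly interpretable magnitude, and
Brownian noise supplies phylogenetically structured overdispersion.
Defaults mirror a temperate snake community survey: 25 species, 8 prey
categories, and about 79 prey records per species (≈1966 specimens over
25 species).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .datamodel import CovariateTable, DietMatrix, HABITAT_LEVELS, ValidationError


@dataclass
class SimulationConfig:
    n_species: int = 25
    n_prey_categories: int = 8
    tree_seed: int = 0
    data_seed: int = 0
    #: clade label -> length-m additive log-preference shift
    clade_effects: dict = field(default_factory=dict)
    brownian_sigma: float = 0.2
    items_per_species: float = 79.0
    #: habitat label -> length-m additive log-preference shift
    habitat_effect: dict = field(default_factory=dict)
    svl_root_log_mm: float = 6.55   # e^6.55 ≈ 700 mm, a mid-sized snake
    svl_brownian_sigma: float = 0.25
    habitat_tree_correlated: bool = True
    habitat_switch_prob: float = 0.35

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValidationError("need at least 4 species")
        if self.items_per_species < 1:
            raise ValidationError("items_per_species must be >= 1")
        for label, eff in self.clade_effects.items():
            arr = np.asarray(eff, dtype=float)
            if arr.shape != (self.n_prey_categories,) or not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"clade effect {label!r} must be a finite length-"
                    f"{self.n_prey_categories} vector"
                )


@dataclass
class SyntheticDataset:
    tree: dendropy.Tree
    Y: DietMatrix
    covariates: CovariateTable
    truth: dict
    config: SimulationConfig


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) topology with unit branch lengths.

    Tips are labeled ``sp01 … spNN`` in creation order; internal nodes
    are labeled ``n1, n2, …`` in preorder (``n1`` is the root).
    Deterministic for a given seed.
    """
    if n_species < 4:
        raise ValidationError("need at least 4 species")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    left, right = tree.seed_node.new_child(), tree.seed_node.new_child()
    leaves = [left, right]
    while len(leaves) < n_species:
        idx = int(rng.integers(len(leaves)))
        parent = leaves.pop(idx)
        leaves.append(parent.new_child())
        leaves.append(parent.new_child())
    width = max(2, len(str(n_species)))
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{i:0{width}d}")
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            node.edge.length = 1.0
    for k, node in enumerate(tree.preorder_internal_node_iter(), start=1):
        node.label = f"n{k}"
    return tree


def internal_node_tips(tree: dendropy.Tree) -> dict[str, list[str]]:
    """Map each labeled internal node to its tip labels."""
    return {
        node.label: sorted(lf.taxon.label for lf in node.leaf_iter())
        for node in tree.preorder_internal_node_iter()
        if node.label
    }


def random_clade(tree: dendropy.Tree, rng: np.random.Generator,
                 min_size: int = 2, max_size: int | None = None) -> str:
    """Label of a uniformly chosen non-root internal node whose tip count
    lies in [min_size, max_size]."""
    n = sum(1 for _ in tree.leaf_node_iter())
    if max_size is None:
        max_size = n - 1
    tips = internal_node_tips(tree)
    root_label = next(tree.preorder_internal_node_iter()).label
    eligible = [lab for lab, t in tips.items()
                if lab != root_label and min_size <= len(t) <= max_size]
    if not eligible:
        raise ValidationError("no internal node in the requested size range")
    return eligible[int(rng.integers(len(eligible)))]


def _brownian_on_tree(tree, rng, sigma: float, dim: int) -> dict[str, np.ndarray]:
    """Per-tip Brownian displacements (dim-vector), variance sigma^2 per
    unit branch length, root at the origin."""
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(dim)
            continue
        bl = node.edge.length or 0.0
        step = rng.normal(0.0, sigma * np.sqrt(bl), size=dim) if sigma > 0 and bl > 0 \
            else np.zeros(dim)
        values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def simulate_covariates(tree: dendropy.Tree, config: SimulationConfig,
                        seed: int | None = None) -> CovariateTable:
    """Tree-correlated covariates: Brownian log-SVL and Markov-walk (or
    i.i.d.) habitat states."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed if seed is not None else config.data_seed), 11])
    )
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    bm = _brownian_on_tree(tree, rng, config.svl_brownian_sigma, 1)
    svl = np.array([np.exp(config.svl_root_log_mm + bm[s][0]) for s in species])

    habitat: dict[str, str] = {}
    if config.habitat_tree_correlated:
        states: dict[int, str] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                states[id(node)] = "terrestrial"
            else:
                parent_state = states[id(node.parent_node)]
                if rng.random() < config.habitat_switch_prob:
                    states[id(node)] = HABITAT_LEVELS[int(rng.integers(len(HABITAT_LEVELS)))]
                else:
                    states[id(node)] = parent_state
            if node.is_leaf():
                habitat[node.taxon.label] = states[id(node)]
    else:
        for s in species:
            habitat[s] = HABITAT_LEVELS[int(rng.integers(len(HABITAT_LEVELS)))]
    return CovariateTable(
        species_ids=species,
        svl_mm=svl,
        habitat=[habitat[s] for s in species],
    )


def simulate_diet(tree: dendropy.Tree, config: SimulationConfig,
                  seed: int | None = None,
                  covariates: CovariateTable | None = None) -> SyntheticDataset:
    """Draw a diet count matrix from the softmax-multinomial model.

    Species rows with zero totals are redrawn; in the rare event that a
    prey category receives no record anywhere, the whole matrix is
    redrawn (up to a bounded number of attempts) so the result satisfies
    the count-matrix invariants without dropping columns.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed if seed is not None else config.data_seed), 13])
    )
    m = config.n_prey_categories
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(species)
    tips = internal_node_tips(tree)
    for label in config.clade_effects:
        if label not in tips:
            raise ValidationError(f"effect clade {label!r} is not a labeled tree node")

    if covariates is None:
        covariates = simulate_covariates(tree, config, seed=seed)
    cov = covariates.reorder(species)

    eta = np.zeros((n, m))
    for label, eff in config.clade_effects.items():
        members = set(tips[label])
        eff = np.asarray(eff, dtype=float)
        for i, s in enumerate(species):
            if s in members:
                eta[i] += eff
    if config.habitat_effect:
        for i, h in enumerate(cov.habitat):
            if h in config.habitat_effect:
                eta[i] += np.asarray(config.habitat_effect[h], dtype=float)
    bm = _brownian_on_tree(tree, rng, config.brownian_sigma, m)
    for i, s in enumerate(species):
        eta[i] += bm[s]
    ez = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs = ez / ez.sum(axis=1, keepdims=True)

    counts = None
    for _attempt in range(100):
        draw = np.empty((n, m))
        for i in range(n):
            total = 0
            while total == 0:
                total = int(rng.poisson(config.items_per_species))
            draw[i] = rng.multinomial(total, probs[i])
        if np.all(draw.sum(axis=0) > 0):
            counts = draw
            break
    if counts is None:
        counts = draw  # let the DietMatrix validator drop the empty column

    Y = DietMatrix(species_ids=species, prey_categories=[f"prey{j+1}" for j in range(m)],
                   counts=counts)
    truth = {
        "clade_effects": {
            lab: {"members": tips[lab], "effect": list(map(float, np.asarray(eff, float)))}
            for lab, eff in config.clade_effects.items()
        },
        "habitat_effect": {
            h: list(map(float, np.asarray(e, float)))
            for h, e in config.habitat_effect.items()
        },
        "brownian_sigma": config.brownian_sigma,
    }
    return SyntheticDataset(tree=tree, Y=Y, covariates=cov, truth=truth, config=config)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Tree + covariates + diet matrix in one call, fully determined by
    the config's two seeds."""
    tree = simulate_tree(config.n_species, seed=config.tree_seed)
    return simulate_diet(tree, config, seed=config.data_seed)
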