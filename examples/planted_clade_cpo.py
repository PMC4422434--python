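"""Constrained ordination of a synthetic community with a planted clade
effect.

Simulates a 25-species community in which one clade of 6-10 species has a
strong preference shift toward one prey category, then asks the
constrained correspondence analysis whether phylogeny structures the diet
and which clade is responsible.
"""
import numpy as np

import cpo

tree = cpo.simulate_tree(25, seed=7)
rng = np.random.default_rng(7)
truth = cpo.random_clade(tree, rng, min_size=6, max_size=10)
effect = np.zeros(8)
effect[0] = 3.0  # +3 log-preference for prey category 1 inside the clade

sim = cpo.SimulationConfig(
    n_species=25, n_prey_categories=8,
    tree_seed=7, data_seed=77,
    clade_effects={truth: effect},
    brownian_sigma=0.2, items_per_species=79.0,
)
ds = cpo.simulate_diet(tree, sim)
X = cpo.clade_matrix_from_tree(tree, species_ids=ds.Y.species_ids)
cfg = cpo.AnalysisConfig(n_permutations=999, seed=1)

glob = cpo.permutation_test(ds.Y, X, config=cfg)
frac = cpo.explained_fraction(ds.Y, X)
trace = cpo.forward_select(ds.Y, X, config=cfg)

print(f"planted clade: {truth} "
      f"({len(cpo.internal_node_tips(tree)[truth])} species)")
print(f"global test: F = {glob.F_observed:.2f}, p = {glob.p_value:.4f}")
print(f"phylogeny explains {100 * frac.phylogeny:.0f}% of diet inertia, "
      f"{100 * frac.unexplained:.0f}% unexplained")
print("forward selection trace (clade, % of total inertia, F, p):")
for step in trace.steps:
    print(f"  {step['clade_name']:>6}  {step['percent_of_reference']:5.1f}%  "
          f"F={step['F']:6.2f}  p={step['p_value']:.4f}")
# The global F and its small p say diet covaries with clade membership
# far beyond chance; the first selected clade should be the planted one,
# and its share of inertia reflects the strength of the planted shift.
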