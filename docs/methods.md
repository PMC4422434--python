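# Methods

## The model

A community diet matrix `Y` (n species × m prey categories, nonnegative
counts) is treated as a contingency table.  Correspondence analysis is
the natural ordination for such data — frequencies with many zeros and
unimodal species–resource relations — and its constrained form (CCA)
relates the table to an explanatory design.  In canonical phylogenetic
ordination the design `X` codes phylogeny itself: one binary column per
clade (internal node of the rooted community phylogeny), 1 for member
species, 0 otherwise.  The root clade (all species) is excluded because
it is collinear with the weighted intercept, and singleton clades are
excluded by default because a single species carries no grouping
contrast; nested nodes that subtend the same analysed species are
collapsed to one column.  A curated-table input path exists for coding a
published clade list directly, including monotypic groups.

### Inertia decomposition

With `P = Y/y··`, row weights `r` and column weights `c`, the
standardized residual matrix is `Q_ij = (P_ij − r_i c_j)/√(r_i c_j)` and
total inertia `ΣQ²` equals the table's Pearson chi-square divided by the
grand total.  Designs are weighted-centered (`Σ r_i X_ij = 0`) and rows
scaled by `√r_i`, so ordinary orthogonal projection in the transformed
space is `r`-weighted projection in species space.  Covariates `Z` are
projected out of `Q` first; the constraints are residualized against `Z`
and `Q`'s projection onto that residual constraint space is decomposed by
SVD.  Canonical eigenvalues are squared singular values;

    covariate + constrained + residual inertia = total   (to 1e−9)

holds by construction and is asserted in tests.  Projector ranks use a
relative singular-value cutoff of 1e−10 (binary clade designs over few
species are frequently exactly collinear), anchored to the pre-
residualization scale so a constraint fully absorbed by covariates is
reported as "no testable constraint" rather than as numerical noise.

### Inference

Pseudo-F uses residual degrees of freedom `n − p − q − 1` (`p` covariate
rank, `q` constraint rank, 1 for the weighted intercept), matching the
convention of the reference CCA implementation in vegan, against which
the core is verified to 12 digits on a fixed table.  Monte Carlo
significance uses the add-one estimator with ties counted as exceedances
(conservative); the minimum attainable p with B permutations is
1/(B+1).  Default B is 9,999 with alpha 0.05.

Two permutation schemes:

* without covariates, whole species rows of `Y` are permuted
  ("unrestricted" units — no blocks).  Row permutation permutes `Q`'s
  rows and the row weights jointly while column weights are unchanged,
  which allows a vectorized implementation (batched SVD over permuted
  designs) that makes thousand-replicate calibration studies cheap;
* with covariates, the default is the reduced-model scheme: rows of the
  covariate-residualized `Q` are permuted while the covariate structure
  stays fixed.  A `raw` flag permutes `Y`'s rows instead and recomputes
  the full partial analysis, since published analyses are often ambiguous
  about which of the two was used; both are first-class.

### Stepwise clade selection

The "manual selection" loop ranks every unselected clade by the inertia
it adds conditioned on (covariates + already-selected clades), then
permutation-tests the top-ranked candidate and admits it if `p < alpha`.
The literal reading — effect size ranks, significance gates, stop on the
first failure — is the default; `fallback_to_next_significant` tests the
next-ranked candidates instead of stopping.  Ties in added inertia break
lexicographically by clade name, and permutation streams are split
deterministically per (step, candidate) with `numpy.random.SeedSequence`,
so an entire analysis is reproducible from one integer seed.  Percentages
can be reported against total inertia (default) or total minus covariate
inertia; the choice is echoed in every report because published tables
rarely state which denominator they used, and both conventions are always
computable.  A marginal-effects table (each clade alone against
covariates only) is provided separately: conditional increments and
marginal shares answer different questions and sum differently.

### Scores

Symmetric biplot scaling splits each singular value evenly between row
(species) and column (prey) scores (factor `s^1/2` each); biplot arrows
for constraints are `r`-weighted correlations with the linear-combination
axes.  Axis percentages are reported both as share of constrained inertia
and share of total inertia.  Published biplots from legacy software are
reproducible only up to axis-wise scalar factors, since that software's
exact scaling constants are not recoverable; the classic weighted-
averaging transition formula is tested instead.

## Complementary analyses

*PCA* of the diet variables standardizes columns to zero mean and unit
variance and eigendecomposes the correlation matrix; percent variance per
axis is eigenvalue/m.  Default input is per-species proportions (the
compositional quantity of ecological interest; raw counts would let
sampling effort leak into the ordination), with a flag for raw counts.
Loading signs are fixed by making each axis's largest-magnitude loading
positive.

*Diet specialization* classifies each species by its largest diet
proportion f: specialist if f > 0.70, trend toward specialization if
0.50 ≤ f ≤ 0.70, generalist if f < 0.50.  The boundary at exactly 70%
goes to "trend" (specialist means strictly over 70%), and the partition
is closed at 0.50 so every f is classified; verbal definitions of the
generalist class as "no item above 49%" are treated as rounding.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
with ground truth recorded:

* **Tree**: pure-birth (Yule) topology, unit branch lengths, labeled
  internal nodes.  Topology-only methods never read the branch lengths.
* **Diet**: species i's category probabilities are
  `softmax(Σ clade effects + habitat effect + ε_i)` with `ε` Brownian on
  the tree (`brownian_sigma` per unit branch length); counts are
  multinomial with Poisson totals.  Softmax-multinomial was chosen over
  Dirichlet-multinomial because additive log-scale effects compose
  transparently and planted effect sizes stay interpretable;
  overdispersion enters through the Brownian term.
* **Covariates**: log-SVL is Brownian (root ≈ 700 mm, sigma 0.25 —
  a plausible spread for a mixed snake community); habitat is either a
  5-state Markov walk on the tree (default) or i.i.d. labels.

Defaults mirror a temperate snake community survey: 25 species, 8 prey
categories, expected 79 prey items per species (≈1966 records across 25
species).  What the generator does **not** emulate: gut-content sampling
biology (digestion, multiple prey per specimen), prey availability,
unbalanced per-species sampling effort, or correlation between effect
clades and habitat beyond what the shared tree induces.  Passing tests on
synthetic data therefore demonstrate correctness of the estimator and
calibration of the test under the stated model, not robustness to field
sampling artifacts.

## Verification strategy and problem sizes

* The chi-square algebra is checked against scipy's Pearson chi-square on
  200 random tables; the eigen-solution against R's vegan (values frozen
  to 12 digits) and against plain CA in the full-rank limit.
* The vectorized permutation engine is checked against naive
  per-permutation recomputation through the full ordination (both
  schemes).
* Type-I calibration: 1,000 exchangeable null communities (25 species,
  Brownian sigma 0, no effects), 999 permutations each; the rejection
  rate at alpha 0.05 must fall in the binomial 95% band [0.036, 0.064].
* Ground-truth recovery and power: 100 replicates with one planted clade
  effect (+3 log-preference on one category in a 6–10 species clade,
  sigma 0.2, ~50 items/species); the truth clade must be admitted first,
  and the global test must reject, in ≥95 of 100.

These replicate counts keep the whole suite under two minutes on one
core while leaving the binomial bands meaningful.

## Known limitations

* Only topology enters the clade coding; branch lengths are ignored by
  design (membership is binary).
* No correction for multiple testing across candidate clades in the
  stepwise loop — the procedure mirrors the classical manual selection,
  which applies none; treat per-clade p-values accordingly.
* The permutation test assumes species rows are exchangeable under the
  null.  Phylogenetically autocorrelated residual variation (Brownian
  noise without a focal clade effect) violates exchangeability and will
  be detected as "phylogenetic structure" — that is the intended
  behavior of the method, not a bug, but it means the type-I guarantee
  applies to the i.i.d. null only.
* With ~25 species, nested clades are often nearly collinear; conditional
  effects of parents and children must be interpreted jointly.
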