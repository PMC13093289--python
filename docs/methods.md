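# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Structured coalescent with serial sampling

Genealogies are simulated backward in time under the continuous-time
structured coalescent. Within a population of haploid effective size *N*,
*k* active lineages coalesce at total rate *k(k−1)/(2N)* per generation, so
E[T₂] = *N* and E[TMRCA(n)] = 2*N*(1 − 1/*n*) for a single population.
Lineages enter the process at their sampling age; ancient samples (e.g. a
population sampled 502 generations before present) therefore cannot
coalesce more recently than their age. Events are applied at their drawn
times:

* **Divergence** (daughter, parent): all daughter lineages move to the
  parent; the daughter is inactive further back in time.
* **Admixture pulse** (recipient, donor, rate *r*): each recipient lineage
  independently moves to the donor with probability *r*. Admixture is
  instantaneous and unidirectional; continuous migration is out of scope
  (mitochondrial scenarios here are pulse-structured).
* **Founder bottleneck** (population, *N_b*, *d_b*): the population's size
  is *N_b* on the backward-time window [*t*_div − *d_b*, *t*_div], i.e. for
  the *d_b* generations immediately following its founding divergence
  (forward view). When a bottleneck carries no explicit time it is tied to
  the population's own divergence. *d_b* gets its own prior, default
  U[1, 50] generations.

The simulator is event-driven: between breakpoints (sampling ages, event
times, bottleneck window edges) population sizes are constant and waiting
times are exponential. The continuous-time approximation was chosen over
generation-by-generation simulation for speed; the test suite checks its
T₂/TMRCA distributions against a discrete-generation Wright–Fisher
simulator (Kolmogorov–Smirnov) and against msprime.

A scenario whose divergence graph does not coalesce to a single root is
rejected at validation; a runtime guard raises if lineages are ever
stranded in populations that can no longer merge.

## Sequence model: HKY + Γ + invariable sites

Sites evolve independently under HKY (base frequencies π, transition/
transversion parameter κ). The rate matrix is normalised to one expected
substitution per unit distance; the branch distance for a site is
μ · t · ρ, where μ is the per-site per-generation mutation rate, t the
branch length in generations, and ρ the site's rate multiplier (0 with
probability p_inv, otherwise Gamma(α, mean 1), drawn continuously rather
than discretised into categories). Transition probabilities use the exact
eigendecomposition of the HKY matrix (symmetrised with √π scaling), so
multiple substitutions per site are modelled exactly rather than through
mutation-event placement. Root states are drawn from π.

Default mutation settings for the shipped model sets (μ prior
U[10⁻⁶, 10⁻⁵] per site per generation, κ prior U[2, 20], α = 0.5,
p_inv = 0.4, π ≈ (0.31, 0.21, 0.14, 0.34)) describe a fast-evolving,
AT-rich mammalian mitochondrial control region; where a test set needs a
fixed mutation process (the two-scenario self-consistency set) μ = 10⁻⁵ is
used so that nucleotide diversity at Nₑ = 1000 is a few differences per
300 bp, typical of intraspecific control-region data.

## Summary statistics

Observed and simulated alignments pass through one `summarize()` code
path producing a fixed-order vector. Per population: number of distinct
haplotypes, segregating sites, mean and variance of pairwise differences,
private segregating sites (polymorphic within the population, monomorphic
across all other samples), Tajima's D. Per population pair: mean
between-population pairwise differences (d_xy), Hudson-type
F_ST = 1 − mean(within)/mean(between), shared haplotype count. Undefined
statistics (Tajima's D with S = 0, F_ST with zero between-population
divergence, statistics of single-sample populations) are encoded as 0 plus
a companion mask column; mask columns travel with the values so forests
see identical encodings for training and observation. The exact statistic
list is a package choice spanning within- and between-population variation;
equivalence with any particular ABC software is at the level of the
method, not statistic-for-statistic output.

## ABC-RF model choice

The reference table holds (scenario, parameter draw, summary vector) rows,
with each row seeded from (master seed, scenario index, row index), so
tables are identical for any worker count. Model choice trains a
random-forest classifier (default 500 trees) on the summary features
augmented with linear-discriminant axes (one fewer than the number of
scenarios); the selected scenario takes the majority of individual tree
votes at the observed point. The posterior probability of the selected
scenario is the prediction, at the observed point, of a second forest
regressing the out-of-bag correct-classification indicator on the same
features; the global (prior) error is the out-of-bag misclassification
rate and the local error is 1 − posterior. Prior-predictive checking
projects simulations and the observed vector onto the first two PCA axes
(constant columns dropped) and reports whether the observed point falls
inside each scenario's convex hull and 1st–99th percentile box.

## Quantile-regression-forest parameter estimation

For each parameter an independent regression forest (500 trees, minimum
leaf size 5) is trained on the selected scenario's rows. Weights at the
observed point follow the quantile-regression-forest construction: for
each tree, training rows sharing the observed point's leaf get weight
1/(leaf size), averaged over trees. The weighted 2.5/50/97.5% quantiles
give the point estimate and the 95% credible interval. Global accuracy is
the out-of-bag mean absolute error normalised by the parameter's mean
absolute value; local accuracy reweights the out-of-bag absolute errors by
the posterior weights. A parameter constant in the table returns a
degenerate interval equal to the constant.

A single non-recombining mitochondrial locus constrains event times
weakly: posterior medians shrink toward the prior midpoint and credible
intervals are wide. Interval *coverage* (checked at 95% nominal over 100
synthetic replicates) is therefore the calibration criterion, not
point-estimate error.

Event times are estimated in generations and converted to calendar years
by multiplying by the generation time (default 7 years); ka values are
reported at one decimal.

## Sea-ice extraction and event overlay

Ice fields are monthly sea-ice concentration grids (fraction of cell
covered, in [0, 1]) at 1 ka snapshots on a Lambert azimuthal equal-area
grid (spherical formulas, pole-centred, configurable central meridian;
coordinates in km, nominal 30 km cells). The projection is implemented
directly from the spherical forward/inverse formulas; its equal-area
property is what makes "cells within a radius" an unbiased area sample,
and is verified in the tests.

For an event between two populations: each population's centroid is the
mean of its herd coordinates on the projected plane, the event centroid is
the midpoint of the two, and (to avoid anchoring on an arbitrary point)
concentration is averaged over *n* random points (default 100) drawn
uniformly over a disc (radius R√u, default R = 100 km) around it. For each
point, every non-land cell whose *center* lies within the extraction
radius contributes; the mean and standard deviation over cells are then
averaged over points, per calendar month and for the annual mean. Land
cells are excluded from both moments (concentration is undefined over
land); a slice where no point sees ocean is flagged missing. The
cell-center inclusion rule is also used by the brute-force oracle in the
tests, so agreement is exact.

The crossing window of a slice is the set of months with mean
concentration ≥ the threshold (default 0.70, the minimum cover reported
for *Rangifer* sea-ice crossings). Event medians and credible-interval
bounds are mapped to the nearest 1 ka slice with exact half-ka ties
resolved toward the *older* slice — conservative toward the pre-event ice
state — and events older than the oldest slice are clamped with a warning.

## Synthetic data

The generators stand in for the study's external inputs and record their
ground truth:

* **Sequence datasets** are simulated from any scenario at pinned or drawn
  parameter values; the truth file carries the full parameter draw. They
  emulate multi-population control-region alignments (including an ancient
  population at 502 generations) but not alignment error, sequencing
  error, or indels — the pipeline consumes pre-trimmed gap-free blocks.
* **Ice fields** follow sic = clip(base + trend·t + A·cos(2π(m−m₀)/12) +
  g·x + ε, 0, 1) with a land-mask strip: a linear millennial trend, a
  seasonal cycle, a spatial gradient and Gaussian noise. Real modelled ice
  has spatially coherent anomalies and land–ocean feedbacks this form does
  not attempt; passing tests demonstrate correct *extraction*, not climate
  realism.
* **Herd tables** scatter herds around stated population centres with a
  configurable dispersion.

The shipped NAAI-like (4 scenarios) and BSI-like (3 scenarios) model sets
reproduce the *structure* of the final island model sets — nested
divergences, one mainland→island admixture, founder bottlenecks, an
ancient Franz-Josef-Land population — with illustrative priors, since the
study's full prior tables live in supplementary material not reproduced
here.

## Problem sizes and defaults

Self-consistency experiments use the two-scenario set (divergence 50 vs
5000 generations, Nₑ = 1000, 10 samples per population, 300 bp) with 5000
simulations per scenario and 500 trees; credible-interval coverage uses a
shared 2000-row table and 100 replicates. Unit tests run the same checks
at smaller replicate counts. K-means uses k-means++ with 25 restarts and a
recorded seed; the elbow is automated as the largest second difference of
within-group variance (anchored at K = 1) with the curve always available
for inspection; cophenetic-correlation ties in agglomeration-method
selection break toward average linkage (UPGMA).

## Known limitations

* No recombination (appropriate for mtDNA) and no continuous migration.
* Scenario posteriors and error rates are conditional on the candidate
  set; they do not measure absolute model adequacy beyond the
  prior-predictive PCA check.
* The posterior-probability threshold (0.65) and local-error threshold
  (~0.20) used to judge final model sets are reporting heuristics, exposed
  as configurable flags, not hard-coded decisions.
* NetCDF I/O uses the NetCDF3 (classic) format via the scipy backend.
* The equal-area projection is spherical; ellipsoidal corrections are
  below the 30 km grid resolution for the latitudes of interest.
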