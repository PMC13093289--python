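# postglacial

Coalescent ABC inference of postglacial Arctic-island colonisation
histories from mitochondrial control-region sequences, with comparison of
inferred demographic event times against modelled paleo sea-ice cover.

## Who this is for

Phylogeographers asking *when* island populations (the motivating system is
Arctic *Rangifer* — reindeer/caribou — on the North American Arctic islands
and the Barents Sea islands) diverged from, or exchanged migrants with,
mainland populations, and whether those events line up with periods when
sea ice was extensive enough (≥ 70% concentration) to support crossings.

## The method

The core is likelihood-free Bayesian model choice and parameter estimation
(ABC-RF) over explicit demographic scenarios:

1. **Scenarios.** Each candidate history is a set of populations with
   haploid mitochondrial effective sizes *Nₑ*, sample sizes, and sampling
   ages (ancient samples enter the genealogy at their age in generations),
   plus backward-in-time events: divergences (daughter lineages merge into
   a parent), instantaneous unidirectional admixture pulses (each recipient
   lineage moves to the donor with probability *r*), and founder
   bottlenecks (size *N_b* for *d_b* generations after colonisation).
   Priors are uniform on stated ranges with order constraints (e.g.
   *t*₂ > *t*₁) enforced by rejection.

2. **Simulation.** The structured coalescent runs in continuous time: in a
   population of haploid size *N*, *k* lineages coalesce at rate
   *k(k−1)/(2N)* per generation. Sequences evolve under HKY with continuous
   Γ-distributed among-site rate variation and a proportion of invariable
   sites, using the exact transition matrix P(t) so multiple hits are
   handled correctly. Each simulated dataset is reduced to a fixed-order
   summary vector (haplotype counts, segregating sites, pairwise-difference
   statistics, Tajima's D, between-population d_xy, Hudson-type F_ST,
   shared haplotypes) by the same code path used for the observed data.

3. **Inference.** A reference table of simulations (scenario, parameter
   draw, summary vector) trains a 500-tree random-forest classifier on the
   summary statistics augmented with LDA axes. The scenario with the
   majority of tree votes at the observed point is selected; its posterior
   probability comes from an out-of-bag regression of the
   correct-classification indicator. Event times are then estimated with
   quantile regression forests (median and 95% credible interval from leaf
   co-occurrence weights) and converted to calendar years at 7 years per
   generation.

4. **Sea-ice comparison.** Gridded monthly sea-ice concentration snapshots
   (1 ka steps, Lambert azimuthal equal-area grid at 30 km) are sampled
   around each event's geographic centroid (100 random points within
   100 km, extraction radii 200–1500 km), and the months with concentration
   ≥ 70% — the crossing window — are tabulated at the model time step
   nearest each inferred event time.

Supporting modules cover the observed-data workflow: alignment trimming to
the gap-free common block, haplotype collapsing, gene diversity, rarefied
allelic richness, pairwise Gst / G'st / Jost's D, Edwards chord distances,
UPGMA with agglomeration-method selection by cophenetic correlation, PCoA,
and K-means with elbow/silhouette selection of K.

## Worked example

```python
from postglacial import DemographicInference
from postglacial.synthdata import SyntheticSpec, make_sequence_dataset, well_separated_pair

scenarios = well_separated_pair()          # "recent" (t=50) vs "deep" (t=5000)
aln, truth = make_sequence_dataset(
    SyntheticSpec(seed=21, scenario=scenarios[1], L=300,
                  true_values={"t_split": 5000.0}))

model = DemographicInference(aln, scenarios, L=300)
results = model.fit(n_per_scenario=300, n_trees=100, seed=4)
print(results.summary())
```

Output (abridged):

```
Demographic ABC-RF inference results
====================================================
Scenarios compared:       2
Reference table rows:     600
Trees per forest:         100
Selected scenario:        deep
Posterior probability:    1.000
Global (prior) error:     0.000
...
Parameter posteriors (generation time 7 y):
parameter  median  ci_2.5%  ci_97.5%  global_nmae  local_error  median_ka  ci_low_ka  ci_high_ka
  t_split    5609     3292      9640       0.1863       0.1929       39.3       23.0       67.5
```

The data were simulated from the deep-divergence scenario with a true split
time of 5000 generations; the fit selects that scenario with every tree
vote, and the 95% credible interval [3292, 9640] generations covers the
truth. The ka columns are the same numbers multiplied by the 7-year
generation time.

A command-line interface mirrors the library:
`postglacial synth | reftable | check | choose | estimate | icecompare`.

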