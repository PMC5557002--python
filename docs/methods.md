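# Methods

`phyloniche` implements a phyloclimatic analysis pipeline for a clade on a
dated phylogeny: occurrence preparation, environmental variable screening,
extant and ancestral climate-niche models, niche-overlap statistics,
ordination, and ancestral range estimation.  The worked defaults throughout
are the settings of the *Asimina*–*Disepalum* study system (18 modelled
species, 20 candidate WorldClim variables, 7 biogeographic areas A–G), but
every component is generic.

## Occurrence preparation

Records are exact-duplicate deduplicated within species.  Species below the
modelling minimum (`min_n = 10` localities) are augmented with
pseudo-occurrences displaced 1 km from true localities:

* 5–9 true points: 1 km east of randomly selected true points (uniform
  without replacement until exhausted, then with replacement; seeded) until
  the minimum is reached;
* 2–4 true points: east/west/north/south offsets, cycling over true points
  in input order and over the four directions in that fixed order, stopping
  exactly at the minimum;
* 1 true point: offsets at 1 km and 2 km in all four cardinal directions
  plus one extra at 3 km east — 9 pseudo-points, 10 total.

Kilometres convert to degrees on a spherical earth, R = 6371.0 km
(1° latitude = 111.195 km; longitude scaled by cos λ).  No geodetic datum is
modelled; at 1–3 km the spherical error is far below the 30-arc-second cell
size.  The 75/25 train/test split is per species, seeded, with the training
count `round(0.75·n)` (ties to even).

## Variable screening

Pairwise Pearson correlations are computed on the pooled environment table
of all unique locality points (pairwise-complete; zero-variance variables
yield undefined correlations and are reported missing).  Predictive power
per variable is the mean over species of the single-variable model's test
AUC.  Pruning then repeatedly takes the currently retained pair with the
largest |r| ≥ 0.8 (ties broken by lexicographic variable-name pair) and
drops the member with the lower mean AUC; mean-AUC ties drop the variable
later in the fixed (ALT, Bio1…Bio19) order.  The procedure is deterministic
and its full trace (kept, dropped, |r|) is part of the report.  On the
packaged 20-variable screening table this retains 9 variables.  The
descending-|r| order is our choice — no ordering is canonical — and with one
near-tied pair (Bio12/Bio19, mean AUC 0.86 vs 0.87 at r = 0.84) the retained
*identity* depends on it; the retained *count* does not.  This is why the
trace is always emitted.

## Extant niche models

**Maximum-entropy-style model.**  A presence–background exponential model
`q(x) ∝ exp(w·f(x))` over a finite background (all jointly valid cells,
thinned to at most 10,000, seeded).  Features are linear and quadratic terms
per variable, standardized over the background; hinge/threshold/product
features are deliberately out of scope, so the fitted response per variable
is Gaussian-shaped.  The fit maximizes the L1-penalized presence
log-likelihood with per-feature penalty `β_j = reg·λ(m)·s_j/√m`, where `reg`
is the user regularization multiplier (study setting 1.0), `m` the presence
count, `s_j` the presence standard deviation of the feature, and `λ(m)` a
sample-size-dependent scale interpolated from 1.0 at m ≤ 10 through 0.5 at
m = 30 to 0.1 at m ≥ 100 — small presence sets are shrunk harder.
Optimization is proximal-gradient (FISTA) with deterministic backtracking;
convergence when the largest weight change is below 1e−6, capped at
`max_iter = 500` (reported).  The logistic output is `e^H q/(1 + e^H q)`
with H the entropy of the fitted background distribution, so an
uninformative model scores 0.5 everywhere and the transform is rank-
preserving.

*Limitation:* without hinge features, a species envelope hugging one extreme
tail of a variable is approximated by a Gaussian whose far tail leaks
suitability beyond the envelope; discrimination degrades there.  Interior
(two-sided) envelopes are fitted well.

**BIOCLIM envelope.**  Binary mode scores 1 iff every variable lies within
its [min, max] training bound.  Percentile mode scores each variable
`2·min(F, 1−F)` with `F = (rank−1)/(n−1)` linearly interpolated between
sorted training values — the training minimum and maximum score exactly 0,
the median exactly 1 — takes the minimum across variables, and scores 0
outside the training range.  This convention was chosen over
`(rank−0.5)/n` so that envelope support coincides exactly with the binary
envelope's interior.

**AUC** is the rank-based (Mann–Whitney) statistic of test presences against
the background sample, ties counted one half; models with AUC > 0.7 are
flagged reliable, following common SDM practice.

## Niche overlap and ordination

Suitability surfaces are normalized to sum 1 over the shared grid;
Schoener's `D = 1 − ½Σ|p−q|` and Warren's `I = 1 − ½Σ(√p−√q)²`
(= 1 − H²/2, H the Hellinger distance).  Cross-region species pairs are
compared after projecting both models onto one configured common extent.
Genus summaries are unweighted means over the C(k,2) within-genus pairs.

DCA follows the classic segment-detrending recipe: variables are min-shifted
and range-scaled to [0, 100] (correspondence analysis needs non-negative
input; the scaling choice is recorded in the ordination metadata),
correspondence analysis is done by singular decomposition of the chi-square
standardized table with row scores in principal coordinates, and axes beyond
the first are centred within 26 equal-width segments of the lower axis.
Hill's rescaling is not applied.  With a single segment, axis 2 is the plain
CA axis 2 minus its mean.  Rank-deficient tables return fewer axes, logged.

## Ancestral niche reconstruction

Per-species climate summaries (mean, sample sd, min, max per selected
variable; single-locality sd = 0) are treated as independent continuous
characters.  Squared-change parsimony assigns internal values minimizing
Σ(parent − child)² over edges; the weighted variant divides each term by
edge duration.  The objective is strictly convex, so the solution is the
unique root of a sparse linear system, solved directly — no iteration, no
seed.  Unweighted optimization is the default (the weighting used in the
original Mesquite runs is not recorded anywhere; both modes are exposed).
The unweighted solution is invariant to edge-duration rescaling; the
weighted one is not.

Ancestral BIOCLIM envelopes take the reconstructed [min, max] per variable
at each node; a crossed reconstruction (min > max, possible because the
characters are optimized independently) is flagged with a warning and
swapped.  Projection is restricted to nodes with posterior support PP ≥
0.95 by default.

## Ancestral range estimation

Ranges are non-empty subsets of the areas, capped at `max_areas = 2`
(28 states over 7 areas).

**DEC.**  Anagenetic generator: range expansion to area *a* at rate
`d·|S|` (all dispersal multipliers 1), local extinction of one area at rate
`e` from widespread ranges.  The generator is conservative over the allowed
states — a singleton range cannot be lost, so an observed lineage never
passes through the empty range, rows sum to 0, and every transition matrix
is stochastic.  Cladogenesis partitions a widespread range equally over the
six scenarios for a two-area range (two vicariance, four subset-sympatry
assignments); singletons are inherited identically.  The likelihood is
computed by post-order pruning with `scipy` matrix exponentials
(scaling-and-squaring Padé) per edge; root states carry equal weight, so a
one-area system scores log-likelihood exactly 0.  `DECModel.fit()`
maximizes over (d, e) by L-BFGS-B on log-rates from a fixed 3×3 multistart
grid, bounds [1e−6, 10] events/Ma — deterministic.  Marginal node ranges
combine inside (pruning) and outside (root-to-node) partials at the point
immediately before cladogenesis and are normalized to % per node.

*Note:* with mostly-singleton tips the likelihood can increase monotonically
in `e` (fast collapse of transient widespread states), so `ê` may sit at
the upper bound; `d̂` remains well identified, and the per-node marginals
should be read with that in mind.

**DIVA parsimony.**  Event costs: +1 per area gained (dispersal), +1 per
area lost (extinction) along branches; vicariance (disjoint bipartition of
the ancestral range) and singleton duplication are free at cladogenesis.
An exact min-plus dynamic program over the state space, with a matching
outside pass, returns *all* ancestral ranges attained in some globally
minimum-cost reconstruction — verified against exhaustive enumeration on
small trees.

**S-DIVA summaries.**  The parsimony runs independently on every tree of a
posterior sample; for each internal node of the reference (MCC) tree,
frequencies are taken over trees containing that node's descendant-tip
bipartition, weighting co-optimal within-tree solutions equally, and
normalized to % (nodes are matched by bipartition, never by index).  The
resampling planner reproduces the study arithmetic: 8 runs × 100 M
generations sampled every 5,000, 25% burn-in, resampled every 600,000 →
1000 trees.

## Synthetic data

The generator supplies every pipeline input with known ground truth:

* **Climate worlds** — per variable, a seeded mixture of longitudinal and
  latitudinal gradients, a sinusoid and low-frequency plane-wave noise; the
  per-variable fields are empirically orthonormalized (QR) and re-mixed
  through the Cholesky factor of the target correlation matrix, so the
  empirical inter-variable correlations equal the target exactly (a
  non-positive-semidefinite target is rejected).  Defaults emulate a
  6°×6° tropical window; means/sds are set per variable.
* **Species** — `n_true` points sampled uniformly over the cells satisfying
  a known rectilinear envelope, jittered within the cell.
* **Traits** — Brownian motion along the chronogram (variance σ² per Ma).
* **Ranges** — forward Gillespie simulation of the DEC process with
  scenarios drawn uniformly at nodes; histories that lose all areas are
  resampled (conditioning on survival, counted and warned).
* **Random chronograms** — coalescent-style: sorted uniform merge ages with
  random pair joins, final merge at the requested depth.

What the generator does **not** emulate: spatial sampling bias, spatial
autocorrelation of residual noise beyond the smooth fields, occurrence
georeferencing error, niche evolution other than Brownian, or
time/distance-stratified dispersal.  Passing recovery tests therefore show
the estimators are correct under their own generating assumptions, not that
real herbarium data meet those assumptions.

The packaged study chronogram carries the published posterior mean ages and
support values for all named clades (tribe crown 66.5 Ma through the
subgeneric crowns at 3.8 and 4.8 Ma); arrangements *within*
*Goniothalamus*, *Diclinanona* and *Asimina*, for which no ages are
published, are synthetic stand-ins consistent with the clade ages and are
labelled as such in the code.  Tip area codings are assigned from the
species' stated extant distributions and documented next to the table.

## Problem sizes and determinism

Default verification runs use 40–70² cell grids, 40–60 occurrences per
synthetic species, 24–50-tip trees, 10–40 simulation replicates, and a
1000-tree sample for the range-frequency summaries; these sizes keep full
runs in minutes on a single core while leaving the stochastic checks
well-resolved.  Every random step takes an explicit seed; pipeline stages
derive per-stage seeds from one master seed, and a rerun with the same
configuration is digest-identical.
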