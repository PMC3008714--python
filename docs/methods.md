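# Methods

This note records the statistical model behind `dynade`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Experimental design assumed

One treated and one control culture measured on a shared time grid
starting at 0 minutes (default grid 0, 40, 100, 200, 340, 440), one
measurement per condition per time point, plus a complete duplicate of the
time-0 sample in both conditions.  Expression values are assumed already
normalized and on the log2 scale; the package never re-normalizes or
re-logs.  An optional many-to-one probe→gene collapse (median of probe
rows) is available in `dynade.io.collapse_probes` but off by default,
since no principled collapse rule is universal.

## Selection model

**Statistic.** For gene *g*, the area A(g) = ∫|d(t)|dt of the
piecewise-linear interpolant of the treated-minus-control differences,
integrated exactly with splitting at zero crossings.  Units are
log2·minutes.  A is invariant to adding a constant to both conditions and
scales linearly with the differences.

**Error model.** The two time-0 replicate pairs (treated and control) are
pooled; genes are ranked by mean replicate intensity and split into
`n_bins` (default 10) equal-count bins; per bin the SD of
(rep_a − rep_b)/√2 estimates the single-measurement SD.  Bins with fewer
than 10 genes merge with a neighbour; lookups clamp to the edge bins.
The per-bin error is modelled as zero-mean Gaussian.  Gaussianity is a
modelling choice — the replicate pair is far too small to estimate a
shape per bin — and `n_bins = 10` balances resolution of the
intensity–variance trend against ~hundreds of genes per bin for a stable
SD at typical array sizes.

**Null and p-values.** Under H₀ the difference at each time point is
e_t − e_c with e ~ N(0, s(I)) independent, so null areas are simulated by
Monte-Carlo (default `n_mc` = 10 000) once per intensity bin and shared by
the genes in that bin; each gene's intensity is the mean of all its
measured values.  p = (1 + #{null ≥ observed})/(1 + n_mc) — the
pseudocount is the standard Monte-Carlo correction keeping p in (0, 1].
Benjamini–Hochberg step-up adjustment controls the FDR; a gene is
selected when its adjusted value is ≤ `fdr_level` (default 0.05).  With
n_mc = 10 000 the smallest attainable p is ≈10⁻⁴, which bounds how small
an FDR threshold is meaningful; raise n_mc for stricter levels.

**Per-timepoint change calls.** Independent of selection, each difference
d at t > 0 is called up/down when |d| exceeds a per-intensity-bin
threshold τ.  The null |d| is half-normal with scale √2·s(I); the observed
|d| in a bin are modelled as a two-component mixture with the null
component fixed and mixing weight π₀ estimated from the observed mass
below the null median (π̂₀ = min(1, 2·F̂(median_null))).  τ minimises the
estimated FP rate + FN rate over the observed values; because the
plug-in alternative CDF is clipped at zero, the risk curve can have a
flat near-minimal plateau, and the smallest τ within 10⁻⁴ of the minimum
is taken (ties resolved toward sensitivity).  When the bin looks purely
null (π̂₀ ≈ 1) the threshold falls back to the 99.9th null percentile and
the event is logged.  Calls are computed for all genes; result tables can
be filtered to selected genes downstream.

## Clustering

Profiles are z-standardized per gene (population SD), making squared
Euclidean distance proportional to 1 − r; Lloyd iterations then implement
Pearson-correlation K-means while keeping the usual convergence guarantee.
Centroids are re-standardized after each update so they live on the same
sphere as the data.  Defaults: K = 7 (the number of temporal archetypes
the design anticipates; exposed as a flag since it is a choice, not an
estimate), 50 seeded restarts keeping the lowest inertia, 300 iterations
max.  Empty clusters are re-seeded from the farthest point.  Constant
profiles have no defined correlation and are excluded with an explicit
"unclustered" label rather than silently dropped.  Whether to standardize
before correlation K-means is not canonical; the standardize-then-
Euclidean embedding is this package's documented choice.

## Enrichment

The term-level test is the one-sided hypergeometric upper-tail
probability; the universe is every gene with at least one (ancestor-
propagated) annotation, and annotations always satisfy the true-path rule.

Levels band terms by selected-annotation percentage in 2 %-wide intervals
(level 1 = [0.98, 1], level ℓ = [1 − 0.02ℓ, 1 − 0.02(ℓ − 1)) ), computed
once from the initial annotations with exact rational arithmetic (float
banding misclassifies boundary fractions like 96/100).  Levels are not
recomputed after removals: "lower-percentage" would otherwise be
ill-defined mid-pass.  Visiting levels in increasing order, each term is
tested with its current annotation set; a term with p < α (default
0.0025 — stringent because no correction is applied across the many
tested terms) removes its current genes from the annotation (annotated
and selected counts both) of all strictly-lower-percentage levels before
those are tested.  Terms within the same level never penalize one
another.  Removal is permanent for all subsequent levels.

Grouping joins enriched terms when one is an ancestor of the other;
connected components of that auxiliary graph are the functional groups.
Sibling terms with no ancestor path stay in separate groups (the
alternative — grouping siblings of a common parent — was considered and
not adopted, as it would merge unrelated branches whenever the parent is
unenriched).  A group's label is the member that is an ancestor of every
other member, else the member of minimal depth (depth = longest path from
the root, robust to multiple parents; ties break lexicographically).
Groups get capital-letter tags in (label depth, label id) order.

Cluster-specific enrichment restricts the universe to selected, clustered
genes and runs a one-sided Fisher test per (cluster, group) cell, flagged
at raw p < 0.05 as is conventional for this small number of cells; 1 − p
is emitted alongside for significance-profile plots.

## qPCR validation

CT values convert to relative quantities with a median calibrator:
ΔΔCT = CT − median(CT over samples per gene), RQ = 2^−ΔΔCT, so RQ ratios
are invariant to constant row shifts and the median ΔΔCT is 0 by
construction.  The design has no separate control channel, so log2(RQ)
plays the role of the treated-minus-control profile in the same area
machinery.  Lacking published time-0 duplicates for this assay, the null
uses a user-supplied CT replicate SD (default 0.25 cycles; one cycle =
one log2 unit) with a single error draw per time point.  The median
calibrator introduces a weak coupling between time points that the null
ignores; at 10 time points the effect on the area null is negligible
relative to the assumed replicate SD.  Cross-platform agreement is a 2×2
table of selected/not-selected calls over a shared gene universe, with
percentages reported rounded to the nearest integer.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Archetypes.** Seven unit-amplitude difference patterns, piecewise
  linear in normalized time through fixed knots: (1) peak near
  mid-course; (2) early down-regulation then plateau; (3) early decrease
  returning to baseline; (4) transient rise then decrease below baseline;
  (5) rise near ~¼ of the course then plateau; (6) down-regulation at
  intermediate times; (7) sustained monotone down-regulation.  All start
  at 0 (the stimulus begins at t = 0).  The knot values are package
  constants chosen to match those qualitative shapes while keeping the
  seven patterns mutually distinguishable under correlation distance.
- **Baselines** uniform on [4, 12] log2 units, spanning the typical
  microarray intensity range.
- **Noise** zero-mean Gaussian with SD falling linearly from 0.4 (low
  intensity) to 0.1 (high intensity) log2 units — the
  intensity-dependent heteroscedasticity that motivates the binned error
  model.  Both conditions get an independent duplicate draw at time 0.
- **Effect size** default 1.0 log2 units at pattern peak.  No
  authoritative magnitude exists for this quantity; 1.0 (a two-fold
  change at peak) is a realistic mid-range response and puts selection in
  a regime where both power and FDR are informative.
- **Ontology** a single-root is_a DAG with every non-root term attached
  to a parent of strictly smaller depth (acyclic by construction, ~20 %
  of terms get a second parent), ancestor-closed annotations, and planted
  terms whose annotations are drawn entirely from a designated selected
  gene set (so their selected percentage is 100 %).
- **qPCR** CT = base − profile + N(0, ct_noise_sd) on a 10-point grid over
  0–480 minutes, mirroring the denser validation design.

What the generator does **not** emulate: probe-level effects and
preprocessing artifacts, within-gene temporal autocorrelation of errors
(errors are independent across time points, matching the null model —
real arrays may violate this), correlated expression between genes,
annotation biases of real ontologies, and amplification-efficiency
variation in qPCR.  Tests passing on these simulations therefore verify
the statistical machinery under its own assumptions, not robustness to
every pathology of real data.

## Problem sizes used in the test and acceptance suites

FDR control is measured on 20 seeded replicates of 2000 genes with 10 %
truly responding at n_mc = 10 000 — large enough that the false-discovery
proportion is stable to ±0.02 — and null calibration on a 2000-gene pure-
null simulation.  Cluster recovery uses 140 profiles (20 per archetype)
at noise SD 0.1, 20 seeds.  The exhaustive Fisher cross-check enumerates
all ~1.2 million hypergeometric tables with universe ≤ 60 in exact
integer arithmetic.

## Known limitations

- The Gaussian per-bin error model is an approximation; an empirical
  resampling null (drawing from observed replicate differences) would
  track heavy tails better but is unstable with a single replicate pair.
- BH assumes independence or positive dependence across genes; gene–gene
  expression correlation in real data can inflate the realized FDR.
- Monte-Carlo p-values are tied within an intensity bin's resolution;
  extremely fine FDR distinctions require larger n_mc.
- K is fixed, not estimated; no model selection for the cluster count is
  provided.
- The elim pass tests every annotated term without cross-term correction;
  α is the only knob controlling family-wise behaviour.
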