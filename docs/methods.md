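# Methods

This note records the statistical models implemented in `xenodissect`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices a maintainer should know
about. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The species-dissection problem

A tumour xenograft mixes RNA from two genomes: human (cancer cells) and
mouse (stroma). Hybridising one tumour's RNA to both a human and a mouse
chip yields two compartment-specific expression profiles — up to
cross-species hybridisation, where a probe set designed against one
species binds transcripts of the other. The workflow therefore starts from
a four-way control experiment (each species' pure RNA on each chip) that
classifies every probe set before the xenograft arrays are interpreted.

## Cross-hybridisation classification

For chip species *A*, two summarised control arrays matter: other-species
RNA on chip *A* (where only cross-hybridisers light up) and own-species RNA
on chip *B* (which shows whether the foreign transcript was present at
all). The classes are:

* `cross_hyb` — other-species signal > τ_x;
* `safe` — not `cross_hyb`, **and** the probe set has an ortholog whose
  signal on the other chip exceeds τ_p. The second condition matters: a low
  other-species signal is only evidence of specificity if the foreign
  transcript was actually there to cross-hybridise.
* `indeterminate` — everything else, including every probe set without an
  ortholog mapping, for which presence of the foreign transcript cannot be
  verified. This is a deliberately conservative rule.

Both thresholds are robust array-relative statistics, τ = median + k·MAD_σ
of the summarised array, with MAD_σ the median absolute deviation scaled by
1.4826 to estimate a normal σ. Default k = 2 for both; under a pure-noise
null this implies a one-sided false-positive rate near 2.3%, consistent
with the κ = 0 behaviour the acceptance suite measures. Absolute log₂
thresholds can be supplied instead when chip-specific calibration data
exist.

Two caveats. First, classification operates on summarised probe-set
expression, not raw probes, matching how such lists are reported. Second,
the presence rule τ_p = median + 2·MAD_σ is tuned for arrays in which a
substantial fraction of probe sets is background; on a synthetic universe
where every transcript is expressed the `safe` class is nearly empty (most
probe sets cannot clear a threshold sitting 2σ above the array median) and
k_p should be lowered, or an absolute τ_p given, if the safe list itself is
of interest.

## RMA-style preprocessing

Per array, background correction assumes observed intensity X = S + B with
signal S ~ Exp(α) and background B ~ N(µ_bg, σ_bg²) and replaces x by

E[S | X = x] = a + σ_bg·φ(a/σ_bg)/Φ(a/σ_bg),  a = x − µ_bg − σ_bg²·α,

evaluated through log-pdf/log-cdf so the deep left tail stays finite. The
parameters are estimated with a closed-form robust recipe — µ_bg the mode
of a Gaussian-kernel density over the lower half of intensities, σ_bg the
normal-consistent MAD of values below µ_bg, α = 1/mean(x − µ_bg | x > µ_bg)
— chosen for stability at small array counts. Bit-level agreement with any
other RMA implementation is explicitly not promised; correctness is pinned
instead by a quadrature oracle for E[S|X] (agreement to 1e-6), strict
monotonicity, and synthetic recovery. Note the estimator presupposes a
background-dominated probe population; arrays on which essentially every
probe carries signal (possible with the generator's defaults) make µ_bg
land inside the signal distribution and distort low-intensity probe sets.

Quantile normalisation forces every array onto the distribution of rank
means; ties receive the mean of the reference values over their rank
range. Median-polish summarisation runs Tukey's alternating row/column
median sweeps on each probe set's log₂(probes × arrays) block until the
largest sweep change is < 0.01 or 10 iterations (both configurable);
probe-set expression per array is overall effect + array effect. Log₂ is
taken after background correction with a floor of 2⁻⁴. Species are
processed independently; excluding flagged cross-hybridisers before
summarisation is available as an optional filter, default off, since with
a clean control-based classification the summaries are essentially
unchanged either way.

One property worth knowing: with a balanced two-group design, quantile
normalisation averages the treated and untreated quantile functions, so a
differentially expressed probe set displaced into a sparsely populated
region of the intensity distribution (typically the extreme upper tail) is
attenuated — by up to ~0.2 log₂ in the noise-free experiments the test
suite runs — while densely surrounded probe sets are recovered almost
exactly. This is inherent to the method, not an implementation artifact,
and is why the noise-free recovery test asserts on the mean member error.

## Moderated-t differential expression

Residual variances s² (d_g = n₁ + n₂ − 2 df) are assumed drawn from a
scaled inverse-χ² prior with parameters (s₀², d₀) estimated by matching the
mean and variance of log s² (digamma/trigamma moment equations, Newton
inversion of the trigamma). If the empirical variance of log s² does not
exceed trigamma(d_g/2), the variances are consistent with a single common
value and d₀ = +∞. The moderated statistic uses the posterior variance
s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g) on d₀ + d_g df; d₀ = 0 reduces exactly to
the ordinary pooled t (verified against an independent implementation to
1e-9), d₀ = ∞ to a z-statistic with variance s₀².

Selection is raw two-sided P < 0.05 with fold change ≥ 1.5, the historical
convention for this design; no multiple-testing correction is applied by
default, but a Benjamini–Hochberg column is always emitted for modern use.
Fold changes come from raw group-mean log₂ differences — effect sizes are
not shrunk. The design is two-group only; covariate extension would slot
into `moderated_t` but is not built.

## Permutation enrichment

Gene labels, not sample labels, are permuted: B random gene lists of the
DE-list size m are drawn uniformly without replacement from the universe,
and the empirical p uses the plus-one rule (never 0, never above 1, lower
bound 1/(B+1)). Because the null is uniform sampling, the exact null
distribution of the overlap is hypergeometric; `hypergeom_tail` computes
P[X ≥ k] by integer-arithmetic summation and serves as the oracle the
permutation machinery is tested against (agreement within 0.02 at B = 10⁴).
The universe defaults to the genes actually measured on the chip after
collapsing probe sets to unique symbols — the measurable background —
and is configurable. One shared set of permutation draws is reused across
all target sets of a collection.

## Cytokine concordance

Concentrations arrive as pg per ml of homogenate supernatant; per-gram
values are pg/ml × extract volume (default 0.2 ml, the standard
homogenisation volume) / tumour mass. Below-detection measurements are
imputed at LOD/2 by default (configurable to 0 or LOD). Group comparison is
an unpaired Student's t on log₁₀ concentrations — immunoassay error is
multiplicative, so the log scale is the natural one; this is stated here
because assay write-ups often leave the scale implicit. Classification
thresholds: protein induced means fold ≥ 2 **and** t-test p ≤ 0.05; RNA
induced means fold ≥ 1.5 (the DE selection threshold). The four classes are
monotone in both folds; in particular raising the RNA fold can only move an
analyte from `post_transcriptional_candidate` to `concordant_induced`.
qPCR relative expression normalises each target Ct by the mean of the YWHAZ
and PPIA housekeeping Cts and reports 2^−ΔΔCt between group means.

## Morphometry

Volumes use the ellipsoid approximation V = 0.52·a²·b (a = minor, b = major
axis, canonicalised by swapping when given reversed). Growth is expressed
relative to each mouse's day-0 volume; the group delay is the first
post-minimum upward crossing of 1.0 of the group-mean curve, linearly
interpolated between measurement days, computed on the group mean (not
per-animal medians) to match how such curves are usually summarised. A
series that never returns to 1.0 is censored (NaN), one that never drops
below 1.0 has delay 0.

Necrosis point counting overlays a square grid (default spacing 80 µm) on
a binary mask; the estimate is 100 × (grid points on necrotic pixels) /
(grid points counted). The default offset is half a spacing in both axes —
never an image corner — to avoid edge-alignment artefacts; randomising the
offset makes the estimator unbiased in expectation, which the acceptance
suite verifies to within one percentage point over 100 random offsets.
When a tissue mask is supplied the denominator counts only grid points over
tissue, the appropriate reading for montages that include empty background;
without one, the whole image counts. For repeated-measures growth
comparisons the classic two-way ANOVA with Bonferroni post-hoc is replaced
by per-timepoint Welch t-tests with Bonferroni correction — a deliberate
simplification of a routine test; one-way ANOVA with Tukey HSD is provided
for single-timepoint group comparisons (necrosis fractions).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
ground truth retained for every emitted object. Defaults define the study
conditions: 1000 probe sets per species × 11 probes; 80% ortholog pairing;
15% cross-hybridising probe sets per chip (echoing the 14–16% seen in real
two-species control experiments); leakage coefficient κ = 0.5; 5 treated vs
5 untreated xenografts per chip; four planted target sets (40/30/30/25
genes, mean log₂ effects 1.2/1.0/0.9/1.0, sd 0.3); baseline log₂ expression
N(8, 1.5²); fixed per-probe affinities N(0, 0.7²) shared across arrays so
median polish has a realistic row structure to remove; per-observation
noise sd 0.25 (log₂); additive optical background N(64, 16²) on the linear
scale. Leakage is additive in linear intensity — leaked signal =
κ × ortholog linear signal — because hybridisation signal is additive in
bound target; planted effects act in log₂ on the species' own transcripts.
Cytokine analytes couple protein to RNA as protein fold = RNA fold × γ,
with γ = 1 for concordant analytes and γ ≫ 1 (68 for the G-CSF-like
analyte) for post-transcriptional ones, 3 mice per group. Tumour growth is
piecewise: untreated exponential (0.08/day); treated regression to fraction
0.3 of the starting volume over 4 days then regrowth at 0.055/day, giving
an analytic return-to-baseline time of ≈ 25.9 days. Necrosis masks are
stamped from random disks until the target pixel fraction is met within
0.01, then trimmed to it. All randomness flows from one root seed through
named substreams (universe, arrays, cytokines, growth, masks) so components
can be regenerated independently.

What the generator does **not** emulate — and hence what passing recovery
tests do and do not show: there are no probe sequences, so cross-
hybridisation is a planted label with a single leakage coefficient rather
than an emergent property of homology; probe affinities are additive in
log₂ with no saturation or GC structure; every transcript is expressed
unless `absent_fraction` > 0 is set (real chips have large absent
fractions, which is exactly what normexp estimation and the presence
criterion exploit — tests that need a background population set this
explicitly); arrays have no spatial artefacts or batch structure; cytokine
assays have no standard-curve nonlinearity. Recovery results on this
generator demonstrate that the estimators are correctly implemented and
calibrated under the stated model, not that the model captures every
failure mode of real chip data.

Two further generator subtleties. The treatment-set sizes are absolute, so
shrinking the universe below ~160 probe sets with the default sets raises
an error rather than silently planting effects in half the chip (planting
a large fraction of the universe breaks the quantile-normalisation
assumption and is almost never what one wants). And the noise-free growth
truth records two numbers: the analytic crossing time of the piecewise
model and the crossing of the linearly interpolated thrice-weekly sampled
curve; a delay read off discrete measurement days equals the latter
exactly and the former only approximately.

## Numerical choices and degenerate inputs

* Normexp evaluation uses log-space Mills ratios; outputs are floored at
  the smallest positive double, never 0. Constant arrays are rejected.
* Quantile normalisation of a single array warns and returns it unchanged.
* Median polish: tolerance 0.01, cap 10 iterations (both configurable);
  empty probe sets are skipped with a warning; a single-probe set's
  expression is the probe's log₂ value.
* `fit_ebayes_prior` needs ≥ 10 positive variances; exactly equal variances
  short-circuit to d₀ = ∞ with s₀² the common value. Zero within-group
  variance with d₀ = 0 yields a flagged row with NaN p rather than a fake
  statistic.
* Empirical p-values are clamped to [1/(B+1), 1] by construction; B < 100
  warns.
* Below-LOD cytokine values are imputed before the per-gram conversion; a
  zero untreated mean (possible under the `zero` policy) flags the analyte
  instead of dividing by zero.
* Grid spacing below one pixel and grids with no intersections (or none on
  tissue) are errors, not silent zeros.
* The growth-delay interpolator requires the series to start at (0, 1.0)
  by construction of the relative-volume transform.

## Known limitations

* The cross-hybridisation thresholds are stand-ins for chip- and
  protocol-specific calibration; published probe-set counts from any real
  experiment depend on those unavailable calibrations and are not
  reproduction targets.
* Raw P < 0.05 selection reflects the historical convention and is
  anti-conservative by modern standards; use the emitted BH column.
* The permutation scheme fixes the DE-list size and permutes gene labels;
  sample-label permutation (which preserves gene–gene correlation) is a
  different null and is not implemented.
* Protein–RNA concordance compares fold changes through a hard threshold
  pair; borderline analytes (protein fold near 2, RNA fold near 1.5) are
  classification-unstable under assay noise, which the recovery tests
  quantify but cannot remove.
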