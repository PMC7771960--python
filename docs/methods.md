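# Methods

## Model

Every replicate measurement of a feature — a gene's TPM or a peak's
normalized fragment-count integral — is treated as a draw from a folded
Gaussian `|Normal(μ, (μ·CV)²)|`, where μ is the condition mean and a
single coefficient of variation is shared by all doses of a signal.
Sharing the CV across the m doses of a signal pools the information of
m·n samples (nine, in the default three-dose three-replicate design)
into one variance parameter per (feature, signal). The per-dose CV uses
the small-sample unbiased estimator `(1 + 1/(4n))·s/x̄`; the shared CV
is the arithmetic mean over doses with a positive mean. Features with
no usable dose are flagged and excluded downstream rather than dropped
silently.

For a feature with baseline `x0` (the normal-density vehicle control
mean) and matched-dose individual effects `ΔA`, `ΔB`, the additive and
multiplicative predictions for the combined treatment are
`x0 + ΔA + ΔB` and `x0·(xA/x0)·(xB/x0)`. The combined response factor
`c = (xAB − x0 − ΔA − ΔB)·x0/(ΔA·ΔB)` is the unique linear
interpolation with c = 0 at the additive and c = 1 at the
multiplicative prediction; it is undefined when `x0 ≤ 0` or
`ΔA·ΔB = 0`, and such records are excluded with a reason. The peak
deviation statistic is the linear fold-change difference
`d = xAB/pred_add − 1` (not a log2 ratio: a distribution of additive
peaks then centers at exactly 0, matching how the statistic is used).

### Classification and the confidence interval

A combined response is classified by where the two predictions fall
relative to the central 80% interval of the combined treatment's
estimated observation distribution, `x̄AB ± q·x̄AB·ĈV`. Interval
endpoints are inclusive, so a prediction exactly on a bound counts as
inside. Genes get the six-way classification (sub-additive / additive /
between / multiplicative / super-multiplicative / ambiguous); peaks get
the three-way additive-centered one, in which a prediction *above* the
interval means the observed response fell short of addition
(sub-additive).

The multiplier `q` is a Student-t quantile with the CV estimator's
degrees of freedom (summed n−1 over the combined signal's doses; 6 by
default), not a normal quantile. The interval's half-width is a
multiple of the *estimated* sd, and the CV from nine samples carries
roughly 29% relative error; with a z quantile the realized coverage of
the 80% interval on truly-additive synthetic peaks is about 74%,
whereas substituting the true CV restores 79–80%. The t quantile is the
standard correction for exactly this plug-in noise and brings realized
coverage to 78–79% under the default generator. `ci_df=None` switches
back to the z form for comparison.

### Filters

The master set of upregulated genes requires significant upregulation
in any dose of the combined treatment (log2 fold-change ≥ 0.5,
BH-adjusted p ≤ 0.05, both configurable) and positive individual
effects at every dose of each signal, which is what guarantees that
sub-additive responses map to c < 0 and super-multiplicative ones to
c > 1. Genes with a zero control baseline are flagged separately: their
c is identically undefined.

The reliability filter keeps records with interaction scale
`ΔA·ΔB/x0 ≥ 2` TPM and `≥ x0` (both boundaries inclusive). The c
estimator is a correlated ratio whose noise scales as the inverse of
the interaction scale; below this threshold single-replicate c values
are dominated by technical variability and their pooled summaries are
biased (the numerator and denominator share `x̄A`, `x̄B`, `x̄0` with
negative covariance, skewing the ratio low). Wherever the package
reports a summary location of c — dose trajectories, the acceptance
script's null-distribution centers — it therefore summarizes reliable
records. The full histograms are built from all master-set records.

## Null simulations

For each feature, new replicate sets are drawn from the fitted noise
model for all four conditions, with the combined mean pinned to the
additive or multiplicative prediction; the statistic is recomputed from
the simulated replicate means. Defaults: 250 simulations per gene per
dose and 10 per peak. The mixture null assigns each (feature, dose)
multiplicative with probability equal to the observed
multiplicative/(additive+multiplicative) frequency at that dose,
ignoring the other categories.

Histograms use 0.25-wide bins with edges aligned at 0 and 1;
overlapping (sliding) windows advance by a half-bin step of 0.125, a
symmetric tiling that keeps edges on both anchors. The mixture scale is
the closed-form least-squares factor over the four bars directly
abutting c = 0 and c = 1 (`Σo·s/Σs²`); the residual after subtracting
the scaled additive component is fit with a Gaussian density
(scipy `curve_fit`, amplitude ≥ 0, center bounded to the fit range
c ∈ [−4, 5], σ ≥ 10⁻³; initialized at the residual's maximum). An
all-explained residual returns a degenerate flag instead of a fit.

Sliding-window Poisson p-values: the observed counts are scaled so
their c = 0 peak height (the sum of the two base bins abutting zero)
matches the mean of 1000 additive simulations of one observation per
gene; each window entirely outside the exclusion zone (−0.3, 0.3) gets
`p = P(Poisson(λ) ≥ k)` with λ the mean simulated window count and k
the scaled observed count rounded to the nearest integer (the tail
needs an integer; windows overlapping the exclusion zone are dropped).
The per-window simulated counts are empirically Poisson-dispersed
(variance/mean ≈ 1 outside the exclusion zone), which the test suite
asserts.

## Differential peak calling

Consensus peaks are 150-bp windows (one nucleosome) centered on the
median summit of single-linkage groups of replicate summits closer than
150 bp, kept when at least 2 of 3 replicates contribute; condition sets
merge into a non-overlapping master set by collapsing overlapping
intervals to their span. Counts are normalized by each sample's
reads-in-peaks total divided by the cross-sample mean total, which
preserves the grand total. This normalization assumes the peak universe
is composition-stable — treatment must not change the total
reads-in-peaks much — which holds when differential peaks are a small
minority (see the generator notes below).

The FDR grid spans 50 geometric steps of minimum fold-change in
[1.1, 10] and 50 of minimum normalized count in [10, 237], endpoints
inclusive. A (peak, condition) pair is differential at a cell iff its
fold-change versus the reference control meets the cell's threshold and
the larger of the two condition means meets the count threshold.
Fold-changes are computed with a pseudocount of 1 and in whichever
direction is larger, since differential sets include closing as well as
opening peaks. Each cell's estimated FDR is
`n_conditions · (mean differential count over extra controls) / (total
experimental differential calls)`; the extra controls are full
replicate groups at 50% and 150% starting density, true nulls by
design. Calls from every cell with FDR < 0.25% are pooled by applying
the union of qualifying threshold regions to experimental and control
comparisons alike, and the pooled FDR is recomputed on that union.
Peaks within 250 bp (inclusive) are then merged, counts re-aggregated
by summation, and a second fixed-threshold pass (fold-change ≥ 1.5,
count ≥ 30, per condition versus the reference) yields the final set
with its own pooled FDR.

With only two extra-control comparisons the FP estimator's resolution
is 0.5 calls: grid cells in the extreme tail can hold a few genuine
noise calls while both controls show zero, yielding an estimated FDR of
exactly 0. The caller logs a warning whenever the pooled FP estimate
saturates at zero over a non-empty call set and reports the implied
resolution bound `n_conditions/(n_controls·n_calls)`; at realistic call
counts (tens of thousands) the saturation disappears.

## Peak–gene and motif integration

Peaks link to genes whose canonical TSS lies within 100 kb of the peak
midpoint (inclusive; midpoint avoids width-dependent asymmetry; strand
is carried but ignored, the window being symmetric). Per-gene peak
counts by category, dual-dominant fractions, and motif statistics carry
90% percentile-bootstrap intervals resampling the analysis unit (genes
for gene-level tables with 10,000 draws, peaks for motif tables with
1000). A peak is signal-exclusive when `max(|ΔA|,|ΔB|)/(|ΔA|+|ΔB|) ≥
0.9`, i.e. the major effect is at least 9× the minor one.

Motif matches collapse into factor groups by taking the maximum member
count per peak (similar position-weight matrices hit the same site;
e.g. three JUN + two FOS + two JDP2 + one BACH1 counts as three AP-1
matches). Densities are grouped matches per 150 bp of peak width. The
dual-motif null shuffles grouped matches within each peak class,
preserving every peak's total match count, and records the fraction of
peaks carrying at least one RA-dominant and one TGFB-dominant match per
shuffle (1000 shuffles; two-sided empirical p with add-one correction).
The group-to-dominance assignment ships as an editable TSV resource
(`src/combisig/resources/motif_groups.tsv`); the retinoic acid receptor
group is included on the RA-dominant side by default and can be removed
there. The motif enrichment score for a condition is the relative
change in mean normalized counts at motif-containing peaks versus the
reference control, pooling all doses and replicates of the condition.
Group comparisons elsewhere use Welch's unequal-variances t-test with
no multiple-comparison correction.

## Synthetic data

The generator emulates the study design the analysis assumes: three
replicates; three doses scaling each feature's effects by (0.5, 1.0,
1.5); folded-Gaussian noise with CV uniform in [0.05, 0.3] per
(feature, signal); gene baselines log-uniform in [1, 500] TPM and peak
baselines log-uniform in [30, 300] normalized counts; per-feature
Δ/baseline ratios log-uniform in [0.1, 2] (individual fold-changes
~1.1–3×, spanning the regimes where the additive and multiplicative
predictions are and are not distinguishable). Ground-truth c defaults
to an equal mixture of Gaussians at 0 and 1 (σ = 0.2), emulating
additive/multiplicative bimodality; ground-truth d is Normal(0, 0.1).
Genes whose implied combined mean would go negative under an extreme
negative c are rejected with a warning.

By default only 25% of peaks respond to the signals at all
(`frac_responsive_peaks`); the rest are a static background. This
matters: reads-in-peaks normalization on an all-responsive universe
systematically shrinks treated samples and destroys the additive
structure it is meant to preserve. Raw counts are the true normalized
values times a per-sample depth factor uniform in [0.6, 1.4], which the
normalization step must undo. Summit files place one summit per true
peak per replicate with Gaussian jitter (σ = 15 bp) and configurable
dropout; two extra control conditions are drawn from the identical
control distribution, so every differential call against them is false
by construction. The surrogate differential-expression table is
computed from the synthetic replicates themselves (Welch test +
Benjamini-Hochberg per dose) as a stand-in for an external DE fit.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: count-based (negative-binomial)
noise and mean–variance trends, correlated noise between genes and
peaks, GC/mappability bias, fragment-length structure, sequence
content, multi-chromosome genomes, and any true coupling between a
peak's d and a nearby gene's c.

## Problem sizes and determinism

Default analysis runs use 250 c-simulations per gene-dose, 10
d-simulations per peak, 1000 Poisson replicates, 10,000/1000 bootstrap
draws, and 1000 shuffles. The test suite and acceptance script run
scaled-down cohorts (hundreds of genes, a few thousand peaks,
30–250 simulations) chosen so each check's Monte-Carlo error is well
inside its assertion tolerance. Every stochastic step takes an explicit
seed; the pipeline derives independent per-stage seeds from one root
seed via `numpy.random.SeedSequence`, logs them at stage boundaries,
and identical (inputs, config, seed) produce byte-identical outputs.

## Known limitations

The c estimator is attenuated when features are selected by their
*measured* interaction scale (selection inflates the denominator), so
reliability-filtered summaries of observed data carry a mild downward
bias that the simulated nulls, whose filter derives from the original
measurements rather than the resimulated noise, do not share; estimates
on truth-selected synthetic features are unbiased in the mean as
replicates grow. The empirical-FDR estimate is resolution-limited at
small call counts (see above). Bootstrap intervals are percentile-type
and can undercover for strongly skewed statistics at small n. The
Gaussian residual fit assumes a single secondary peak; more structure
is reported only through the sliding-window p-values.
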