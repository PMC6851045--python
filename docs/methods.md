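# Methods

## Count model and differential testing

Per-transcript counts from each assay (RNA-seq or Ribo-seq) are modelled as
negative binomial with a log link:

    y_gj ~ NB(mean = s_j · m_gc,  var = mean + α_g · mean²)

where `s_j` is a library size factor, `m_gc` the normalized mean of
transcript `g` in condition `c`, and `α_g` the over-dispersion (squared
biological coefficient of variation in the deep-sequencing limit).

**Size factors** are median-of-ratios: each library's factor is the median
over all-positive transcripts of the ratio of its count to the
per-transcript geometric mean, normalized to geometric mean 1.  When no
transcript is covered in every library the estimator falls back to
total-count ratios (with a warning).

**Dispersions** are estimated per transcript by method of moments on
size-factor-normalized counts within each condition, `(v − m)/m²`, averaged
across conditions with residual-df weights, and then shrunk toward a
mean–dispersion trend `a₀ + a₁/mean` fitted by least squares with
non-negative coefficients.  The shrinkage weight defaults to 0.8: with only
two residual degrees of freedom per condition at the default three
replicates, the per-transcript estimate is mostly noise and strong
moderation toward the trend is the standard remedy.  Estimates are floored
at 1e-8; Poisson-like data therefore reports the floor.

**Testing.**  Every design used here is saturated (one mean per condition,
or per assay-by-condition cell), so the GLM maximum likelihood factorizes
into independent one-dimensional fits solved by vectorized Fisher scoring on
the log mean.  A pseudocount of 0.5 is added to the fitted normalized group
means before forming log2 fold changes, which bounds estimates in the
presence of zeros at the price of slightly compressing fold changes of
weakly expressed transcripts.  The Wald statistic is the (pseudocounted)
log fold change over its information-based standard error.

Because the dispersion is a plug-in estimate, the Wald z is measurably
heavier-tailed than normal at small replicate numbers.  Statistics are
therefore referred to a t distribution; its default 40 degrees of freedom
were calibrated by null simulation at the default settings (3 replicates
per condition, shrinkage 0.8), where they render the p-value distribution
uniform at both the 5% and 1% levels and slightly conservative in the far
tail.  `df=None` restores the asymptotic normal reference, and the value
should be recalibrated if the replicate structure or moderation changes.

All-zero transcripts are reported with `base_mean 0, log2fc 0, p 1`.
Transcripts with normalized mean below 1 in both assays are excluded from
testing by the pipeline (reported as filtered); both thresholds are
configurable.

## Enhanced-TE classification

RNA status is `up`/`down` when |log2FC| strictly exceeds 2, with no
p-value condition; occupancy status requires p < 0.01 **and** |log2FC| >
0.5, both strict.  `enhanced_te` is exactly {RNA unchanged} ∩ {occupancy
up}.  Because fold changes are oriented as perturbed-vs-reference, a
program that is enhanced in the *reference* (deficient) arm appears as
occupancy **down**; the pipeline's `deficient_arm` option selects which
direction is reported as the enhanced-TE set.

The GLM confirmation stacks both assays and fits
`condition + assay + condition:assay` with per-assay size factors as
offsets and a single per-transcript dispersion (the average of the two
per-assay estimates).  The saturated structure makes the interaction
coefficient identically `(ribo log2FC) − (rna log2FC)` with variance the
sum of the four cell variances — this additivity is asserted numerically in
the tests.

**Power at the default conditions.**  With dispersion α and n replicates
per condition the interaction estimator's variance is bounded below by
4α/n on the natural-log scale regardless of sequencing depth; at α = 0.1,
n = 3 that is sd ≥ 0.365, so a +1 log2 shift is at most a ~1.9σ effect.
Program-level quantities (the mean interaction coefficient, the enhanced-TE
set, set-level enrichment) are therefore the meaningful readouts at this
design size, while per-transcript interaction significance after BH — and
any planted-vs-null ranking by two-sided p-value, whose AUROC is capped
near 0.84 by the same bound — is intrinsically power-limited.

## RPKM and TE

RPKM = count / (effective library size in millions) / (length in kb), with
effective library size defined as the size factor times the geometric mean
of size-factor-normalized library totals; this form is exactly invariant to
rescaling any single library.  TE matrices are (Ribo-RPKM + pc)/(RNA-RPKM
+ pc) with pc = 0.5.

## Bisulfite methylation

Methylation level is unconverted/coverage; zero coverage is missing, not
zero.  Conversion failure is modelled as false methylated signal only:
observed = m + (1 − m)(1 − e).  Efficiency `e` is estimated by pooling
declared known-unmethylated control sites, and levels are corrected by
inverting the forward model with clipping to [0, 1].  The high-methylation
screen pools counts across replicates of the stated condition and calls
sites strictly above the threshold (default 0.90 — "over 90%") at pooled
coverage ≥ 30.  Coordinates are 1-based throughout, matching the rRNA
convention (C3782 on the human 28S).

**Moderated t.**  Replicate-level proportions are variance-stabilized with
the arcsine-square-root transform by default (`transform="none"` for raw
proportions; the transform choice is a design decision, as is the use of
replicate-level proportions rather than read counts).  The pooled per-site
variance s² (d residual df) is shrunk to the posterior
s̃² = (d₀s₀² + d·s²)/(d₀ + d) under a scaled inverse-chi-square prior whose
parameters are fitted by matching the first two moments of log s² to the
scaled-F model s² ~ s₀²·F(d, d₀), solving for d₀ by trigamma inversion.
Exactly constant observed variances are a degenerate case of that model
and yield d₀ = ∞ with s₀² equal to the common value.  The statistic
Δ/(s̃·√(1/nA + 1/nB)) is referred to t with d₀ + d df (normal when d₀ = ∞);
d₀ = 0 reproduces the ordinary pooled-variance t exactly.

**Clone analysis** scores each clone at the reference's queried cytosines
(all cytosines for RNA, CpG-context only for DNA CpG-island amplicons):
C = methylated, T = unmethylated, anything else ambiguous and excluded
from that position's denominator.  Fewer than eight clones triggers a
warning, mirroring the benchmark design's minimum.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) with universe = all transcripts tested
in the TE analysis (not the genome), BH FDR across sets, default set-size
bounds [5, 2000] after restriction to the universe.

## Synthetic data

The generator emulates the perturbation design: log-uniform transcript
lengths in [300, 10000] bp with counts scaling linearly in length (making
RPKM normalization consequential), log-normal baseline abundances
(log2 mean 7, sd 1.5), uniform library sizes in [0.8M, 1.2M] entering only
through size factors, shared NB dispersion 0.1, and three replicates per
condition (replicate counts for the emulated experiments are not published;
three is a choice).  Planted sets have size floor(fraction × n) and are the
leading blocks of a seeded permutation: 2% of transcripts shift both assays
by ±3 log2 (random sign), a disjoint 5% shift the Ribo assay only by
+1 log2.  The bisulfite generator draws Poisson(100) coverage and binomial
unconverted counts with a 1% conversion-failure rate, one planted site at
0.05/0.95 by condition on a 2% background.  Clone simulation writes
bisulfite-converted molecules with per-site Bernoulli methylation and an
optional uniform sequencing-error substitution.

What the generator does **not** emulate: multimapping and positional
coverage bias, isoform structure, codon-level occupancy, batch effects,
per-transcript dispersion heterogeneity, strand-specific bisulfite
artefacts, or non-conversion clustered in structured RNA.  Passing tests
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data phenomena.

## Numerical choices

Fisher scoring runs at most 60 iterations with steps clipped to ±4 on the
log scale; all-zero groups short-circuit to mean 0.  Trigamma inversion
uses Newton's method with the standard 0.5 + 1/y initialisation.  BH
adjustment is the step-up cumulative minimum from the largest rank.  Ties
in p-value sorting use a stable mergesort.  All tables are written with
`%.10g` float formatting so that identically seeded runs are byte-identical.

## Seeds

The pipeline fans a single global seed out per stage via
`SeedSequence([seed, stage_index])` reduced mod 2³¹, so toggling stages
never changes another stage's data; the acceptance script derives its
per-analysis seeds the same way.
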