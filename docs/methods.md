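# Methods

This note records the models implemented in `growthlnc`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about behaviour on real data.

## Growth models and the inflection point

All three models describe pooled (age, weight) observations of a cohort
with a single parameter triple (A, B, k): A > 0 the asymptotic (mature)
weight in kg, B > 0 a dimensionless shape constant fixing the curve's
position relative to birth, k > 0 the rate constant per day. The models
assume monotone sigmoidal growth with a single inflection; they do not
model seasonal effects, illness-related dips, or per-animal parameter
variation (the fit is a population-average curve).

Closed-form inflection quantities:

* logistic `W = A/(1+Be^{-kt})`: age ln(B)/k, weight A/2, max gain k·w/2;
* Gompertz `W = A·exp(-B e^{-kt})`: age ln(B)/k, weight A/e, max gain k·w;
* von Bertalanffy `W = A(1-Be^{-kt})³`: age **ln(3B)/k**, weight 8A/27,
  max gain 3k·w/2.

The Gompertz form above is the classical one consistent with its
inflection formulas. For the von Bertalanffy cubic the analytic inflection
(second derivative zero) sits at ln(3B)/k, not ln(B)/k: differentiating,
W′ = 3ABk·e^{-kt}(1-Be^{-kt})², and W″ = 0 where Be^{-kt} = 1/3. With
typical parameters (B < 1) ln(B)/k would be negative, i.e. before birth,
while ln(3B)/k reproduces the expected turning point; the package
implements ln(3B)/k. Unit conventions: weights kg, ages days, maximum
daily gain reported in g/day (×1000).

When the shape argument is ≤ 1 (B ≤ 1 for logistic/Gompertz, 3B ≤ 1 for
von Bertalanffy) the analytic inflection precedes birth. The computed
negative age is returned unclamped with a `before_birth` flag and a
warning — clamping to zero would silently fabricate a turning point.

**Fitting.** Damped least squares (`scipy.optimize.least_squares`,
Levenberg–Marquardt) on θ = (ln A, ln B, ln k), which enforces positivity
without constraints. Initialisation: A₀ = 1.05 × max observed weight; k₀
from the slope of the model's linearising transform regressed on age over
the interquartile weight range; B₀ solved from the earliest observation.
Convergence tolerances 10⁻¹² on step, cost and gradient, capped at 2000
residual evaluations. A constant-weight input (zero total sum of squares)
or a solver failure yields a fit flagged `converged=False` with NaN R² —
never a silent wrong answer. Ties in model ranking are broken by model
name so ranking is deterministic.

## Synthetic data

The generators are pure functions of their parameters and a seed, and they
encode the study conditions the pipeline is meant to handle.

**Growth cohorts.** 126 animals weighed at 18 ages evenly spaced on
[0, 400] d, by default. Each animal scales the asymptote by a
Normal(1, 0.1) factor — 10% between-animal CV, matching the dispersion
typical of slaughter weights in an unselected herd — and every weighing
adds Normal(0, 2 kg) measurement noise; weights are floored at 0.1 kg.
What this does not emulate: correlated within-animal deviations over time,
batch effects between weighing rounds, or selective mortality. Parameter
recovery on these cohorts therefore shows the fitter is unbiased under
independent noise, not that it is robust to structured dropout.

**Toy genomes.** Genes occupy slots spaced 300 kb apart on 16-Mb
chromosomes, so any two genes in different slots are > 100 kb apart; the
requested number of planted cis lncRNAs are instead placed 0–90 kb
downstream of a designated mRNA. This makes the set of distance-eligible
lncRNA–mRNA pairs exactly the planted set — a sharp oracle for the cis
screen, at the price of a gene density far below a real genome's.
Transcript lengths and exon counts are drawn so lncRNAs skew short
(mode 200–1000 nt) with 1–2 exons (~85%) and mRNAs longer (mode
600–3000 nt) with ≥ 3 exons; coding-potential scores are Normal(−5, 2)
CNCI / Normal(−3, 1) CPC for lncRNAs and Normal(+5, 2) / Normal(+2, 1) for
mRNAs, so a small fraction of boundary crossers exercises the cutoffs.

**Expression.** Gene baselines are log-normal(ln 50, 1), capped at 1% of
the library so no single gene dominates; each gene × library draws a gamma
multiplier with mean 1 and variance φ (default overdispersion φ = 0.1,
typical of bulk RNA-seq), and exactly `depth` reads (default 5 × 10⁶) are
sampled multinomially from the resulting composition. Per-gene counts are
therefore marginally gamma-Poisson — negative binomial with variance
μ + φμ² — while library sizes equal the requested depth by construction,
as in read-sampling views of sequencing. φ = 0 gives Poisson sampling.
Planted DE genes (default 50, |log2FC| ∈ [1.5, 3], 3 replicates per
condition) split the fold change symmetrically between conditions. Planted
cis-pair partners replace their independent gamma multipliers with a
single shared log-normal(σ = 0.3) factor per sample and are floored at
0.2% of the library, which drives their TPM correlation to ≈ 1 robustly
even at n = 6 samples — an additive latent factor under independent NB
noise would leave the pair correlation near 0.86, below the 0.9 cis
threshold. Not emulated: isoform-level ambiguity, GC/length biases,
batch effects, or realistic correlation among non-planted genes (the null
genes are independent, which makes the DE false-positive rate estimate
optimistic relative to correlated real data).

## lncRNA identification

All threshold comparisons are strict (<), so boundary values (length
exactly 200 nt, exactly 3 reads, CNCI exactly 0, CPC exactly −1) are
retained or classed mRNA accordingly. The default `min_exons=1` keeps
every exon count — the literal reading of the "fewer than 1 exon" rule —
and is exposed in the signature; ≥ 2 exons is common practice and one
keyword away. Rejections are attributed to the first failing rule in the
order length, exons, reads, so the report's counts partition the input.
Records with missing scores are rejected and listed rather than guessed.

## Differential expression

The empirical-noise (M, D) engine is fully determined by the replicate
design: with r replicates per condition and G genes the null has
G·2·C(r, 2) points (900 points at the default 150 genes, 3 + 3 samples).
The add-one smoothed exceedance fraction bounds the smallest achievable
p at 1/(N+1), so with very few genes the p < 0.05 gate may be
unreachable — the hand-checkable minimum is N ≥ 20 null points. The
pseudocount (default 0.5 on TPM means) stabilises ratios of
low-expression genes; M is computed as a difference of logs so that
swapping condition labels negates every M exactly in floating point and
preserves every p bit-for-bit. No multiple-testing correction is applied
to DE p-values: the significance rule is the joint filter p < 0.05 and
|log2FC| ≥ 1, and the planted-truth simulations (20 seeds) put the
empirical null call rate well under the 5% nominal level precisely
because of the added fold-change filter. "Up" always means higher in
condition A (the first label in sorted order); outputs state this.

An exact parametric negative-binomial test would be a drop-in alternative
engine; it is a documented extension point, not shipped, since the
empirical engine is the one fully specifiable from the replicate design.

## Cis neighbors and enrichment

Distance is the gap in bp between the closest ends of the two gene spans
(union over transcripts), 0 if they overlap, strand-agnostic — "upstream
or downstream" collapses to a symmetric window (default 100 kb). GTF
coordinates (1-based inclusive) are converted to 0-based half-open for
the gap arithmetic. The cis rule inherits the p < 0.05 requirement of the
co-expression rule in addition to |PCC| > 0.9; at n = 6 samples |r| > 0.9
implies p < 0.05 anyway, so this is conservative and costs nothing. The
t-transform p-value at n = 6 rests heavily on bivariate normality and is
fragile; it is reported as-is rather than "fixed". Genes absent from the
annotation, or with constant expression, are listed and excluded from the
distance test; the run continues.

Enrichment is the hypergeometric upper tail of the observed overlap
between the neighbor set and each gene set within the supplied universe,
Benjamini–Hochberg adjusted across sets. Gene-set content is entirely
user-supplied; no ontology structure is used.

## Trait comparison

Welch's unequal-variance t-test is the default even though the classical
choice for such tables is Student's pooled test: published trait tables of
this kind show group variances differing several-fold, where the pooled
test is anticonservative. The pooled variant is available via
`equal_var=True`. Traits with fewer than two observations in a group are
skipped with a warning. The default fatty-acid class map is
SFA {C14:0, C16:0, C18:0, C20:0}, MUFA {C16:1, C18:1, C20:1},
PUFA {C18:2, C18:3, C20:4, C20:5, C22:6}; any column matching the
`C<m>:<n>` shorthand must be mapped (an unmapped column is an error, not
a silent omission), and the map is fully overridable.

## Problem sizes and determinism

The test suite and examples run the generators at their default sizes —
126 × 18 growth records, 150-gene genomes, 3-vs-3 libraries of 5 × 10⁶
reads — and replicated checks (parameter recovery, ranking, DE power and
null rate) use 20 fixed seeds each; the whole suite completes in a few
seconds. Every stochastic operation takes an explicit seed and no global
random state is touched, so all reported numbers are reproducible
bit-for-bit.

## Known limitations

* Growth fits are population-average; no mixed-effects or per-animal
  random parameters, no Richards or other 4-parameter families, and no
  confidence intervals (bootstrap would be the natural hook).
* The DE engine's probability is empirical and discrete; with few genes
  or replicates its p-values are coarse.
* The cis screen tests all pairs without correcting correlation p-values
  for the number of pairs; with n = 6 samples the p-value is fragile.
* Coding-potential scoring from sequence, transcript assembly, read
  alignment and isoform quantification are out of scope: scores, GTFs and
  count matrices are inputs.
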