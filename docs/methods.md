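# Methods

## Normalized dinucleotide content

For each gene the analysis window is the 5'-most `min(len, 1000)` bases of
the coding sequence; restricting to the first kilobase controls for
transcript-length effects and for the 3'-ward decline of gene body
methylation. With L' the number of unambiguous (A/C/G/T) positions in the
window, D the number of overlapping dinucleotide positions whose two bases
are both unambiguous, and n_X counts over those positions, the
observed/expected ratio of dinucleotide XpY is

    O/E = (n_XY / D) / ((n_X / L') · (n_Y / L')).

The dinucleotide frequency is taken over D (= L'−1 for a clean window) and
the mononucleotide frequencies over L'. This differs from the common
shortcut (n_XY·L)/(n_X·n_Y) by O(1/L) — negligible at ≥300 bp — but is
fixed so counting is bit-exactly testable against a positional-scan
oracle. Positions that are not A/C/G/T are dropped from mononucleotide
counts and any dinucleotide touching them is dropped from D, which avoids
biasing either numerator or denominator. Parsing is case-insensitive and U
is treated as T, since transcriptome FASTA dialects vary.

Filters: sequences under 300 bp are flagged `TOO_SHORT`; genes with an
undefined CpG O/E (no C or no G in the window) are `UNDEFINED`; CpG O/E
outside the **inclusive** interval [0.001, 2.0] is `OUT_OF_BOUNDS`
(boundary values pass). Only `PASS` genes enter downstream analyses; other
genes keep their computed values for reporting. Restriction to annotated
genes is optional (`--annotations` on `cpgbm compute`), keeping the
sequence module independent of annotation availability.

## Mixture model and component split

CpG O/E values of PASS genes are modeled as a k-component univariate
Gaussian mixture with unequal variances (the two modes of real data have
visibly different widths). Fitting is EM with:

- initial means at the evenly spaced sample quantiles (25th/75th
  percentiles for k = 2), initial SDs equal to the sample SD, equal
  weights;
- 10 restarts, restarts 1+ perturbing the initial means with seeded
  Gaussian noise (SD = 0.25 × sample SD), the highest-likelihood restart
  winning — deterministic given the seed;
- convergence on the log-likelihood increment (< 1e-8), matching EM
  theory rather than parameter-change criteria;
- components with SD < 1e-6 abort the restart; if every restart collapses
  a `SigmaCollapseError` is raised rather than returning a degenerate fit.

BIC is reported as p·ln(n) − 2·loglik with p = 3k−1 free parameters, lower
better (some packages report the negated form; one convention is fixed and
documented). The BIC trace over k = 1..k_max is diagnostic: classification
always uses k = 2, for comparability with the two-class convention of gene
body methylation studies, even when BIC prefers k > 2.

The LOW/HIGH boundary is the solution of
w₁·φ(x; μ₁, σ₁) = w₂·φ(x; μ₂, σ₂) inside (μ₁, μ₂), obtained from the
quadratic in x that results from equating log densities (for equal
variances the quadratic degenerates to the linear closed form
x = (μ₁+μ₂)/2 + σ²·ln(w₁/w₂)/(μ₂−μ₁)). If no root lies between the means
— possible when one weighted component dominates everywhere — an error is
raised that suggests an explicit midpoint fallback; the fallback is never
applied silently. A gene exactly at the threshold is labeled HIGH: a
measure-zero event whose handling must nevertheless be fixed for
reproducibility.

## GO-term analysis

Per term: mean CpG O/E, SE = sample SD/√n, component counts, and both
one-sided Fisher exact tests of the 2×2 table
[in term vs not] × [LOW vs HIGH] against the full labeled background. The
reported direction is the side with the smaller p when it clears the star
threshold (default 0.05); no multiplicity correction is applied across
terms, matching the per-term asterisk convention of this kind of figure.
Terms with fewer than 20 annotated genes are excluded, not tested. The
term panel is supplied by the caller (file/config), not hard-coded,
because biological-process names map to different GO identifiers across
annotation pipelines. The across-term ANOVA treats a multi-term gene as
one observation per term — pseudo-replication accepted, and flagged here,
because the grouping is by annotation. `reduced_term_summary` recomputes a
parent term after subtracting nested sub-term gene sets (e.g. stress
response minus oxidative-stress genes).

## Expression association

Adjusted p-values use the Benjamini–Hochberg step-up rule (via
statsmodels); significance at a cutoff is **strict** (`padj < cutoff`).
Effect sizes are natural-log ratios ln(mean_a/mean_b); the base only
rescales magnitudes, so rank-based analyses are base-invariant. Genes with
a zero group mean have no effect size and leave magnitude analyses but
stay in significance-based analyses. The component enrichment test is the
one-sided Fisher exact test for over-representation of significant genes
in the HIGH component (the hypergeometric upper tail on `high_sig` given
the margins) — the directional hypothesis being that flexible expression
concentrates among weakly methylated genes. Quantile trends sort genes by
CpG O/E (ties broken by gene id for determinism) into contiguous
near-equal bins, the first `n mod q` bins taking the extra gene. Magnitude
analyses use |effect|. The Welch test of mean expression between
components defaults to the raw scale with a `log_scale` flag.

## Synthetic data generator

The generator emulates the mutational mechanism, not its history: each
gene draws a methylation class (HYPER with probability 0.45, matching the
weight of the low mode), a length uniform on [300, 2000] bp, i.i.d. bases
(uniform composition by default; configurable, since real transcriptome
composition varies), and then every CpG has its C replaced by T with the
class conversion probability (defaults 0.7 HYPER / 0.2 HYPO). A single
left-to-right pass is exact because a C→T conversion can create an
upstream TpG but never a new CpG. This one-parameter-per-class shortcut
reproduces the two observable signatures — CpG deficit and TpG excess,
hence the strong negative CpG–TpG correlation — without simulating a
multi-generation mutation–selection process.

DE tables are generated directly at the summary level: per gene,
`is_de ~ Bernoulli(p_de_class)` with defaults 0.01 (HYPER) / 0.03 (HYPO),
true effects Normal(0, 1.0) for DE genes vs Normal(0, 0.2) for null genes,
p-values Beta(0.05, 1) for DE genes vs Uniform(0,1) for nulls, and group
means built from a log-normal baseline (log-mean 3, log-SD 1) times
exp(effect). Count-level simulation is deliberately avoided: the DE test
itself is out of scope and downstream statistics consume only means,
effects and p-values. The Beta shape 0.05 makes roughly 60% of true DE
genes survive BH at 1% FDR at these sample sizes, a realistic detection
fraction for a well-powered design. Annotation tables sample terms
uniformly (null terms) or with a class bias (housekeeping-like terms 70–80%
HYPER, dynamic terms 20–30%), plus an 11-gene term to exercise the
minimum-size exclusion.

Everything is deterministic given the config seed; sequences, DE and
annotations use independent derived streams so tables can be regenerated
separately.

What the generator does **not** emulate: codon structure and selection,
GC heterogeneity along genes, length–methylation correlations, annotation
transfer noise, and count-level sampling noise in expression. Passing
tests therefore demonstrate that the pipeline recovers the statistical
structure it assumes — bimodality, anti-correlation, class-biased DE —
not that real transcriptomes satisfy those assumptions.

## Validation problem sizes

The self-validation suite (`cpgbm.evaluation`, exercised by the test suite
and `scripts/acceptance.py`) uses: 100 random admissible parameter sets
against a 1e-6-step grid for the intersection; 20 seeded simulations of
10,000 draws from 0.45·N(0.36, 0.08²) + 0.55·N(0.74, 0.15²) — magnitudes
chosen to mirror the component means reported for a coral transcriptome —
for parameter recovery; 100 full-pipeline replicates at 12,000 genes for
end-to-end recovery; 500 null replicates for type-I calibration (a 30-gene
term on a 5,000/5,000 background; 500-per-group Welch; 25-quantile ANOVA
on 1,000 genes). Dataset-scale quantities that depend on the original
transcriptome (e.g. the exact 0.46 split point or a genome-wide rho of
0.138) are illustrative magnitudes only and are never asserted.

## Known limitations

- The EM fitter is univariate by design; no covariates, censoring or
  non-Gaussian components.
- Fisher enrichment p-values are exact but conservative for small terms;
  calibration is verified at term size 30, where the discrete null rate
  is 0.049.
- The ANOVA across terms inherits the pseudo-replication noted above.
- GO structure is taken from the annotation table as given; no ontology
  graph traversal.
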