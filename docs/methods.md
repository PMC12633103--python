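# Methods

This note documents the models and procedures implemented in `svomics`,
the defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Variant data model and coordinates

Variants live on 1-based inclusive coordinates matching VCF POS; interval
arithmetic is closed `[start, end]`. A deletion/duplication/inversion
occupies `[start, end]` with length `end − start`; an insertion stores the
inserted-sequence length and occupies `[start, start + length]` for
distance purposes. SV types require length ≥ 50 bp; SNVs have length 1.
This convention reproduces printed breakpoint/length pairs of the form
`chr16:72057133–72058849 → 1716 bp` exactly, which is what validated it.
BED export converts to 0-based half-open at the boundary. Multi-allelic
VCF rows are split into biallelic records at read time, each split
genotype counting only its own allele.

Allele frequency is `Σ dosage / (2 × non-missing count)`; MAF =
min(AF, 1 − AF); variants missing in more than half the cohort are
excluded before QTL work and common variants are MAF ≥ 0.02 (both
boundaries retain at equality). Missing dosages are imputed by iterative
truncated-SVD reconstruction (defaults: rank 10, tol 1e-4, ≤200
iterations), initializing at column means; observed cells are never
altered and imputed cells are clipped to [0, 2]. Genotype r² is squared
Pearson correlation over pairwise-complete entries; the LD proxy of an SV
is the argmax-r² SNV within the window, ties broken by distance then id.

## Population analyses

Cross-technology merging pairs records greedily by nearest start within
500 bp, same type, and reciprocal size ≥ 0.7 (community-standard
tolerances; exposed as flags). Discovery saturation accumulates distinct
carried variants over random genome orderings (mean over 100 orders) per
AF stratum; the saturation point is the first n after which the marginal
gain stays below 0.5 new variants/genome for a 20-genome lookahead — the
rule is a package choice, exposed as parameters, since saturation points
are descriptive rather than inferential. Extrapolation treats a variant
of frequency f as detected in n diploid genomes with probability
1 − (1 − f)^(2n), integrates over the empirical AF density above the
target frequency, and reports the smallest n with expected undiscovered
fraction < 1%. Locus burden counts SVs whose interval gap to the anchor
is ≤ d (0 when overlapping; inclusive at the threshold).

## Omics normalization

Two tracks are deliberately separate. The QTL track takes raw counts
through library-size log normalization (`log1p(1e4·c/lib)`) and a
per-feature inverse-normal transform `Φ⁻¹((r − ½)/n)` with average ranks
for ties; the (r − ½)/n offset (vs Blom) is recorded in the matrix
metadata, the difference being negligible above n ≈ 100. The outlier
track standardizes log values per feature, removes the top PCs of the
standardized matrix together with age and sex by per-feature OLS, and
re-standardizes; the PC count is a per-ome configuration because hidden
structure differs by platform. Note the inverse-normal transform
compresses tails: standardized effects of rare variants estimated on the
rank-normalized response are attenuated by a few percent at MAF ≈ 0.02,
which is a property of the transform, not of the estimator.

Global-outlier samples are those whose count of |z| > 3 features exceeds
the upper Tukey fence (Q3 + 1.5·IQR) of the per-sample count
distribution. When the count distribution is degenerate (Q1 = Q3 = 0) the
fence is meaningless — it would remove every sample with a single call —
so removal is skipped with a warning. Fewer than 8 samples also skips
removal. Outlier calls require |z| ≥ 2 with direction from the sign.

Feature filtering drops an expression gene only when it fails both the
CV² trend test (log CV² residual above the log-mean trend) and the
minimum-expression rule; proteins use the minimum-expression rule alone.

## Methylation segments

CpGs are segmented per chromosome by a greedy left-to-right scan: a CpG
joins the open segment iff its correlation with the segment's running
mean profile is ≥ 0.5 (inclusive) and its gap to the previous CpG is
≤ 1 kb. The rule is deterministic and sample-order invariant; defaults
were chosen so that planted segment boundaries are recovered with Rand
index ≥ 0.9 when CpG noise SD ≤ 0.05. Autosomes only by default.

Variability screening transforms betas as `t = logit(1 − |0.5 − β|)`
(symmetric under β → 1 − β; clamped at 1 − 1e-3 to avoid the logit(1)
singularity at β = 0.5) and compares each segment's CV² of t against a
local trend of log CV² on log mean t. The trend is a running median over
quantile bins of the mean (≈15 segments per bin, 4–30 bins),
interpolated between bin centers, with residuals standardized by
1.4826·MAD; segments above 3 robust SDs are variable. A running median
was chosen over local regression because a genuinely variable segment is
often isolated on the mean axis and any pointwise-fitted smoother chases
it (residual ≈ 0, never flagged), while a bin median is immune to a
minority within its bin.

Two limitations of the transform are worth knowing. Near β = 0.5 its
slope diverges, so flat segments with near-0.5 means acquire large
amplified CV² and the screen cannot separate true variability there; and
segments with means near 0 or 1 cannot physically host large beta shifts
(values clip to [0, 1], with clip counts reported by the generator).
Synthetic outlier-recall conditions therefore plant shifts on variable
segments with interior means outside a band around 0.5.

Outlier calls require both |z| ≥ 2.5 (z from scaled segment betas) and
|Δ| ≥ 0.25, where Δ is the sample beta minus the cohort median (a robust
reference); the delta gate exists precisely so that low-variance segments
cannot produce large-z, biologically negligible calls. Global-outlier
samples are removed by the same Tukey rule and calls re-emitted.

## Enrichment

The unit of analysis is the (feature, sample) pair, pooled across
samples. Exposure: the sample carries (dosage ≥ 1) a rare SV — AF below
the stratum threshold, or allele count exactly 1 for singletons — whose
interval lies within the window (default 100 kb) of the feature anchor.
Outcome: outlier status at the stratum's signed z threshold. The odds
ratio is the sample cross-product with Haldane +0.5 on all cells iff any
cell is zero; the 95% CI is `exp(log OR ± 1.96·√Σ1/cell)`; the p-value is
the two-sided exact hypergeometric test. Only features present in the
ome's matrix are tested. The prioritization cascade labels each rare
SV–gene pair by tiers — near a gene; + outlier |z| > 2; + risk gene;
posterior score strictly > 0.6; score + risk gene — with the functional
posterior supplied externally (the hierarchical outlier-integration model
that produces it is out of scope here; any score in [0, 1] plugs in).

## Cis SV-QTL model

Pairs are enumerated interval-aware: an SV enters a feature's cis set iff
its full closed interval intersects the ±1 Mb window around the anchor
interval; reported distance is the gap to the anchor itself. Each pair is
fit by OLS of the rank-normalized phenotype on dosage plus an intercept,
age, sex, one-hot diagnosis (healthy-control reference) and the top
phenotype PCs; dosage is additive 0/1/2 with PCA-imputed missing values.
The full scan residualizes phenotypes and dosages once against the shared
design (Frisch–Waugh), after which each pair's coefficient, SE and
two-sided t-test (n − k − 1 df) are inner-product ratios — verified
identical to the per-pair fit within 1e-10. Bonferroni scope is all
tested pairs of the ome (the BH alternative is a flag), retaining
adjusted p < 0.05. `beta_std` (beta × SD(dosage)) is reported alongside
the per-allele beta for cross-frequency comparisons. PC-count
optimization refits the scan over a grid and returns the count maximizing
the significant-association yield, ties toward fewer PCs.

## Fine-mapping (Sum of Single Effects)

The genetic effect is a sum of L = 10 single effects, each placing all
its weight on one variant; fitting is coordinate ascent (IBSS) on the
variational family that factorizes over effects. Per effect, the
single-effect regression posterior is exact: per-variant Bayes factors
under a N(0, σ0²) prior give inclusion weights α. σ0² is estimated per
effect by maximizing the SER marginal likelihood (bounded scalar
optimization on the log scale), with the optimum required to beat the
σ0² = 0 boundary by 0.1 log-likelihood units — without that margin,
effects fitting pure noise linger with tiny prior variances and their
near-uniform α inflate every PIP (the duplicated-variant split degrades
from 0.5/0.5 to ≈0.66). Dropped effects (σ0² = 0) contribute nothing and
are excluded from PIPs. The residual variance update is ERSS/n. Both
updates are exact coordinate maximizations of the evidence lower bound,
so the ELBO is non-decreasing across sweeps; this is asserted at runtime
(tolerance 1e-6). Convergence: ELBO change < 1e-3 or 100 sweeps.

Level-0.95 credible sets are the smallest α-prefix per active effect;
sets with purity (minimum |r| among members) below 0.25 are discarded,
duplicate member sets deduplicated, and each set is labelled SV-led
(lead = argmax PIP is an SV), contains-SV (an SV present, SNV lead) or
SNV-only. Phenotypes entering fine-mapping are the covariate residuals
from the QTL model, standardized; genotype columns are standardized with
zero-variance columns dropped (index mapping preserved). SV-vs-SNV PIP
enrichment pools 2×2 tables over fits at each PIP threshold.

## Colocalization

Per variant, the Wakefield log approximate Bayes factor is computed from
the two-sided p-value, MAF and N: `z = Φ⁻¹(1 − p/2)`,
`V = 1/(2·N·f·(1−f))` (additionally ÷ s(1−s) for case-control with case
fraction s), `r = W/(W+V)`, `log ABF = ½log(1−r) + ½z²r`, with prior
effect SDs 0.15 (quantitative) / 0.2 (case-control) — the established
defaults of the p-value-only method, exposed as configuration. Hypotheses
H0–H4 are enumerated with priors p1 = p2 = 1e-4, p12 = 1e-5 using
log-sum-exp throughout; H3 subtracts the shared-variant diagonal in log
space. The enumeration agrees with a brute-force linear-space oracle to
1e-9 (log scale) on ≤20-variant loci. Loci are ±100 kb windows around
variants with p < 1e-5 (GWAS) or p < 1e-4 (QTL), merged when overlapping
and retained only when holding both signals. Reports keep PP.H4 strictly
above 0.5, annotate SV-in-credible-set and SV-is-lead from the
fine-mapping output, and derive risk genes by the max-PP.H4-over-contexts
rule. Variants match across datasets by (chrom, pos) with id fallback;
allele harmonization is unnecessary because p-value ABFs are sign-free.
p = 0 inputs are clipped to the smallest positive float.

## Synthetic cohorts: what they emulate, and what they do not

Defaults mirror a 551-sample aged cohort: age ~ U(55, 90), balanced sex,
diagnosis over HC/MCI/AD/PD (0.5/0.2/0.2/0.1). MAFs are drawn from a
Beta(0.4, 1.5) density over [0.001, 0.5], giving a rare-heavy spectrum
(roughly 40% below 1%); SV lengths mix log-normal modes at 300 bp /
2.5 kb / 6 kb (Alu/SVA/LINE-1 weights 0.45/0.12/0.08) over a log-uniform
background; 2% of genotypes are set missing to exercise imputation.

LD is induced by copy-then-perturb: the tag SNV starts as a copy of the
SV column and entries are resampled until realized r² is within 0.02 of
target; tags share the SV's MAF unless overridden, and explicit overrides
are validated against the comonotone bound
`r² ≤ p1(1−p2)/((1−p1)p2)`. Realized MAFs and LD targets are self-checked
on every generated fixture (±0.1 per target at n ≥ 500).

Phenotypes follow `y = Σβ·std(g) + covariates + loadings·factors + ε`
with the residual variance chosen so total variance equals `noise_sd²`
(default 1): planted betas are therefore directly the standardized
effects the mapper estimates. Hidden factors carry a fixed per-feature
variance fraction (default 0.3 over 5 factors). Expression maps the
latent through a log-normal mean to a Poisson draw (the count model is a
package choice). Rare-outlier planting at a target odds ratio converts
the target to a per-exposed-pair shift probability
`q = (p1 − p0)/(1 − p0)` with `p0 = 2Φ(−z_thr)` and
`odds1 = OR·p0/(1 − p0)`, then shifts by ±6 feature SDs; an OR is
rejected as unreachable when no rare-SV carrier pair exists. Methylation
tiles segments of 3–8 CpGs with per-segment latent levels (flat SD 0.02;
a 15% variable fraction at SD 0.08; CpG noise 0.03; values clipped to
[0, 1] with counts reported). GWAS summary statistics draw
`z ~ N(R·λ, R)` for a PSD LD matrix R and non-centrality λ at causal
variants.

What the generator does **not** emulate: haplotype structure and
recombination (LD is pairwise-targeted, not genome-wide), genotyping
error beyond uniform missingness, count overdispersion beyond
Poisson-log-normal, batch or platform effects beyond linear hidden
factors, cell-type composition, and any relationship between diagnosis
and molecular state. Passing tests on these cohorts therefore validate
the statistical machinery — calibration, recovery, discrimination — not
robustness to those real-data complications.

## Problem sizes used in the tests and acceptance script

Null QTL calibration uses 500 samples × 5,000 cis tests per replicate
(200 replicates in the test suite, 60 in the script); effect recovery
uses a 3×3 beta-by-MAF grid at n = 500 over 200 replicates; fine-mapping
coverage uses 500 (test) / 300 (script) single-effect replicates at
n = 500, p = 40 in LD blocks; colocalization uses 200/100 locus pairs at
15 variants with AR(0.5) LD and non-centrality 8; enrichment uses
n = 2,000 samples × 500 features with a planted OR of 5; methylation uses
200 samples × 150 true segments. These sizes make each stage's sampling
error small relative to its acceptance margin while the whole suite runs
in about a minute.

## Known limitations

* The interval convention is validated against printed examples but BND
  (breakend) records, phased genotypes and copy numbers beyond {0,1,2}
  are out of scope.
* Fine-mapping is individual-level only; no summary-statistic mode.
* The variability screen is uninformative for segments with cohort means
  at the transform singularity (β ≈ 0.5) and cannot flag shifts adjacent
  to the [0, 1] boundary; see the methylation section.
* The saturation point and the extrapolation rule are descriptive
  conventions, configurable, and should not be compared across pipelines
  without aligning those conventions.
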