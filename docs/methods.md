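# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `methwas`, together with what the bundled simulator
does and does not emulate.

## Scales and transforms

Probe-level methylation arrives as β-values (methylated fraction, [0, 1]).
All modelling happens on M-values, the base-2 logit `M = log2(β/(1−β))`,
because β-values are strongly heteroscedastic near 0 and 1 while M-values
are approximately homoscedastic. β is clamped to `[1e-6, 1 − 1e-6]` before
the transform so boundary values stay finite without materially moving
interior values; `m_to_beta` is the exact inverse away from the clamp.

## Quality control

Nine rules, each entity attributed to the first rule that removes it, so the
per-rule ID lists are disjoint and
`probes_retained = probes_in − probes_removed_qc − probes_removed_sex`
holds by construction:

* probe rules — any missing β; aggregate detection p > 0.05; fewer than 75%
  of samples confidently detected (detection p < 1e-5); SNP-overlapping
  probes; cross-reactive probes;
* sample rules — any missing β; aggregate detection p > 1e-5; fewer than
  75% of sites confidently detected;
* sex-chromosome probes (chrX/chrY, case-insensitive, `chr` prefix
  tolerated), counted separately from the QC failures.

Two readings of the rules are deliberately configurable:

* **Aggregation.** The scalar "detection p of a probe/sample" is not a
  primitive quantity; it is reduced from the per-cell matrix. The default is
  the mean over the other axis (`max`/`any` are available). Note that with
  the mean and the 1e-5 sample threshold, a single failing cell
  (detection p ≥ 0.05) in an otherwise clean sample is enough to reject the
  sample — the rule effectively demands a spotless detection profile.
* **Order.** By default probe rules run before sample rules
  (`QCThresholds.samples_first=False`). The reverse order is supported, but
  with the strict sample aggregate above, a probe-confined defect (one
  missing β cell, one failed probe) would then remove every sample touching
  it rather than the probe, and a chip-scale cohort can empty entirely.
  Probes-first keeps probe-level defects attributed to probes; for fixtures
  in which every removed entity violates exactly one rule the retained set
  is provably order-independent, and the test suite checks this.

Emptying the cohort raises an explicit error rather than returning a
degenerate object.

## Quantile normalization

Classic across-sample quantile normalization on M-values: the reference
distribution is the per-rank mean of the column-sorted matrix; each sample's
values are replaced by the reference at their ranks, and tied values share
the mean of the reference values their rank span covers. After the
operation, every sample carries an identical empirical distribution and the
operation is idempotent. A single-sample matrix is returned unchanged with a
warning. Quantile normalization is mildly conservative for spiked effects:
mapping through a common distribution shrinks extreme group separations by a
few percent (visible in the simulator recovery checks when normalization is
included).

## Island collapsing

Probes sharing a verbatim non-empty island name (grammar
`chrN_CLASS:start-end`, 1-based inclusive; compound names joined by ";" are
keyed verbatim and displayed by their first span; en-dashes are tolerated)
are replaced by one location whose per-sample value is the arithmetic mean
of the members. Free-standing probes pass through. For S retained sites with
m members of I distinct islands the location count is S − m + I, and the
member-weighted grand mean of M is preserved. Collapsing runs after
normalization, i.e. normalization operates at probe level.

An island's gene annotation is not well defined when members disagree; the
member with the smallest |distance to TSS| wins, ties broken by the
lexicographically smallest probe ID — deterministic and auditable. Islands
whose members are all removed by QC are simply absent. Probes with a missing
CpG-density class are treated as non-island; locations with an empty gene
field carry the sentinel `NA` and are excluded from gene-level intersection.

## Per-location model and moderated statistics

Design: `[1, G, T, W, B]`, plus `S` in the second model; samples with any
missing covariate are dropped and logged; a rank-deficient design (e.g. a
single-sex cohort making G constant) raises an error naming the collinear
columns.

**Robust fit.** Huber M-estimation by iteratively reweighted least squares:
tuning constant c = 1.345, scale re-estimated each iteration as
median(|r|)/0.6745, convergence when the largest coefficient change drops
below 1e-8, at most 10 000 iterations (non-convergence sets a flag rather
than raising). The IRLS is vectorized across locations (a batched 5×5
normal-equation solve per iteration), which is what makes chip-scale runs
take seconds. With `robust=False` the fit is exact OLS.

Two corrections keep the robust path calibrated under Gaussian noise:

* the weighted residual sum of squares over d = n − p estimates only a
  fraction E[min(z², c|z|)] = 2Φ(c) − 1 ≈ 0.8214 of the error variance, so
  the residual variance s² is divided by that consistency constant;
* the unscaled standard errors sqrt(diag((X′WX)⁻¹)) are multiplied by
  Huber's finite-sample factor K = 1 + (p/n)·var(ψ′)/E[ψ′]², with the
  moments taken empirically from the within-band weight fraction.

Without these, every moderated t is inflated by ~10% and the null
raw-p < 0.05 fraction lands near 0.065 instead of 0.05; with them, pooled
null calibration sits at 0.049–0.053 in the test conditions. The residual
degrees of freedom are taken as n − p with no effective-df correction — a
documented simplification.

**Empirical-Bayes moderation.** The variance prior (d₀, s₀²) is estimated
by matching moments of log s² against the scaled-F model: with
e = log s² − ψ(d/2) + log(d/2), the excess variance of e over ψ′(d/2)
determines d₀ through the trigamma inverse (Newton iteration), and the mean
of e determines s₀². If the empirical spread is at or below the minimum
achievable, d₀ = ∞ and s₀² is the pooled mean variance. The posterior
variance is s̃² = (d₀s₀² + d·s²)/(d₀ + d); the moderated t is
b/(u·s̃) with u the contrast's unscaled standard error, referred to a t
distribution on d₀ + d df (normal when d₀ = ∞; d₀ = 0 reproduces the
classical per-location t and is accepted as an explicit prior override).
The non-robust path of this machinery agrees with Bioconductor limma's
`lmFit`+`eBayes` to machine precision on a shared fixture, which the test
suite verifies through `Rscript`; the robust path is additionally checked
against `statsmodels` RLM coefficient-wise.

Multiple testing uses the Benjamini–Hochberg step-up adjustment (own
implementation, cross-checked against `statsmodels` and a brute-force
definition). Ranking is by ascending raw p (ties broken by location ID),
matching how such top-K tables are conventionally ordered; both raw and
adjusted p are reported, and the significance flag (adjusted p ≤ 0.05) is
reported without suppressing the top-K tables when nothing passes it.

## Dual-contrast discovery

The top-k (default 15) tables of the weight model and the genotype model are
intersected at the gene level only — never by coordinate overlap. Matching
is token-based: a symbol contributes itself plus its "-"-separated
components, so a read-through annotation like `CORO7-PAM16` matches
`CORO7`; exact-symbol matching is available by configuration. Each match
reports both rows and a direction-consistency flag (coefficient signs
agree). The intersection is symmetric in its arguments and monotone in k.

## The simulator

`simulate_cohort` emulates the data structures the pipeline consumes, not
array chemistry:

* **Baseline methylation** per probe from a three-component Beta mixture
  (defaults: 55% unmethylated Beta(2, 18), 15% hemimethylated Beta(5, 5),
  30% methylated Beta(18, 2)), giving the bimodal marginal typical of
  promoter-focused arrays.
* **Effects** are injected additively on the M scale — where the model
  lives — and mapped back to β for storage: a signed weight effect applied
  to obese samples and a signed per-allele genotype effect, each for a
  configurable fraction of probes (disjoint truth sets; random signs, since
  both hyper- and hypomethylation occur; recovery checks therefore align by
  the true sign). Within-group noise is Gaussian on the M scale,
  sd 0.5 by default — a convention, as real cohort within-group variance is
  not specified anywhere authoritative.
* **Covariates** follow a pediatric two-sex cohort: at the default n = 69,
  exactly 47 girls (24 obese / 23 normal-weight) and 22 boys (11 / 11);
  other sizes scale proportionally. Tanner stage is mildly confounded with
  weight category (Gaussian-copula correlation 0.3) to exercise covariate
  adjustment; WBC is log-normal; genotype dose is Binomial(2, 0.45).
* **Annotation**: islands are contiguous runs along synthetic autosomes
  (boundaries never split an island), named `chrN_CLASS:start-end` from the
  member span; genes tile the genome with island members sharing a gene;
  SNP/cross-reactive flags and sex-chromosome probes at configurable rates.
* **Defects**: detection failures are whole-probe (a failed probe fails in
  every sample, cells Uniform(0.05, 1); passing cells Uniform(0, 1e-6), so
  draws fall unambiguously on either side of both QC thresholds), keeping
  the marginal cell-level exceedance equal to `detection_fail_rate`.
  Scattered independent cell failures are deliberately not simulated: under
  the strict sample aggregate rule they would reject essentially every
  sample at chip scale, which is not the regime the pipeline targets.
  Missing β is one cell per affected probe. Truth probes are kept clear of
  QC defects so injected effects survive filtering.

What passing tests on simulated data do **not** show: robustness to
cell-composition shifts or batch effects (no surrogate-variable or
deconvolution adjustment — only the measured WBC covariate), to correlated
probes within a region beyond shared island means, to dye or background
artifacts (out of scope; assumed handled upstream), or to genuinely
heavy-tailed biological outliers beyond what Huber weighting absorbs.

## Problem sizes and determinism

The acceptance script runs the QC accounting at full chip scale (27 578
probes), the collapse arithmetic at 18 339 probes, null calibration on
5 × 5 000 locations × 69 samples through the full chain, FDR/recovery on
5 × 3 000 probes, and discovery on a 600-probe cohort — sizes chosen so the
whole recomputation completes in well under a minute while keeping the
Monte-Carlo error of the pooled fractions near 0.001. Every random draw
derives from a single seed (simulation configs refuse to run without one;
the pipeline manifest echoes it), and identical config + seed reproduces
byte-identical outputs.

## Known limitations

* The robust-fit residual df (n − p) ignores the effective-df loss of
  M-estimation; the finite-sample K factor compensates at first order only.
* Island gene assignment by minimal |TSS distance| is one defensible
  convention among several; real annotations may disagree.
* The comma-decimal report rendering is cosmetic (write-only); all internal
  numbers and re-readable files use decimal points.
* No GEO download, IDAT parsing or liftover between array generations; the
  annotation manifest is an input, taken at face value.
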