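# Methods

This note records the statistical model behind `mrmediation`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, the numerical conventions, and the design decisions taken
where the methodology left genuine freedom.

## Study design

The package implements a two-sample MR mediation study over three
summary-level sources: an exposure GWAS, an outcome GWAS, and a
gene-expression (cis-eQTL) study for a candidate mediator. Five causal
arrows are fitted: the forward total effect c (exposure→outcome), the
reverse effect d (outcome→exposure, as a directionality check), the
exposure→mediator effect a, the mediator→outcome effect b (drug-target
style, instrumented by the mediator's own cis-eQTLs, with SMR alongside
IVW), and the decomposition c = c′ + a·b with proportion mediated a·b/c.
All effects live on an additive (log/SD) scale; odds-ratio columns are the
exp transform of beta ± 1.96·SE, a reporting convention.

Validity rests on the three IV assumptions. The sensitivity battery probes
their failure modes: Cochran's Q for heterogeneity among per-SNP ratios,
the Egger intercept for directional pleiotropy, the MR-PRESSO-style global
RSS test with per-SNP outlier p-values, and leave-one-out refits for
single-SNP leverage.

## Instrument selection

Defaults (all configurable per trait): candidate p-value threshold 1·10⁻⁵
(strict inequality), greedy LD clumping at r² < 0.01 within a 30 kb
same-chromosome window, per-SNP F > 10 applied after clumping, cis window
±1 Mb around the gene body, eQTL pruning at r² < 0.30 with no distance
window. The clumping rule is deterministic: rank by p, ties broken by
position then identifier; each promoted index SNP removes remaining SNPs
in conflict with it. A brute-force re-statement of this rule is kept as a
test oracle; the two agree on every instance up to 8 SNPs.

The F statistic is the squared Wald z, (β/σ)². An alternative based on
R² = 2p(1−p)β², F = (n−2)R²/(1−R²), is available via
`compute_f_stat(..., method="r2")` for standardized traits. The 30 kb
window is unusually narrow for GWAS clumping (10 Mb-scale windows are more
common); it is the package default deliberately and is a single config
value when a different window is wanted.

## Harmonization

Matching is by SNP identifier only. Non-palindromic mismatches resolve by
orientation swap (sign flip, eaf ↦ 1−eaf) and/or strand complement.
Palindromic pairs (A/T, C/G) carry no strand information in their labels,
so orientation is inferred from effect-allele frequency: if both sides lie
outside the ambiguity zone [0.5−z, 0.5+z] (default z = 0.08), agreement in
side of 0.5 means aligned, disagreement means flipped; otherwise — or when
a frequency is missing — the SNP is dropped as ambiguous rather than
guessed. Dropped rows stay in the output table with raw values and a
reason code for audit; estimators consume only retained rows. Harmonizing
an already-aligned table is the identity, and every estimator is invariant
to the allele representation of the outcome file (tested).

## Estimators

Per-SNP Wald ratios use first-order SEs σ_Yj/|β_Xj| by default; the
second-order variant adding β_Yj²σ_Xj²/β_Xj⁴ is a flag. First-order is
the dominant convention and makes IVW exactly a weighted least squares of
β_Y on β_X through the origin with weights σ_Yj⁻² — an identity exploited
as an independent test oracle at 1e-10.

IVW defaults to multiplicative random effects with the scale
max(1, √(Q/(J−1))): under-dispersion never shrinks the SE below the
fixed-effects value. MR-Egger orients every SNP to β_X ≥ 0 (required for
identifiability), solves the weighted normal equations directly, scales
coefficient SEs by max(1, √(RSS_w/(J−2))) and tests against t(J−2).
Minimum instrument counts: IVW 1, Egger 3, median/modes 3, MR-PRESSO 4.

The weighted median interpolates the ratio at standardized cumulative
weight 0.5, p_j = (S_j − w_j/2)/S_J. The mode estimators maximize a
normal-kernel density over the ratios (weights 1 or w_j) on a 512-point
grid spanning the ratio range ± 3 bandwidths, bandwidth
0.9·min(sd, IQR/1.349)·J^(−1/5) times a user factor. Median and mode SEs
come from a parametric bootstrap (β_X, β_Y redrawn from their reported
SEs; 1,000 replicates by default); the seed is a required argument — no
hidden global RNG anywhere in the package.

SMR uses the strongest retained eQTL: b_xy = β_GWAS/β_eQTL,
T = z_G²z_e²/(z_G²+z_e²) against χ²(1), SE = |b_xy|/√T. The companion
HEIDI heterogeneity test is out of scope.

## Mediation

Indirect effect a·b with delta-method SE √(b²σ_a² + a²σ_b²); direct
effect c′ = c − a·b with SE √(σ_c² + σ_ab²); proportion a·b/c with SE
computed as hypot(σ_ab/c, a·b·σ_c/c²) — the standard delta form written
to degrade gracefully when the product underflows or is zero — and a
symmetric normal 95% CI. Exact additivity (indirect + direct = total)
holds by construction; in floating point it is exact to one rounding of
the largest term, which the property tests assert. The two MR steps are
treated as independent because they come from non-overlapping source
studies; covariance between â and ĉ (which share exposure instruments) is
ignored — conservatively, since that covariance is positive. A bootstrap
CI is intentionally not the default: the delta CI is symmetric about the
point estimate, matching the reporting convention the pipeline mirrors.

In repeated synthetic studies at the reference conditions the delta CI
covers the true proportion at ≈94–95% (measured over 2,000 seeds); mild
undercoverage relative to nominal is expected for a symmetric interval on
a ratio whose denominator has ~9% coefficient of variation.

## The synthetic generator

`simulate_mediation_study` emits summary statistics only — no
individual-level genotypes. For a standardized trait measured in n
samples, the SE of a per-allele effect at frequency p is (2p(1−p)n)^(−1/2)
exactly; observed effects are normal draws around the structural truth.
Exposure SNP j has true effect γ_j (normal draws rescaled so the
instrument set explains a target variance fraction, default 0.10), a
pleiotropic path α_j ~ N(μ_α, σ_α²) straight to the outcome, and induces
a·γ_j on the mediator and (c′ + a·b)·γ_j + α_j on the outcome. A disjoint
cis-eQTL set (effects δ_k, variance target 0.10 within a declared ±1 Mb
gene window) drives the mediator and b·δ_k on the outcome; a third
disjoint set with direct outcome effects (variance target 0.05) gives the
reverse-MR arm genuine instruments. The eQTL table is an independent
re-measurement of the same expression effects, mirroring the
non-overlapping-study assumption used in the mediation SEs.

Reference conditions (the generator defaults): a = 0.4, b = 0.5,
c′ = 0.3 — hence c = 0.5 and proportion mediated 0.4 — 30 exposure
instruments, 10 cis-eQTLs, 15 outcome-specific SNPs, three studies of
n = 50,000, balanced pleiotropy σ_α = 0.02. Instrument counts for the
mediator and outcome sets, and the variance-explained targets, are chosen
to give mean per-SNP F well above the selection threshold (≈170–500), the
regime in which the estimators' consistency properties are meant to hold.
Alleles, frequencies and positions are emitted so that harmonization and
clumping are genuinely exercised: ~15% of SNPs are palindromic, and a
perturbation flag (default on, 20% of outcome records) applies orientation
swaps, strand complements, and palindromic strand flips that harmonization
must undo; perturbed and unperturbed datasets yield identical retained
tables (tested). LD is block-diagonal with configurable block size and
within-block r² (default: independent SNPs; clump-interaction tests build
linked panels explicitly).

What the generator does not emulate: realistic LD decay from a reference
panel, allele-frequency misestimation between studies, sample overlap,
winner's-curse-inducing discovery/replication asymmetries beyond the
p-filter itself, non-normal effect-size distributions, and indels.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated sampling model, not robustness to
every pathology of real consortium data.

## Test-bed design points

Choices made in the validation battery, with their rationale:

- **Q calibration** uses homogeneous *no-effect* tables (θ = 0), where Q
  is exactly χ²(J−1) regardless of exposure-side noise; with θ ≠ 0 the
  first-order weights ignore β_X noise and Q is mildly inflated (a known
  NOME-violation effect, visible if the same battery is run at θ = 0.5).
- **Egger intercept recovery** is tested with negligible exposure-side
  noise (I²_GX ≈ 1). With noisy instruments the Egger slope suffers
  regression dilution and the intercept absorbs the slack — a documented
  limitation of MR-Egger, not an implementation defect; the strong-
  instrument regime is where the consistency claim applies.
- **Weighted-median breakdown** plants 3 of 10 equally-weighted
  instruments at ratio 3.0 against truth 0.5. With minority invalid
  weight the estimator sits at the 0.5/0.7 quantile of the valid ratios,
  so it carries a small positive finite-sample offset of ≈0.57·σ_ratio
  (≈0.03 at the test's instrument strength) while IVW is dragged to
  ≈1.25; the battery asserts closeness to truth within the estimator's
  own uncertainty, not exact unbiasedness.
- **Directionality** is checked on pure X→Y data (a = b = 0, c′ = 0.1,
  no pleiotropy). With a large total effect and strong instruments the
  exposure SNPs genuinely reach the selection threshold in the outcome
  GWAS, so a naive reverse MR picks them up — a real property of
  bidirectional MR without directionality filtering (e.g. Steiger), which
  is out of scope.
- **Replicate counts** (10,000 null tables for Q; 1,000 studies for
  recovery and coverage; 500 for robustness) keep Monte-Carlo noise small
  relative to the assertion bands while the whole suite runs in about a
  minute on one core.

## Numerical conventions

Two-sided p-values from the normal (IVW, median, modes, SMR via χ²(1)) or
t (Egger) distributions; empirical p-values use add-one smoothing
(1+k)/(n+1) and are never exactly zero; Bonferroni-adjusted outlier
p-values are capped at 1. I² = max(0, (Q−df)/Q) is reported next to Q as a
convenience and is not part of the mirrored analysis. Files are
tab-delimited with `NA` for missing values and floats written at full
precision (`%.17g`), which is what makes repeated runs byte-identical.
Ties in clumping break by position then identifier; ties in the mode grid
argmax break toward the lower grid point. LD matrices are symmetrized only
within 1e-8 and rejected beyond; diagonals must be 1 within 1e-8.

## Known limitations

No proxy-SNP lookup for unmatched instruments, no Steiger filtering, no
multivariable or multi-mediator MR, no MR-RAPS/contamination-mixture
estimators, no HEIDI, no MR-PRESSO distortion test, and no LD computation
from genotype panels — LD is always consumed as a supplied matrix. The
mediation algebra requires all three effects on one additive scale;
feeding it odds ratios from heterogeneous scales will produce proportions
that do not reconstruct, which is why the pipeline computes a, b, c itself
on the beta scale.
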