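# Methods

This note documents the statistical models implemented in `cismr`, the
choices made where the methodology is genuinely open, and what the
synthetic-data generators do and do not establish.

## Setting and assumptions

The pipeline performs two-sample summary-statistic MR: gene–exposure
associations (cis-pQTLs or cis-eQTLs, per-allele effects in SD units of
the molecular trait) come from one cohort, gene–outcome associations
(log-odds for a binary disease) from another, with no sample overlap
assumed. Causal interpretation rests on the instrumental-variable
assumptions (relevance, independence, exclusion restriction);
restricting to cis instruments reduces, but does not eliminate,
horizontal pleiotropy. Estimates are "per SD of exposure" by
convention — no attempt is made to rescale across platforms, so
cross-platform comparisons are directional, not magnitude-for-magnitude.

## Instrument selection

- cis window: gene body ± 1 Mb (closed interval, 1-based inclusive
  coordinates). Configurable; 1 Mb is the convention of the large pQTL
  studies this pipeline is designed around.
- p ≤ 5×10⁻⁸ (genome-wide significance) and F = (β/se)² ≥ 10. With
  these defaults every selected instrument satisfies the conventional
  weak-instrument bound by construction.
- Independence by greedy LD clumping in ascending p order (keep a
  candidate iff r² ≤ 0.01 with everything kept so far). Without a
  regional LD matrix the clump degenerates to the single lowest-p
  variant — deliberately conservative, and the reason most scan results
  are single-SNP Wald ratios. Conditional/stepwise selection is out of
  scope.

## Harmonization

Eight reporting orientations of an exposure/outcome record pair are
recoverable (either exposure allele coding × outcome allele swap ×
outcome strand flip); all are resolved by exact allele matching, then
reverse-complement matching for SNPs. Indels are matched by exact
string or swap only (reverse complement is ill-defined for
length-mismatched alleles). Palindromic SNPs carry no strand
information, so orientation is inferred from effect-allele-frequency
concordance; the pair is dropped when either frequency lies within
`eaf_window` (default 0.08) of 0.5, or when a frequency is missing.
The default policy and window are assumptions — standard two-sample MR
practice — and are configurable (`palindrome_policy: drop` disables
frequency inference entirely). No LD-proxy substitution is performed;
exposures whose instruments are absent from the outcome GWAS are
reported "unavailable", which the manifest counts (the analyzable-over-
total tally mirrors how platform coverage is reported in practice).

## MR estimators

- **Wald ratio** (k = 1): β_out/β_exp. SE by the two-term first-order
  delta method, √(se_out²/β_exp² + β_out²·se_exp²/β_exp⁴). The second
  term matters at moderate F; dropping it (the common "exact exposure"
  shortcut) is anti-conservative.
- **IVW** (k ≥ 2): weights w_j = β_exp,j²/se_out,j², algebraically a
  WLS fit of β_out on β_exp through the origin. Default is
  multiplicative random effects — SE inflated by √max(1, Q/(k−1)) with
  Cochran's Q over the ratios — which equals fixed effects under
  homogeneity and never undercuts it.
- **MR-Egger** (k ≥ 3): WLS of β_out on β_exp with intercept, weights
  1/se_out², after orienting all exposure effects positive. The
  residual scale is floored at 1 (same multiplicative-random-effects
  logic); inference uses t with k−2 df. The intercept estimates average
  directional pleiotropy under InSIDE.
- **Weighted median** (k ≥ 3): the ratio at which the cumulative
  standardized inverse-variance weight (1/se_wald²) crosses 0.5, with
  linear interpolation; SE by seeded parametric bootstrap (default
  2000 draws of each β from its sampling distribution).
- Sensitivity estimators below their minimum instrument count return a
  structured `NotEstimable` value, so a proteome-wide scan reports
  infeasibility instead of aborting — single-SNP exposures are the
  common case, not an error.
- p-values use the two-sided normal reference (t for Egger); CIs use
  the conventional 1.96 multiplier. BH-FDR is applied within each
  platform/tissue separately (`fdr_universe: pooled` switches to one
  global universe).

## Colocalization

Per-variant Wakefield log approximate Bayes factors,
labf = ½(log(1−r) + r·z²) with r = W/(W+V), V = se², are aggregated
under the assumption of at most one causal variant per trait per
region. With S1 = ΣBF1, S2 = ΣBF2, S12 = Σ(BF1·BF2), the unnormalized
hypothesis masses are H0 ∝ 1, H1 ∝ p1·S1, H2 ∝ p2·S2,
H3 ∝ p1·p2·(S1·S2 − S12), H4 ∝ p12·S12. All sums run in log space
(log-sum-exp; the H3 difference via log1p), so |z| up to ~100 is safe;
a single-variant region has exactly zero H3 mass. Priors p1 = p2 =
10⁻⁴, p12 = 10⁻⁵ and effect-variance W = 0.15² (quantitative) / 0.2²
(binary log-odds) are the field-standard defaults of the ABF framework
and are echoed in every output row. The colocalization region is the
same cis window used for instrument selection (the alternative — gene
body only — is narrower than the signal in many loci); the region is
restricted to variants harmonizable between the two datasets.
"Supported by colocalization" defaults to PP.H4 ≥ 0.8. The conditional
metric PP.H4/(PP.H3+PP.H4) is reported alongside: it answers "if both
traits have a causal variant here, is it the same one?", and is the
more informative quantity when regional power dilutes the marginal
PP.H4.

## Triangulation

eQTL "corroboration" of a protein association requires FDR significance
of the transcript MR in that tissue *and* sign agreement with the
protein's outcome-effect direction (nominal significance is a config
switch; whether published analyses required FDR here is typically
unstated). Directional consistency across datasets demands a strict
shared sign — an estimate of exactly 0 is inconsistent. The T1/T2/T3
tier labels are an interpretive layer of this package (the underlying
evidence classes — multi-platform MR significance, colocalization
support, eQTL corroboration — are standard); thresholds are
configurable and the tier is a pure function of the evidence fields.

## Validation statistics

Intensities follow the mass-spectrometry convention: zero/missing means
not detected. A protein is testable when detected in ≥ 50% of samples
of each group (configurable); tested proteins are log2-transformed and
compared by two-sided Welch t-test (pooled-variance optional — the
appropriate published choice is usually unverifiable from printed
rounding), with BH across tested proteins. The effect size is
log2FC = mean log2(case) − mean log2(control). Categorical baseline
covariates use the Pearson chi-square without continuity correction —
the only variant that reproduces printed baseline-table p-values from
recoverable 2×2 counts (e.g. 2/50 vs 0/50 → χ² = 2.041, p = 0.153);
constant covariates get a missing p rather than an error.

## Synthetic data: what it emulates, what it does not

Summary statistics are drawn directly from the multivariate-normal
sampling distribution of marginal GWAS estimates — no individual-level
genotypes. For a standardized trait the per-variant sampling variance
is 1/(2n·maf(1−maf)); binary-trait variances are inflated by
1/(φ(1−φ)) with case fraction φ = 1917/11209 ≈ 0.171 by default,
matching the information content of a 1917-case/9292-control GWAS.
Defaults state the emulated world once:

- Regions: 500 variants, AR1 LD with ρ = 0.9, n = 20 000 per trait,
  MAF ~ U(0.05, 0.5), causal effects sized to put the causal variant's
  expected |z| at 10 (clearly detectable, not overwhelming). H3
  scenarios place the two causal variants at the quarter points, where
  AR1 decay makes their LD r² ≪ 0.05.
- MR studies: exposure cohort n = 35 000 (large pQTL panel) vs outcome
  n = 11 209; per-instrument F drawn uniformly from (30, 300) — the
  spread matters, since Egger regression is only well identified when
  instrument strengths vary. Directional pleiotropy is defined relative
  to the exposure-increasing allele (independent of instrument
  strength, so InSIDE holds); an earlier draft applied it on the
  arbitrary allele coding, which cancels its mean after orientation —
  the Egger-recovery oracle caught this.
- The strong-instrument parameter-recovery check uses F = 1000
  (degenerate band), the scale of sentinel cis-pQTL instruments, so the
  Monte-Carlo SE of a 1000-replicate mean (~0.007) sits well inside the
  0.02 bias tolerance being asserted; the type-I-error check keeps
  F ≈ 100.
- Proteomics: log2-normal intensities, σ = 1, 50 cases vs 50 controls,
  shifts applied on the log2 scale; fully masked proteins emulate
  "below detection".

Not emulated: realistic genome-wide LD (AR1 only; arbitrary matrices
can be supplied from file), haplotype structure, sample overlap between
exposure and outcome cohorts, platform-specific epitope artifacts, and
assay-dependent missingness patterns. A green test therefore
establishes correctness of the estimators and the pipeline plumbing
under the stated generative model — not robustness to those real-data
pathologies.

## Numerical choices and degenerate inputs

- Duplicate variant keys in input: lowest p kept, ties to first
  occurrence (deterministic, matches common QTL-export conventions).
- Instrument sorting: (p, position, variant id) — fully deterministic
  and independent of input row order.
- β_exp = 0 raises a degenerate-instrument error in ratio-based
  estimators; p-values are floored at the smallest positive double to
  stay in (0, 1].
- Weighted-median bootstrap draws hitting β_exp = 0 exactly are nudged
  to the smallest positive double (probability-zero event, guards a
  division).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the scan derives per-trait bootstrap
  seeds from the config seed, and identical (config, seed) runs are
  byte-identical.

## Known limitations

- No MR-PRESSO / mode-based / contamination-mixture estimators, no
  Steiger filtering, no LD-proxy lookup, no multiple-causal-variant
  colocalization (SuSiE-style) — single-causal-variant ABF only.
- LD matrices are consumed, never computed from genotypes.
- The per-dataset FDR universe treats platforms as separate analyses;
  pooled correction is available but changes the discovery threshold.
- OR magnitudes across platforms are not comparable without external
  scaling of the exposure SD units.
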