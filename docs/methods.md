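# Methods

## Data model

The atomic unit is one case-control study of one biallelic variant, stored
as genotype counts keyed off the declared *effect allele* of the contrast:
`n_eff_hom` carries two copies, `n_het` one, `n_other_hom` none. Orientation
is fixed once per variant by the declared contrast (e.g. "T vs C") and never
re-derived per study from minor-allele frequency, because the minor allele
flips between ethnicities for common variants and MAF-based orientation
silently inverts odds ratios. Present/null variants (whole-gene deletions
such as GSTM1/GSTT1) use a two-cell carrier scheme; carrier- and
genotype-scheme studies of the same gene are never pooled together, since
their contrasts measure different exposures.

Missing metadata (virus type, control source) defaults to `unknown` rather
than dropping the row; genotype counts are never imputed.

## Per-study effects

Each 2x2 contrast yields log OR = ln(ad/bc) with Woolf standard error
sqrt(1/a + 1/b + 1/c + 1/d). If any raw cell is zero, 0.5 is added to all
four cells (Haldane–Anscombe) and the effect is flagged `corrected`; this is
the default of the major meta-analysis packages. A table with an empty
margin (no cases, no exposed subjects, ...) is not estimable and raises; the
pipeline logs and skips such studies rather than aborting the synopsis.

Hardy–Weinberg equilibrium in controls is tested with the asymptotic 1-df
Pearson chi-square against expected counts n·(p², 2pq, q²) at the observed
allele frequency, alpha = 0.05. Exact tests are deliberately out of scope;
at the study sizes that reach a meta-analysis (hundreds of controls) the
asymptotic test is adequate, and the test is used as a screening device, not
an inference target. Monomorphic controls satisfy HWE trivially (chi² = 0,
p = 1) and are flagged degenerate. HWE violation does **not** exclude a
study from the primary analysis; it is a sensitivity analysis (re-pool on
the passing subset) because deviation *may* denote bias but is not proof.

## Pooling

Primary estimates are DerSimonian–Laird random effects; fixed-effect
(inverse-variance) results are always computed alongside as a diagnostic.
With w_i = 1/se_i²:

* fixed pool: θ̂_F = Σw_iθ_i/Σw_i, se = (Σw_i)^(-1/2)
* Cochran's Q = Σw_i(θ_i − θ̂_F)², df = k − 1, Ph from chi-square(df)
* I² = max(0, (Q − df)/Q)·100, classified mild (< 25), moderate (25–50,
  inclusive) and large (> 50)
* τ̂²_DL = max(0, (Q − df)/(Σw − Σw²/Σw))
* random pool re-weights with w*_i = 1/(se_i² + τ̂²); OR = exp(θ̂), 95% CI
  = exp(θ̂ ± 1.96·se), two-sided normal p.

1.96 (not the exact quantile) is used for the 95% CI to match the
conventional printed CI arithmetic. With τ̂² = 0 the random pool equals the
fixed pool to machine precision, which the suite asserts. DL is the only
offered τ² estimator; REML/Paule–Mandel would change none of the downstream
rules and are omitted for parity with standard synopsis software. The
implementation is cross-checked in the tests against R `metafor`'s
`rma(method="DL")` on a shared instance.

**Eligibility.** A meta-analysis needs at least three *independent sources*,
defined as distinct publications (PubMed ID, falling back to study ID): two
cohorts inside one publication count once toward the threshold but both
contribute effects. Ethnicity subgroup analyses run only when the subgroup
itself has three sources. Internally p-values are kept at full precision;
the synopsis display rounds to three decimals and prints values below
0.0005 as "0".

## Publication bias

* **Egger**: OLS of the standard normal deviate θ_i/se_i on precision
  1/se_i (the classic form, rather than the weighted effect-on-se variant);
  two-sided t-test on the intercept with k − 2 df. The intercept is
  invariant under jointly rescaling all (θ, se), which the suite checks.
* **Begg–Mazumdar**: Kendall rank correlation between the standardized
  deviates (θ_i − θ̂_F)/sqrt(var_i − var_F) and the variances, with the
  radicand floored at 1e−12 (the most precise study can make it
  non-positive through rounding); tie-corrected asymptotic p via
  `scipy.stats.kendalltau`.

Both tests are near-powerless at small k; results with k < 10 carry a
`low_power` flag but are still reported. Leave-one-out sensitivity re-pools
after omitting each study; `robust` means no single omission flips
nominal significance at 0.05. A k = 3 baseline still runs, with its k = 2
omission re-pools flagged sub-threshold.

## Venice grading

* amount of evidence: total effect-allele copies among cases and controls
  combined — estimated as 2·(n_cases + n_controls)·(pooled control allele
  frequency) when genotype-level totals are not at hand; A above 1,000,
  B 100–1,000 inclusive, C below 100, with a caution note attached for
  variants under 1% frequency. The published per-row amount letters are not
  reproducible under any single counting rule, so this package implements
  the stated rule and treats per-row amount letters as judgment-dependent.
* replication: I² below 25% A, 25–50% inclusive B, above 50% C. The
  inclusive-interval convention reproduces all 31 published middle letters.
* protection from bias: C when the OR magnitude max(OR, 1/OR) is below 1.15
  or bias is evident (Egger p < 0.05, or a caller-supplied hard flag for
  the unautomatable indicators — genotyping error, population
  stratification, phenotype misclassification); A when the magnitude is at
  least 1.15 with no evidence of bias (Egger p ≥ 0.10, no flags, or the
  test not computable); B between. The prospective-replication exemption to
  the 1.15 rule is a manual flag, off by default. The 0.10 boundary for "no
  observable bias" is this package's convention; only the 0.05 "evident"
  threshold is forced by the grading rules.
* composite: strong iff AAA, weak iff any C, moderate otherwise — monotone
  under degrading any letter (asserted exhaustively).

## Synthetic data

The generator stands in for the undeposited literature-extracted dataset and
emulates exactly the structure the pooling model assumes:

* controls: genotype counts multinomial at HWE proportions (p0², 2p0q0, q0²);
* cases: genotype probabilities proportional to the control proportions
  times exp(θ_s·g), g = effect-allele copies. This per-allele odds law is
  again HWE at p' = p0·e^θ/(p0·e^θ + q0), so the population allelic OR is
  *exactly* e^θ — parameter recovery is a sharp oracle, not an
  approximation;
* heterogeneity: study-level θ_s ~ Normal(θ, τ²);
* publication bias: a study whose additive-contrast p is ≥ `censor_alpha`
  is suppressed with probability `censor_prob` — the simplest mechanism
  that makes the Egger/Begg power checks constructive;
* reproducibility: one global seed, per-study streams spawned with
  `numpy.random.SeedSequence`, so study i is byte-identical whatever k is.

Defaults (k = 10, 1000/arm, p0 = 0.3, θ = 0, τ² = 0) describe a typical
mid-size candidate-gene literature. What the generator does *not* emulate:
linkage disequilibrium between variants, covariate confounding, genotyping
error, or ethnicity-correlated allele frequencies (ethnicity labels are
drawn independently of p0 unless configured per variant). Passing tests
therefore validate the statistical engine and decision rules, not
robustness to those real-data pathologies.

## Problem sizes in the verification suite

The suite sizes its simulations to make each property sharp but cheap:
parameter recovery at k = 200 studies of 2,000/arm under homogeneity, and
CI coverage / τ̂² recovery over 500 replicates of k = 20 meta-analyses at
τ² = 0.05. Null calibration uses 2,000 HWE-true control draws of n = 500 at
p0 = 0.3 (a regime where the 1-df asymptotic chi-square holds) and 500
unbiased gaussian funnels of k = 15 for Egger, each judged against a 99%
binomial band around 5%.

## Reference surface

The original per-study extraction tables behind the published synopsis were
never deposited, so the package verifies against what was printed: the 31
synopsis rows shipped verbatim in `hccmeta/data/published_synopsis.csv`.
Three kinds of checks run against them: the composite rule reproduces all
31 evidence labels (1 strong / 14 moderate / 16 weak), the I² rule
reproduces all 31 replication letters, and every printed OR/CI/P triplet is
Wald-consistent once the two-decimal rounding of the printed OR and CI is
propagated into the recomputed p (exact-precision comparison without that
propagation fails for 14 of 36 triplets — an artifact of printing, not of
arithmetic). The published tallies of amount-of-evidence and replication
letters disagree internally with the printed rows (they sum to 30 over 31
rows) and are asserted nowhere.

## Known limitations

* Crude (unadjusted) per-study ORs only, as in the source literature;
  covariate-adjusted effect extraction is out of scope.
* No multiple-testing correction by default (synopsis practice reports
  nominal p); Bonferroni/FDR columns can be enabled in the pipeline config.
* No trim-and-fill, selection models, network meta-analysis or Bayesian
  pooling.
* Amount and bias letters automate only the codified parts of the grading;
  judgment-based indicators must be supplied as flags.
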