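# Methods

## Data model

One record per study × SNP: metadata (author, year, nationality,
ethnicity, source of controls HB/PB, genotyping method PCR-RFLP/PCR,
Newcastle–Ottawa components) plus six genotype counts — case and
control 11/12/22, where allele 1 is the reference allele and allele 2
the risk allele tested. A citation contributing two case series that
share one control arm is stored as two records with the control counts
duplicated; that is the unit of analysis used in pooling and is why the
packaged dataset counts nine Fas −670 studies from seven citations, and
why control totals (1072) count the shared arm twice.

The packaged fixture stores both Sziller arms with method PCR-RFLP.
The source table of study characteristics prints "PCR" for them, but
every published subgroup statistic (the k = 6 / k = 3 method split and
each subgroup OR, CI and heterogeneity p) is consistent only with the
PCR-RFLP coding, so the fixture follows the analysis rather than the
metadata table.

## Per-study effects

Woolf log odds ratio, ln(ad/bc), with standard error
√(1/a + 1/b + 1/c + 1/d) and Wald 95% CI. If a table contains a zero
cell, 0.5 is added to all four cells (Haldane–Anscombe) and the
estimate is flagged; the fixture has no zero cells, so its results are
unaffected. A table with an empty case or control arm has no defined
odds ratio and raises an error.

## Pooling

**Fixed effect** is Mantel–Haenszel — OR = Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) over
*uncorrected* cells (MH tolerates zeros; the continuity correction is
applied only to per-study display estimates) — with the
Robins–Breslow–Greenland variance for the pooled log OR. This pairing
is the default of the mainstream meta-analysis packages for 2×2 data
and reproduces the published values to printed precision. The per-study
weights reported are the normalized MH weights bᵢcᵢ/nᵢ.

**Random effects** is DerSimonian–Laird: τ² = max(0, (Q − df)/(Σw −
Σw²/Σw)) from fixed inverse-variance weights w = 1/se², pooled with
weights 1/(se² + τ²). When Q ≤ df, τ² = 0 and the result collapses to
inverse-variance fixed pooling.

**Heterogeneity** is Cochran's Q about the inverse-variance fixed mean,
referred to χ² with k−1 df, summarised as I² = max(0, 100·(Q − df)/Q).

**Method selection.** The published methods text mixes two triggers
("I² < 50% or P > 0.1 → fixed"), which conflict on this dataset: the
allele model has p_het = 0.083 yet is pooled fixed, while a two-study
analysis with p_het = 0.117 is pooled random. Only the I² ≥ 50% rule is
consistent with the labelled total rows, so that rule (threshold
configurable) drives selection, applied independently per subgroup and
per leave-one-out subset. A single-study analysis is passed through as
the study's own Woolf estimate, flagged "not pooled".

P-values for pooled effects are two-sided normal on z = log OR / se;
0.05 is the significance threshold throughout.

## Hardy–Weinberg screening

Control-arm genotype counts are tested with the plain Pearson χ²
(no continuity correction) against expected counts n(1−q)², 2nq(1−q),
nq² at the estimated allele frequency q, 1 df, α = 0.05. Monomorphic
arms are flagged rather than tested. Studies out of HWE are flagged but
retained in pooling, matching the source analysis (both deviating
control arms — the two FasL −844 studies — are pooled). No exact test
is provided; the screening role does not need one at these sample
sizes.

## Publication bias

Egger's test: OLS of the standardised effect (log OR/se) on precision
(1/se); the intercept is tested against zero with t on k−2 df
(two-sided). Begg's test: Kendall rank correlation between the
variance-stabilised deviations from the fixed inverse-variance pooled
mean, (θᵢ − θ̄)/√(vᵢ − 1/Σw), and the variances vᵢ; S is referred to
the normal approximation with variance k(k−1)(2k+5)/18 and a continuity
correction, without a tie adjustment (variances of real tables are
almost surely distinct). Both tests require k ≥ 3 and are skipped with
a notice for two-study analyses.

## Synthetic data

The generator emulates the statistical structure the estimators assume:
study i draws θᵢ = ln(OR) + N(0, τ²); the control risk-allele frequency
q0 is shifted on the odds scale to the case frequency q1ᵢ =
q0·eᶿ/(1 − q0 + q0·eᶿ); each arm's genotype counts are multinomial
under Hardy–Weinberg proportions at its allele frequency. The true
effect is injected on the allelic-odds scale, so dominant/recessive
true values are implied rather than set. SOC and method labels are
drawn categorically so subgrouping runs on simulated data. Per-study
generators are spawned from one seed sequence, making datasets
reproducible and study i independent of k.

Defaults — k = 9 studies, 150 cases and 150 controls each, q0 = 0.30,
true allelic OR 1.5, τ = 0 — mirror the scale of the fixture (median
arm ≈ 140 subjects, control G frequency ≈ 0.3, pooled allelic OR 1.54).

What the generator does **not** emulate: genotyping error and HWE
violation, shared control arms, covariate confounding, linkage between
SNPs, and selective publication. Passing calibration checks therefore
validate the estimators under a correctly specified sampling model,
not robustness to those artefacts.

Calibration (seeded, 1000 replicates each, run by the test suite):
DL 95% CI coverage of the true OR 0.961 at the defaults; Q-test type-I
error 0.054 at OR = 1; |bias| of the pooled DL log OR < 0.01 at
n = 300/300, τ = 0.2; control arms fail the HWE screen at ≈ 4–5%.
These replicate counts keep the whole suite within a few seconds while
leaving the binomial noise well inside the asserted bands.

## Reporting

Internal computation is full precision. Tabular output rounds ORs and
CI bounds to 2 decimals and p-values to 3 (displayed as "<0.001" below
10⁻³ in Markdown); JSON retains full precision and round-trips to an
equal in-memory report. Reports are byte-identical across runs on the
same input; every analysis row records the Q, p_het and I² that drove
its fixed/random decision.

## Known limitations and discrepancies

- **Heterozygote model, Fas −670.** The published heterozygote rows
  cannot be derived from the published genotype counts. The
  population-based single-study row prints 5.75 (2.31, 14.29), which
  matches the odds ratio and Woolf standard error of the table
  (29, 8, 29, 46) — the case AG count re-entered as the control exposed
  cell — while the actual counts give 2.45 (1.03, 5.84); the pooled
  heterozygote rows (total 2.11, hospital-based 1.82) are likewise
  irreproducible, and substituting the printed single-study value still
  does not recover them. Faithful computation gives a total DL OR of
  1.75 (1.23, 2.47) with I² = 48.9%, which under the I² rule is pooled
  *fixed* (1.67), whereas the published label is random. This package
  reports the values computed from the data.
- The allele-model PCR subgroup row prints the fixed MH value although
  its computed I² (63%) selects random effects; the package applies its
  selection rule uniformly per subgroup.
- Mantel–Haenszel and inverse-variance fixed pooling agree within 1% on
  the large-count analyses (Fas −670, FasL −844) but differ by up to
  2.4% for FasL 124 A/G models with 4-count cells; MH is the reported
  fixed estimator.
- No Peto OR, Hartung–Knapp adjustment, meta-regression, trim-and-fill
  or exact HWE test; single-SNP analyses only, no gene–gene or
  gene–environment modelling.
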