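# Methods

This note documents the models, estimators, numerical choices and
limitations behind `famrare`. Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`.

## Data model and variant identity

Variants are identified by `chrom:pos:ref:alt` with 1-based VCF
coordinates. No normalization or left-alignment is applied: inputs are
assumed pre-normalized, so two representations of the same indel are
distinct identities. Multi-allelic sites are split on read into one record
per alternate allele; the per-sample dosage of each record counts that
allele specifically, so the split preserves total alternate dosage per
site. Sex chromosomes are treated as diploid autosomal; the dominant model
used by the segregation filter does not depend on phase.

Functional classes are normalized through an explicit alias table
(`stopgain` → `stop-gain`, `nonsynonymous SNV` → `nonsynonymous`,
`splicing` → `splice-site`, …); unrecognized labels map to `other` rather
than erroring, because exome annotation tables routinely contain classes
the cascade never filters on.

## Prioritization funnel

*Deleterious* means: functional class in {stop-gain, stop-loss,
nonsynonymous, splice-site} **and** max allele frequency over all consulted
databases ≤ 0.005. The boundary is inclusive (an AF of exactly 0.5 %
passes), whereas the burden-QC filter excludes strictly above 0.005; the
two boundaries are deliberately asymmetric because that is how the two
screens are defined. Absence from every database counts as AF 0.

Rarity classes: *novel* = absent from every database; *ultra-rare* =
max AF < 0.001; *rare* = max AF < 0.005; *common* otherwise. The class
boundaries leave AF exactly 0.001 formally ambiguous between ultra-rare and
rare; it is classed *rare* here (the `<` on the ultra-rare bound is taken
literally).

*Segregation* under the dominant model requires every affected genotyped
member to carry ≥ 1 alternate allele and every unaffected member to carry
none. Carrier status (dosage ≥ 1) is used rather than strict
heterozygosity: "carries the risk allele" is the testable reading of
cosegregation, and a homozygous affected member would not contradict
dominant transmission. Members with unknown affection are ignored. Missing
genotypes fail the variant under the default `strict` policy (conservative:
prevents false candidates) or are skipped under `ignore`.

*Control exclusion* computes the control MAF as alternate alleles over
2 × non-missing genotypes and excludes the candidate if any alternate
allele is observed — a family-private, fully penetrant allele should be
absent from healthy controls. A variant absent from the control panel is
kept (MAF 0); an all-missing column leaves the MAF undefined and keeps the
variant with a warning.

The three filters are independent per-variant predicates, so stage order
cannot change the final set (asserted by test); the fixed order is
cheapest-first. In-house controls are a separate exclusion source, never
merged into the database frequencies, mirroring the two-step screening
design.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes — not sequencing artefacts.

**Family.** The default pedigree has three generations and 13 members, 10
genotyped (7 affected, 3 unaffected); its topology is synthetic. Founders
draw each background genotype from Hardy–Weinberg equilibrium at the
variant's true AF; non-founders receive one allele per parent, each
transmitted with probability 1/2. Background variants are unlinked (no LD):
the analysis nowhere uses LD and independence keeps every oracle tractable.
The default background spectrum is a point-mass mix: 45 % common (AF 0.10),
20 % low-frequency (0.02), 15 % rare (0.004), 12 % ultra-rare (0.0008) and
8 % database-novel (true AF 0.002 but absent from the emulated databases).
Reported database AFs equal true AFs (no sampling noise in the databases);
variants in the novel bin and the planted variant are absent from all
sources. Functional classes follow an exome-like mix (44 % nonsynonymous,
40 % synonymous, 5 % splice-site, 4 % stop-gain, 1 % stop-loss, 6 % other).

The planted variant is assigned by a penetrance model: an affected member
carries one copy with probability `penetrance_affected` (default 1.0) and
an unaffected member is a non-carrier with probability
`penetrance_unaffected` (default 1.0). Under complete penetrance the
realized assignment is checked for obligate-carrier consistency (a carrier
whose parents are both present and both non-carriers is an error). Below
complete penetrance the assignment is status-driven rather than
allele-dropped — it models phenocopies/non-penetrance for filter testing,
not a joint genotype-phenotype likelihood.

**Cohort.** Defaults: 285 cases, 445 controls, five genes. Controls draw
genotypes from HWE at each variant's MAF. Enrichment is carrier-based: the
per-variant HWE carrier odds are multiplied by the gene's odds ratio in
cases, and carrier genotype (het vs hom-alt) keeps the HWE conditional
proportions. Carrier-level (not per-allele) enrichment matches the
collapsing tests being validated. The default gene models (23/8/20/7/15
variants with per-variant MAFs 0.0007/0.00115/0.00215/0.00112/0.00135)
give expected control carrier frequencies near 3.2 %, 1.8 %, 8.3 %, 1.6 %
and 4.0 % — the shape of a targeted-sequencing screen of one candidate gene
plus four comparator genes.

**Seeding.** One master seed; component streams derive from fixed
`SeedSequence` spawn keys; replicate streams use seed·100003+replicate.
Identical seeds give byte-identical output files.

## Association statistics

**Fisher exact (two-sided).** Conditional on the margins the first cell is
hypergeometric; the two-sided p sums the probabilities of all tables as or
less probable than the observed one. Probabilities are compared with
relative tolerance 1e-7 so exact rational ties are counted as ties despite
floating point. The implementation evaluates the log-pmf via `gammaln` and
normalizes over the support; tests verify agreement with an independent
`scipy.stats.hypergeom` enumeration to 1e-12 on every table with n ≤ 60,
and with `scipy.stats.fisher_exact`. Degenerate tables (an empty margin)
return p = 1 with a warning. Significance uses a strict `<` against the
Bonferroni threshold α/m.

Odds ratios use the Haldane +0.5 correction when any cell is zero, and the
output flags when the correction was applied. The default single-locus
table is carrier/non-carrier (consistent with the collapsing framework);
allelic mode is available.

**Burden QC.** Genotypes with quality strictly below 99 are masked to
missing *first*; call rate is computed on the masked matrix; variants are
excluded for any-database or in-house AF > 0.005 or call rate < 0.90. The
quality floor is interpreted as a per-genotype quality (the natural reading
for a genotype-level QC step); genotypes without a quality value are kept.
The exclusion log records one reason per variant (frequency checked before
call rate).

**Carrier collapsing.** Counts are carriers (subjects with ≥ 1 rare allele
in the gene), not alleles; frequencies are percentages of the full cohort
sizes, rounded half-up to two decimals to match the usual report
formatting. 21/285 and 14/445 reproduce 7.37 % and 3.15 % exactly.

**CMC** is implemented as pure collapsing + two-sided Fisher exact — the
rare-variant-only degenerate case of the combined multivariate and
collapsing framework. Published implementations differ in the final test
(score, Firth logistic); p-values from other software are therefore not
expected to match to the digit, while counts and frequencies are exact.

**Madsen–Browning.** Weights w_j = 1/√(n_j q_j (1−q_j)) with q_j the
allele frequency among unaffected subjects with a +1 pseudo-count and n_j
the number of genotyped subjects at variant j. Per-subject score
Σ_j w_j·dosage; the statistic is the sum of case ranks (average ranks on
ties); p = (1 + #{permuted ≥ observed}) / (1 + B), one-sided toward case
excess, default B = 9,999; an exhaustive mode enumerates all label
assignments when C(n, n_cases) is small. Missing dosages contribute no
alleles to the score. Degenerate inputs (all scores equal) return p = 1.

**SKAT-O.** With score residuals s_j = Σ_i (y_i − ȳ) g_ij and weights w_j
(default Beta(1,25) density at the pooled-sample MAF; Madsen–Browning and
uniform schemes available),

    Q_ρ = (1−ρ) Σ_j (w_j s_j)² + ρ (Σ_j w_j s_j)²,   ρ ∈ {0, 0.1², …, 0.9², 1}.

Missing dosages are mean-imputed per variant. The null covariance of the
weighted scores is Σ = (n/(n−1)) σ² W Gcᵀ Gc W with σ² = ȳ(1−ȳ) and Gc the
column-centred dosage matrix; the n/(n−1) factor is the exact
finite-population variance of a linear permutation statistic and matters at
realistic cohort sizes. Per-ρ p-values use the modified moment-matching
(four-cumulant non-central chi-square) approximation to the weighted
chi-square mixture with eigenvalues of R_ρ^{1/2} Σ R_ρ^{1/2}; ρ = 1 is
handled exactly as the rank-one case (single eigenvalue 1ᵀΣ1).

For the grid minimum T = min_ρ p_ρ, note each per-ρ p is a fixed monotone
function of Q_ρ, so {min_ρ p_ρ ≤ T} is exactly {∃ρ: Q_ρ ≥ q_ρ(T)} with
q_ρ(T) the inverse of that function. Writing Q_ρ = (1−ρ)Q_skat + ρQ_burden
and conditioning on the burden component a = Σ_j U_j (Q_burden = a²), the
remaining scores are Gaussian with mean proportional to a, making
Q_skat | a a *noncentral* weighted chi-square mixture. The combined p is
then a one-dimensional integral over the χ²₁ law of a²/Var(a), with the
conditional mixture tail evaluated by Imhof's characteristic-function
integral (vectorized trapezoid with truncation chosen from the envelope
decay; a Lugannani–Rice saddlepoint fallback covers configurations too
oscillatory for the grid and the deep tail). Unlike the common
variance-shrinkage decomposition, this introduces no distributional
approximation beyond the Gaussian score law itself; against a direct
Gaussian Monte-Carlo of the same event the result agrees to ~1e-3. The
final p is clipped to [T, |grid|·T] (the combination can never beat the
best single ρ nor exceed its Bonferroni bound). ρ selected is the grid
minimizer; with one variant all ρ give identical statistics and p equals
the per-ρ value. A label-permutation mode (vectorized, (1+hits)/(1+B))
serves as fallback for singular configurations and as an independent
oracle in tests.

Known limitation: the remaining gap between the analytic p and the exact
permutation distribution is the Gaussian approximation of the score vector,
whose error is O(1/n) and grows with weight concentration and allele
rarity. On 30/30 toys with common variants the analytic and
99,999-permutation p-values agree to ~1e-3–1e-2 depending on the realized
genotype matrix; with very rare variants or strongly skewed Beta(1,25)
weights at small n, permutation is the method of choice and is provided.
Type-I error of all three burden tests at the default cohort size
(285/445) is verified by null simulation to sit at or conservatively below
nominal.

**Power ordering.** A sanity property asserted by the suite: when all
causal variants in a gene act in the same direction with equal effects
(scenario: 8 variants at MAF 0.004, carrier odds ratio 2.0, 285/445), the
burden-style statistics — CMC, Madsen–Browning (at 9,999 permutations, so
the p resolution sits below the analytic p-values being compared) and
SKAT-O restricted to ρ = 1 — produce a smaller p than SKAT-O restricted to
ρ = 0 in at least 60 % of replicates. The variance-component statistic is
designed for mixed-direction effects and cedes power in this regime.

## Morphometry statistics

G-ratio = naked axon diameter / myelinated fibre diameter, defined only for
0 < naked < myelinated, hence always in (0,1) and invariant to unit
rescaling. The group-comparison procedure applies a two-sided F-test to the
ratio of sample variances (p = twice the smaller tail) and uses Student's
pooled-variance t-test when p ≥ 0.05, Welch's otherwise, both two-sided.
The F-test is a variance-homogeneity gate — it does not assess normality —
and the gate is the faithful reading of the two-stage
"F-test then Student/Welch" procedure this module reproduces. Zero-variance
samples are rejected rather than silently producing p = 0 or 1.

## Problem sizes used by the checks

The acceptance script and test suite use simulation sizes chosen to give
stable Monte-Carlo estimates at interactive runtimes: 100 families for
funnel-recovery rates (a binary outcome with expected rate 1), 400–500 null
cohorts for type-I error at α = 0.05 (99 % binomial band ±0.025), 150–200
replicates for enrichment ranking at odds ratio 2.5, 500 replicates for the
single-locus family-wise error, and exhaustive enumeration for every 2×2
table with n ≤ 60. The published-count arithmetic (thresholds, carrier
frequencies) is exact and size-independent.

## What passing tests do and do not show

The generators emulate HWE genotypes, Mendelian transmission, carrier-level
enrichment and missingness — not LD, population stratification, relatedness
within the case-control cohort, genotyping error beyond quality masking, or
variant-calling artefacts. Passing tests therefore demonstrate correctness
of the statistics and filters under their own model assumptions; on real
data, confounding by structure or batch remains the analyst's
responsibility (no covariate adjustment or kinship correction is provided,
by design).
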