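# Methods

This note documents the statistical models implemented in `mqtlnet`, the
parameters that matter, what the synthetic-cohort generator does and does
not emulate, and the design choices made where more than one reasonable
convention exists.

## Pre-analysis chain (`mqtlnet.qc`)

The chain is strictly ordered — run-day normalization → missingness
filter → kNN imputation → outlier removal → inverse normal transform —
and the order is enforced through a stage tag on the abundance matrix.

**Run-day normalization.** Mass-spectrometry intensities drift between
instrument tuning days, multiplicatively to good approximation. For
metabolite *j*, sample *i* on day *d*:
`out = in × median_j(all) / median_j(day d)`, medians over non-missing
cells. Consequences worth knowing: (i) a metabolite constant within a
day maps exactly onto the overall median (the per-day median equals the
overall median after scaling — a tested invariant); (ii) because the day
factor is *estimated from the corrected samples themselves*, a
post-normalization ANOVA of intensity on day is conservative
(super-uniform p-values), not uniform — the batch factor is removed, and
then some. A per-(day, metabolite) batch option exists in the generator
to stress this correction.

**Missingness filter.** Metabolites missing in strictly more than
`max_missing` (default 0.20) of samples are dropped; exactly 20% is kept.

**kNN imputation.** Neighbors are *metabolites*, not samples. The
distance between two metabolites is the root-mean-square intensity
difference over samples where both are observed (scaling by the shared
count makes distances comparable across pairs with different overlap).
A missing cell takes the mean of its k=10 nearest metabolites' values at
that sample; neighbors missing there are skipped, and if none remain the
metabolite's own mean is used (logged). The unweighted neighbor mean
follows the common gene-wise kNN convention.

**Subject outliers.** Per metabolite, z-scores across subjects; per
subject, the median of those z-scores; the medians are standardized
across subjects and subjects with |standardized median| > 3.5 removed.
Two-sided by default — a subject uniformly low is as suspect as one
uniformly high; a one-sided flag reproduces the high-side-only rule.
Fewer than three subjects makes the standardization degenerate; the
guard removes nobody. Zero-variance metabolites contribute zero z-scores
with a warning.

**Inverse normal transform.** `Φ⁻¹((rank − c)/(n − 2c + 1))` with the
Blom offset c = 3/8 (the common metabolomics default; configurable).
Ties receive average ranks and identical transformed values; constant
columns become all-zero with a warning. The transform makes every
downstream linear model distribution-free in the metabolite marginal,
which is also why the generator's log-normal marginal choice is
innocuous.

## Phenotype associations (`mqtlnet.assoc`)

Model families by phenotype type: linear for FEV₁pp, FEV₁/FVC and
percent emphysema (metabolite as response; the reported beta is the
phenotype coefficient), logistic for chronic bronchitis and negative
binomial for exacerbation counts (phenotype as response, metabolite as
exposure; NB falls back to Poisson when the dispersion fit degenerates,
and non-converged fits are reported with a convergence flag rather than
dropped). Default covariates for all five phenotypes: age, sex, BMI,
current smoking, pack-years, clinical center (dummy-coded);
per-phenotype overrides are accepted. Significance is Bonferroni within
phenotype over the metabolite count — 0.05/995 ≈ 5.03×10⁻⁵ at the
reference metabolome size. The regression direction for continuous
phenotypes is switchable (`metabolite_as_response=False`), since both
conventions appear in the literature; betas differ, p-values are
asymptotically equivalent for the simple-model case.

Cohort characteristics tables are tested with Pearson chi-square (no
continuity correction) for binary traits — excluding any group without a
defined classification — and one-way ANOVA reconstructed exactly from
per-group n/mean/SD for continuous traits (SSB from group means,
SSW = Σ(nᵍ−1)sdᵍ²; identical to raw-data ANOVA when the summaries are
exact, which is a tested identity).

## met-QTL scan and conditioning (`mqtlnet.qtl`)

SNPs are MAF-filtered (>1% in the analysis sample). The scan
residualizes metabolites and dosages on the covariate design (clinical
covariates plus ancestry PCs, default 5) and tests the residual
correlation with df = n − 1 − rank(design); by Frisch–Waugh–Lovell this
equals the per-pair full regression exactly, which the test suite
verifies to 10⁻¹⁰. Dosages are used as-is; missing dosages are
mean-imputed per SNP for the scan only. The significance bar is
alpha/(metabolites × SNPs). Sub-threshold storage is capped (top 100
SNPs per metabolite by default) to bound memory at genome scale. The
reported per-pair r² is the squared partial correlation — variance
explained beyond covariates — consistent with the scan statistic.

Recursive conditioning per metabolite: the smallest-p SNP is admitted
outright; every remaining candidate is then refit (complete case) as
`metabolite ~ candidate + admitted + covariates`; the best conditional p
is admitted iff it is below 0.05/(number remaining), and the loop stops
otherwise. Candidates collinear with the admitted set (perfect LD) are
dropped with a log entry. Ties break by (chrom, pos, id), making the
procedure deterministic. Note the procedure's false-admission rate is
~5% per metabolite *by design* (the within-round Bonferroni), so in
simulation a weak LD shadow is occasionally admitted; recovery tests are
therefore phrased over replicate fixtures. Ancestry PCs are included in
the conditioning design by default for consistency with the scan (a
flag restricts to the clinical covariates only).

Variance decomposition fits nested models in admission order:
covariates-only r², then one increment per SNP. Increments are
non-negative by construction and sum to the genetic share. Plain r² is
the default; adjusted r² (`adjusted=True`) reproduces the convention of
decomposition tables that penalize model size.

## Network and modules (`mqtlnet.network`)

**GGM.** Metabolites are residualized on confounders, then the
correlation matrix is shrunk toward the identity with the
Schäfer–Strimmer analytic intensity λ = Σ var̂(r_ij)/Σ r_ij² (recorded in
the network metadata) before inversion to partial correlations. With
hundreds of metabolites and comparable n the unshrunk matrix is
(near-)singular; at n ≫ p the shrunk and plain estimates agree to 0.02
elementwise (tested). Edge rule: partial correlation > 0.2 **and**
Fisher-z p below alpha/denominator; negative partial correlations are
treated as spurious and never edged. The Bonferroni denominator defaults
to (number of metabolites)², switchable to p(p−1)/2. Edge p-values use
Fisher z with effective df n − 3; the classical full-order correction
(subtracting the conditioning count) is invalid under shrinkage, so this
is an approximation, deliberately on the simple side — the pcor > 0.2
magnitude rule, not the p-value, is the binding constraint at realistic
n. A caveat: λ shrinks toward zero correlation, so weak true edges
(pcor just above 0.2 before shrinkage) can fall under the magnitude bar
when most of the matrix is null; planted-structure tests use
intra-module correlations ≥ 0.5 for this reason.

**SNP nodes.** One node per independent met-QTL SNP, one edge per
admitted (SNP, metabolite) pair, provenance-tagged; metabolite edges are
untouched. SNP–SNP edges never exist.

**Module search.** The phenotype is first residualized on its covariate
set; each metabolite node and candidate module is scored by −log₁₀ p of
the slope in `profile ~ residualized phenotype`, with the module profile
the unweighted mean of member intensities. Every metabolite node seeds a
search; at each step the *best admissible* neighbor joins, where
admissible means the extended score strictly exceeds the current module
score and every member's individual score (the strictly-greater reading
of the admission rule; admissibility is checked before choosing the
best, because the highest-scoring extension may be inadmissible while a
lesser one is not). Ties break by metabolite id. Overlapping seed-optima
merge (union) when the merged module passes the same rule, else the
higher-scoring one is kept. The module p-value is Bonferroni-corrected
over the number of seeds — a documented choice; the correction behind
published "adjusted scores" is not standardized — and only modules with
adjusted p < alpha are returned. Log-scale p computation
(`t.logsf`) keeps scores finite far beyond float underflow.

**Module variance decomposition.** The first PC of the members'
standardized intensities (oriented so the mean loading is ≥ 0; all
reported quantities are sign-invariant) is regressed on the union of the
members' independent met-QTL SNPs, and separately on the clinical
covariates; the two r² are reported side by side.

## Enrichment (`mqtlnet.enrich`)

One-tailed (over-representation) Fisher's exact test of significant
features per annotation group against the full feature universe, with
Benjamini–Hochberg adjustment across groups. Unmapped ids form an
explicit "unannotated" group; groups below 2 members are reported but
flagged underpowered rather than dropped.

## Synthetic cohorts (`mqtlnet.simulate`)

Each metabolite has a unit-variance latent Gaussian assembled from:
covariate effects (a configurable fraction of metabolites receives a
±effect coefficient per covariate), planted SNP effects (coefficient
√v on the sample-standardized dosage, so the SNP explains exactly v of
the latent variance in expectation), a shared module factor (loading
√ρ, giving intra-module correlation ρ), and independent noise absorbing
the remainder; configurations where the planted fractions reach 1 are
rejected naming the metabolite. Intensities are
exp(μ_j + σ_j·latent)·day-factor with per-metabolite location/scale and
a log-normal multiplicative run-day factor (log-SD `runday_scale`,
default 0.15; per-(day, metabolite) factors optional). Genotypes are
simulated at the haplotype level so LD pairs have an exact copy
probability r (r = 1 gives identical dosages). Phenotype marginals
imitate a smoking-enriched COPD cohort (e.g. FEV₁pp ≈ N(76.6, 26.5)
clipped, exacerbations Poisson on a log-linear latent, bronchitis
Bernoulli on a logistic latent); a planted module with per-member effect
e loads its factor on the phenotype latent at e/√ρ, so each member's
correlation with the phenotype latent is exactly e. Outlier subjects are
shifted +6 latent SD on a random 80% of metabolites. Missingness is
uniform (missing completely at random). A fixed seed reproduces every
output bit-identically, and all planted effects are retrievable from the
truth registry, including each QTL's realized latent-scale r².

What the generator does **not** emulate — and what passing tests
therefore do not establish about real cohorts: genome-scale LD structure
(only explicit pairwise LD), informative/intensity-dependent missingness
(real MS dropout is left-censored), non-multiplicative batch effects,
covariate→phenotype confounding paths (phenotype latents depend on
module factors only), population stratification behind the ancestry
PCs, and measurement-platform annotation ambiguity.

## Default simulation sizes in the test and acceptance suites

Oracle-equivalence checks run on 50–60 subjects with a handful of SNPs
and metabolites (exhaustive per-pair regression is the oracle);
parameter-recovery checks use n = 1000–2000 where sampling bounds are
tight; null-calibration suites use 100–200 replicate cohorts at
150–400 subjects; the module-power suite uses 100 replicates of a
20-metabolite, 1000-subject cohort (per-member effect 0.12,
intra-correlation 0.6); the end-to-end run uses 500 subjects ×
200 metabolites × 2000 SNPs. These sizes are the package's validation
design; every rate or bound asserted in `tests/` is computed by the
suite itself at run time.

## Known limitations

- The GGM edge p-value is approximate under shrinkage (see above); the
  pcor threshold dominates in practice.
- The greedy module search is deterministic but path-dependent; it
  matches an exhaustive-subset search on planted 3-member modules in
  simulation, with no optimality guarantee in general.
- Negative-binomial fits can be fragile at small n; the Poisson fallback
  is logged per record via the `converged`/family fields.
- VCF support covers DS-dosage and GT-allele-count records; phased or
  multi-allelic records are out of scope (first ALT only).
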