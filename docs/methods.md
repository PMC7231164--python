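# Methods

## The single-generation selection (SGS) test

**Model.** A panmictic cohort settles into two environments; one episode of
viability selection plus sampling produces two same-generation samples with
allele counts (x₁, n₁) and (x₂, n₂) at a biallelic locus (n in alleles,
i.e. 2 × diploids). Under the null of no selection, both samples are draws
from a common pool frequency p, which is itself uncertain. The null of the
test statistic Δp = |x₁/n₁ − x₂/n₂| is built hierarchically:

1. *frequency layer*: p* ~ Beta(x + a, n − x + b) with (x, n) the pooled
   counts of the two compared samples and (a, b) a prior, flat Beta(1, 1)
   by default. This layer carries the uncertainty in the pool frequency —
   at the resolution the samples provide — which is the finite-size
   component of the variance of Δp.
2. *sampling layer*: x₁* ~ Bin(n₁, p*), x₂* ~ Bin(n₂, p*) independently.

The Monte-Carlo P-value is the add-one estimate
P = (1 + #{Δp* ≥ Δp_obs})/(n_iter + 1), ties counted as extreme, so P > 0
always; the default n_iter is 10,000. Per-locus RNG substreams are derived
from (seed, locus index), making a genome scan independent of locus order
and trivially parallelizable.

Integrating the Beta layer analytically gives the exact joint null
P(x₁*, x₂*) = C(n₁,x₁*) C(n₂,x₂*) B(A+x₁*+x₂*, B+n₁+n₂−x₁*−x₂*) / B(A, B),
a *correlated* beta-binomial (the two counts share p*). `sgs_exact_tail`
enumerates it; the test suite verifies the Monte-Carlo tail against this
enumeration for every count configuration with n₁ = n₂ ≤ 20 alleles, using
exact binomial consistency intervals per configuration (the normal "k SE"
approximation is meaningless in far-tail cells where n_iter·q ≪ 1, and the
maximum of thousands of z-scores exceeds 3 by order statistics alone even
for a perfect implementation).

**Pooling choice.** The null frequency is estimated from the two compared
samples pooled, not from the baseline, so the juvenile-vs-juvenile
comparison is self-contained. The baseline (larval) sample enters only
through descriptive classification: per outlier, whether the baseline
frequency is intermediate between the two group frequencies, and whether a
group frequency falls outside the equal-tailed Beta-posterior credibility
interval (90% by default) of the baseline frequency.

**Deliberate conservativeness.** Δp is discrete (a lattice of
|k₁/n₁ − k₂/n₂|), and a tail-probability P-value of a discrete statistic
with ties counted as extreme is *superuniform*: Pr(P ≤ α) ≤ α at every α.
The deviation from exact uniformity is bounded below by half the largest
probability atom; at 200+200 alleles the atom at Δp = 0 is ≈ 0.04, so the
empirical P-value distribution on neutral data sits detectably above
uniform near P = 1 (a KS test against the uniform on 10⁴ loci rejects, KS
statistic ≈ 0.05–0.07) and the rejection rate at α = 0.05 is ≈ 0.040–0.046
rather than 0.050. A mid-P tie correction roughly halves but does not
remove the deviation. We keep the conservative convention: the test never
over-rejects, which is the property that matters for an outlier scan, and
the suite asserts superuniformity across a range of levels. With unequal
sample sizes (the usual field situation) exact ties are rare and the
conservatism shrinks accordingly.

**Swappability.** The null construction is isolated in `sgs_null_draws`;
an alternative null (e.g. one that models census population size
explicitly, or a different prior) can be substituted without touching the
scan machinery.

## Viability-selection simulator and power

One replicate at (p, s): the standing allele count is drawn
Bin(2N, p) (one generation of drift at N = 10,000 by default), genotype
counts are formed at Hardy–Weinberg proportions, sample 1 (n₁ diploids) is
drawn without selection (multivariate hypergeometric), and sample 2 is
drawn from survivors of viability selection with ω_AA = 1+s, ω_Aa = 1,
ω_aa = 1−s. Survival is independent Bernoulli with probability
ω_g / max(ω) by default; a weighted-sampling-without-replacement scheme is
available behind `survival_scheme="weighted"` since the mechanism is a
modeling choice, not an observable. Power is the rejection fraction at
α = 0.05 over replicates per (p, s) cell, for the SGS test and for the
two-sided Fisher exact test on the allele-count table (one-sided available
via `fisher_alternative`).

Grid-level properties (type-I error at s = 0, monotonicity of power in s)
are asserted on cells pooled over the p grid: with 100–200 replicates per
cell, per-cell comparisons have ~2–5% false-violation probability each and
a grid of 25 pairs would fail by chance in most runs; pooling is the
statistically appropriate aggregate for a property of the true power
function.

## Phenotypes

- **Relative condition factor K**: observed weight divided by the weight
  predicted from the OLS fit of log w on log L over *all* juveniles
  jointly. By construction the geometric mean of K is 1; K is invariant to
  rescaling all weights.
- **Standardized length**: z-score of total length within each
  habitat × sampling-date stratum (growth proxy robust to heterochronous
  sampling). Singleton or zero-variance strata yield NaN with a logged
  warning rather than a silent 0.
- **Interaction ANCOVA** `y ~ group * x` (OLS via statsmodels): reports
  per-group slopes and intercepts, overall R², the model F-test, and the
  interaction F-test computed by comparing the full model against the
  additive one — valid for any number of groups. Constant covariates
  (overall or within a group) raise an error naming the degenerate term.

## Polygenic scores and the threshold sweep

At each locus the allele at higher frequency in group A than group B is
the A-favored allele (ties default to the reference allele with a flag);
the two favored alleles are complementary by construction, so with
complete data score_A + score_B = 2 × (number of loci) exactly. Missing
calls contribute 0 to both scores — no imputation by default, matching the
low-missingness regime the design assumes; with missing data the identity
becomes score_A + score_B = 2 × (loci − missing calls).

The sweep recomputes scores over the outlier sets at a decreasing ladder
of nominal SGS thresholds and fits trait ~ habitat × score at each; the
explained-variance curve typically rises while added loci are mostly true
positives, plateaus once they are captured, and falls as null loci dilute
the score. Because the plateau is flat relative to the sampling error of
the R² estimate, the "peak" reported by the validation study is the
plateau onset (first threshold within 5% of the curve maximum) rather than
the literal argmax.

Per-SNP GWA fits (simple / environment-covariate / interaction OLS models)
report the SNP term for the first two and the interaction term for the
third; the genome-wide threshold divides α by the number of distinct
RAD-tags among tested loci, treating SNPs within a tag as one effective
test. `independent_association` refuses scored individuals that overlap
the discovery sample, preserving the independent-validation logic.

## Survival surfaces

Individuals are placed on the two leading PCs of the outlier loci (calls
mean-imputed, unit-scaled; axis signs fixed so each component's loading sum
is non-negative). For each habitat, a product-Gaussian KDE of the
post-selection sample minus the KDE of the pre-selection (larval) sample on
a shared 100 × 100 lattice gives the relative survival surface z; positive
where genotype combinations were enriched by selection. Bandwidths follow
the per-axis normal reference rule 1.06·min(sd, IQR/1.34)·n^(−1/5) and are
computed from the *pooled* samples and shared between the two densities —
unequal smoothing would masquerade as enrichment. The lattice pads the
pooled range by three bandwidths so each density integrates to 1 within
1% by the trapezoid rule (one-bandwidth padding truncates ~2% of the mass
at the pre-selection sample size of 44) and z integrates to ~0. Scores are
bilinear interpolations of z at individual coordinates; points outside the
lattice are clipped and flagged. The score is a raw density difference —
relative, sign-interpretable, not a probability.

## Synthetic cohorts

`generate_cohort` emulates the study design: a panmictic baseline sample
(default 44), two juvenile samples (default 106 + 106), 5,000 neutral SNPs
plus 20 planted loci. Neutral baseline frequencies are uniform on
(0.05, 0.95); planted loci draw from (0.25, 0.75), since antagonistic
selection acts like balancing selection and maintains intermediate
frequencies. Planted |s| defaults to 0.5 ("moderate, detectable" in this
design); antagonism flips the sign of s between habitats
(conditional neutrality — s = 0 in habitat B — is available, as both
architectures are biologically plausible). Juvenile genotypes at planted
loci are drawn from Hardy–Weinberg proportions reweighted by viability
fitness — the exact infinite-settler-pool limit, which factorizes per locus
for multiplicative fitness across unlinked loci; the finite-N machinery
lives in the simulator module where power is the question.

Traits are environment-dependent linear combinations of the planted
genotypes plus unit Gaussian noise: the genetic value weights each planted
locus by |s|, and the habitat-specific slope is +b in the habitat matching
the score and −b in the other, with b set so the interaction explains a
target fraction of trait variance (condition ≈ 8.7%, growth ≈ 3.9%,
larval growth ≈ 21% — the regime the analysis is designed for). Lengths
and weights are back-transformed (habitat/date-specific length means, a
common cubic length-weight allometry with a multiplicative condition
residual) so that `condition_factor` and `standardized_length` recover the
planted structure. Read depths are Poisson totals with binomial het splits;
biased loci under-read the locus's minor allele, the artifact the
allele-balance filter targets.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: linkage between SNPs (loci are independent;
RAD-tag ids group loci for Bonferroni accounting only), genotyping error
and allele dropout, population structure or kinship, multi-generation
drift, habitat choice, and trait architectures beyond additive-with-G×E.

## Validation study sizes

The studies in `sgskit.benchmarks` (run by the test suite and by
`scripts/acceptance.py`) use: 10,000 neutral loci at 100+100 diploids with
2,000-iteration P-values for calibration; all ~3,300 count configurations
with n₁ = n₂ ≤ 20 alleles at 10⁵ iterations for exactness; a 5 × 6 (p, s)
grid with N = 10,000, n = 100, 200 replicates per cell for power; the
default 5,020-locus cohort for recovery; and 20 cohort seeds of 1,020 loci
for the sweep study — sizes chosen so the whole battery completes in a few
minutes on one CPU while keeping every assertion's Monte-Carlo error well
inside its tolerance.

## Known limitations

- The SGS P-value is conservative (see above); at matched sample sizes the
  rejection rate runs ~10–20% below nominal at α = 0.05.
- The beta-binomial null captures pool-frequency uncertainty at the
  samples' resolution but does not model census size N separately from
  sample size; a cohort much smaller than the sample-implied resolution
  would need the null swapped out.
- Fisher-vs-SGS power comparisons use the same simulated replicates for
  both tests (paired design): cell-level differences are more precise than
  the per-test SEs suggest, but the reported SEs are the marginal ones.
- The survival surface is a density difference, sensitive to bandwidth at
  small baseline n; only its sign and ordering are interpreted, never its
  magnitude.
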