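# Methods

This note documents the statistical model behind each module, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
demonstrate.

## Data model

Genotypes are biallelic dosage codes: 0 = homozygous for the panel's
declared common allele, 1 = heterozygous, 2 = homozygous variant; −1 marks
a missing call. The common allele is part of the panel metadata, not
inferred per file, so the coding is deterministic across inputs (PED/MAP
allele pairs are recoded against it; a file read without a panel falls
back to the file-observed majority allele with an alphabetical tie-break).
Missing genotypes are handled complete-case per analysis: each operation
drops only the subjects missing one of the SNPs it actually uses.
Genomic coordinates are opaque `chrom:pos` labels; no build arithmetic.

A fixed missing-token set (`NA`, `nan`, `.`, empty) maps to missing on
input; any other uninterpretable genotype token is a parse error naming
the file line — readers never coerce silently.

## Single-SNP association

Each inheritance model fixes one exposure orientation (codominant het/hom
vs common homozygote; dominant = common homozygote vs variant carriers;
recessive = variant homozygote vs rest; over-dominant = heterozygote vs
homozygotes; additive = variant vs common allele counts). Published ORs
computed the other way round are reciprocals of these; a single convention
keeps results testable. The additive model is an allele-count 2×2 in the
crude scan and a per-allele-dose logistic term in adjusted fits.

Wald 95% CIs use ln OR ± 1.96·SE with SE = √(1/a+1/b+1/c+1/d). The
Haldane–Anscombe 0.5 correction applies to all four cells, but only when a
zero cell occurs and at least one diagonal product is nonzero; a table
with both diagonal products zero (e.g. an empty exposure margin) has no
meaningful OR and is signalled as degenerate. Fisher p-values are always
computed on uncorrected counts.

The Hardy–Weinberg χ² test is the 1-df Pearson statistic against
expectations from the observed allele frequency; the exact test
enumerates all heterozygote counts conditional on the allele counts and
sums the probabilities of outcomes no more probable than the observed one
(no mid-p). Monomorphic SNPs return p = 1 by convention. The 2×3 genotype
test enumerates all tables with the observed margins (log-gamma
arithmetic, vectorised over the two free cells), two-sided by the same
no-more-probable rule.

Adjusted odds ratios come from `statsmodels` logistic fits of status on
the model-coded genotype term plus covariates; quasi-separation (detected
on the reported genotype coefficient: non-convergence, |β| > 15 or
SE > 100, or a perfect-separation signal from the optimiser) yields a
flagged result with undefined CI rather than a silent fallback. AIC model
selection compares five fits — codominant is a single 2-df fit — with
ties broken in the fixed order codominant, dominant, recessive,
over-dominant, additive. Note a structural property of this family: when
the truth is exactly recessive (or dominant), the codominant model nests
it with one extra parameter, so AIC picks codominant with asymptotic
probability P(χ²₁ > 2) ≈ 0.157; model "recovery" rates above ~84% are not
achievable and the tests assert accordingly.

## Quality control

Defaults: MAF ≥ 1% (all complete calls), HWE in controls at α = 0.05
(deviation in controls flags genotyping artefacts; cases may deviate
through true association), pairwise LD pruning at r² ≤ 0.1 with the later
SNP of an offending pair dropped (panel order, deterministic). LD is the
squared Pearson correlation of dosage codes (composite LD); a monomorphic
SNP makes it undefined and is signalled, not silently skipped. Worth
knowing: the packaged reference counts themselves put rs361525's controls
out of HWE (χ² p = 0.016), so the default filter drops that SNP — the
filter reports, it does not editorialise.

## MDR engine

Cell labelling uses the class-normalised ratio
R = (cell cases / total cases) / (cell controls / total controls), high
iff R > T strictly. T defaults to 1.05; the classic MDR variant (T = 1)
is a parameter away. Cells with cases but no controls are high; cells
never seen in training classify as low risk (conservative; with T ≥ 1 a
zero-information guess can only be "low"). Covariates are invisible to
the engine by design — genotype attributes only.

Cross-validation uses exactly stratified folds: a seeded shuffle within
each class, fold index = position mod n_folds. Per fold the winner is the
combination minimising training classification error (1 − balanced
accuracy), ties to the first combination in lexicographic order; the
reported model per k is the modal fold winner refit on all data with test
metrics averaged over folds, and consistency = folds choosing it. The
overall best model maximises mean test balanced accuracy, ties broken by
higher consistency then smaller k. The permutation p-value is
(r + 1)/(n_perm + 1), never zero.

A caveat on monotonicity: with T = 1 the high/low labelling is exactly
the balanced-accuracy-optimal labelling, so the best training BA is
non-decreasing in k; with T > 1 a refined cell whose ratio falls in
(1, T] loses a positive contribution, and training BA can in principle
dip. The property test therefore runs at T = 1.

## Entropy scores

Plug-in empirical entropies, base 2, no bias correction (matching the
lineage of the original MDR software); all scores are percentages of
H(class), so the base cancels. Pairs use the product genotype space.
Interaction information is computed with all three terms on the same
complete-case subject set, keeping the decomposition exact; on exact
empirical distributions I(AB;C) ≥ max(I(A;C), I(B;C)) and a duplicated
SNP gives IG = −I(A;C) precisely. The dendrogram's dissimilarity
d(A,B) = S_max − S(A,B) with average linkage is a pragmatic choice (the
original software's transform is undocumented): monotone in synergy, so
the strongest interaction merges first at height 0.

## Synthetic cohorts

The generator emulates the reference study's design: 221 cases / 710
controls, five biallelic SNPs, clinical covariates with the published
class-specific summaries. Genotypes are i.i.d. HWE draws per SNP
(no LD, no population structure — deliberately outside scope); disease
is Bernoulli from a k-locus penetrance table; case-control ascertainment
is rejection sampling in batches with a 10⁷-draw cap so degenerate specs
fail loudly. The XOR constructor (risk p_high iff exactly one locus
heterozygous) yields pure epistasis at MAF 0.5: expected prevalence
p_low + ½(p_high − p_low), exactly equal single-locus marginal
penetrances, all signal in the pair.

Covariates: normal variables from mean/SD; right-skewed laboratory values
(glucose, LDL, triglycerides) from a log-normal fitted by least squares
to the three published log-quartiles (an exact two-point fit to the
median plus IQR width leaves one quartile off by more than one unit at
the reference glucose values; the least-squares fit keeps all three
implied quartiles within one unit). Sex is Bernoulli per class. LDL can
also be derived from the lipid panel by the Friedewald (TC − HDL − TG/5)
or DeLong (TC − HDL − 0.16·TG) equations; BMI classes use the half-open
bins <25, [25, 30), ≥30 (the published class edges leave (29.9, 30)
ambiguous; half-open bins make an exhaustive partition).

The marginal resampler permutes, per class and SNP, the exact genotype
multiset given by the reference counts. It is marginal-exact for any
seed, but joint genotype structure across SNPs is independence given
class: the study's true joint distribution was never published. Any
multi-locus quantity on resampled data therefore reflects single-SNP
margins only, which is why the published multi-locus accuracy/OR figures
are validated by construction (oracle equivalence, XOR recovery, null
calibration) rather than by numeric reproduction.

## Validation design and problem sizes

The test suite checks three layers: printed-figure reproduction (nine
crude ORs, four Wald CIs and two allele percentages recompute from the
packaged counts to within one unit in the last printed decimal — the
source's own rounding is off by up to 0.008 in two entries, so exact
match to the printed rounding is not attainable); brute-force oracle
equivalence (MDR search vs a naive dict/loop reference on 20 random
datasets of n ≤ 200, k ≤ 2; entropy scores vs triple-loop tallies to
1e-12 on 30 random tables); and statistical behaviour under known
architectures (XOR recovery with consistency ≥ 8/10 in ≥ 90% of 50
seeded cohorts of 400+400; causal-pair synergy in ≥ 95% of seeds;
permutation p-values uniform by KS over 500 replicates of 199
permutations; null cross-validated balanced accuracy within
[0.45, 0.55] in ≥ 90% of 50 null cohorts of 500+500). Simulation sizes
are chosen so the full suite runs in a few minutes on one CPU while
keeping the binomial noise on each asserted rate well below its margin.

Passing these tests shows the arithmetic is right and the machinery is
calibrated; it does not show that real cohorts satisfy the generator's
assumptions (HWE, no LD, independent covariates, binary phenotype without
misclassification).

## Known limitations

- No covariate-adjusted MDR variants (model-based MDR, GMDR).
- No haplotype, multi-allelic or imputation support; VCF is out of scope.
- Entropy estimates are uncorrected plug-ins; small cells inflate
  apparent information.
- The resampler cannot recover joint genotype structure from marginals;
  conclusions about specific multi-locus combinations in the reference
  panel are emulation, not reproduction.
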