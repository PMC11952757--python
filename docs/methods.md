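# Methods

This note documents the models implemented in `podpop`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not establish.

## Trait model

Pod dehiscence is scored as an ordinal rating 1–5 anchored to open-pod
percentages (1 = 0%, 2 = 12.5%, 3 = 25%, 4 = 37.5%, 5 = 50%; the top
class is open-ended and contributes its 50% floor, a conservative,
deterministic choice).  Averaged ratings are linearly interpolated
between adjacent anchors before the arcsine–square-root transform
Y(x) = sin⁻¹(√x), which stabilizes the variance of a bounded
percentage and is the response used by the association and prediction
models.

Panel screening uses the χ² confidence interval for a population
standard deviation,
√((n−1)s²/χ²_{α/2,n−1}) < σ < √((n−1)s²/χ²_{1−α/2,n−1});
a panel is retained when its own rating s strictly exceeds the pooled
upper limit.  The pooled interval is computed on raw ratings (the
screening step precedes the transform in the workflow).

## Genotype QC and imputation

Panels are inbred lines, so residual heterozygous calls are treated as
genotyping noise and converted to missing before filtering.  The
missingness filter is strict ("exceeding 10%" removes > 0.10, keeps
= 0.10).  The across-panel monomorphic filter removes only SNPs fixed
for the *same* allele in every panel — a SNP fixed for different
alleles in two panels is jointly polymorphic and is exactly the signal
the divergence scan needs.  Filtering precedes the common-SNP
intersection, following the narrative order of the original workflow.

LD-kNN imputation: for each missing call, other SNPs within 10⁷ bp on
the same chromosome are ranked by r² with the target SNP (Pearson on
numeric-coded calls over complete pairs — the published LDKNNi method
ranks by LD without restating the metric); the k = 10 accessions with
the fewest mismatches over the top 30 LD SNPs vote, and the majority
genotype is imputed.  Ties: neighbour ties break by accession input
order, vote ties fall back to the panel-wide major genotype (the
deterministic, major-allele-biased convention of the kNN literature).
The 10⁷ bp default reads the printed parameter "10e6" literally; it is
a configurable argument.  Observed calls are never altered.  Missing
trait values use a plain kNN (k = 5, Euclidean distance on genotype
dose) over accessions with observed ratings.

## Diversity and divergence

Accessions are treated as single sequences (inbred lines).  Per SNP,
pairwise diversity is 2p(1−p)·n/(n−1); genome-wide totals Π and
Θ = S/a₁ (S segregating SNPs) enter Tajima's
D = (Π − Θ)/√(e₁S + e₂S(S−1)) with the standard constants computed
from the sample size.  π and θ are reported per ascertained SNP, not
per base pair, because chip SNPs are an ascertained set.  D is
genome-wide per panel (no windowing): the statistic is used as a
panel-level non-neutrality indicator, not a local scan.

The χ² divergence test exists in two forms.  The relative-frequency
form — cells are the two panels' reference-allele frequencies, expected
value their pooled mean — is the printed formula and is kept as the
operation default; note it is algebraically bounded (χ² ≤ 1, attained
at complete fixation difference, p ≈ 0.317), so it is a descriptive
index, not a calibrated test.  The pipeline (`divergence_table`)
therefore defaults to the count-based contingency form (observed allele
counts vs pooled-frequency expectations, df = 1), which scales with
sample size and yields usable p-values; this is also what
frequency-table software actually computes.  Benjamini–Hochberg
q-values are computed separately within each wild–cultivated pair.

F_ST = s²/(T(1−T)) uses the divisor-2 (population) variance of the two
frequencies, so F_ST(0,1) = 1 and the statistic respects the
0.05/0.15/0.25 differentiation bands.  With an n−1 divisor ("sample
variance" read literally) the statistic would reach 2 and contradict
those bands, so the population-variance reading is used and flagged
here.

A SNP is domestication-related when three criteria hold jointly in at
least one wild–cultivated pair: the cultivated panel's genome-wide
|D| > 2, the pair's q-value is significant (default q < 0.05), and the
pair's F_ST is strictly greater than 0.05.

PCA runs on the 0/1 coding (homozygous major allele = 1, minor = 0),
column-centered only — no variance scaling, matching the stated coding.
Eigenvalues are those of the SNP covariance matrix.  The Evanno ΔK
statistic |L(K+1) − 2L(K) + L(K−1)| / s(K) is computed from supplied
replicate log-likelihoods; the admixture model itself is out of scope,
and ΔK is undefined at the endpoint K values.  Windowed LD reports
squared Pearson r over complete pairs within 30 kb, after per-panel
monomorphic SNPs are removed.

## GWAS

Doses are 0/2 on the major allele (panels carry no heterozygotes after
QC).  The GLM scan is per-SNP least squares with optional covariates
and a two-sided t-test on the dose coefficient.  The mixed model
estimates (σ²_g, σ²_e) once by REML on the null (no-SNP) model through
the eigendecomposition of the kinship matrix, then tests every SNP by
weighted least squares in the rotated space — the
population-parameters-previously-determined shortcut, appropriate at
panel scale where per-SNP REML buys nothing.  The per-SNP reference
distribution is t with OLS residual degrees of freedom, which makes the
mixed model reduce *exactly* to the GLM when the kinship is the
identity (a tested invariant).  REML optimizes the variance ratio on a
bounded log₁₀ grid [−6, 6].

Kinships: IBS proportion rescaled as max(0, 2(IBS − 0.5)), and
VanRaden's ZZ'/(2Σp(1−p)) on centered doses.  For fully inbred panels
the VanRaden diagonal is ≈ 2 (= 1 + F with F = 1); the REML variance
components absorb the scale, so no renormalization is applied.
Significance uses BH q < 0.05 by default (the cutoff is a parameter; no
canonical printed value exists).  A genomic-inflation factor
(median χ²/0.456) is provided as a diagnostic.

Support intervals: the 1.5-LOD interval spans the contiguous run of
SNPs around a peak with LOD ≥ peak − 1.5, with physical bounds at the
first SNPs *outside* the run (the interval must contain the crossing);
at a chromosome end the bound is the run edge.  Genetic coordinates use
the linear 0.44 Mb/cM consensus-map ratio (5 cM ≡ 2.2 Mb); the ratio is
configurable.  Literature RIL QTLs without printed intervals get the
163/(N·R²) cM width.  Colocalization requires the identical SNP id
significant in ≥ 2 panels; single-panel hits survive only when a prior
QTL lies within the 2.2 Mb tight-linkage window on the same chromosome.

## Selection

MAS: at each QTL SNP, accessions split by homozygous genotype and the
allele of the lower-mean-rating group is favorable (ties go to the
major allele — deterministic and the weaker intervention).  Carrier
percentages are tabulated per integer rating group (averaged ratings
round to the nearest group); empty groups are undefined rather than
zero.  Selection efficiency = (mean favorable % in rating-1 group +
mean unfavorable % in the top observed rating group)/2/100; the top
group defaults to the largest rating actually observed, handling panels
whose worst class is 4.  The panel statistic equals the mean of the
per-SNP statistics by construction — an algebraic identity the tests
assert.

gBLUP: y = 1μ + u + e with u ~ (0, K σ²_u), REML via the
eigendecomposition of K.  GBV = σ²_u K P y and
PEV = diag(σ²_u K − σ²_u K P K σ²_u), with P the projection form of
V⁻¹ absorbing the fixed intercept — PEV therefore accounts for
estimating μ.  "K-fold cross-validation with replacement" is
implemented as bootstrap fold assignment (each accession's fold label
drawn independently per repetition), with classical partitioned folds
behind `mode="partition"`; repetitions yielding a fold of fewer than 3
held-out accessions (or a constant held-out trait) are redrawn and
logged.  Variance components are estimated once on the full data and
reused across folds — at panel scale the components are stable and this
keeps a 1,000-repetition protocol tractable; predictions for held-out
accessions use only training phenotypes through
σ²_u K[test,train] V_train⁻¹ (y_train − ȳ_train).

## Synthetic data generator

The generator emulates the observed study structure: one wild panel
strongly differentiated from several mutually similar cultivated
panels, ~20 chromosomes of biallelic SNPs, a 1–5 ordinal trait driven
by a handful of QTLs at high heritability, sparse missingness and rare
heterozygotes.  Defaults: ancestral allele frequencies uniform on
[0.05, 0.95] (ascertained-chip spectrum, which also reproduces the
strongly positive Tajima's D regime of cultivated panels);
sweeps at 5% of SNPs displace the shared cultivated frequency by 0.8
toward fixation (clipped to [0,1]), giving wild–cultivated F_ST around
0.3–0.5 at swept SNPs, the substantial-differentiation regime; each
cultivated panel perturbs the shared post-sweep vector by Gaussian
noise (sd 0.02), keeping between-cultivated F_ST at the few-percent
level; heritability defaults to 0.8, inside the 0.62–0.97 broad-sense
range reported for the trait; missingness 2% and heterozygosity 1% are
realistic chip-panel levels.  Genotypes are homozygous draws from the
panel frequency (inbred lines), with a uniformly chosen `het_rate`
fraction of calls relabeled heterozygous so the het→missing QC step has
work to do.  The trait is a liability threshold model: standardized
breeding value × √h² plus Gaussian noise × √(1−h²), cut at fixed
thresholds (−0.8, −0.25, 0.25, 0.8) chosen to populate all five rating
classes; one value per accession (the source data are per-accession
averages; year and replicate effects are not modelled).

What the generator does **not** emulate: linkage disequilibrium between
neutral SNPs (sites are drawn independently given the frequency
vector), recombination maps, coalescent ancestry, genotype–environment
interaction, and maturity-group structure.  Consequently, passing tests
demonstrate the correctness and calibration of the statistics under
the intended signal structure — not LD-aware fine-mapping resolution on
real panels, where support intervals and imputation behave differently.
LD-dependent operations are validated on purpose-built blocks
(duplicated columns give r² = 1) rather than on the genome-wide panels.

## Problem sizes and numerics

Validation runs use panels of 150–500 accessions and 500–2,000 SNPs,
sizes at which every statistic is exercised in its intended regime
(type-I calibration uses 10,000 permuted tests; power and recovery use
20 replicates) while the full suite stays desk-scale.  Degenerate
inputs are handled explicitly: fully missing SNPs stay missing with a
warning; constant traits are an error for scans and a zero-variance
short-circuit for gBLUP; collinear SNPs get p = 1 with a warning;
χ² and F_ST return 0 when the pooled frequency is 0 or 1; ΔK with zero
replicate SD is an error.  All stochastic components accept explicit
seeds and are bitwise reproducible.
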