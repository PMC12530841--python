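# Methods

## Trait model

Traits are integer-graded observations on accessions. Qualitative traits
carry fixed code sets; quantitative traits are graded from replicate
measurements by the LSD method: a one-way ANOVA of value on accession gives
MSE and df<sub>error</sub>, LSD<sub>α</sub> = t(1−α/2, df)·√(2·MSE/r) with r
the harmonic-mean replicate count, and the class width is the smallest width
exceeding 2·LSD that still spans the observed range within the requested odd
number of classes. Boundaries are laid out so the grand mean is the midpoint
of the middle class; intervals are half-open [b, b′) with unbounded extreme
classes, so grading is total on the reals. A panel with zero variance
degenerates to a single class with LSD 0.

Descriptive statistics use the population (divide-by-n) SD. This convention
is pinned by a binary-trait identity: for class counts (a, b),
SD² = ab/(a+b)², which reproduces the reference row mean 0.97 / SD 0.16 /
CV 16.51% exactly, whereas the n−1 convention gives CV 16.59%. CV of a
zero-mean trait is reported missing rather than infinite. H′ is computed on
class frequencies (graded codes), is 0 for monomorphic traits and at most
ln k for k observed classes, and is invariant to relabeling codes. Pairwise
trait correlations are Pearson on graded codes with two-sided t-test
p-values, pairwise-complete over missing cells; zero-variance traits are
excluded with a warning.

## Core-trait selection

PCA is an eigendecomposition of the trait correlation matrix after dropping
invariant traits and standardizing (missing codes mean-imputed, i.e. zero
after centering). Component scores are standardized to unit variance and the
sign convention fixes each loading vector's largest-magnitude entry positive,
making F reproducible across eigensolvers. Retention follows the Kaiser rule
(λ > 1, minimum one). The composite score weights each retained component's
score by its eigenvalue share; weights sum to 1 and F is therefore invariant
to accession ordering and to rescaling any input trait.

Stepwise selection is forward OLS of F on the traits significantly
correlated with F, with coefficient-level entry/removal tests (defaults
0.05/0.10, the common statistical-package convention; equal thresholds are
rejected to prevent cycling). Entry ties break by larger |r| with F, then
trait order. Because F is by construction an exact linear combination of all
analyzed traits, the full model has R² = 1; the interesting behaviour is
which traits enter first and where the entry test stops.

## SSR model

Genotypes are unordered diploid allele pairs keyed by fragment size in bp,
taken as already-binned integers; a single detected peak is stored as
homozygous, and missing is per-cell. Frequencies are counted over the 2N
copies of typed individuals. The per-locus estimators are the classical
frequency sums (see README); PIC uses the identity
Σ<sub>i&lt;j</sub> 2pᵢ²pⱼ² = (Σp²)² − Σp⁴, and a brute-force enumeration
oracle verifies all of them to 1e-12 in the tests. He uses the unbiased
small-sample correction 2N·h/(2N−1) — the convention is pinned by the
printed estimate pairs at N = 113 (h 0.7886 → He 0.7921; 0.7592 → 0.7626).
Useful orderings hold on polymorphic loci: PIC < h < He, Ne ≤ Na,
I ≥ ln Ne.

HWE is a plain chi-square goodness-of-fit over all a(a+1)/2 genotype classes
with df = a(a−1)/2 and no rare-class pooling (no pooling procedure is
specified in the workflows this mirrors); a seeded Monte-Carlo p-value
(re-pairing permuted allele copies) is available for sparse tables.
Monomorphic subsets return a not-testable result (df 0).

## Distances, trees, duplicates

The default individual-level distance is allele sharing:
GD(x, y) = 1 − (1/L)·Σ(shared copies)/2 over jointly typed loci (pairwise
deletion), so GD ∈ [0, 1] and GD = 0 exactly at multilocus genotype
identity — which makes the duplicate criterion (connected components at
GD ≤ 0) provably equivalent to genotype-string matching, an equivalence the
tests assert. Nei's (1972) standard distance per individual-as-population is
offered as an alternative but is infinite for pairs sharing no alleles and
is documented as exploratory.

UPGMA is implemented directly: average linkage, node height = half the
between-cluster mean distance (hence ultrametric trees), and a fixed
deterministic tie-break (lexicographically smallest pair of minimum leaf
labels; children ordered by minimum leaf label). scipy's average-linkage
heights serve as an independent cross-check in the tests. Fixed-k cuts
remove the k−1 highest merges; tied heights fall back to the nearest
attainable k with a warning, and clusters are numbered by decreasing size.
PCoA is Gower double-centering of −D²/2 with negative eigenvalues clipped to
zero under a warning (allele-sharing GD is not guaranteed Euclidean);
scikit-bio's implementation is the test oracle.

Homonym detection deliberately takes an explicit accession→name map rather
than fuzzy string matching: a name group with ≥ 2 members and maximum
pairwise GD > 0 is flagged.

## AMOVA

The three-level allele-level layout (among groups, among individuals within
groups, within individuals) is identified by its df column
(g−1, N−g, N; total 2N−1). With the allele-mismatch metric, every sum of
squares reduces to allele counts via SS = (m² − Σc²)/(2m) for a set of m
copies, which equals the mean pairwise squared distance formulation — the
tests verify this against explicit pair enumeration. Components follow
nested-ANOVA expectations with n₀ = (N − Σnᵢ²/N)/(g−1); negative estimates
truncate at zero before percentages (the convention of the standard
codominant-AMOVA software), which makes the null distribution of Φ_ST
slightly positive — at the simulated panel sizes the null mean stays below
0.01. Φ_ST is the among-group share of total variance; a seeded permutation
test shuffles whole individuals. On Balding–Nichols panels the estimator
recovers the generator F (0.2 ± 0.03 in mean over 20 seeds at n = 200,
19 loci). Gene flow uses the island-model identity Nm = (1 − F)/(4F),
defined only on 0 < F < 1.

## Admixture model

The Gibbs sampler implements the classic admixture model for unlinked
codominant loci with uncorrelated allele frequencies (symmetric Dirichlet
λ = 1): allele-frequency update, per-copy origin update, Dirichlet(α + counts)
membership update, and a random-walk Metropolis step (step 0.025, reflecting)
for a single shared α on a uniform(0, 10) prior. The no-admixture variant
samples one hard cluster per individual from its marginal likelihood.
Missing genotypes are uninformative: their copies are assigned from the
prior membership alone and excluded from allele counts. ln P(X|K) is the
harmonic-style estimator mean(lnL) − var(lnL)/2 over post-burn-in sweeps,
with lnL = log P(X | P, Q). Runs are bit-reproducible given a seed;
replicate seeds in a K sweep are spawned from one master seed.

ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(L(K)) is defined at interior K with ≥ 2
replicates and nonzero sd; zero sd raises rather than returning infinity.
Replicate Q matrices are aligned to the first run by the column permutation
maximizing summed columnwise dot products (exhaustive for K ≤ 8, greedy
beyond), then averaged.

Default sampler settings in the pipeline config mirror the reference
workflow (burn-in 100,000, 200,000 recorded sweeps, K 1–10, 10 replicates).
Tests and examples run reduced settings — the ΔK-recovery experiment uses
burn-in 2,000 / 8,000 sweeps on 90 individuals × 10 loci over K 1–5 with 2
replicates — chosen as the smallest scale at which the planted K = 3 is
recovered in ≥ 8/10 sweeps.

## Synthetic data

The genotype generator is Balding–Nichols: per-locus ancestral frequencies
p ~ Dirichlet(1) over 4–15 alleles (di-nucleotide size ladder), group
frequencies ~ Dirichlet(p(1−F)/F) so E[F_ST] = F, individuals drawn as two
independent copies (HWE within groups — the tests confirm a ~5% rejection
rate). Clones are bit-identical copies under new ids (groups of configurable
sizes); homonyms are distinct genotypes assigned a shared variety name;
missing cells are masked at a configurable rate. All randomness derives from
one seed via SeedSequence spawning, so sub-streams are independently
reproducible. Realized allele counts can fall below the configured maximum
when rare alleles fail to be sampled; the tests therefore bound Na by the
configured maximum only.

The study-scale fixture is one call producing 113 accessions × 19 loci with
five groups sized (75, 27, 6, 3, 2) at F = 0.32 (matching the reference
panel's differentiation), nine clone groups totalling 28 members
(19 redundant, 94 distinct) and three homonym groups, plus a 50-trait table
with 10 invariant traits — the end-to-end pipeline input for the integration
tests.

The trait generator plants a low-rank structure built for identifiability of
its 14-trait core: 14 latent factors share a common axis (pairwise
correlation 0.3, the way real trait complexes co-vary) and carry gently
declining scales (1.2 → 0.85) so the eigen-spectrum is ordered rather than
degenerate; each core trait tracks one factor (residual sd 0.1); each
non-core variable trait mixes two cyclically assigned factors (magnitude
~0.8, residual 0.5), keeping every factor supported and the idiosyncratic
noise bulk below the Kaiser threshold. Quantitative traits are observed as
30 noisy replicates (sd 0.3; five field replicates of six plants) and graded
through the LSD machinery, so tests exercise the real grading path.

A sample-size caveat, found while designing this generator: at the reference
panel size (n = 113, 40 analyzed traits) sample-eigenvalue spreading leaves
only ~12 components above λ = 1, so two to three planted factors are
excluded from F regardless of the generative design and their core traits
cannot be recovered by any F-based screen (~9–10/14 recovered). The
core-recovery experiment therefore simulates n = 400 accessions, where
retention is near-complete and mean recovery is ≥ 12/14 over 10 seeds. The
practical implication for real panels of ~100 accessions is that
Kaiser-retained PCA composites under-represent weak trait complexes, and a
core set screened this way should be read as covering the dominant axes of
variation only.

What the simulations do not emulate: genotyping error, null alleles and
stutter, linkage between loci, polyploidy (the diploid two-peak scoring
convention is assumed), environment-by-genotype interaction in traits, and
non-normal trait distributions. Passing the planted-truth tests therefore
demonstrates correctness of the estimators and selection machinery under the
stated models, not robustness to these real-data complications.

## Numerical conventions

Grading intervals are half-open with unbounded extremes; CV of zero-mean
traits is missing; eigenvalues are clipped at 0 and zero-variance components
get zero scores; UPGMA ties and cluster numbering are deterministic as
above; Q-matrix rows renormalize exactly to 1; chi-square p-values come from
the upper tail; permutation p-values use the add-one estimator
(1 + hits)/(1 + B). Newick branch lengths serialize at 12 significant
digits, which round-trips topology and heights to 1e-9.

## Pipeline

`run_pipeline` executes trait statistics → core selection → morphological
clustering → locus summaries → HWE → distances/UPGMA/PCoA →
duplicates/homonyms → AMOVA → admixture sweep, with per-stage switches, and
writes plain-text tables plus a manifest of parameters, seeds and SHA-256
content hashes. Outputs are a pure function of (inputs, config, seed);
re-runs are hash-identical, which the integration tests assert. The
`cross_tabulate` helper builds the morphological-vs-genetic correspondence
table.
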