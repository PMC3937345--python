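# Methods

## Data model and conventions

Samples are rows and variables/features are columns in every table. Files are
tab-separated UTF-8 with one header row, no quoting and `NA` as the only
missing marker; emitted files sort rows by sample id and columns
lexicographically, so write∘read is the identity (labels exact, values to the
last bit — the readers use a correctly-rounded float parser). Abundance
matrices carry an explicit normalization state (`raw_counts`,
`genome_equivalent_normalized`, `proportions`) and refuse state-inconsistent
operations; in the proportions state rows must sum to 1 within 1e-9.

Samples with missing environmental values are kept and flagged at read time;
they are dropped, with a warning, only when an RCCA is fitted. No imputation
is attempted.

## Genome-equivalent normalization

GE = total base pairs / average genome size estimates the number of genomes
sampled. Dividing each sample's counts by its GE removes the coupling between
read yield and community genome size, making per-genome abundances comparable
across samples of different depth and genome-size composition. Normalization
commutes with closing the data to proportions (proportions are GE-invariant),
which the tests assert.

## Profile construction

* **Size-fraction merging** sums raw counts across filter fractions sharing a
  (station, depth) key, *before* normalization — one defensible order of
  operations, applied consistently.
* **Taxonomic collapsing** sums taxa over their ancestor at a chosen rank.
  Taxa absent from the lineage table, or unannotated at that rank, pool into
  an explicit `unclassified` column rather than being dropped, so count
  conservation is exact on integers; optional top-k grouping pools the
  remainder into `Other` the same way.
* **Module profiling** maps a KO matrix through a KO→module membership table.
  Module abundance is the **mean** over member KOs (absent KOs count 0). The
  mean removes module-size bias relative to the sum; because it is a fixed
  linear map, every downstream correlation statement is unaffected by the
  choice up to per-module scaling, and the aggregation is trivially swappable.
* **Taxon stratification** filters the joint (sample, taxon, KO, count)
  annotation table to taxa whose lineage contains a given label (the label
  `root` keeps everything), sums to a KO matrix over all samples, then
  profiles modules. Strata empty in ≥ half the samples warn; strata empty
  everywhere are an error.

## RCCA

Within-set correlation matrices are shrunk as R + λI on the correlation
scale, which keeps λ unit-free; the eigenproblem is solved on the smaller
side for stability, eigenvalues are clipped to [0, 1] (values below −1e-8
raise), and λ = 0 is refused with a singular within-set matrix — in
particular whenever variables outnumber samples, the expected regime for
module matrices. Reported canonical correlations are the *empirical* Pearson
correlations of the paired variates (under regularization these can differ
slightly from the eigenvalue square roots); variates are ordered by that
empirical correlation.

Signs in CCA are arbitrary, so each weight/variate pair is flipped to make
the largest-magnitude environmental weight positive (ties to the lowest
index), making repeated fits bit-identical.

Regularization is selected on a 7×7 grid
{0, 1e-4, 1e-3, 1e-2, 0.1, 0.5, 1}² by leave-one-out cross-validation: fit on
n−1 samples (standardizing with training statistics only), project the
held-out sample onto the first weight pair, and score the Pearson correlation
of the n held-out projection pairs. Failed fits (λ=0, singular) and
degenerate projections score −1; ties break toward the smallest (λx, λy)
lexicographically. The per-fold correlation matrices do not depend on λ and
are computed once, which keeps the 49-pair × n-fold search fast (~0.2 s at
n=21, q=12).

Structure correlations (variable vs variate) are the biplot coordinates.
Variance explained by the first d variates is the mean over variables of the
summed squared structure correlations. A variable is dimmed when its first
two squared structure correlations sum to strictly less than radius² (default
0.5² = 25%); a point exactly on the inner circle stays shown.

## Group comparison

Welch's t-test (scipy's unequal-variance t-test supplies the statistic,
Welch–Satterthwaite df and p-value), a 95% CI as diff ± t₀.₉₇₅,df·SE, and
Bonferroni correction with m = number of categories tested. A category with
zero variance in both groups and equal means yields t=0, p=1; zero variance
with unequal means is degenerate and raises. The brackish/marine split
helper labels samples below a salinity threshold (default 10 PSU) as group A;
it is a labelling convenience, not inference.

## Synthetic gradient generator

The generator emulates a ~21-sample limnic-to-marine transect (0–35 PSU,
equal spacing plus jitter sd 0.5):

* **Covariates.** Temperature rises (0.25 °C/PSU, noise sd 1.5) and oxygen
  falls weakly (0.06 per PSU, noise sd 1.0) with salinity; the N:P ratio,
  chlorophyll a (log scale) and total P are driven by a latent standard-normal
  axis independent of salinity; pH is noise around 7.9. Coefficients were
  chosen once to give a clearly detectable but not deterministic
  oxygen–salinity relation (population r ≈ −0.5) and a distinct second
  environmental axis.
* **Taxa.** 24 taxa with Gaussian salinity niches (optima spread over 0–35
  PSU, breadths 4–7 PSU, equal baselines) and genome sizes from 1.2 Mbp
  (streamlined pelagic) to 5.2 Mbp; three cyanobacteria-like taxa additionally
  load (coefficient 0.8) on the latent axis, read back through the observable
  standardized N:P column so that community generation needs only (spec, env,
  seed). Twenty-four abundant taxa is a realistic count for gradient-scale
  profiles at genus-like resolution while keeping every niche segment
  populated.
* **Counts.** Per-sample relative abundances are Dirichlet around the niche
  weights (concentration 50 — overdispersed enough that recovery is
  nontrivial); reads are multinomial (depth 50 000) with sampling probability
  proportional to abundance × genome size. That genome-size bias is exactly
  what GE normalization must undo: GE = Σ_t count_t·g_t / mean(g).
* **Function.** Four analogous-pathway pairs (NDH/NQR, MK/UQ, EMP/ED,
  MEP/MVA, real KEGG module ids) plus four housekeeping modules carried by
  all taxa. Each taxon carries exactly one member per pair, the marine member
  with probability logistic((μ − 10 PSU)·0.5); carriage is fixed per taxon
  within a run and redrawn across seeds. Every read of a carrier taxon is
  annotated to each member KO (two synthetic KOs per module), so module
  counts are sums over carrier taxa and conservation is exact on integers.
  The planted expected signs (fresh −, marine +, housekeeping 0) depend only
  on the parameterization, not the seed.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes — niche-driven
compositional turnover, covariate collinearity, genome-size-biased sampling,
overdispersed counts, pathway trade-offs with planted signs. It does not
simulate read sequences, annotation error, viral or eukaryotic compartments,
within-taxon strain variation, or spatial autocorrelation between stations;
passing recovery tests therefore demonstrates correctness of the pipeline's
statistics under its own assumptions, not robustness to annotation noise in
real data.

### A note on the no-link null

Setting the carriage logistic slope to 0 removes the pathway–salinity link
*in expectation*: every taxon picks the marine member with probability ½
regardless of niche. Each finite draw over 24 taxa is nevertheless
niche-imbalanced by chance, and because module abundances are sums over
carrier taxa while the taxa themselves turn over with salinity, module
matrices retain genuine, phylogenetically confounded salinity structure that
RCCA correctly detects (median |cor(salinity, feature variate 1)| ≈ 0.9
across seeds). This is the familiar phylogeny–function interlinkage of real
communities, inherent to any community-based simulation with finitely many
taxa; the corresponding acceptance test documents the behaviour and currently
fails by design of the generator rather than by defect of the fit.

## Problem sizes and numerics

Default test and acceptance runs use 100 simulated transects for the recovery
and null studies (~20 s each), 1000 replicates for Welch type-I calibration
and 200 for power; these sizes give Monte-Carlo error well inside the asserted
bands. Tolerances: exact equality for integer conservation and byte-level
reproducibility; 1e-12 for closed forms; 1e-8 against the classical-CCA
reference (whiten + SVD, an independent code path used only in tests).
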