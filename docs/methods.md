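# Methods

This note records the models, conventions, parameter choices and known
limitations of `hybridscape`, in the order the pipeline runs.

## Forward admixture simulator

**Model.** Diploid Wright–Fisher population of constant size N, formed at
generation 0 from two parental species: each founder is a pure parent-1
diploid with probability p0, else pure parent-2. Each subsequent generation:
(1) relative fitness from the selection model; (2) each offspring draws two
parents (independently, so selfing is possible) with probability
proportional to fitness; (3) meiosis: the number of crossovers per gamete
and chromosome is Poisson in the genetic map length, positions are placed
uniformly on the genetic map (no interference) and converted to basepairs
through the map; (4) migration: each offspring is replaced by a pure
parent-1 (parent-2) individual with probability m1 (m2). Mitochondria are
inherited from the first-drawn parent and replaced on migration.

**Founding generation.** Fitness is *not* applied when the first offspring
generation is sampled: hybridization happens first, selection acts on hybrid
genotypes from the F1s onward. With selection applied to the founders
themselves, a strongly selected locus (s near 1) removes every pure
minor-parent founder before any admixed genotype exists, so no minor
ancestry would ever enter the population — a degenerate reading of
"hybridization followed by selection".

**Selection models.**
- *directional*: multiplicative fitness 1, 1−s/2, 1−s per minor-ancestry
  dosage at each selected locus (additive within a locus, multiplicative
  across loci);
- *dmi_pairs*: two-locus incompatibility between parent-1 ancestry at locus
  1 and parent-2 ancestry at locus 2; with dosages d1, d2 the number of
  incompatible pairings is d1·d2 (0–4) and fitness is multiplied by
  1 − s·(d1·d2/4)^h. Dominance h is configurable (default 1, codominant)
  because the incompatibility's dominance is genuinely uncertain;
- *mitonuclear*: the directional penalty at the nuclear locus, applied only
  to individuals carrying the mismatched (major-parent) mitochondrion.

Selection coefficients may be drawn from an exponential distribution
(`s_mean`), the regime used for strong-selection experiments; draws are
capped at s = 1.

**Coordinates.** Tracts are 0-based half-open [start, end); marker
positions are 1-based, so the site at position p lies in the tract whose
half-open interval contains p−1. All BED output is 0-based half-open.

**Junction accumulation.** Because founders are pure diploids, the first
round of meioses creates no ancestry junctions; the neutral junction density
approaches 2·p0·(1−p0)·t per Morgan only as t grows. The test suite checks
the simulator against an independent marker-matrix Wright–Fisher Monte
Carlo run under identical founding conditions.

**What the generator does and does not emulate.** It produces
multi-chromosome diploid hybrids with recombination, drift, migration and
selection, and exact (error-free) posterior tracks; `inject_call_errors`
adds symmetric state-flip errors. It does not model sequencing depth,
marker ascertainment, reference bias, sex, age structure, or mutation —
so passing tests demonstrate the statistical machinery under the stated
population model, not robustness to every artifact of real data.

## Hard calls, filters, windows

A state is hard-called when its posterior is ≥ 0.9 (the threshold itself
qualifies); otherwise the site is masked. Site filters (each independently
switchable): coverage < 25% of individuals; at most one marker per 240 bp
(the first marker of a run is kept — the choice of representative is
deterministic and arbitrary); 1 Mb chromosome-end exclusion; repeat-mask
overlap; windows whose marker count falls in the lower 5% tail of the
genome-wide distribution (low power to infer ancestry). Ancestry-informative
sites require a ≥ 98% parental frequency difference, excluding sites
confidently called homozygous in F1s.

Window means pool all non-missing (individual, site) hard calls —
mean(dosage)/2 — rather than averaging per-individual means; with balanced
coverage the two differ negligibly, and pooling keeps empty-individual
handling trivial. Genetic-distance windows have equal cM spans obtained by
inverting the cumulative map; trailing partial windows are kept and
flagged. Thinning keeps the first window per 1 Mb or 1.5 cM block, with
blocks laid out in genome coordinates so missing windows do not shift them.
The minor parent is determined per population as the source with the lower
genome-wide mean ancestry.

## Correlation statistics

Spearman correlations use midranks and the t-approximation (the exact
permutation p is available by resampling if needed). The partial Spearman
rank-transforms all variables, residualizes x and y on the covariates by
least squares, and correlates residuals; for one covariate this equals the
recursive partial-correlation formula. A variable fully explained by the
covariates gets partial correlation 0. Cross-population correlations join
two window tables on their common frame, drop missing windows pairwise,
thin, then correlate.

The region depletion test probes a 50 kb window at each candidate region's
center and compares the mean ancestry against resampled probe sets, either
genome-wide or restricted to the lowest-5% recombination stratum — the
stratified null asks whether candidate regions (e.g. inversions) are more
depleted than *any* low-recombination region. Empirical p-values use the
add-one rule throughout.

The Hardy–Weinberg incompatibility expectation is p², the fraction of
offspring homozygous for minor ancestry at a locus whose homozygous state is
incompatible on a fixed mismatched mitochondrial background; it is computed
per locus.

## Wavelet-scale decomposition

Ancestry is linearly interpolated per individual onto a uniform grid (bin
centers, 1 kb and 32 kb supported) and averaged across individuals.
Recombination values are winsorized at ρ = 0.005 rather than dropped —
capping preserves the grid; a drop flag is available.

The transform is the orthonormal decimated Haar DWT on the maximal dyadic
prefix of each chromosome. With prefix length n, the wavelet variance at
level j is Σd²/n, so variances sum exactly to the population variance of
the prefix (Parseval; tested to 1e-9). Scale labels are grid_step·2^(j−1):
level j measures contrasts between adjacent blocks of 2^(j−1) grid points.
Per-scale correlations are uncentered correlations of detail coefficients
(details are contrasts, so centering is a no-op in expectation); scales with
zero variance are masked, never imputed as zero. The contribution of scale j
to the overall Pearson correlation is corr_j·√(varA_j·varB_j)/√(varA·varB)
with detail products pooled across chromosomes; the "chrom" component
carries the covariance of per-chromosome means and the "scl" component is
the remainder from non-dyadic tails (exactly zero on power-of-two
chromosomes). Contributions sum to the overall Pearson correlation by
construction.

Uncertainty comes from a weighted delete-one-chromosome jackknife with
weights proportional to coefficient counts; with equal weights it reduces to
the textbook jackknife. Whether the original analyses used a decimated or
maximal-overlap DWT is not knowable from the description; all checks here
are internal-consistency based and do not depend on that choice.

## Ancestry deserts and islands

Detection is seeded at sites whose mean minor (for deserts) or major (for
islands) ancestry falls in the lower 5% tail of the site-level genome-wide
distribution, confirmed in the covering 0.05 cM window against the 10% tail
of the window-level distribution, and expanded window-by-window until a
window exceeds the 10% tail. The 5% seed quantile is computed over sites
and the 10% expansion quantile over window means (the reference
distribution for the expansion tail was an open choice; both are exposed).
Quantiles are per population. Implementation note: the per-seed expansion
equals "maximal runs of tail windows containing at least one seed window",
which is what the code computes; the test suite verifies equivalence
against a literal per-seed bidirectional scan.

Same-kind regions within 50 kb are merged transitively, then filtered
(≥ 10 AIMs, ≥ 10 recombination-map SNPs, ≥ 10 kb). Sharing is ≥ 1 bp
overlap of half-open intervals. Two nulls: (1) naive — shuffle window
ancestry (with each window's site-level aggregates) genome-wide in both
populations and rerun the whole chain, 1000 permutations by default;
(2) shift — circularly rotate one population's window labels by multiples
of 12.5 cM in genetic coordinates (wrapping across chromosome boundaries;
per-chromosome rotation is available) and count overlaps with the other
population's fixed regions, preserving local autocorrelation. Time trends
of outlier regions are OLS of region ancestry on sampling year with
optional Benjamini–Hochberg adjustment.

## Ancestry transitions

A transition interval runs from the last site confidently supporting the
old diploid state to the first site confidently supporting the new state;
a dosage jump of 2 with no intermediate heterozygous site is one
transition. Transitions flanked by a confident same-state segment shorter
than 5 kb are removed (switch-and-revert artifacts); the first and last
segments of a track are treated as supported, since their true extent is
censored by the track boundary. Intervals longer than 250 kb are excluded
from sharing analyses as poorly resolved. The indicator matrix for
ordination bins transition midpoints into 0.5 cM windows (midpoints are
used only for the matrix; full intervals are used for overlap counting).
The placement null redraws each transition's location with probability
proportional to the genetic length of 100 kb windows (ancestry-fixed
windows excluded), start uniform within the window, length preserved
exactly — intervals that would overhang a chromosome are shifted left to
fit, which preserves lengths at a slight cost in boundary uniformity.

## Mismatch statistic

Within supplied shared-ancestry tracts, the statistic for a pair of
individuals is (# sites where one is homozygous reference and the other
homozygous alternate) / (# sites passing quality in both). Heterozygous
sites count in the denominator only; missing or quality-failed sites count
in neither. Variant-quality decisions are taken upstream; the module
consumes a per-site pass flag.

## ABC demographic inference

Priors: p0 ~ U(0.5, 1); N ~ U(2, 10000); t ~ U(10, 400) generations; m1,
m2 log-uniform on [1e-6, 0.03] per generation (a log-uniform prior cannot
start at zero; 1e-6 sits well below the smallest migration rate data of
this kind can resolve). The reference simulation is one 25 Mb chromosome;
summary statistics are the sample admixture proportion, the CV of
genome-wide ancestry across individuals, the CV of local ancestry across
100 kb-window means, and the median minor-parent tract length (the phrase
"genome-wide and local ancestry variation" is disambiguated this way).

Fitting standardizes statistics by the median absolute deviation, accepts
the ⌈tolerance·n⌉ nearest rows by Euclidean distance (tolerance 0.005),
and applies Epanechnikov-weighted local-linear regression of each parameter
on the statistics; adjusted draws are the fit at the observed point plus
residuals, truncated to the prior support. Migration rates are regressed on
the log scale, matching their prior geometry. With too few accepted rows
the fit falls back to pure rejection with a warning. The MAP is the mode of
a Silverman-bandwidth Gaussian KDE on a 512-point grid over the prior
support, with a multimodality flag. Coverage self-validation re-fits held
out table rows and reports how often truths fall in the central 95%/50%
intervals; population size is expected to be weakly identified.

Desk-scale runs cap the simulated N (default tables use a few hundred
simulations with N ≤ 100–200); the prior draw is still recorded and used
for inference. The full 150,000-row table is available through the same
interface.

## Desk-scale calibration experiments

`hybridscape.calibration` fixes the paired-population study conditions:
two 25 Mb chromosomes with a uniform 1 cM/Mb map (map points every 10 kb),
N = 1000, population A with initial minor ancestry 0.24 and 137 generations
of admixture, population B with 0.12 and 263 generations, migration rates
of order 1e-4 (the inferred values), samples of 69 and 242 individuals,
ancestry-informative markers every 10 kb, and a shared selected locus at
the center of chromosome 1. Power is the fraction of replicate pairs in
which that locus falls inside a detected shared desert; the neutral
experiment runs the identical pipeline with no selection. These sizes are
the package's desk-scale defaults: large enough for stable quantile
thresholds, small enough that a hundred replicate pairs run in minutes.

## Known limitations

- Genome-wide strong selection (s ~ Exp(0.5) at many loci) cannot run for
  a century of generations on a ~100 Mb genome without purging minor
  ancestry entirely — on a small genome every site is within a few cM of a
  selected locus. The strong-selection correlation experiments therefore
  use a short post-hybridization horizon; on full-size genomes the same
  architecture leaves segregating ancestry far from selected sites.
- The simulator's tract lists assume markers are error-free projections of
  tracts; real ancestry HMM output has autocorrelated, coverage-dependent
  errors that the symmetric error injector only approximates.
- The shift permutation treats the genome as a single genetic-coordinate
  circle by default; with few chromosomes the number of non-overlapping
  tilings is small and p-value resolution is correspondingly coarse.
- Detection quantiles are estimated from the analyzed data themselves; on
  very small genomes (few hundred windows) threshold noise contributes to
  replicate-to-replicate power variation.
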