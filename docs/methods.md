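# Methods

## The allele-sharing (matching) framework

Every F-statistic in this package derives from pairwise *matching
proportions*.  For two diploid individuals with alt-allele dosages
`x_i, x_j ∈ {0,1,2}` at a site, the probability that one allele drawn from
each matches is

    m_ij = (x_i·x_j + (2−x_i)(2−x_j)) / 4

and the matching matrix entry `M_ij` is the mean of `m_ij` over the sites
where both genotypes are called (a ratio of sums, unbiased under
missing-at-random).  An individual's self-matching `M_ii` is 1 at a
homozygous site and 0 at a heterozygous one, averaged over its called
sites.  Every coefficient is then of the form `(M − M̄_B)/(1 − M̄_B)` for
an appropriate baseline `M̄_B`:

- **β relatedness** — baseline is the mean matching over all distinct pairs
  in the analysed panel, so β averages to zero over pairs by construction.
- **Group-specific FST** (the "island-specific" FST of the scans) —
  `M_within` averages over all unordered pairs of distinct target
  individuals, *including* cross-population pairs inside the target group
  (the island group is treated as one unit); `M_between` averages over
  target × reference pairs; the statistic is
  `(M_within − M_between)/(1 − M_between)`.  It asks whether the target
  individuals resemble one another more than they resemble the reference —
  a moment estimator that needs no independence assumption among
  populations and isolates the signal in the target group, which is what
  makes it usable when the contrast groups are internally structured.
- **Pairwise FST** — `M_w` is the unweighted mean of the two
  within-population averages, `M_b` the cross-population average.
- **F_IT / F_IS** — self-matching against the panel-wide (resp.
  within-population) pair baseline; **overall FST** contrasts mean
  within-population pair matching with the mean between-population
  matching.

Pairs are weighted equally when group means are formed (matching is
averaged per pair over sites first, then over pairs), provided each pair
reaches `min_snps` usable sites.  A between-baseline of exactly 1 leaves
the coefficient undefined; it is reported missing with a warning.

Under a Balding–Nichols model in which each population's allele frequency
is Beta-distributed around a shared ancestral frequency with drift
parameter `F`, the pairwise estimator's expectation is `F` exactly (the
site-level numerator and denominator are both proportional to
`p̄(1−p̄)`), which is what the parameter-recovery checks exploit.

## Windowed scans

Windows are 100 kb with 20-kb steps per scaffold, starting at 0; trailing
partial windows are not emitted.  Per window the matching matrix is rebuilt
from the window's SNPs and the configured contrasts evaluated on it.
Nucleotide diversity uses the unbiased per-site form
`π = Σ 2p(1−p)·n/(n−1) / L` and absolute divergence
`d_xy = Σ [p_A(1−p_B) + p_B(1−p_A)] / L`, with `L` the window length in bp:
the input is a genome-wide SNP table, so unlisted positions count as
invariant.  Windows with fewer than `min_snps = 10` SNPs keep their row but
carry missing statistics and are excluded from threshold estimation (the
cut controls the variance of per-window estimates; the value is a package
default).

Blocked LD summarises the squared Pearson correlation of dosages
(pairwise-complete, no imputation — missingness is capped at 5% upstream)
between non-overlapping blocks of 100 consecutive SNPs per scaffold, after
excluding SNPs at or below 5% minor-allele frequency *within the analysed
group* (strictly-greater-than rule).  Within-block entries average distinct
pairs only; a final partial block is flagged.

## Peak calling

The outlier threshold is `mean + 5·SD` of the focal statistic over all
non-missing windows genome-wide (sample SD, n−1), computed once per run —
not per scaffold.  Five sigma corresponds to a one-sided standard-normal
tail of ≈2.87×10⁻⁷, i.e. about one random window in 3.5 million.  Windows
strictly above the threshold are chained into clusters wherever their
genomic spans overlap (with 20-kb steps and 100-kb windows, consecutive
above-threshold windows always chain); clusters with at least two
supporting windows become regions spanning the union of their windows.
Strict inequalities are used throughout: a tie at a mean+5SD boundary is
measure-zero, and strictness reads naturally as "higher than".

The dual-criteria mode, used for the east-vs-west contrast, additionally
requires a population-specific statistic to exceed its genome-wide 99th
quantile (linear interpolation between order statistics, so results are
bit-reproducible).  A gene is assigned to a region on ≥1 bp of half-open
overlap — containment is not required — and gene lists are deduplicated in
position order.

## Genotype input

VCF reading keeps biallelic SNP records only, drops configured scaffolds
(e.g. sex-linked super-scaffolds), converts GT to alt-dosage (phase
discarded — nothing downstream uses it) and `./.` to missing.  The
missingness filter keeps sites with strictly less than 5% missing
genotypes.  The exact Hardy–Weinberg test uses Levene's conditional
distribution of the heterozygote count given the allele counts; the
p-value sums the probabilities of outcomes no more probable than the
observed one.  It is applied to all samples pooled (the neutral-structure
dataset of the study design is filtered this way; the selection scans can
run on either set via a flag).  LD pruning follows the plink
`--indep-pairwise 50 10 0.1` greedy scheme, removing the later-positioned
SNP of any offending pair — deterministic and order-stable.

Coordinates are 0-based half-open internally; VCF and GFF3 are converted
on read, BED is written natively, and TSV reports keep what the column
documents.

## OMI niche analysis

Environmental variables are standardized to weighted mean 0 / variance 1
under the site weights (uniform by default; exposed for raster-cell area
weighting), after dropping later variables perfectly correlated with an
earlier one.  A species' niche centroid is the occurrence-weighted mean of
the standardized site rows; its OMI (marginality) is the squared length of
that centroid — the squared distance between the conditions the species
uses and the average conditions available.  Each species' inertia
decomposes exactly as `inertia = OMI + Tol + Rtol`, where Tol is the
occurrence-weighted variance of the species' site scores along its own
marginality direction (niche breadth) and Rtol the remaining within-niche
inertia.  Ordination axes are eigenvectors of the species-weighted
cross-product of the centroid matrix; per-axis percentages are eigenvalue
shares, and axis signs are fixed by making the largest-magnitude loading
positive.  A seeded permutation test (999 random reassignments of site
rows) is available but off by default.

## Diversity summaries

Observed heterozygosity is the per-individual fraction of called sites
that are heterozygous.  An allele is private to a population when at least
one non-missing genotype carries it there and none does elsewhere (missing
genotypes carry no evidence).  Rarefaction draws `g = 9` individuals per
population without replacement (Monte-Carlo, seeded; an exhaustive
enumeration mode exists for small panels) and recounts; populations may be
merged first via a mapping on the sample sheet (the study design merges
the two smallest mainland populations).  Note that because *all*
populations are subsampled, the rarefied count can exceed the raw count —
subsampling the other populations unmasks alleles as private.

## The synthetic-data generator

The generator produces data with exactly the structure the analyses
assume, so every stage is testable end to end without external downloads.

**Neutral background.**  Per SNP, an ancestral frequency
`p̄ ~ Uniform(0.05, 0.95)` (bounded away from 0/1 because the real input
is a SNP set) and per-population frequencies
`p_pop ~ Beta(p̄(1−F)/F, (1−p̄)(1−F)/F)`; genotypes are
`Binomial(2, p_pop)` per individual.  Sites are unlinked: LD exists only
where a sweep is planted, making the LD contrast a clean signature.
Defaults mirror the study conditions — populations EC 10, WC 9, MA 3,
PT 9, IS 9 (the mainland trio stresses the small-group code paths), drift
F of 0.10/0.09/0.05/0.05/0.07 giving genome-wide differentiation of order
0.05–0.10, and 30,000 SNPs over ten 5-Mb scaffolds (≈60 SNPs per 100-kb
window, enough for stable window statistics at desk scale).

**Planted sweep.**  One 1-Mb region in which a single haplotype is carried
by the island group at frequency 0.97.  Exactly `round(f·2N)` of the
group's 2N chromosomes are replaced by the swept haplotype, assigned to
individuals by a seeded shuffle.  Enforcing the realized frequency (rather
than drawing per-individual copy numbers binomially) is deliberate: at
N=19 a binomial draw fixes the haplotype outright in about a third of
replicates, which would erase the residual within-region variation — and
with it the region-wide LD — that the fixture exists to provide.  The
per-individual copy number is shared across the region's SNPs, which
produces the joint signature: elevated island-specific FST, reduced island
π, reduced EC–WC d_xy, and elevated LD among islanders but not
mainlanders.  Because swept sites sit near 3% island MAF, the LD signature
is *measured* with the MAF filter disabled in the validation runs; the
descriptive pipeline keeps the >5% cut.

**East-west fixture.**  Two 1-Mb regions on the neutral background, one
swept in EC only and one in WC only.  Each spans ≈2% of scan windows, so
each island's 99th-quantile F threshold lands inside its own swept
windows, far above the mild elevation the other island's sweep induces
(a single shared haplotype makes the between-population matching term
coherently noisy in that region).  At desk scale — a few thousand windows
rather than half a million — this is what keeps the two region lists
cleanly separated; with a full-size genome the quantile would instead sit
deep in the neutral tail, below the peak values.

**Niche data.**  300 sites × 13 standard-normal variables (matching the
13 bioclim variables of the study design).  The specialist samples sites
with probability ∝ exp(z·offset), offset +2 on a temperature-like variable
and −2 on a precipitation-like one (a hot-arid displacement, one dominant
axis); the generalist samples uniformly.  Record counts are 73 and 79.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: linkage and recombination-rate variation
outside planted regions, genotyping error and depth-dependent missingness,
shared drift/admixture between populations (populations are conditionally
independent given the ancestral frequency), and selection regimes other
than a hard shared haplotype.  Parameter-recovery and recovery-rate
results are statements about this generative model at the stated sizes.

## Validation problem sizes and determinism

Oracle-equivalence checks run on toy inputs against brute-force
enumeration (allele-pairing enumeration for matching, exact combinatorial
HWE probabilities, site-by-site π/d_xy sums, exhaustive rarefaction, dense
eigen-decomposition for OMI) at 1e-9.  Parameter recovery uses two
populations of 10 at 20,000 SNPs (±0.02 on F; |FST| < 0.01 for the
panmictic limit).  Planted-sweep recovery runs the full default
configuration; the null false-positive sweep uses 100 seeded replicates of
a reduced null genome (4 × 2 Mb contigs, 8,000 SNPs, ≈370 windows) and
requires zero called regions in ≥99% of them.  All randomness flows
through `numpy.random.default_rng` seeded from configuration; identical
configurations give byte-identical VCF/TSV output.

## Known limitations

- `FST^ILvsML` is computed as the pooled-group pairwise matching FST; the
  study pipeline obtained its equivalent from an external script whose
  estimator family is not named.  The statistic is descriptive only here
  (the island-specific FST is the scan statistic of record).
- The HWE filter is dataset-wide; on strongly structured data it removes
  sites for structure, not genotyping error (a per-population option
  exists but is off by default).
- Window statistics assume the SNP table is genome-wide complete after
  upstream filtering; regions where many sites were filtered out will have
  π/d_xy biased downward, as with any SNP-only input.
- The niche permutation test permutes site rows jointly for all species;
  species-specific habitat availability constraints are not modelled.
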