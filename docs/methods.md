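# Methods

This note documents the models, decision rules, and numerical choices
behind `zwscout`, and what the bundled simulator does and does not emulate.

## Coverage-based sex linkage

**Model.** Under ZW heterogamety the per-copy sequencing depth is shared
across the genome, so expected depth is proportional to copy number:
autosomes 2:2 (male:female), Z 2:1, W 0:1. After normalizing each sample by
its median window coverage (≈ the diploid autosomal level, since autosomes
dominate the genome) and averaging windows within each sex, the
male:female ratio *R* per scaffold has expectation ≈ 1, 2, and ≪ 1 for
autosome, Z, and W.

**Procedure.** Depth is tallied in nonoverlapping 500 bp windows (BED
coordinates, 0-based half-open). Window values are per-base means (window
sum ÷ window length) so the partial terminal window of each scaffold stays
comparable; partial windows are flagged and excluded from dispersion
statistics but kept in the means. Normalization divides each sample's
window values by that sample's median over *all* its windows; afterwards
every sample's median is exactly 1, and all downstream results are
invariant to rescaling any single sample's raw counts. Summaries default to
unweighted window averages; a length-weighted variant (equivalent to one
whole-scaffold tally divided by scaffold length) is available and differs
only at partial windows.

**Classification.** The field practice is to read scaffolds off a ratio
plot against the theoretical autosome and Z lines; `zwscout` replaces that
with an explicit, testable rule on log2 *R*: autosome if |log2 *R*| ≤ 0.35,
Z if |log2 *R* − 1| ≤ 0.35, W if log2 *R* ≤ −1, otherwise ambiguous. The
half-width 0.35 makes the autosome and Z intervals disjoint with a
symmetric dead zone between them; the W cutoff (−1, i.e. at least twofold
female excess) is deliberately loose because the W ratio depends on how
much repeat-driven cross-mapping male coverage it collects. Scaffolds with
fewer than 10 windows, or with normalized mean coverage below 0.1 in the
informative sex, are labeled ambiguous with the reason recorded; the W is
exempt from the male-side floor because near-zero male coverage *is* its
signature. These thresholds are package choices, not published values.

**Pseudocount and ratio bias.** The reported ratio is
(*m̄* + ε)/(*f̄* + ε) with ε = 0.01 on the normalized scale, keeping W
ratios finite when male coverage is ~0. Two small deterministic effects
pull the Z's reported ratio below 2: the pseudocount (×(1+ε)/(0.5+ε)/2 ≈
0.99), and the Z's own windows (present at single copy in females)
depressing the female median slightly — noticeable here because the
simulated Z is ~10% of the desk-scale genome, a couple of percent at
realistic genome sizes. Both means are therefore reported raw as well
(`mf_ratio_raw` and the per-sex means), and quantitative checks of the
twofold expectation use the plain ratio of mean window counts; the
pseudocounted ratio is the classification statistic. For XY systems the
same machinery applies with the ratio interpretation mirrored.

## Synteny blocks and karyotype events

Anchors (query position → reference chromosome, position, strand) are
sorted per query scaffold and chained greedily: a block is a maximal run
with a single reference chromosome, successive query gaps ≤ 1 Mb, and
reference positions monotone in either direction. Runs shorter than 3
anchors are dropped as noise — this also absorbs short local inversions,
which are irrelevant to fusion counting; longer inversions simply become
separate blocks of the same chromosome pair. Full-row lexicographic
sorting before chaining makes the output invariant to input row order.

A fusion is called on a query scaffold whose blocks cover ≥ 2 reference
chromosomes with ≥ 3 anchors each (support counts anchors, not blocks); a
fission on a reference chromosome hosted on ≥ 2 query scaffolds at the
same per-query support. Breakpoints are reported as the interval between
flanking blocks, never a point. Chromosome arithmetic is degree-weighted:
each event of *m* members changes the count by *m* − 1, which reduces to
counting events in the usual all-pairwise case (31 − 3 = 28 for the
default three-fusion simulation).

Defaults (3 anchors minimum, 1 Mb gap) are tuned to the simulator's scale
and anchor density (~300/Mb); with real aligner output both should be
scaled to the observed anchor density.

## Sex-differential k-mers

K-mers are counted canonically (a k-mer and its reverse complement merge
under the lexicographically smaller form; k odd so no k-mer is its own
reverse complement), packed 2 bits/base into 64-bit integers, k ≤ 31.
For each k-mer with ≥ 10 combined counts, the female count out of the
total is tested two-sided against the exact binomial null p₀ =
female_lib/(male_lib + female_lib); p-values are BH-corrected over all
tested k-mers. A call is *female-enriched* when q ≤ 0.05 **and** the
library-size-scaled rate ratio (pseudocount 0.5 on both counts, applied to
the ratio only, never the test) is ≥ 4. The exact test is computed
vectorized over the distinct (female, total) pairs, grouped by total; the
implementation is cross-checked against `scipy.stats.binomtest` in the
test suite.

**Repeat families.** Significant k-mers are clustered single-linkage on
shared (k−1)-mers (either orientation) into unitig-like families with a
greedy consensus path. Family candidacy is additionally restricted to
high-abundance k-mers — by default female count ≥ 2× the coverage-peak
depth of the k-mer histogram — because repeat families are by definition
multi-copy, and because on a female-limited chromosome *every* k-mer is
female-specific: without the abundance floor, single-copy W background
chains the planted families into one giant component through the k-mers at
repeat boundaries. This enrichment + abundance + overlap-clustering
pipeline is a deliberately simplified, fully specified stand-in for
graph-based comparative read clustering (RepeatExplorer-class tools); it
tests the same claim — female-enriched repeat families exist and are
recoverable — without the heavy machinery. Recovered families legitimately
include a few "margin" k-mers reaching one base into the flanking
sequence when the same flank base recurs across copies.

**Genome size.** From the histogram (depth → number of distinct k-mers):
the error threshold is the first depth at which the histogram stops
decreasing (separating the low-depth error peak); the coverage peak is the
modal depth above it, refined by a ±2-bin centroid because for a
near-Poisson histogram adjacent bins can be equiprobable and the raw
argmax is then a coin flip worth ~3% of the estimate. Size =
Σ_{d>threshold} d·hist[d] ÷ peak depth. A monotone histogram (no coverage
peak) is an error advising deeper coverage.

## The simulator

The generator emulates the statistical structure of a chromosome-level ZW
assembly with resequencing data, not its sequence realism:

* **Karyotype.** 31 ancestral chromosomes (ancZ + 30 autosomes) merged by
  a fusion plan; the default plan fuses ancZ with a ~100 kb autosome
  (producing a neo-Z with annotated ancestral/neo segments) plus two
  autosome–autosome fusions, yielding 27 autosomes + Z, named chr1..chr28
  by decreasing size with the Z first, plus an assembled W fragment
  (chr29) covering 10% of the full W — mirroring an assembly in which the
  W is only fractionally represented (~1/10 of the Z-sized W).
* **Scale.** Desk scale: ancestral autosomes 40–80 kb (rounded to 1 kb),
  Z = 150 + 100 kb, W fragment 25 kb, ~2 Mb total. All structural ratios
  of interest (Z largest; W fragment ≈ Z/10; ≥ 10 windows per scaffold;
  ~300 anchors/Mb) are preserved while the full test suite, including the
  replicate-based property checks (100-seed fusion robustness, 50-seed
  family recovery, 20-seed null FDR), runs in minutes on one CPU.
* **Depth.** Window-level Poisson counts with mean = mean_depth (default
  30 per haploid copy) × copy number × window-length fraction; no
  read-level simulation, since the downstream statistic consumes window
  counts. W windows are cross-mapping hotspots with probability 0.1, in
  which case male samples collect a full mean_depth of stray reads —
  hotspots are a window property shared across males, reproducing the
  characteristic high window-to-window ratio variance of the W with one
  interpretable parameter (expected male W coverage = rate × depth).
* **K-mer pools.** Per-sex counts are Poisson(depth × copy-weighted
  genomic multiplicity) per distinct canonical k-mer over the assembled
  scaffolds; sequencing errors inject singleton random k-mers at rate
  k × 0.001 per counted k-mer instance. Two 500 bp repeat families are
  planted at 10 copies each on the W, so their k-mers are female-specific
  at ~10× single-copy abundance.
* **Anchors.** Poisson counts per scaffold (~300/Mb) at uniform positions,
  labeled with the true ancestral chromosome and collinear reference
  positions (one random orientation per segment); a configurable fraction
  (default 2%) is relabeled to a random wrong chromosome. The W, having no
  ancestral composition, emits no anchors.
* **Not modeled:** read-level artifacts (GC bias, mapping quality, indels),
  TE sequence evolution and real cross-mapping homology (replaced by the
  hotspot parameter), Hi-C/assembly-graph structure, heterozygosity.
  Passing tests therefore demonstrate correct inference under the stated
  statistical model, not robustness to alignment pathology in real data.

Sequences are i.i.d. uniform nucleotides apart from planted repeats —
only k-mer uniqueness matters downstream. Everything is a deterministic
function of the configuration seed, with independent per-stage RNG
streams, so byte-identical reruns are guaranteed and exercised in tests.

## Degenerate inputs and tie-breaks

Empty anchor sets yield empty block/event lists (not errors); unsorted
anchor input is sorted internally; event ordering and member sets are
lexicographic, so outputs are permutation-invariant. Samples with zero
median coverage, sexes with zero samples, windows larger than the shortest
scaffold, mismatched k between pools, even k, and fusion plans naming
unknown or overlapping chromosomes raise errors naming the offender.
`n_autosomes` in the simulator configuration is derived from the ancestral
count and fusion plan (27 under defaults); an explicit value is validated
against the derived one. Setting the assembled W fraction to 0 disables
the W entirely (the null genome used for FDR checks).

## Known limitations

* The coverage classifier assumes a single sequencing technology and no
  systematic sex-specific library bias; strong GC or PCR bias would need
  an additional correction step upstream.
* Fusion detection counts chromosome-composition changes only; it does not
  catalogue inversions or translocations, and a reciprocal translocation
  would surface as a fusion + fission pair.
* The k-mer stand-in nominates repeat families; it does not classify them
  (no LTR/DNA-transposon typing) and does not estimate heterozygosity from
  the spectrum.
* Genome-size estimation assumes a visible unimodal coverage peak above
  the error peak; highly heterozygous or contaminated libraries violate
  this.
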