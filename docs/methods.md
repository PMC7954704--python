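# Methods

## The signal

Strand-seq sequences only the template DNA strand of each homologous
chromosome in a single cell.  For a given cell and chromosome, each of the
two homologs contributed either its Watson (minus) or its Crick (plus)
template strand, independently and uniformly at random, so reads from that
chromosome map in one of three strand states: WW, WC or CC, in expected
proportions 1:2:1 across cells.  Two consequences drive everything in this
package:

1. **Co-clustering.**  All contigs from the same chromosome show the *same*
   strand state in any one cell; contigs from different chromosomes agree
   only at the chance level (3/8 per cell).  A few dozen cells therefore
   suffice to group de novo contigs by chromosome without a reference.
2. **Chromosome-length phase.**  In a WC cell, every Watson read comes from
   one homolog and every Crick read from the other, regardless of distance.
   Heterozygous SNVs observed in WC regions are thus phased relative to one
   another across the whole chromosome.

Sister chromatid exchanges (SCEs) flip the template strand downstream of a
random position in single cells.  They are rare, cell-private events; a
strand-state change recurring at the same position in many cells is instead
the signature of a misassembled contig.  Because nearby contigs are
separated by an SCE in fewer cells than distant ones, the fraction of cells
in which two contigs disagree is a proxy for their physical distance and is
used for ordering.

## Synthetic data generator (`simdata`)

The generator emulates a diploid genome and every input of the workflow,
with complete truth tables.

* **Genome**: per-chromosome random sequence; heterozygous biallelic SNVs
  are Bernoulli per bp (default density 1e-3/bp, the order of magnitude of
  a human genome's ~2.5 M het SNVs scaled to tens of Mbp); H1/H2 differ at
  exactly the SNV positions.  Default study genome: 5 chromosomes x 10 Mbp.
* **Contigs**: each chromosome is tiled without gaps; piece lengths are
  Uniform(0.6, 1.4) x target N50 (default 800 kbp, giving ~60 contigs all
  >= 100 kbp); orientation per contig is uniform.  Injected errors are
  recorded in truth: a *chimera* concatenates contigs of two chromosomes, a
  *misorientation* reverse-complements an internal interval.  Injected flip
  intervals are kept between 600 kbp and 45 % of the contig: intervals well
  under the 200-kbp analysis bin are invisible by construction, and a
  flipped majority would make the minority frame look canonical.
* **Strand-seq**: per cell, per chromosome, per homolog a template strand
  is drawn uniformly; SCE counts are Poisson(rate/2) per homolog (rate is
  per chromosome, default 0.2/chromosome/cell — a free parameter, not a
  published value) with uniform positions; read direction follows the
  template of the originating homolog, flipped on minus-strand contig
  segments; a `background` fraction of reads (default 0.05; the study runs
  use 0.1) gets a uniformly random direction.  Reads are 100 bp, mapq 60,
  base quality 30 by default; covered SNVs report the homolog's allele,
  flipped with probability `allele_error`.  Re-supplying the truth
  templates and SCE tables replays the same cell inheritance on a corrected
  contig set, emulating realignment.
* **Long reads** are allele observations at covered SNV sites (exponential
  lengths, mean 15 kbp; exactly half of the reads from each haplotype).
  Base-level sequences are never needed downstream of variant calling, so
  they are not materialized.

What the generator does **not** model: base-calling errors and chimeric
reads, GC/mappability bias, library-preparation artifacts, lineage
structure between cells, inversions and other true SVs.  Passing tests
therefore demonstrate the correctness and statistical behaviour of the
algorithms under the inheritance model, not robustness to every artifact of
real libraries.

## Strand-state genotyping (`strandstate`)

Reads with mapping quality < 10 or a duplicate flag are discarded.  Counts
are taken in fixed 200-kbp bins (a terminal bin shorter than 50 kbp is
merged into its predecessor — it cannot be genotyped on its own); a
"dynamic" mode bins by a fixed number of mappable positions, approximated
as distinct read-start positions, for uneven coverage.  With n = W + C >=
50 reads and Watson fraction f = W/n, the hard call is WW if f >= 1 - 2b,
CC if f <= 2b, WC if |f - 0.5| <= 0.15, else unknown (b = background,
default 0.1; the bands are this package's concretization of a symmetric
background-noise tolerance).  SCE breakpoints are emitted between
consecutive 500-kbp windows with different called states and refined to
read resolution by maximizing the two-segment binomial likelihood over all
split points.

WC (haplotype-informative) regions merge runs of WC windows; runs separated
by less than 5 Mbp of *uncalled* windows are joined, but an intervening
confident WW/CC window always terminates the region — at 10-Mbp synthetic
chromosome scale, joining across a definite opposite state (a double-SCE
stretch) would mix homolog assignments within one region.  Regions shorter
than 5 Mbp are dropped.

## Clustering contigs into chromosomes (`saarclust`)

**Model.**  Cluster k has, per cell j, a latent state distribution
theta_kj over {WW, WC, CC}.  The Watson count of bin i in cell j is
Binomial(n_ij, p) with p = 1 - eps (WW), 0.5 (WC), eps (CC); eps (default
0.05) absorbs symmetric background.  Each bin carries a latent orientation;
a minus-oriented bin observes the state flipped WW <-> CC.  EM alternates a
responsibilities step over (cluster, orientation) pairs and closed-form
updates of theta and the mixing weights; the log-likelihood is checked to
be non-decreasing every iteration.  Initialization is k-means++ on per-bin
Watson-fraction vectors with a fixed seed; ties break to the lowest contig
id; everything is deterministic given the seed.  K defaults to 30 for the
synthetic study genome (the number of initial clusters only needs to
comfortably exceed the chromosome count; human-scale runs of this kind of
model use 100-150).

**Merging.**  Per-cell hard states (argmax theta) of two clusters are
compared under both relative frames (direct, and WW<->CC flipped); clusters
agreeing in >= 70 % of cells are connected and merged by connected
components, with frame parity tracked through the union-find.  The 0.7
default reflects two facts measured on the generator: SCEs genuinely
decorrelate distant parts of one chromosome (15-25 % of cells at 0.2
SCE/chromosome/cell), while distinct chromosomes agree at the ~3/8 chance
baseline; 0.9 would leave one chromosome split across components.  When a
desired cluster count is given (one per expected chromosome), only the
top components by mixing mass are reported; small residual components are
overfit fragments, and their bins are reassigned by a posterior restricted
to the surviving clusters.

**Filtering.**  Contigs shorter than 100 kbp are dropped before analysis.
Contig-level posteriors are length-weighted geometric means of bin
posteriors over *merged* components; a contig whose runner-up posterior
reaches 0.25 is discarded as ambiguous.  (Ambiguity is assessed after
merging: before merging, one chromosome is legitimately represented by
several initial clusters, which splits posteriors without any genuine
ambiguity.)  Contigs genotyped WC in more than 80 % of informative cells
are discarded as haplotype-uninformative: an ordinary contig is WC in ~50 %
of cells by the inheritance model, a hemizygous or both-homolog artifact in
~100 %, so a threshold at 50 % would discard a coin-flip half of the good
contigs.

**Orientation and order.**  Within each merged cluster, contigs are split
into two groups by average-linkage hierarchical clustering on the pairwise
directionality-disagreement distance (fraction of WW/CC-informative cells
with opposite states); if the groups truly oppose each other (mean
inter-group distance > 0.5), the group with the smaller total length is
flipped.  The coinheritance distance D[a, b] — the fraction of informative
cells in which a and b differ — feeds an open-path traveling-salesman
ordering (nearest-neighbour construction from every start plus 2-opt; a
`greedy` mode stops after chaining).  An all-zero distance matrix (no SCEs)
returns the input order with a low-confidence flag.

**Misassembly detection and correction.**  Chimeras appear as contiguous
bin blocks of one contig assigned to different merged components;
misoriented intervals as bin runs whose orientation posterior opposes the
contig consensus within one component block, corroborated by WW<->CC
switches at the run boundaries in >= 25 % of WW/CC-informative cells (the
biological expectation at a true misorientation boundary is ~100 % of such
cells, against ~0 % at an SCE, which is private to one cell).  Bins
straddling the true breakpoint are mixtures and are absorbed into a
neighbouring block before calling; the within-contig orientation consensus
prefers the hypothesis that yields a single internal run over two end-runs,
since an inverted internal interval is the error mode being modelled.
Breakpoints are refined to read resolution by pooling cells whose states
disagree across the boundary (Crick-state cells flipped) and maximizing the
binomial split score; corrections (splitting at chimera breakpoints,
reverse-complementing flip intervals) therefore leave no bin-scale residue,
and re-clustering corrected contigs reports zero errors.

## Phasing (`strandphase`)

Within each cluster scaffold, allele observations (base quality >= 20,
mapping quality >= 10) from reads inside a cell's WC regions populate one
Watson row and one Crick row per (cell, region).  Rows are per region, not
per cell: after an SCE pair, the Watson template of two WC regions in the
same cell can belong to *different* homologs, and pooling them provably
injects switch errors even on error-free data.  Conflicting duplicate
observations at one (row, site) resolve by majority, ties to missing.

The iterative assignment is pinned exactly so results are reproducible:
initialize H1 from the row with the most observations and H2 from its
partner row (complemented where missing); for two iterations, assign each
row pair to (H1, H2) or (H2, H1) by mismatch count (ties keep the previous
assignment), then rebuild the consensus per site by majority (partner
strands vote the complement; ties stay unphased).  H1 is canonicalized to
carry the reference allele at the first phased site.

The sparse strand backbone is densified with long reads: each read is
assigned to a haplotype by majority agreement at backbone sites (strict
ties unassigned), and a backbone-unphased site becomes phased when >= 2
assigned reads cover it, each non-empty haplotype read set is >= 80 %
unanimous, and the two sets (when both present) vote opposite alleles; when
only one haplotype's reads cover a biallelic het site the other allele is
the complement.  Backbone sites are never flipped, so the phased fraction
is monotone.  This densifier is a deliberately transparent majority-vote
step; it does not implement the weighted minimum-error-correction model of
full long-read phasers, and in particular it cannot repair backbone sites
that were phased from a single noisy observation.  At background 0.1 with
per-site strand coverage of ~1-2 observations this leaves a visible
backbone error rate (reported, not asserted, by the acceptance script);
with clean input the recovery is exact, and with >= 10 observations per
site a 1 % allele error rate yields < 0.5 % Hamming error.

## Haplotagging (`haplotag`)

A read votes at every phased site it covers; tag = argmax of the two
agreement counts; strict ties (including zero informative sites) stay
untagged.  No base-quality weighting: the simplest deterministic rule is
pinned (a weighted mode could sit behind the same interface).  Splitting
partitions reads exactly into {h1, h2, untagged}; the `-un` sets duplicate
untagged reads into both haplotype bins, matching the haploid-assembly
strategy of the workflow; per-cluster splitting optionally discards reads
from other clusters.

## Evaluation statistics (`evaluate`)

* **Switch error / Hamming.**  Only sites phased in both callsets are
  compared.  Per chromosome, the haplotype pairing minimizing the Hamming
  distance is chosen once and reused for the switch count.  Each haplotype
  is recoded over neighbouring SNV pairs (0 = same allele, 1 = different);
  the switch rate divides string differences by the number of compared SNVs
  per haplotype (pinned here; note that a per-pair denominator is the other
  common convention).  Rates are returned as fractions.
* **QV** = -10 log10(1 - identity/100) with identity =
  100 * matches / (matches + mismatches + indel bases); an N-bp indel is N
  errors; perfect identity reports an infinite (capped) QV.
* **N50**: largest L such that contigs >= L hold half the total length.
* **LOH.**  Heterozygosity fraction in 200-kbp windows sliding by 10 kbp;
  binarized at the 25th quantile (strictly below -> 0, otherwise 1 — the
  tie at the quantile keeps the non-LOH value, a fixed deterministic rule);
  self-contained binary segmentation minimizing within-segment variance
  with minimum segment length 200 windows and a split-gain penalty of
  2 ln(n); segments with median binarized value <= 0.05 are
  LOH.  Windows with no variants score 0, so variant deserts genotype as
  LOH — with assembly-based callsets every window contains calls.
* **Collapses**: maximal runs with coverage > mean + 3 SD (length-weighted
  moments) and length >= 15 kbp; runs > 75 % covered by the repeat/TR
  annotation are excluded.
* **Common breaks**: contigs < 100 kbp are dropped; each inter-contig gap
  contributes a breakpoint at its midpoint; a common break is a 500-kbp bin
  holding breakpoints from every assembly, reported as [first, last]
  breakpoint and annotated with features within 10 kbp.
* **SD resolution**: an SD is resolved at extension X when one alignment
  spans it with >= X bp beyond both flanks (a single-flank mode exists);
  the percentage is averaged over X in {10, 20, 30, 40, 50} kbp.

## Pipeline and experiment sizes

`pipeline.run_pipeline` wires simulate -> count -> cluster (EM, merge,
orient, order) -> optional error detection -> phase -> haplotag ->
evaluate, entirely in memory, with one seed feeding every stage; the same
configuration and seed reproduce the report exactly.  The default study
conditions are 5 chromosomes x 10 Mbp, ~60 contigs, 120 libraries of
10,000 100-bp reads (2 % of the genome per cell, typical of real Strand-seq
libraries), background 0.1 and 0.2
SCE/chromosome/cell; a full run takes about half a minute on one core.
The downsampling experiment re-runs the pipeline on uniform cell subsets.
The noise-free phasing conditions set background, allele error and SCE rate
to zero: SCEs are biology rather than noise, but at 500-kbp window
resolution a strand switch inside a WC-called transition window leaks a
handful of wrong-homolog singleton observations (~0.1-0.3 % of sites),
which is a property of window-resolution region export rather than of the
phasing algorithm, so the exactness check isolates the latter.

`scripts/acceptance.py --seed N --out FILE` re-runs the study-scale
scaffolding, noise-free phasing, misassembly-detection/correction and 40 %
downsampling experiments from scratch and writes their headline numbers as
JSON.

## Known limitations

* The EM emission model assumes symmetric background noise and a single
  ploidy of two everywhere; aneuploid or hemizygous regions surface only
  through the always-WC filter.
* Contig order within a cluster is identifiable only up to overall
  reversal, and orientation up to a global flip per cluster; metrics are
  reported modulo these symmetries.
* Misoriented intervals shorter than ~3 analysis bins are undetectable by
  construction; the simulator injects only resolvable errors.
* The long-read densifier trusts the backbone; systematic backbone errors
  propagate into extended sites covered only by reads assigned through
  those errors.
* Inversion genotyping from recurrent WC states is out of scope.
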