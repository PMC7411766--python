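# Methods

This note documents the models, defaults, and numerical choices behind
`srna-census`: what the annotation cascade computes, what the synthetic
data generator emulates (and what it deliberately does not), and where
the design was genuinely open.

## The annotation cascade

Reads of 15–50 nt (post-trimming; reads containing `N` are dropped and
tallied) are collapsed to unique sequences with per-library counts.
Every downstream statistic is **count-weighted**: a collapsed sequence
contributes its read multiplicity. Classification is sequential
depletion with a fixed stage order; a read annotated at one stage is
removed before the next, so the order is part of the method's semantics
and is itself exercised by a test (an ambiguous read that matches both a
mature miRNA and a TE consensus changes label when the stages are
permuted).

1. **Genome gate.** Exact (0-mismatch) all-hits mapping to the genome,
   both strands. Reads with no placement are `unmapped` and excluded
   from annotation, not folded into `unannotated`.
2. **miRNA.** A read is miRNA if it matches a mature reference exactly
   or any of its genomic placements falls inside an annotated hairpin
   window (default width 250 nt). Known-miRNA matching is reference-set
   driven; de-novo hairpin prediction is out of scope.
3. **tRNA/rRNA.** A genomic placement overlapping a tRNA or rRNA gene
   model. Because gene models are genomic annotations, this stage is
   implemented as hit∩interval rather than re-mapping against extracted
   gene sequences — equivalent for ungapped reads and much cheaper. A
   read hitting both biotypes is attributed to tRNA (documented
   tie-break), then by lexicographic gene id.
4. **TE-piRNA.** A match to the TE consensus library at ≤ 2 mismatches
   (all-hits, best stratum kept). Per-read TE attribution takes the
   fewest-mismatch hit, ties broken by lexicographic TE id, then offset,
   then strand — the tables are deterministic. Class membership is
   defined by the TE hit, not by a size gate; the 25–30 nt piRNA size
   range emerges in the histograms rather than being imposed.
5. **mRNA-derived.** A genomic placement inside a protein-coding gene
   span; the read is assigned sense/antisense relative to the gene and
   to a feature (5'UTR/CDS/3'UTR, below).
6. Everything else is `unannotated`.

Composition percentages are reported over all trimmed reads (the six
labels sum to 100), with the genome-mapped total as the default RPM
denominator (configurable to raw-trimmed).

### The mapper

All-hits Hamming mapping with caps 0–3, both strands, `N` matching
nothing on either side. Implementation: 2-bit k-mer index over the
concatenated reference plus pigeonhole seeding (a read with ≤ m
mismatches carries one of m+1 disjoint anchored seeds exactly);
candidates are verified base-by-base. For exact matching one shared seed
length (the shortest read in the batch, ≤ 32) serves all read lengths so
a large genome is indexed once per call. Correctness is defined by — and
tested for exact agreement with — an independent brute-force scan over
every offset and strand; the seeding is purely an optimization.
Unique-mapping means exactly one placement in the best (minimum
mismatch) stratum; ≥ 2 best-stratum placements is multi-mapping,
unmapped reads are in neither bin.

### miRNA homolog discovery and enrichment

Candidates are unannotated 20–25 nt sequences with **strictly more
than 200 reads**. Homology to a mature database entry is scored by the
best ungapped offset alignment: `score = 100 · (1 − mm / read length)`,
requiring ≤ 3 mismatches and score ≥ 80. This identity score is a
declared proxy for alignment-tool scores of miRNA databases; exact
parity with any specific search tool is a non-goal, and the printed
cutoff (80) together with the 3-mismatch example on a 22-mer
(score 86.4) is consistent with it. Tissue enrichment uses one-way
ANOVA followed by Tukey HSD (scipy/statsmodels); a tissue is called
enriched only when it holds the strict maximum mean and every pairwise
comparison against it is significant at α (default 0.05; observed
p-values are reported verbatim). Degenerate inputs are defined:
identical values everywhere → F = 0, no call; zero within-group variance
with unequal means → p = 0 for differing pairs. AGO-IP cross-reference
counts reads matching a candidate exactly in the mature's own
orientation and reports the share of the library's annotated-miRNA
total (counting both strands would double-count hairpins whose 3p arm is
the reverse complement of the 5p arm).

### piRNA statistics

Strand fractions are relative to the TE consensus ('+' = sense).
Positional bias matrices are per-position base frequencies (RNA
alphabet, 1-based, 5'→3' in the read's own orientation) for one read
length and orientation; 27 and 28 nt are the default report lengths,
any length is available. Cluster calling bins unique-mapping reads by
their hit start into fixed, 0-aligned windows (default 1 Mb, matching
the Mb-resolution locus naming convention for full-size genomes) and
returns bins above a minimum share (default 1 %), sorted by share with
deterministic tie-breaking — output is invariant to chromosome input
order.

### mRNA-derived calling

Two rules, worded exactly as applied: the top unique sequence must hold
**at least 10 %** (inclusive) of the gene's reads, and the gene must
carry **more than 1000** reads (strict) pooled across the tissue's
replicates. Feature assignment returns the feature fully containing the
read; boundary-spanning (or feature-less) reads are `junction` and count
once in summary distributions, to the feature containing the read's 5'
end (leftmost base for a '+' hit, rightmost for a '−' hit). Orientation
classes use a 0.95 sense-fraction threshold — the class labels are
established, the numeric cutoff is this package's choice and is
configurable.

## The synthetic data generator

`simdata` exists because the statistics above were established on
~10⁸-read libraries against a 273-Mb genome — not reproducible at desk
scale. The generator builds a ~5.1-Mb genome over six chromosomes
(2R, 2L, 3R, 3L, X, UNKN) and plants:

* 25 miRNA hairpins (mature lengths peaked at 22 nt, arm3 = revcomp of
  arm5, 150-nt loop), with log-normal expression weights;
* 30 tRNA (75 nt) and 10 rRNA (600 nt) genes;
* 30 coding genes (150-nt 5'UTR, 900-nt CDS, 250-nt 3'UTR, random
  strand), each with one fixed "dominant" 29-nt 3'UTR fragment;
* a TE landscape per class (LTR / non-LTR / DNA): 2 multi-copy families
  of 4 **identical** copies (so exact-match reads from them are
  multi-mapping by construction; per-copy divergence is available via
  `te_copy_divergence`, default 0 so the configured multi-mapping
  fraction is exact), plus single-copy 800-nt loci whose reads are
  unique-mapping.

Two cluster windows hold dedicated single-copy loci and receive
configured shares of the unique-mapping piRNA reads (defaults 17.7 % on
2R and 3.3 % on 3L); the remaining single-copy loci are placed one per
genomic bin, stratified across non-cluster bins, so the background
unique-mapping signal is flat at bin scale and planted clusters are the
only structures above it. **Bin size scaling:** the full-size analysis
names cluster loci at 1-Mb resolution on a ~273-Mb genome (~270 bins);
the generator's cluster experiments use 100-kb bins on the ~5-Mb genome
(~51 bins) to preserve that bins-per-genome ratio. The analysis
function's default stays 1 Mb.

Library simulation draws a class per read from the tissue mixture
(defaults: the per-tissue composition rows, normalized — the printed
rows are replicate-averaged ratios summing to 100.9–104.1), then:

* **miRNA** reads are exact mature sequences;
* **tRNA/rRNA** reads are gene subsequences (tRNA lengths ~N(32, 2),
  rRNA uniform 15–50, tRNA share 0.25);
* **TE-piRNA** reads (lengths 25–30, peak 27/28) are antisense with
  p = 0.77 and drawn from multi-copy sources with p = 0.828; position-1
  U is imposed with p = 0.9 (both orientations) and position-10 A with
  p = 0.9 (sense only) by rejection-sampling the source offset, so reads
  remain exact genomic substrings and the imposed frequency equals the
  configured probability;
* **mRNA-derived** reads (lengths ~N(29, 2) clipped to 15–37) land fully
  inside one feature with an overall 60 % 3'UTR share and 96 % sense
  share; the per-gene dominant fragment (emitted with probability 0.25,
  always sense/3'UTR) is folded into those totals by adjusting the
  conditional shares of the non-dominant draw;
* **unannotated** reads (lengths ~N(41, 3)) come from intergenic space —
  they map but match no feature, deliberately distinct from the
* **unmappable** class: random sequence verified absent from the genome
  (expected label `unmapped`).

The 3' adapter (Illumina TruSeq small RNA by default) is appended to
every read and removed again by the pipeline's trimmer. Everything is
deterministic under a fixed seed, including feature placement and read
order.

**What the simulator does not model** — sequencing error and quality
scores, PCR duplication, adapter dimers, isomiR/length heterogeneity of
matures, nested or overlapping gene models, TE insertion polymorphism,
and ping-pong partner structure (5'-overlap statistics are a non-goal
throughout). Passing recovery tests therefore demonstrates that the
cascade and statistics are correct and unbiased under clean mapping
conditions; they do not certify behaviour on noisy real libraries,
where trimming and mismatch settings matter.

## Validation experiments and problem sizes

`srna_census.experiments` drives the recovery experiments used by the
test suite and the reproduction script: per-tissue composition
(10 replicates × 100,000 reads per tissue preset), piRNA strand
(10 × 20,000 TE-piRNA reads), TE-class and multi-mapping recovery
(10 × 50,000), cluster shares (10 × 50,000 unique mappers), and
mRNA-derived 3'UTR/sense shares (10 × 50,000). These sizes put the
binomial standard error of every recovered percentage at ≤ 0.2 points,
an order of magnitude below the acceptance tolerances (±1.0 points for
composition, ±1.5 for TE classes, ±0.5 for cluster shares), so the
tests check systematic correctness rather than sampling luck.

## Numerical and edge-case conventions

* Coordinates are 0-based half-open internally; GFF3 is 1-based
  inclusive and BED 0-based half-open at the file boundary.
* Sequences are stored as DNA (U→T on ingest) and rendered as RNA where
  the field prints RNA (bias matrices, candidate tables).
* Adapter trimming removes the leftmost occurrence of a ≥ 8-nt adapter
  prefix and everything 3' of it; untrimmed reads are dropped by default
  (configurable keep) — trim settings of the original workflow are not
  published, so both the adapter and the policy are explicit config.
* Hit ordering, TE attribution, candidate ordering, cluster ordering,
  and tie-breaks are all specified and deterministic; pipeline reruns
  under the same seed produce byte-identical TSVs.
* SEM = sd/√n over replicates; a single replicate reports SEM 0.
* The heatmap abundance filter keeps rows whose per-row **maximum** RPM
  exceeds 10^threshold (default threshold 1, i.e. RPM > 10); max was
  chosen over mean so a gene abundant in a single tissue survives, and
  the statistic is configurable.

## Known limitations

* The mapper is ungapped by design; indels in reads or references are
  outside the model (as they are for the Hamming-distance semantics it
  implements).
* Interval queries assume annotation tracks with shallow overlap
  (features of distinct genes do not nest deeply), which holds for the
  generated genomes and typical ncRNA/coding tracks.
* The homolog identity score is not a drop-in replacement for any
  specific database search tool's score; it is documented, monotone in
  mismatches, and calibrated to the published cutoff behaviour.
* `unannotated` composition depends on annotation completeness by
  construction; on real data it should be read as "not yet annotated",
  not as a biological class.
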