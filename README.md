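# srna-census

Hierarchical annotation of insect small RNA-Seq libraries.

Small RNA libraries from mosquito (and other insect) tissues mix several
biologically distinct read populations: miRNAs (~20–25 nt), tRNA/rRNA
fragments (broad, peak ~32 nt), transposon-targeting piRNAs (~25–30 nt),
mRNA-derived small ncRNAs (peak ~29 nt), and material that maps to the
genome but matches no annotation. `srna-census` classifies each read by
**sequential depletion** — the order of the stages is part of the method,
and an earlier stage always wins:

```
trimmed reads (15–50 nt)
  └─ map to genome ───────────── fail → unmapped
       └─ match mature miRNA / hairpin window → miRNA
            └─ hit tRNA/rRNA gene model ─────→ tRNA_rRNA
                 └─ hit TE consensus (≤2 mm) → TE_piRNA
                      └─ hit coding gene ───→ mRNA_derived
                           └─ remainder ────→ unannotated
```

On top of the cascade the package computes the statistics each class is
studied with:

* **piRNA biology** — sense/antisense fractions relative to the TE
  consensus, positional nucleotide bias matrices (the 1U/10A signature),
  TE-class breakdown (LTR / non-LTR / DNA), per-TE coverage tracks,
  unique- vs multi-mapping partition, per-chromosome contribution, and
  piRNA-cluster calling by fixed-width genomic binning of unique mappers.
* **mRNA-derived small ncRNAs** — candidate genes must have one unique
  sequence holding ≥ 10 % of the gene's reads *and* > 1000 reads pooled
  across replicates; reads are assigned to 5'UTR/CDS/3'UTR and genes
  classed sense / antisense / sense-antisense.
* **miRNA homolog discovery** — 20–25 nt sequences with > 200 reads are
  scored against a mature-miRNA database by ungapped identity
  (`100·(1 − mm/len)`, cutoff 80, ≤ 3 mismatches), quantified against a
  genome locus window, tested for tissue enrichment (one-way ANOVA +
  Tukey HSD), and cross-referenced against AGO1/AGO2 IP libraries.
* **Reports** — composition tables (mean ± SEM over replicates), size
  histograms, RPM tables with a log10 abundance filter, and
  Euclidean/average-linkage clustered heatmap matrices.

The mapper underneath is exhaustive and deterministic: every placement
on either strand within the mismatch cap (Hamming distance; `N` never
matches), verified in the test suite against an independent brute-force
scan.

Because real libraries of the relevant scale run to ~10⁸ reads, the
package ships a **ground-truthed simulator** (`srna_census.sim`): a
desk-scale synthetic genome with planted hairpins, tRNA/rRNA genes,
UTR-structured coding genes, multi-copy and single-copy TE loci, and
piRNA cluster windows, plus library simulation with per-class size
profiles, strand and 1U/10A biases, a controlled multi-mapping fraction,
and a per-read ground-truth table. The generator's defaults encode the
tissue compositions and piRNA statistics reported for *Anopheles
gambiae*, so classification can be validated end to end against known
labels.

## Worked example

```python
from srna_census import classify, prepare_library
from srna_census.pirna import strand_fractions, te_class_breakdown
from srna_census.sim import SimConfig, build_genome, simulate_library

config = SimConfig(seed=1, n_reads=20_000)
bundle = build_genome(config)                       # synthetic references
records, truth = simulate_library(bundle, tissue="OV", replicate=1)
library = prepare_library(records, "OV-1", tissue="OV", replicate=1)
result = classify(library, bundle)

print(result.composition.round(2).to_string())
te = result.te_table()
print("antisense fraction:", round(strand_fractions(te)["antisense"], 3))
print(te_class_breakdown(te).round(1).to_string())
```

prints

```
miRNA            1.83
tRNA_rRNA        6.15
TE_piRNA        33.13
mRNA_derived     6.44
unannotated     52.22
unmapped         0.24
antisense fraction: 0.773
LTR        57.4
non-LTR    33.9
DNA         8.7
```

An ovary-preset library is dominated by TE-piRNAs and unannotated
25–30 nt material; the recovered composition tracks the generator's
configured mixture, the piRNA strand bias sits at the configured 77 %
antisense, and the TE-class split recovers the configured 56/35/9 within
sampling error at this library size.

The same analysis runs from the shell:

```bash
census run --config config.yaml --out results/
```

where the YAML names either a simulation preset or paths to a genome
FASTA, mature-miRNA FASTA, GFF3 gene models, TE FASTA (with
`class=LTR|non-LTR|DNA` tags), and FASTQ libraries.

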