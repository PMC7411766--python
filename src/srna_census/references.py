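"""Reference containers: sequence sets, gene models, interval lookup.

A :class:`ReferenceSet` is a named, ordered collection of reference
sequences of one category (genome chromosomes, miRNA matures, TE
consensus sequences, ...) with per-sequence metadata (e.g. the TE class).
:class:`GeneModelSet` carries genomic gene annotations (tRNA/rRNA genes
and protein-coding genes with 5'UTR/CDS/3'UTR intervals) with fast
overlap queries. All internal coordinates are 0-based half-open; GFF3 is
1-based inclusive at the file boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import encode, to_dna

UTR5 = "5'UTR"
CDS = "CDS"
UTR3 = "3'UTR"
TE_CLASSES = ("LTR", "non-LTR", "DNA")


@dataclass
class Reference:
    """One reference sequence with free-form metadata."""

    id: str
    sequence: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = to_dna(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet:
    """Ordered, named collection of references of a single category.

    Category is one of ``genome | miRNA | ncRNA-gene | TE | mRNA``
    (free-form strings are accepted; the cascade only relies on the
    bundle slots). The set lazily builds a concatenated 2-bit encoding
    that the mapper's k-mer indexes are computed over.
    """

    def __init__(self, name: str, category: str, references: Iterable[Reference]):
        self.name = name
        self.category = category
        self.references: list[Reference] = list(references)
        self._by_id = {r.id: r for r in self.references}
        if len(self._by_id) != len(self.references):
            raise ValueError(f"duplicate reference ids in set {name!r}")
        self._concat: np.ndarray | None = None
        self._starts: np.ndarray | None = None
        self._index_cache: dict = {}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.references)

    def __iter__(self) -> Iterator[Reference]:
        return iter(self.references)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def get(self, ref_id: str) -> Reference:
        try:
            return self._by_id[ref_id]
        except KeyError:
            raise KeyError(f"reference {ref_id!r} not in set {self.name!r}") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.references]

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.references}

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.references)

    # -- encoded view used by the mapper ------------------------------------
    def _ensure_encoded(self) -> None:
        if self._concat is None:
            parts = [encode(r.sequence) for r in self.references]
            self._concat = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
            )
            lens = np.array([len(r) for r in self.references], dtype=np.int64)
            self._starts = np.concatenate([[0], np.cumsum(lens)])

    @property
    def concat(self) -> np.ndarray:
        self._ensure_encoded()
        return self._concat

    @property
    def starts(self) -> np.ndarray:
        """Global start offset of each reference in :attr:`concat` (+ end sentinel)."""
        self._ensure_encoded()
        return self._starts

    def ref_of(self, global_pos: int) -> int:
        """Index of the reference containing a global concat offset."""
        return int(np.searchsorted(self.starts, global_pos, side="right") - 1)

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path, name: str, category: str) -> "ReferenceSet":
        """Load a FASTA (gzip by extension). ``key=value`` tokens in the
        description become metadata (e.g. ``class=LTR`` for TE libraries)."""
        refs = []
        with _maybe_gzip(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                meta = {}
                for token in rec.description.split()[1:]:
                    if "=" in token:
                        key, val = token.split("=", 1)
                        meta[key] = val
                refs.append(Reference(rec.id, str(rec.seq), meta))
        return cls(name, category, refs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(r.sequence),
                id=r.id,
                description=" ".join(f"{k}={v}" for k, v in sorted(r.metadata.items())),
            )
            for r in self.references
        ]
        with _maybe_gzip(path, "wt") as handle:
            SeqIO.write(records, handle, "fasta")


def _maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class IntervalIndex:
    """Overlap queries against a (mostly disjoint) set of genomic intervals.

    Stores per-chromosome sorted starts plus a running maximum of ends, so
    an overlap query is two binary searches and a short scan. Suited to
    annotation tracks where features rarely nest deeply.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, object]]):
        per_chrom: dict[str, list[tuple[int, int, object]]] = {}
        for chrom, start, end, payload in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, payload))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort(key=lambda t: (t[0], t[1]))
            starts = np.array([t[0] for t in ivs], dtype=np.int64)
            ends = np.array([t[1] for t in ivs], dtype=np.int64)
            maxend = np.maximum.accumulate(ends)
            payloads = [t[2] for t in ivs]
            self._chroms[chrom] = (starts, ends, maxend, payloads)

    def query(self, chrom: str, start: int, end: int) -> list:
        """All payloads whose interval overlaps [start, end)."""
        entry = self._chroms.get(chrom)
        if entry is None:
            return []
        starts, ends, maxend, payloads = entry
        lo = int(np.searchsorted(maxend, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        out = []
        for i in range(lo, hi):
            if ends[i] > start:
                out.append(payloads[i])
        return out

    def query_first(self, chrom: str, start: int, end: int):
        hits = self.query(chrom, start, end)
        return hits[0] if hits else None

    def covers(self, chrom: str, start: int, end: int) -> bool:
        """True if some single interval fully contains [start, end)."""
        entry = self._chroms.get(chrom)
        if entry is None:
            return False
        starts, ends, maxend, _ = entry
        lo = int(np.searchsorted(maxend, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            if starts[i] <= start and ends[i] >= end:
                return True
        return False


@dataclass
class GeneModel:
    """A gene with genomic span, strand, biotype, and feature intervals.

    ``features`` maps 5'UTR/CDS/3'UTR to ordered genomic interval lists
    (0-based half-open). For a minus-strand mRNA the 3'UTR is the
    leftmost genomic interval; feature labels are biological, coordinates
    genomic.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str  # mRNA | tRNA | rRNA
    features: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def feature_length(self, label: str) -> int:
        return sum(e - s for s, e in self.features.get(label, []))


_GFF_FEATURE_MAP = {
    "five_prime_UTR": UTR5,
    "CDS": CDS,
    "three_prime_UTR": UTR3,
}


class GeneModelSet:
    """Collection of gene models with per-biotype interval indexes."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        self.skipped_features = 0  # unknown GFF feature types seen on load
        self._trna_rrna_index: IntervalIndex | None = None
        self._mrna_index: IntervalIndex | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in model set") from None

    def by_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == biotype]

    @property
    def trna_rrna_index(self) -> IntervalIndex:
        """Index of tRNA/rRNA gene spans; payload (gene_id, biotype)."""
        if self._trna_rrna_index is None:
            self._trna_rrna_index = IntervalIndex(
                (g.chrom, g.start, g.end, (g.gene_id, g.biotype))
                for g in self.genes.values()
                if g.biotype in ("tRNA", "rRNA")
            )
        return self._trna_rrna_index

    @property
    def mrna_index(self) -> IntervalIndex:
        """Index of protein-coding gene spans; payload gene_id."""
        if self._mrna_index is None:
            self._mrna_index = IntervalIndex(
                (g.chrom, g.start, g.end, g.gene_id)
                for g in self.genes.values()
                if g.biotype == "mRNA"
            )
        return self._mrna_index

    # -- GFF3 boundary -------------------------------------------------------
    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModelSet":
        """Parse a GFF3 file of gene models.

        Recognized feature types: gene, mRNA, five_prime_UTR, CDS,
        three_prime_UTR, tRNA, rRNA. Unknown types are skipped and
        counted in :attr:`skipped_features`. GFF 1-based inclusive
        coordinates become 0-based half-open.
        """
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        known = {"gene", "mRNA", "five_prime_UTR", "CDS", "three_prime_UTR",
                 "tRNA", "rRNA"}
        skipped = 0
        genes: list[GeneModel] = []
        for gene in db.features_of_type("gene", order_by=("seqid", "start")):
            if gene.end < gene.start:
                raise ValueError(f"gene {gene.id}: end < start in GFF")
            biotype = "mRNA"
            features: dict[str, list[tuple[int, int]]] = {}
            for child in db.children(gene.id, order_by="start"):
                if child.featuretype not in known:
                    skipped += 1
                    continue
                if child.end < child.start:
                    raise ValueError(f"feature under {gene.id}: end < start")
                if child.featuretype in ("tRNA", "rRNA"):
                    biotype = child.featuretype
                label = _GFF_FEATURE_MAP.get(child.featuretype)
                if label is not None:
                    features.setdefault(label, []).append(
                        (child.start - 1, child.end)
                    )
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    start=gene.start - 1,
                    end=gene.end,
                    strand=gene.strand if gene.strand in "+-" else "+",
                    biotype=biotype,
                    features=features,
                )
            )
        for ft in db.all_features():
            if ft.featuretype not in known:
                # children already counted; top-level strays land here too
                pass
        out = cls(genes)
        out.skipped_features = skipped
        return out

    def to_gff3(self, path: str | Path) -> None:
        inv = {v: k for k, v in _GFF_FEATURE_MAP.items()}
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start)):
                attrs = f"ID={g.gene_id}"
                fh.write(
                    f"{g.chrom}\tsrna_census\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                if g.biotype in ("tRNA", "rRNA"):
                    fh.write(
                        f"{g.chrom}\tsrna_census\t{g.biotype}\t{g.start + 1}\t"
                        f"{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}.t1;"
                        f"Parent={g.gene_id}\n"
                    )
                    continue
                fh.write(
                    f"{g.chrom}\tsrna_census\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.m1;Parent={g.gene_id}\n"
                )
                n = 0
                for label in (UTR5, CDS, UTR3):
                    for s, e in g.features.get(label, []):
                        n += 1
                        fh.write(
                            f"{g.chrom}\tsrna_census\t{inv[label]}\t{s + 1}\t{e}"
                            f"\t.\t{g.strand}\t.\tID={g.gene_id}.f{n};"
                            f"Parent={g.gene_id}.m1\n"
                        )


@dataclass
class HairpinLocus:
    """A planted/annotated miRNA hairpin window on the genome."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class ReferenceBundle:
    """Everything the annotation cascade needs, in one object.

    Slots mirror the cascade stages: the genome, the mature-miRNA set,
    hairpin windows on the genome, ncRNA/coding gene models, and the TE
    consensus library (each TE carries a ``class`` metadata tag in
    {LTR, non-LTR, DNA}).
    """

    genome: ReferenceSet
    mirna_mature: ReferenceSet
    gene_models: GeneModelSet
    te: ReferenceSet
    hairpins: list[HairpinLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._hairpin_index: IntervalIndex | None = None
        for ref in self.te:
            if ref.metadata.get("class") not in TE_CLASSES:
                raise ValueError(
                    f"TE reference {ref.id!r} lacks a class tag in {TE_CLASSES}"
                )

    @property
    def hairpin_index(self) -> IntervalIndex:
        if self._hairpin_index is None:
            self._hairpin_index = IntervalIndex(
                (h.chrom, h.start, h.end, h.name) for h in self.hairpins
            )
        return self._hairpin_index

    # -- serialization -------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        self.mirna_mature.to_fasta(outdir / "mirna_mature.fa")
        self.te.to_fasta(outdir / "te.fa")
        self.gene_models.to_gff3(outdir / "genes.gff3")
        with open(outdir / "mirna_hairpins.bed", "w") as fh:
            for h in self.hairpins:
                fh.write(
                    f"{h.chrom}\t{h.start}\t{h.end}\t{h.name}\t0\t{h.strand}\n"
                )

    @classmethod
    def load(cls, indir: str | Path) -> "ReferenceBundle":
        indir = Path(indir)
        hairpins = []
        bed = indir / "mirna_hairpins.bed"
        if bed.exists():
            with open(bed) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    hairpins.append(
                        HairpinLocus(
                            name=parts[3],
                            chrom=parts[0],
                            start=int(parts[1]),
                            end=int(parts[2]),
                            strand=parts[5] if len(parts) > 5 else "+",
                        )
                    )
        return cls(
            genome=ReferenceSet.from_fasta(indir / "genome.fa", "genome", "genome"),
            mirna_mature=ReferenceSet.from_fasta(
                indir / "mirna_mature.fa", "mirna_mature", "miRNA"
            ),
            gene_models=GeneModelSet.from_gff3(indir / "genes.gff3"),
            te=ReferenceSet.from_fasta(indir / "te.fa", "te", "TE"),
            hairpins=hairpins,
        )
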