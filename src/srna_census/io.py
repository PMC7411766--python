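"""Read/trim/collapse plumbing and count normalization.

Small RNA libraries enter as single-end FASTQ, get adapter-trimmed, pass
the 15-50 nt / no-N gates, and are collapsed to unique sequences with
per-library counts — the atom of every downstream statistic. ``U`` is
converted to ``T`` on ingest; report code renders RNA where the field
prints RNA.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .references import GeneModelSet
from .sequences import is_valid_read, to_dna

MIN_READ_LEN = 15
MAX_READ_LEN = 50

#: Illumina TruSeq small RNA 3' adapter — the de facto default for this
#: library type; always configurable, the simulator uses the same one.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class CollapsedRead:
    """A unique read sequence with its per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = to_dna(self.sequence)
        if not is_valid_read(self.sequence):
            raise ValueError(
                f"collapsed read contains non-ACGT characters: {self.sequence!r}"
            )
        for lib, c in self.counts.items():
            if c < 1:
                raise ValueError(f"count for library {lib!r} must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, library_id: str) -> int:
        return self.counts.get(library_id, 0)


@dataclass
class Library:
    """One sequencing library after trimming and collapsing."""

    library_id: str
    tissue: str
    replicate: int
    reads: list[CollapsedRead]
    total_raw: int
    total_trimmed: int
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_trimmed > self.total_raw:
            raise ValueError("total_trimmed cannot exceed total_raw")
        total = sum(r.count(self.library_id) for r in self.reads)
        if total != self.total_trimmed:
            raise ValueError(
                f"library {self.library_id}: collapsed counts sum to {total}, "
                f"expected total_trimmed={self.total_trimmed}"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (read-id, sequence, quality) from a 4-line FASTQ.

    gzip is detected by a ``.gz`` extension. Malformed records raise
    ValueError naming the offending line number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(
                    f"{path}: line {lineno}: FASTQ header must start with '@'"
                )
            seq = fh.readline()
            if not seq:
                raise ValueError(f"{path}: line {lineno + 1}: truncated record")
            plus = fh.readline()
            if not plus.startswith("+"):
                raise ValueError(
                    f"{path}: line {lineno + 2}: separator line must start with '+'"
                )
            qual = fh.readline()
            if not qual:
                raise ValueError(f"{path}: line {lineno + 3}: truncated record")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: line {lineno + 3}: sequence and quality lengths "
                    f"differ ({len(seq)} vs {len(qual)})"
                )
            yield header[1:].strip().split()[0], seq, qual
            lineno += 3


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality) records as FASTQ (gzip by extension)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Trimming / gating / collapsing
# ---------------------------------------------------------------------------

def trim_adapter(
    sequence: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 8,
    policy: str = "drop",
) -> str | None:
    """Remove the 3' adapter from a read.

    Finds the leftmost exact occurrence of a >= ``min_overlap`` nt prefix
    of the adapter and removes it plus everything 3' of it. Reads with no
    adapter match are dropped (``policy='drop'``, the default) or kept
    untrimmed (``policy='keep'``). Returns None for a dropped read.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if policy not in ("drop", "keep"):
        raise ValueError("policy must be 'drop' or 'keep'")
    sequence = to_dna(sequence)
    probe = to_dna(adapter)[: min_overlap]
    pos = sequence.find(probe)
    if pos >= 0:
        return sequence[:pos]
    return None if policy == "drop" else sequence


def passes_gates(sequence: str, min_len: int = MIN_READ_LEN,
                 max_len: int = MAX_READ_LEN) -> bool:
    """Length gate (15-50 nt after trimming) plus the no-N gate."""
    return min_len <= len(sequence) <= max_len and is_valid_read(sequence)


def collapse_reads(sequences: Iterable[str], library_id: str) -> list[CollapsedRead]:
    """Collapse trimmed sequences to unique reads with multiplicities.

    The total count is conserved; output is sorted by sequence so the
    trim -> gate -> collapse path is order-deterministic.
    """
    counts: dict[str, int] = {}
    for seq in sequences:
        counts[seq] = counts.get(seq, 0) + 1
    return [
        CollapsedRead(seq, {library_id: c}) for seq, c in sorted(counts.items())
    ]


def prepare_library(
    records: Iterable[tuple[str, str, str]],
    library_id: str,
    tissue: str = "other",
    replicate: int = 1,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 8,
    untrimmed_policy: str = "drop",
) -> Library:
    """Trim, gate, and collapse raw FASTQ records into a Library."""
    kept: list[str] = []
    dropped = {"untrimmed": 0, "length": 0, "with_n": 0}
    total_raw = 0
    for _rid, seq, _qual in records:
        total_raw += 1
        trimmed = trim_adapter(seq, adapter, min_overlap, untrimmed_policy)
        if trimmed is None:
            dropped["untrimmed"] += 1
            continue
        if not MIN_READ_LEN <= len(trimmed) <= MAX_READ_LEN:
            dropped["length"] += 1
            continue
        if not is_valid_read(trimmed):
            dropped["with_n"] += 1
            continue
        kept.append(trimmed)
    return Library(
        library_id=library_id,
        tissue=tissue,
        replicate=replicate,
        reads=collapse_reads(kept, library_id),
        total_raw=total_raw,
        total_trimmed=len(kept),
        dropped=dropped,
    )


def load_library(
    fastq_path: str | Path,
    library_id: str,
    tissue: str = "other",
    replicate: int = 1,
    **kwargs,
) -> Library:
    """Convenience: :func:`read_fastq` piped into :func:`prepare_library`."""
    return prepare_library(
        read_fastq(fastq_path), library_id, tissue, replicate, **kwargs
    )


# ---------------------------------------------------------------------------
# Normalization / annotation input
# ---------------------------------------------------------------------------

def rpm(count: float, denominator: float) -> float:
    """Reads-per-million: count * 1e6 / denominator.

    The denominator is the library's genome-mapped read total by default
    convention (configurable to raw-trimmed upstream).
    """
    if denominator <= 0:
        raise ValueError("RPM denominator must be > 0")
    return count * 1e6 / denominator


def read_gene_models(gff_path: str | Path) -> GeneModelSet:
    """Load gene models (tRNA/rRNA genes, coding genes with UTR/CDS) from GFF3."""
    return GeneModelSet.from_gff3(gff_path)
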