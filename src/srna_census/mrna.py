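"""mRNA-derived small ncRNA calling.

Candidate coding genes pass a two-rule filter: the most abundant unique
sequence must represent at least 10% of the reads mapping to the gene,
and the gene must carry strictly more than 1000 reads pooled across a
tissue's biological replicates. Reads are additionally assigned to
5'UTR/CDS/3'UTR (boundary-spanning reads are ``junction``, attributed
to the feature containing their 5' end in summaries), and each gene's
orientation is classed sense / antisense / sense+antisense.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .references import CDS, UTR3, UTR5, GeneModel

SENSE = "sense"
ANTISENSE = "antisense"
BOTH = "sense/antisense"
JUNCTION = "junction"

_FEATURE_ORDER = (UTR5, CDS, UTR3)


def assign_feature(chrom: str, start: int, end: int,
                   gene: GeneModel) -> str:
    """Feature fully containing the read interval, else ``junction``.

    A read overlapping a feature boundary — or lying outside every
    annotated feature of the gene — is a junction read.
    """
    if chrom != gene.chrom:
        return JUNCTION
    for label in _FEATURE_ORDER:
        for s, e in gene.features.get(label, []):
            if s <= start and end <= e:
                return label
    return JUNCTION


def attributed_feature(chrom: str, start: int, end: int, strand: str,
                       gene: GeneModel) -> str | None:
    """Feature used in summary distributions: containment wins; junction
    reads count once, to the feature containing the read's 5' end.

    The 5' end is the leftmost base for a plus-strand read and the
    rightmost base for a minus-strand read (genomic strand of the hit).
    """
    label = assign_feature(chrom, start, end, gene)
    if label != JUNCTION:
        return label
    five_prime = start if strand == "+" else end - 1
    for lab in _FEATURE_ORDER:
        for s, e in gene.features.get(lab, []):
            if s <= five_prime < e:
                return lab
    return None


def orientation_class(sense_count: float, antisense_count: float,
                      threshold: float = 0.95) -> str:
    """Gene orientation class from sense/antisense read totals.

    sense when the sense fraction is >= threshold, antisense when it is
    <= 1 - threshold, otherwise mixed (sense/antisense).
    """
    total = sense_count + antisense_count
    if total <= 0:
        raise ValueError("orientation_class requires at least one read")
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1.0]")
    frac = sense_count / total
    if frac >= threshold:
        return SENSE
    if frac <= 1.0 - threshold:
        return ANTISENSE
    return BOTH


@dataclass
class GeneCandidate:
    """An mRNA-derived small ncRNA candidate gene."""

    gene_id: str
    total_reads: int
    top_sequence: str
    top_fraction: float
    orientation: str
    feature_distribution: dict[str, int]
    size_range: tuple[int, int]


def call_candidates(
    mrna_table: pd.DataFrame,
    min_reads: int = 1000,
    min_top_fraction: float = 0.10,
    orientation_threshold: float = 0.95,
) -> list[GeneCandidate]:
    """Apply the two-rule candidate filter to pooled per-gene read tables.

    ``mrna_table`` holds one row per collapsed read with columns
    sequence/count/gene_id/feature_attr/sense/length, counts pooled
    across a tissue's replicates. A gene is emitted when its top unique
    sequence holds >= ``min_top_fraction`` of the gene's reads AND the
    gene total is strictly greater than ``min_reads``. Output is ordered
    by descending total then gene id.
    """
    out: list[GeneCandidate] = []
    if mrna_table.empty:
        return out
    for gene_id, grp in mrna_table.groupby("gene_id", sort=True):
        total = int(grp["count"].sum())
        if total <= min_reads:
            continue
        per_seq = grp.groupby("sequence")["count"].sum()
        top_count = int(per_seq.max())
        top_seq = min(per_seq.index[per_seq == top_count])
        top_fraction = top_count / total
        if top_fraction < min_top_fraction:
            continue
        sense_count = int(grp.loc[grp["sense"] == True, "count"].sum())  # noqa: E712
        feat = {
            lab: int(grp.loc[grp["feature_attr"] == lab, "count"].sum())
            for lab in _FEATURE_ORDER
        }
        out.append(GeneCandidate(
            gene_id=str(gene_id),
            total_reads=total,
            top_sequence=top_seq,
            top_fraction=top_fraction,
            orientation=orientation_class(
                sense_count, total - sense_count, orientation_threshold,
            ),
            feature_distribution=feat,
            size_range=(int(grp["length"].min()), int(grp["length"].max())),
        ))
    out.sort(key=lambda c: (-c.total_reads, c.gene_id))
    return out


def candidates_frame(candidates: list[GeneCandidate]) -> pd.DataFrame:
    """Candidate list as a flat table (TSV-ready)."""
    rows = [
        {
            "gene_id": c.gene_id, "total_reads": c.total_reads,
            "top_sequence": c.top_sequence,
            "top_fraction": round(c.top_fraction, 6),
            "orientation": c.orientation,
            "utr5_reads": c.feature_distribution.get(UTR5, 0),
            "cds_reads": c.feature_distribution.get(CDS, 0),
            "utr3_reads": c.feature_distribution.get(UTR3, 0),
            "min_nt": c.size_range[0], "max_nt": c.size_range[1],
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "total_reads", "top_sequence",
                       "top_fraction", "orientation", "utr5_reads",
                       "cds_reads", "utr3_reads", "min_nt", "max_nt"],
    )
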