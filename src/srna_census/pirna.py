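"""piRNA-specific statistics over TE-annotated and genome-mapped reads.

All fractions are count-weighted (a collapsed sequence contributes its
read multiplicity, not 1): TE-class breakdown, sense/antisense strand
fractions relative to the TE consensus, positional nucleotide bias
matrices (the 1U/10A signature), per-TE coverage tracks, per-chromosome
contribution of unique-mapping reads, and genomic cluster calling by
fixed-width binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .references import ReferenceSet, TE_CLASSES
from .sequences import to_rna

RNA_BASES = ("A", "C", "G", "U")


def te_class_breakdown(te_table: pd.DataFrame) -> pd.Series:
    """Percent of TE-piRNA reads per TE class (LTR / non-LTR / DNA).

    Attribution follows the cascade's best-hit rule; percentages sum to
    100 over reads with a TE hit.
    """
    out = pd.Series(0.0, index=list(TE_CLASSES))
    if te_table.empty:
        return out
    if te_table["te_class"].isna().any():
        raise ValueError("TE hit without a class tag")
    totals = te_table.groupby("te_class")["count"].sum()
    grand = float(totals.sum())
    for cls in TE_CLASSES:
        out[cls] = 100.0 * float(totals.get(cls, 0)) / grand
    return out


def strand_fractions(te_table: pd.DataFrame) -> dict[str, float]:
    """Sense/antisense fractions of TE-piRNA reads (sense = '+' vs consensus)."""
    if te_table.empty:
        return {"sense": 0.0, "antisense": 0.0}
    total = float(te_table["count"].sum())
    sense = float(te_table.loc[te_table["strand"] == "+", "count"].sum())
    return {"sense": sense / total, "antisense": 1.0 - sense / total}


@dataclass
class PositionalBias:
    """Per-position base frequencies of reads of one length and orientation.

    The matrix is 1-based position x RNA base, 5'->3' in the read's own
    orientation — position 1 of an antisense read is its own 5' end, as
    in standard piRNA signature logos.
    """

    length: int
    orientation: str
    matrix: pd.DataFrame   # index 1..L, columns A/C/G/U
    n_reads: int


def positional_bias(te_table: pd.DataFrame, length: int,
                    orientation: str) -> PositionalBias:
    """Positional nucleotide frequency matrix for one read length/orientation.

    ``orientation`` is 'sense' or 'antisense' relative to the TE
    consensus. With no qualifying reads the matrix is empty and
    ``n_reads`` is 0.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError("orientation must be 'sense' or 'antisense'")
    strand = "+" if orientation == "sense" else "-"
    sub = te_table[(te_table["length"] == length) &
                   (te_table["strand"] == strand)]
    if sub.empty:
        return PositionalBias(length, orientation,
                              pd.DataFrame(columns=list(RNA_BASES)), 0)
    counts = np.zeros((length, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(RNA_BASES)}
    for seq, c in zip(sub["sequence"], sub["count"]):
        for pos, base in enumerate(to_rna(seq)):
            counts[pos, base_idx[base]] += int(c)
    n_reads = int(sub["count"].sum())
    matrix = pd.DataFrame(counts / n_reads, index=range(1, length + 1),
                          columns=list(RNA_BASES))
    return PositionalBias(length, orientation, matrix, n_reads)


def te_coverage_profile(te_table: pd.DataFrame, te_set: ReferenceSet,
                        te_id: str) -> pd.DataFrame:
    """Read-start and coverage tracks along one TE consensus.

    Returns a per-position table with sense/antisense read-start and
    coverage counts; exports conventionally draw sense up and antisense
    down (see :func:`signed_coverage`).
    """
    te_len = len(te_set.get(te_id))  # KeyError for unknown te_id
    cols = ["sense_starts", "antisense_starts", "sense_cov", "antisense_cov"]
    track = pd.DataFrame(0, index=range(te_len), columns=cols)
    sub = te_table[te_table["te_id"] == te_id]
    starts = np.zeros((te_len, 2), dtype=np.int64)
    cov = np.zeros((te_len + 1, 2), dtype=np.int64)  # diff array
    for start, strand, length, c in zip(sub["start"], sub["strand"],
                                        sub["length"], sub["count"]):
        col = 0 if strand == "+" else 1
        starts[start, col] += int(c)
        cov[start, col] += int(c)
        cov[min(start + length, te_len), col] -= int(c)
    track["sense_starts"] = starts[:, 0]
    track["antisense_starts"] = starts[:, 1]
    track["sense_cov"] = np.cumsum(cov[:-1, 0])
    track["antisense_cov"] = np.cumsum(cov[:-1, 1])
    return track


def signed_coverage(track: pd.DataFrame) -> pd.DataFrame:
    """Sense-up / antisense-down rendering of a coverage track."""
    out = track.copy()
    out["antisense_starts"] = -out["antisense_starts"]
    out["antisense_cov"] = -out["antisense_cov"]
    return out


def chromosome_contribution(genome_table: pd.DataFrame) -> pd.DataFrame:
    """Read count and percent per chromosome for unique-mapping reads."""
    sub = genome_table[genome_table["unique"]] if "unique" in genome_table \
        else genome_table
    if sub.empty:
        return pd.DataFrame(columns=["chrom", "reads", "percent"])
    totals = sub.groupby("chrom")["count"].sum().sort_index()
    grand = float(totals.sum())
    return pd.DataFrame({
        "chrom": totals.index,
        "reads": totals.values,
        "percent": 100.0 * totals.values / grand,
    }).reset_index(drop=True)


@dataclass
class PiClusterMap:
    """Binned genomic map of unique-mapping piRNA reads."""

    bin_size: int
    bins: pd.DataFrame     # chrom, bin_start, count, share_pct
    total_reads: int


def bin_unique_reads(genome_table: pd.DataFrame,
                     bin_size: int = 1_000_000) -> PiClusterMap:
    """Bin unique-mapping reads into fixed, 0-aligned genomic windows.

    Reads are assigned by their 5'-most mapped position (the hit start);
    bin counts conserve the unique-mapping total.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    sub = genome_table[genome_table["unique"]]
    if sub.empty:
        return PiClusterMap(bin_size,
                            pd.DataFrame(columns=["chrom", "bin_start",
                                                  "count", "share_pct"]),
                            0)
    binned = sub.assign(bin_start=(sub["start"] // bin_size) * bin_size)
    counts = (binned.groupby(["chrom", "bin_start"])["count"].sum()
              .reset_index())
    total = int(counts["count"].sum())
    counts["share_pct"] = 100.0 * counts["count"] / total
    counts = counts.sort_values(["chrom", "bin_start"]).reset_index(drop=True)
    return PiClusterMap(bin_size, counts, total)


def call_clusters(pi_map: PiClusterMap, min_share: float = 1.0) -> pd.DataFrame:
    """Bins holding at least ``min_share`` percent of unique mappers.

    Output is sorted by descending share (ties by chromosome then bin)
    and labelled by the bin's start offset in Mb, independent of
    chromosome input order.
    """
    if not 0 < min_share <= 100:
        raise ValueError("min_share must be in (0, 100]")
    bins = pi_map.bins
    if bins.empty:
        return pd.DataFrame(columns=["chrom", "bin_start", "count",
                                     "share_pct", "label"])
    hits = bins[bins["share_pct"] >= min_share].copy()
    hits = hits.sort_values(
        ["share_pct", "chrom", "bin_start"], ascending=[False, True, True]
    ).reset_index(drop=True)
    hits["label"] = [
        f"{c}:{s / 1e6:g}Mb" for c, s in zip(hits["chrom"], hits["bin_start"])
    ]
    return hits


def clusters_to_bed(clusters: pd.DataFrame, bin_size: int) -> str:
    """BED6 text for called clusters (score = share in 1/100 percent)."""
    lines = []
    for _, row in clusters.iterrows():
        score = int(round(row["share_pct"] * 100))
        lines.append(
            f"{row['chrom']}\t{int(row['bin_start'])}\t"
            f"{int(row['bin_start']) + bin_size}\t{row['label']}\t{score}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
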