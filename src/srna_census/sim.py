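"""Synthetic genome and small RNA library generator with ground truth.

The generator builds a desk-scale genome (~5 Mb over six chromosomes
named after the An. gambiae karyotype) with planted miRNA hairpins,
tRNA/rRNA genes, protein-coding genes with UTR/CDS structure, and a TE
landscape of multi-copy (identical copies, hence multi-mapping) and
single-copy (unique-mapping) elements. Libraries are then simulated with
a configurable class mixture per tissue, class-specific read-length
profiles, piRNA strand/1U/10A biases, a controlled multi-mapping
fraction, planted piRNA cluster loci, and a configurable 3'UTR share for
mRNA-derived reads. Every emitted read carries a ground-truth record, so
the whole annotation cascade can be scored against known labels.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import labels
from .io import DEFAULT_ADAPTER, write_fastq
from .mapping import map_reads
from .references import (
    CDS,
    UTR3,
    UTR5,
    GeneModel,
    GeneModelSet,
    HairpinLocus,
    Reference,
    ReferenceBundle,
    ReferenceSet,
)
from .sequences import decode, encode, revcomp

#: Per-tissue class percentages as printed in the source composition
#: table (replicate-averaged ratios; rows do not re-sum to exactly 100
#: and are normalized on use).
TISSUE_MIXTURES: dict[str, dict[str, float]] = {
    "FB-Ab": {
        labels.MIRNA: 13.43, labels.TRNA_RRNA: 49.89, labels.TE_PIRNA: 2.21,
        labels.MRNA_DERIVED: 15.56, labels.UNANNOTATED: 18.63,
        labels.UNMAPPABLE: 0.29,
    },
    "MG": {
        labels.MIRNA: 22.62, labels.TRNA_RRNA: 52.80, labels.TE_PIRNA: 0.94,
        labels.MRNA_DERIVED: 11.45, labels.UNANNOTATED: 13.09,
        labels.UNMAPPABLE: 1.35,
    },
    "OV": {
        labels.MIRNA: 2.07, labels.TRNA_RRNA: 6.24, labels.TE_PIRNA: 34.72,
        labels.MRNA_DERIVED: 6.47, labels.UNANNOTATED: 54.33,
        labels.UNMAPPABLE: 0.26,
    },
    "R": {
        labels.MIRNA: 3.71, labels.TRNA_RRNA: 77.24, labels.TE_PIRNA: 0.76,
        labels.MRNA_DERIVED: 9.07, labels.UNANNOTATED: 10.38,
        labels.UNMAPPABLE: 0.45,
    },
}

TE_CLASS_ORDER = ("LTR", "non-LTR", "DNA")


def mixture_for(tissue: str) -> dict[str, float]:
    """Normalized class mixture for a tissue preset."""
    raw = TISSUE_MIXTURES[tissue]
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _normalize_mixture(mixture: dict[str, float]) -> dict[str, float]:
    unknown = set(mixture) - set(labels.SIM_CLASSES)
    if unknown:
        raise ValueError(f"unknown simulation classes: {sorted(unknown)}")
    total = sum(mixture.values())
    if total <= 0:
        raise ValueError("class mixture must have positive mass")
    return {c: mixture.get(c, 0.0) / total for c in labels.SIM_CLASSES}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the emulated study conditions.

    Class mixtures default to the per-tissue composition rows; size
    profiles to the observed per-class modes (miRNA ~22 nt, tRNA/rRNA
    peak 32 nt, TE-piRNA 25-30 nt, mRNA-derived peak 29 nt, unannotated
    peak 41 nt); piRNA strand/positional biases and the multi-mapping
    fraction to the reported ovary values.
    """

    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: {
        "2R": 1_100_000, "2L": 950_000, "3R": 900_000,
        "3L": 1_000_000, "X": 700_000, "UNKN": 450_000,
    })
    n_reads: int = 100_000
    class_mixture: dict[str, float] | None = None  # default: tissue preset
    adapter: str = DEFAULT_ADAPTER

    # --- TE / piRNA structure ---
    te_class_mixture: dict[str, float] = field(default_factory=lambda: {
        "LTR": 0.56, "non-LTR": 0.35, "DNA": 0.09,
    })
    multi_fraction: float = 0.828  # fraction of TE-piRNA reads that multi-map
    antisense_prob: float = 0.77
    p1u: float = 0.9          # P(position-1 U), sense and antisense piRNAs
    p10a_sense: float = 0.9   # P(position-10 A), sense piRNAs only
    pirna_length_pmf: dict[int, float] = field(default_factory=lambda: {
        25: 0.08, 26: 0.17, 27: 0.25, 28: 0.25, 29: 0.17, 30: 0.08,
    })
    te_multi_families_per_class: int = 2
    te_copies_per_multi_family: int = 4
    te_multi_length: int = 1500
    te_single_length: int = 800
    #: background single-copy loci are spread one-per-genomic-bin so the
    #: non-cluster unique-mapping signal is flat (no spurious clusters)
    te_single_background: dict[str, int] = field(default_factory=lambda: {
        "LTR": 20, "non-LTR": 14, "DNA": 10,
    })
    te_single_per_cluster: dict[str, int] = field(default_factory=lambda: {
        "LTR": 2, "non-LTR": 2, "DNA": 2,
    })
    te_copy_divergence: float = 0.0  # per-base divergence of planted copies

    # --- piRNA clusters (bin start offsets, shares in % of unique mappers) ---
    clusters: list[tuple[str, int, float]] = field(default_factory=lambda: [
        ("2R", 300_000, 17.7), ("3L", 200_000, 3.3),
    ])
    cluster_bin_size: int = 100_000

    # --- miRNA structure ---
    n_hairpins: int = 25
    hairpin_loop: int = 150
    hairpin_window: int = 250
    mirna_length_pmf: dict[int, float] = field(default_factory=lambda: {
        20: 0.05, 21: 0.20, 22: 0.40, 23: 0.20, 24: 0.10, 25: 0.05,
    })
    mirna_weights: dict[str, float] | None = None  # per-mature override

    # --- tRNA / rRNA structure ---
    n_trna: int = 30
    trna_length: int = 75
    n_rrna: int = 10
    rrna_length: int = 600
    trna_share: float = 0.25      # tRNA vs rRNA share of the class
    trna_read_length: tuple[float, float] = (32.0, 2.0)  # mean, sd

    # --- mRNA-derived structure ---
    n_mrna: int = 30
    utr5_length: int = 150
    cds_length: int = 900
    utr3_length: int = 250
    mrna_feature_shares: dict[str, float] = field(default_factory=lambda: {
        UTR5: 0.10, CDS: 0.30, UTR3: 0.60,
    })
    mrna_sense_prob: float = 0.96
    mrna_dominant_share: float = 0.25  # per-gene fixed dominant fragment
    mrna_dominant_length: int = 29
    mrna_read_length: tuple[float, float] = (29.0, 2.0)
    mrna_read_bounds: tuple[int, int] = (15, 37)
    mrna_gene_weights: list[float] | None = None

    # --- other classes ---
    unannotated_length: tuple[float, float] = (41.0, 3.0)
    mismatch_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in [
            ("multi_fraction", self.multi_fraction),
            ("antisense_prob", self.antisense_prob),
            ("p1u", self.p1u), ("p10a_sense", self.p10a_sense),
            ("mrna_sense_prob", self.mrna_sense_prob),
            ("mrna_dominant_share", self.mrna_dominant_share),
            ("trna_share", self.trna_share),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.class_mixture is not None:
            self.class_mixture = _normalize_mixture(self.class_mixture)
        share3 = self.mrna_feature_shares.get(UTR3, 0.0)
        if self.mrna_dominant_share > share3 + 1e-12:
            raise ValueError(
                "mrna_dominant_share cannot exceed the 3'UTR share "
                "(the dominant fragment lives in the 3'UTR)"
            )
        if self.mrna_dominant_share > self.mrna_sense_prob + 1e-12:
            raise ValueError(
                "mrna_dominant_share cannot exceed mrna_sense_prob "
                "(the dominant fragment is sense)"
            )


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

class PlacementError(RuntimeError):
    pass


class _Placer:
    """Rejection-samples non-overlapping feature placements."""

    def __init__(self, rng: np.random.Generator, chrom_sizes: dict[str, int],
                 margin: int = 60):
        self.rng = rng
        self.sizes = chrom_sizes
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in chrom_sizes
        }
        self._names = list(chrom_sizes)
        self._weights = np.array([chrom_sizes[c] for c in self._names], float)
        self._weights /= self._weights.sum()

    def _fits(self, chrom: str, start: int, end: int) -> bool:
        m = self.margin
        for s, e in self.occupied[chrom]:
            if start < e + m and end > s - m:
                return False
        return True

    def place(self, length: int, chrom: str | None = None,
              window: tuple[int, int] | None = None,
              tries: int = 500) -> tuple[str, int]:
        for _ in range(tries):
            c = chrom or self._names[self.rng.choice(len(self._names),
                                                     p=self._weights)]
            lo, hi = window if window else (0, self.sizes[c])
            hi = min(hi, self.sizes[c])
            if hi - lo < length:
                raise PlacementError(
                    f"window {c}:{lo}-{hi} too small for length {length}"
                )
            start = int(self.rng.integers(lo, hi - length + 1))
            if self._fits(c, start, start + length):
                self.occupied[c].append((start, start + length))
                self.occupied[c].sort()
                return c, start
        raise PlacementError(
            f"could not place a {length} nt feature after {tries} tries; "
            f"occupancy report: "
            + ", ".join(
                f"{c}:{sum(e - s for s, e in iv)}/{self.sizes[c]}"
                for c, iv in self.occupied.items()
            )
        )


@dataclass
class _TeLocus:
    te_id: str
    te_class: str
    chrom: str
    start: int
    length: int
    zone: str  # 'multi', 'background', or 'cluster<i>'


@dataclass
class SimulatedBundle(ReferenceBundle):
    """Reference bundle plus the generator's private structures."""

    config: SimConfig = None
    chrom_seqs: dict[str, str] = field(default_factory=dict)
    mature_ids: list[str] = field(default_factory=list)
    mature_weights: np.ndarray = None
    te_multi: dict[str, list[dict]] = field(default_factory=dict)
    te_single: dict[str, dict[str, list[_TeLocus]]] = field(default_factory=dict)
    trna_weights: np.ndarray = None
    rrna_weights: np.ndarray = None
    mrna_weights: np.ndarray = None
    mrna_dominant: dict[str, tuple[str, int]] = field(default_factory=dict)
    intergenic: list[tuple[str, int, int]] = field(default_factory=list)

    def window_sequence(self, chrom: str, start: int, end: int) -> str:
        seq = self.chrom_seqs[chrom]
        if not 0 <= start < end <= len(seq):
            raise ValueError(f"window {chrom}:{start}-{end} outside genome")
        return seq[start:end]


def build_genome(config: SimConfig) -> SimulatedBundle:
    """Build the synthetic genome and all reference sets, deterministically."""
    rng = np.random.default_rng(config.seed)
    chrom_arrays = {
        c: rng.integers(0, 4, size=n, dtype=np.uint8)
        for c, n in config.chromosomes.items()
    }
    placer = _Placer(rng, config.chromosomes)

    # --- TE landscape ------------------------------------------------------
    te_refs: list[Reference] = []
    te_multi: dict[str, list[dict]] = {c: [] for c in TE_CLASS_ORDER}
    te_single: dict[str, dict[str, list[_TeLocus]]] = {
        c: {} for c in TE_CLASS_ORDER
    }
    cluster_zones = [f"cluster{i}" for i in range(len(config.clusters))]

    def _random_seq(length: int) -> np.ndarray:
        return rng.integers(0, 4, size=length, dtype=np.uint8)

    def _plant(chrom: str, start: int, codes: np.ndarray) -> None:
        arr = codes
        if config.te_copy_divergence > 0:
            arr = codes.copy()
            mut = rng.random(arr.size) < config.te_copy_divergence
            arr[mut] = (arr[mut] + rng.integers(1, 4, mut.sum())) % 4
        chrom_arrays[chrom][start : start + arr.size] = arr

    # single-copy loci inside cluster windows first (constrained placement)
    for zi, (cchrom, cstart, _share) in enumerate(config.clusters):
        zone = cluster_zones[zi]
        window = (cstart, cstart + config.cluster_bin_size)
        for cls in TE_CLASS_ORDER:
            te_single[cls][zone] = []
            for j in range(config.te_single_per_cluster.get(cls, 0)):
                codes = _random_seq(config.te_single_length)
                te_id = f"TE_{cls}_C{zi}_{j}"
                chrom, start = placer.place(codes.size, chrom=cchrom,
                                            window=window)
                _plant(chrom, start, codes)
                te_refs.append(Reference(te_id, decode(codes),
                                         {"class": cls}))
                te_single[cls][zone].append(
                    _TeLocus(te_id, cls, chrom, start, codes.size, zone)
                )
    # background single-copy loci: stratified one-per-bin over non-cluster
    # bins so the background unique-mapping signal is flat at bin scale
    bg_bins: list[tuple[str, int]] = []
    cluster_spans = {
        (c, s) for (c, s, _share) in config.clusters
    }
    for chrom, size in config.chromosomes.items():
        for bstart in range(0, size - config.te_single_length,
                            config.cluster_bin_size):
            if (chrom, bstart) not in cluster_spans:
                bg_bins.append((chrom, bstart))
    bg_order = [bg_bins[i] for i in rng.permutation(len(bg_bins))]
    bin_cursor = 0
    for cls in TE_CLASS_ORDER:
        te_single[cls]["background"] = []
        for j in range(config.te_single_background.get(cls, 0)):
            codes = _random_seq(config.te_single_length)
            te_id = f"TE_{cls}_S{j}"
            bchrom, bstart = bg_order[bin_cursor % len(bg_order)]
            bin_cursor += 1
            bend = min(bstart + config.cluster_bin_size,
                       config.chromosomes[bchrom])
            chrom, start = placer.place(codes.size, chrom=bchrom,
                                        window=(bstart, bend))
            _plant(chrom, start, codes)
            te_refs.append(Reference(te_id, decode(codes), {"class": cls}))
            te_single[cls]["background"].append(
                _TeLocus(te_id, cls, chrom, start, codes.size, "background")
            )
    # multi-copy families: identical copies => exact reads multi-map
    for cls in TE_CLASS_ORDER:
        for f in range(config.te_multi_families_per_class):
            codes = _random_seq(config.te_multi_length)
            te_id = f"TE_{cls}_M{f}"
            copies = []
            for _ in range(config.te_copies_per_multi_family):
                chrom, start = placer.place(codes.size)
                _plant(chrom, start, codes)
                copies.append((chrom, start))
            te_refs.append(Reference(te_id, decode(codes), {"class": cls}))
            te_multi[cls].append(
                {"te_id": te_id, "copies": copies, "length": codes.size}
            )

    # --- miRNA hairpins -----------------------------------------------------
    mat_lens = np.array(sorted(config.mirna_length_pmf), dtype=int)
    mat_p = np.array([config.mirna_length_pmf[i] for i in mat_lens], float)
    mat_p /= mat_p.sum()
    mature_refs: list[Reference] = []
    hairpins: list[HairpinLocus] = []
    for i in range(config.n_hairpins):
        mlen = int(rng.choice(mat_lens, p=mat_p))
        arm5 = decode(_random_seq(mlen))
        loop = decode(_random_seq(config.hairpin_loop))
        arm3 = revcomp(arm5)
        hp = arm5 + loop + arm3
        hp_id = f"hp{i:02d}"
        chrom, start = placer.place(len(hp))
        chrom_arrays[chrom][start : start + len(hp)] = encode(hp)
        pad = max(0, (config.hairpin_window - len(hp)) // 2)
        hairpins.append(
            HairpinLocus(hp_id, chrom, max(0, start - pad),
                         min(config.chromosomes[chrom], start + len(hp) + pad))
        )
        mature_refs.append(
            Reference(f"aga-miR-sim{i}-5p", arm5, {"hairpin": hp_id}))
        mature_refs.append(
            Reference(f"aga-miR-sim{i}-3p", arm3, {"hairpin": hp_id}))

    # --- ncRNA and coding gene models --------------------------------------
    genes: list[GeneModel] = []
    for i in range(config.n_trna):
        chrom, start = placer.place(config.trna_length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"tRNA-{i:02d}", chrom, start,
                               start + config.trna_length, strand, "tRNA"))
    for i in range(config.n_rrna):
        chrom, start = placer.place(config.rrna_length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"rRNA-{i:02d}", chrom, start,
                               start + config.rrna_length, strand, "rRNA"))
    gene_len = config.utr5_length + config.cds_length + config.utr3_length
    mrna_dominant: dict[str, tuple[str, int]] = {}
    for i in range(config.n_mrna):
        chrom, start = placer.place(gene_len)
        strand = "+" if rng.random() < 0.5 else "-"
        u5, cd, u3 = (config.utr5_length, config.cds_length,
                      config.utr3_length)
        if strand == "+":
            features = {
                UTR5: [(start, start + u5)],
                CDS: [(start + u5, start + u5 + cd)],
                UTR3: [(start + u5 + cd, start + gene_len)],
            }
        else:  # minus strand: 3'UTR is the leftmost genomic interval
            features = {
                UTR3: [(start, start + u3)],
                CDS: [(start + u3, start + u3 + cd)],
                UTR5: [(start + u3 + cd, start + gene_len)],
            }
        genes.append(GeneModel(f"PCG{i:03d}", chrom, start, start + gene_len,
                               strand, "mRNA", features))
        # fixed dominant 3'UTR fragment (sense), planted per gene
        u3s, u3e = features[UTR3][0]
        off = int(rng.integers(0, (u3e - u3s) - config.mrna_dominant_length + 1))
        mrna_dominant[f"PCG{i:03d}"] = (chrom, u3s + off)

    # --- finalize genome -----------------------------------------------------
    chrom_seqs = {c: decode(a) for c, a in chrom_arrays.items()}
    genome = ReferenceSet(
        "genome", "genome",
        [Reference(c, chrom_seqs[c]) for c in config.chromosomes],
    )
    bundle = SimulatedBundle(
        genome=genome,
        mirna_mature=ReferenceSet("mirna_mature", "miRNA", mature_refs),
        gene_models=GeneModelSet(genes),
        te=ReferenceSet("te", "TE", te_refs),
        hairpins=hairpins,
        config=config,
        chrom_seqs=chrom_seqs,
        mature_ids=[r.id for r in mature_refs],
        te_multi=te_multi,
        te_single=te_single,
        mrna_dominant={
            g: (chrom_seqs[c][s : s + config.mrna_dominant_length], s)
            for g, (c, s) in mrna_dominant.items()
        },
    )
    # dominant fragment is stored in gene-sense orientation
    for g, (seq, s) in list(bundle.mrna_dominant.items()):
        if bundle.gene_models.get(g).strand == "-":
            bundle.mrna_dominant[g] = (revcomp(seq), s)

    # expression weights (log-normal; one draw per genome)
    bundle.mature_weights = _lognormal_weights(rng, len(mature_refs), 1.0)
    bundle.trna_weights = _lognormal_weights(rng, config.n_trna, 1.0)
    bundle.rrna_weights = _lognormal_weights(rng, config.n_rrna, 1.0)
    bundle.mrna_weights = _lognormal_weights(rng, config.n_mrna, 1.2)

    # intergenic space = complement of every placed feature, with margin
    bundle.intergenic = _intergenic_intervals(
        config.chromosomes, placer.occupied, margin=25, min_len=120
    )
    return bundle


def _lognormal_weights(rng: np.random.Generator, n: int,
                       sigma: float) -> np.ndarray:
    w = rng.lognormal(0.0, sigma, size=n)
    return w / w.sum()


def _intergenic_intervals(sizes, occupied, margin, min_len):
    out = []
    for chrom, size in sizes.items():
        cursor = 0
        for s, e in sorted(occupied[chrom]) + [(size, size)]:
            lo, hi = cursor + margin, s - margin
            if hi - lo >= min_len:
                out.append((chrom, lo, hi))
            cursor = max(cursor, e)
    return out


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "read_id", "sequence", "true_class", "source_id", "strand", "offset",
    "feature", "sense", "multi", "zone", "tissue", "replicate",
]


def _sample_lengths(rng, n, mean, sd, lo, hi):
    return np.clip(np.rint(rng.normal(mean, sd, size=n)).astype(int), lo, hi)


def _pmf_choice(rng, pmf: dict[int, float], n: int) -> np.ndarray:
    keys = np.array(sorted(pmf), dtype=int)
    p = np.array([pmf[k] for k in keys], float)
    return rng.choice(keys, size=n, p=p / p.sum())


def simulate_library(
    bundle: SimulatedBundle,
    tissue: str = "OV",
    replicate: int = 1,
    n_reads: int | None = None,
    seed: int | None = None,
    class_mixture: dict[str, float] | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one library: FASTQ-ready records plus a ground-truth table.

    Records are (read-id, insert + adapter, quality). The ground truth has
    one row per emitted read with the true class, source feature, strand,
    and per-class extras (feature/sense for mRNA-derived, multi/zone for
    TE-piRNA).
    """
    cfg = bundle.config
    n = int(n_reads if n_reads is not None else cfg.n_reads)
    if class_mixture is not None:
        mixture = _normalize_mixture(class_mixture)
    elif cfg.class_mixture is not None:
        mixture = cfg.class_mixture
    else:
        mixture = _normalize_mixture(mixture_for(tissue))
    if seed is None:
        tissue_code = sum(ord(ch) for ch in tissue)
        rng = np.random.default_rng([cfg.seed, tissue_code, replicate])
    else:
        rng = np.random.default_rng(seed)

    probs = np.array([mixture[c] for c in labels.SIM_CLASSES])
    counts = rng.multinomial(n, probs)
    rows: list[dict] = []
    generators = {
        labels.MIRNA: _gen_mirna,
        labels.TRNA_RRNA: _gen_trna_rrna,
        labels.TE_PIRNA: _gen_te_pirna,
        labels.MRNA_DERIVED: _gen_mrna,
        labels.UNANNOTATED: _gen_unannotated,
        labels.UNMAPPABLE: _gen_unmappable,
    }
    for cls, cnt in zip(labels.SIM_CLASSES, counts):
        if cnt:
            rows.extend(generators[cls](bundle, cfg, rng, int(cnt)))

    _inject_mismatches(rows, cfg, rng)
    order = rng.permutation(len(rows))
    records = []
    truth_rows = []
    for out_i, i in enumerate(order):
        r = rows[i]
        rid = f"r{out_i:07d}"
        insert = r["sequence"]
        records.append((rid, insert + cfg.adapter, "I" * (len(insert) + len(cfg.adapter))))
        truth_rows.append({
            "read_id": rid, "sequence": insert,
            "true_class": r["true_class"], "source_id": r.get("source_id", ""),
            "strand": r.get("strand", "."), "offset": r.get("offset", -1),
            "feature": r.get("feature", ""), "sense": r.get("sense", ""),
            "multi": r.get("multi", ""), "zone": r.get("zone", ""),
            "tissue": tissue, "replicate": replicate,
        })
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return records, truth


def _inject_mismatches(rows, cfg, rng):
    for r in rows:
        rate = cfg.mismatch_rate.get(r["true_class"], 0.0)
        if rate <= 0:
            continue
        seq = list(r["sequence"])
        for i in range(len(seq)):
            if rng.random() < rate:
                seq[i] = "ACGT"[(("ACGT".index(seq[i])) +
                                 int(rng.integers(1, 4))) % 4]
        r["sequence"] = "".join(seq)


def _gen_mirna(bundle, cfg, rng, n):
    weights = bundle.mature_weights
    if cfg.mirna_weights is not None:
        weights = np.array([
            cfg.mirna_weights.get(mid, 0.0) for mid in bundle.mature_ids
        ])
        rest = 1.0 - weights.sum()
        if rest < -1e-9:
            raise ValueError("mirna_weights sum above 1")
        free = weights == 0
        if free.any() and rest > 0:
            weights = weights + free * (rest * bundle.mature_weights * free /
                                        max((bundle.mature_weights * free).sum(),
                                            1e-300))
        weights = weights / weights.sum()
    idx = rng.choice(len(bundle.mature_ids), size=n, p=weights)
    out = []
    for i in idx:
        ref = bundle.mirna_mature.references[i]
        out.append({
            "sequence": ref.sequence, "true_class": labels.MIRNA,
            "source_id": ref.id, "strand": "+", "offset": 0,
        })
    return out


def _gen_trna_rrna(bundle, cfg, rng, n):
    trna = bundle.gene_models.by_biotype("tRNA")
    rrna = bundle.gene_models.by_biotype("rRNA")
    is_trna = rng.random(n) < cfg.trna_share
    out = []
    for take_trna, group, weights in (
        (True, trna, bundle.trna_weights),
        (False, rrna, bundle.rrna_weights),
    ):
        cnt = int(is_trna.sum()) if take_trna else int((~is_trna).sum())
        if cnt == 0 or not group:
            continue
        gidx = rng.choice(len(group), size=cnt, p=weights)
        if take_trna:
            lens = _sample_lengths(rng, cnt, *cfg.trna_read_length, 15,
                                   min(50, cfg.trna_length))
        else:
            lens = rng.integers(15, 51, size=cnt)
        for gi, L in zip(gidx, lens):
            g = group[gi]
            L = int(min(L, g.end - g.start))
            off = int(rng.integers(0, (g.end - g.start) - L + 1))
            window = bundle.chrom_seqs[g.chrom][g.start + off : g.start + off + L]
            seq = window if g.strand == "+" else revcomp(window)
            out.append({
                "sequence": seq, "true_class": labels.TRNA_RRNA,
                "source_id": g.gene_id, "strand": g.strand, "offset": off,
            })
    return out


def _gen_te_pirna(bundle, cfg, rng, n):
    classes = list(cfg.te_class_mixture)
    cls_p = np.array([cfg.te_class_mixture[c] for c in classes], float)
    cls_p /= cls_p.sum()
    cls_idx = rng.choice(len(classes), size=n, p=cls_p)
    is_multi = rng.random(n) < cfg.multi_fraction
    antisense = rng.random(n) < cfg.antisense_prob
    lens = _pmf_choice(rng, cfg.pirna_length_pmf, n)
    shares = np.array([s for (_c, _b, s) in cfg.clusters], float) / 100.0
    zone_p = np.concatenate([shares, [1.0 - shares.sum()]])
    if zone_p[-1] < 0:
        raise ValueError("cluster shares exceed 100%")
    zone_names = [f"cluster{i}" for i in range(len(cfg.clusters))] + ["background"]
    out = []
    for i in range(n):
        cls = classes[cls_idx[i]]
        L = int(lens[i])
        sense = not antisense[i]
        if is_multi[i]:
            fam = _choice(rng, bundle.te_multi[cls])
            chrom, start = fam["copies"][int(rng.integers(len(fam["copies"])))]
            locus_len, te_id, zone = fam["length"], fam["te_id"], "multi"
        else:
            zone = zone_names[int(rng.choice(len(zone_p), p=zone_p))]
            loci = bundle.te_single[cls].get(zone) or []
            if not loci:
                zone = "background"
                loci = bundle.te_single[cls]["background"]
            loc = loci[int(rng.integers(len(loci)))]
            chrom, start, locus_len, te_id = (loc.chrom, loc.start,
                                              loc.length, loc.te_id)
        want_1u = rng.random() < cfg.p1u
        want_10a = sense and (rng.random() < cfg.p10a_sense)
        cseq = bundle.chrom_seqs[chrom]
        seq, off = None, 0
        for _try in range(100):
            off = int(rng.integers(0, locus_len - L + 1))
            w = cseq[start + off : start + off + L]
            cand = w if sense else revcomp(w)
            ok = (cand[0] == "T") == want_1u
            if ok and sense and cfg.p10a_sense > 0:
                ok = (cand[9] == "A") == want_10a
            if ok:
                seq = cand
                break
        if seq is None:  # bias not satisfiable in this locus; take the draw
            seq = w if sense else revcomp(w)
        out.append({
            "sequence": seq, "true_class": labels.TE_PIRNA,
            "source_id": te_id, "strand": "+" if sense else "-",
            "offset": off, "multi": bool(is_multi[i]), "zone": zone,
        })
    return out


def _choice(rng, seq):
    return seq[int(rng.integers(len(seq)))]


def _gen_mrna(bundle, cfg, rng, n):
    genes = bundle.gene_models.by_biotype("mRNA")
    weights = bundle.mrna_weights
    if cfg.mrna_gene_weights is not None:
        weights = np.asarray(cfg.mrna_gene_weights, float)
        weights = weights / weights.sum()
    d = cfg.mrna_dominant_share
    # conditional shares for the non-dominant draw so that the *overall*
    # 3'UTR and sense shares equal the configured values
    q = {
        UTR5: cfg.mrna_feature_shares[UTR5] / (1 - d) if d < 1 else 0.0,
        CDS: cfg.mrna_feature_shares[CDS] / (1 - d) if d < 1 else 0.0,
        UTR3: (cfg.mrna_feature_shares[UTR3] - d) / (1 - d) if d < 1 else 1.0,
    }
    feat_names = [UTR5, CDS, UTR3]
    feat_p = np.array([q[f] for f in feat_names], float)
    feat_p = feat_p / feat_p.sum()
    sense_q = (cfg.mrna_sense_prob - d) / (1 - d) if d < 1 else 1.0
    gidx = rng.choice(len(genes), size=n, p=weights)
    dominant = rng.random(n) < d
    out = []
    lo, hi = cfg.mrna_read_bounds
    for i in range(n):
        g = genes[gidx[i]]
        if dominant[i]:
            seq, _ = bundle.mrna_dominant[g.gene_id]
            out.append({
                "sequence": seq, "true_class": labels.MRNA_DERIVED,
                "source_id": g.gene_id, "strand": g.strand,
                "offset": 0, "feature": UTR3, "sense": True,
            })
            continue
        feat = feat_names[int(rng.choice(3, p=feat_p))]
        sense = rng.random() < sense_q
        fs, fe = g.features[feat][0]
        L = int(min(_sample_lengths(rng, 1, *cfg.mrna_read_length, lo, hi)[0],
                    fe - fs))
        off = int(rng.integers(0, (fe - fs) - L + 1))
        w = bundle.chrom_seqs[g.chrom][fs + off : fs + off + L]
        sense_read = w if g.strand == "+" else revcomp(w)
        seq = sense_read if sense else revcomp(sense_read)
        out.append({
            "sequence": seq, "true_class": labels.MRNA_DERIVED,
            "source_id": g.gene_id,
            "strand": g.strand if sense else ("-" if g.strand == "+" else "+"),
            "offset": off, "feature": feat, "sense": bool(sense),
        })
    return out


def _gen_unannotated(bundle, cfg, rng, n):
    ivs = bundle.intergenic
    lens = _sample_lengths(rng, n, *cfg.unannotated_length, 15, 50)
    w = np.array([e - s for (_c, s, e) in ivs], float)
    w /= w.sum()
    iidx = rng.choice(len(ivs), size=n, p=w)
    out = []
    for i in range(n):
        chrom, s, e = ivs[iidx[i]]
        L = int(min(lens[i], e - s))
        off = int(rng.integers(0, (e - s) - L + 1))
        window = bundle.chrom_seqs[chrom][s + off : s + off + L]
        strand = "+" if rng.random() < 0.5 else "-"
        out.append({
            "sequence": window if strand == "+" else revcomp(window),
            "true_class": labels.UNANNOTATED, "source_id": "intergenic",
            "strand": strand, "offset": s + off,
        })
    return out


def _gen_unmappable(bundle, cfg, rng, n):
    lens = _sample_lengths(rng, n, *cfg.unannotated_length, 15, 50)
    seqs = [decode(rng.integers(0, 4, size=int(L), dtype=np.uint8))
            for L in lens]
    # verify absence from the genome (both strands, 0 mismatches)
    for _round in range(10):
        res = map_reads(seqs, bundle.genome, 0, "all")
        bad = [i for i in range(len(seqs)) if res.hits[i]]
        if not bad:
            break
        for i in bad:
            seqs[i] = decode(rng.integers(0, 4, size=len(seqs[i]),
                                          dtype=np.uint8))
    return [{"sequence": s, "true_class": labels.UNMAPPABLE,
             "source_id": "random", "strand": ".", "offset": -1}
            for s in seqs]


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_simulation(
    bundle: SimulatedBundle,
    outdir: str | Path,
    libraries: Iterable[tuple[list, pd.DataFrame, str]],
    gzip_fastq: bool = False,
) -> None:
    """Write references plus (records, truth, library-id) triples."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.write(outdir)
    for records, truth, lib_id in libraries:
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        write_fastq(records, outdir / f"{lib_id}{suffix}")
        truth.to_csv(outdir / f"{lib_id}.truth.tsv", sep="\t", index=False)
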