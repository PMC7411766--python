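"""Sequential-depletion annotation of small RNA reads.

Reads are first mapped to the genome (failures become ``unmapped``), then
classified through an ordered cascade where the earlier stage always
wins: (1) miRNA — exact match to a mature reference or a genome hit
inside an annotated hairpin window; (2) tRNA/rRNA — a genome hit inside
a tRNA or rRNA gene model; (3) TE-piRNA — a match to the transposable
element consensus library at up to 2 mismatches; (4) mRNA-derived — a
genome hit inside a protein-coding gene model; the remainder is
``unannotated``. The module also provides miRNA homolog discovery by
ungapped identity scoring, locus-window quantitation, tissue-enrichment
testing (one-way ANOVA + Tukey HSD), and AGO-IP cross-referencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import labels
from .io import CollapsedRead, Library, rpm
from .mapping import Hit, MappingResult, best_te_hit, map_reads
from .mrna import assign_feature, attributed_feature
from .references import Reference, ReferenceBundle, ReferenceSet


@dataclass
class CascadeParams:
    """Stage mapping parameters. Genome/gene-model stages default to exact
    matching; the TE stage allows 2 mismatches."""

    genome_max_mismatches: int = 0
    mirna_max_mismatches: int = 0
    te_max_mismatches: int = 2
    alpha: float = 0.05


#: The shipped stage order (earlier stage always wins).
STAGE_ORDER = (labels.MIRNA, labels.TRNA_RRNA, labels.TE_PIRNA,
               labels.MRNA_DERIVED)


@dataclass
class ReadAnnotation:
    """Everything the cascade decided about one collapsed read."""

    label: str
    genome_hits: list[Hit] = field(default_factory=list)
    te_hit: Hit | None = None
    te_class: str | None = None
    gene_id: str | None = None          # tRNA/rRNA or mRNA gene
    gene_biotype: str | None = None
    feature: str | None = None          # 5'UTR | CDS | 3'UTR | junction
    feature_attr: str | None = None     # junction attributed to 5'-end feature
    sense: bool | None = None           # relative to the gene / TE consensus
    mirna_id: str | None = None

    @property
    def n_genome_hits(self) -> int:
        return len(self.genome_hits)

    @property
    def unique_mapping(self) -> bool:
        return len(self.genome_hits) == 1


@dataclass
class ClassificationResult:
    """Cascade output for one library."""

    library: Library
    annotations: list[ReadAnnotation]
    composition: pd.Series          # label -> percent of trimmed reads
    size_histogram: pd.DataFrame    # length x label -> read count
    depletion_log: pd.DataFrame     # stage, remaining_before, assigned

    @property
    def reads(self) -> list[CollapsedRead]:
        return self.library.reads

    def _weights(self) -> np.ndarray:
        lib = self.library.library_id
        return np.array([r.count(lib) for r in self.reads], dtype=np.int64)

    def label_counts(self) -> pd.Series:
        w = self._weights()
        out = {lab: 0 for lab in labels.CLASS_LABELS}
        for ann, c in zip(self.annotations, w):
            out[ann.label] += int(c)
        return pd.Series(out)

    def mapped_total(self) -> int:
        """Genome-mapped read count (the default RPM denominator)."""
        w = self._weights()
        return int(sum(
            c for ann, c in zip(self.annotations, w)
            if ann.label != labels.UNMAPPED
        ))

    # -- tables consumed by the piRNA / mRNA statistics modules -------------
    def te_table(self) -> pd.DataFrame:
        """Per TE-piRNA read: count, attributed TE, class, strand, length."""
        lib = self.library.library_id
        rows = [
            {
                "sequence": r.sequence, "count": r.count(lib),
                "te_id": ann.te_hit.ref_id, "te_class": ann.te_class,
                "strand": ann.te_hit.strand, "start": ann.te_hit.start,
                "length": r.length,
            }
            for r, ann in zip(self.reads, self.annotations)
            if ann.label == labels.TE_PIRNA
        ]
        return pd.DataFrame(
            rows, columns=["sequence", "count", "te_id", "te_class",
                           "strand", "start", "length"],
        )

    def genome_table(self, label: str | None = labels.TE_PIRNA) -> pd.DataFrame:
        """Per-read genome mapping summary (optionally one class only)."""
        lib = self.library.library_id
        rows = []
        for r, ann in zip(self.reads, self.annotations):
            if label is not None and ann.label != label:
                continue
            if not ann.genome_hits:
                continue
            h = ann.genome_hits[0]
            rows.append({
                "sequence": r.sequence, "count": r.count(lib),
                "chrom": h.ref_id, "start": h.start, "strand": h.strand,
                "n_hits": ann.n_genome_hits, "unique": ann.unique_mapping,
                "length": r.length,
            })
        return pd.DataFrame(
            rows, columns=["sequence", "count", "chrom", "start", "strand",
                           "n_hits", "unique", "length"],
        )

    def mrna_table(self) -> pd.DataFrame:
        """Per mRNA-derived read: gene, feature assignment, orientation."""
        lib = self.library.library_id
        rows = [
            {
                "sequence": r.sequence, "count": r.count(lib),
                "gene_id": ann.gene_id, "feature": ann.feature,
                "feature_attr": ann.feature_attr, "sense": ann.sense,
                "length": r.length,
            }
            for r, ann in zip(self.reads, self.annotations)
            if ann.label == labels.MRNA_DERIVED
        ]
        return pd.DataFrame(
            rows, columns=["sequence", "count", "gene_id", "feature",
                           "feature_attr", "sense", "length"],
        )

    def trna_rrna_table(self) -> pd.DataFrame:
        """Per tRNA/rRNA read: attributed gene and biotype."""
        lib = self.library.library_id
        rows = [
            {
                "sequence": r.sequence, "count": r.count(lib),
                "gene_id": ann.gene_id, "biotype": ann.gene_biotype,
                "length": r.length,
            }
            for r, ann in zip(self.reads, self.annotations)
            if ann.label == labels.TRNA_RRNA
        ]
        return pd.DataFrame(
            rows, columns=["sequence", "count", "gene_id", "biotype",
                           "length"],
        )


def classify(
    library: Library,
    bundle: ReferenceBundle,
    params: CascadeParams | None = None,
    stage_order: Sequence[str] = STAGE_ORDER,
) -> ClassificationResult:
    """Run the depletion cascade on one library.

    ``stage_order`` permutes stages 2-5 (the genome-mapping gate always
    runs first); the shipped order is miRNA -> tRNA/rRNA -> TE-piRNA ->
    mRNA-derived. Raises KeyError naming the stage when the bundle lacks
    a reference set.
    """
    params = params or CascadeParams()
    if set(stage_order) != set(STAGE_ORDER):
        raise ValueError(f"stage_order must permute {STAGE_ORDER}")
    for slot, stage in [("genome", "genome"), ("mirna_mature", "miRNA"),
                        ("gene_models", "tRNA/rRNA+mRNA"), ("te", "TE")]:
        if getattr(bundle, slot, None) is None:
            raise KeyError(f"reference bundle missing {slot!r} "
                           f"(required by stage {stage})")
    reads = library.reads
    n = len(reads)
    genome_res = map_reads(reads, bundle.genome,
                           params.genome_max_mismatches, report="best")
    ann = [ReadAnnotation(label="", genome_hits=genome_res.hits[i])
           for i in range(n)]
    remaining = []
    for i in range(n):
        if not ann[i].genome_hits:
            ann[i].label = labels.UNMAPPED
        else:
            remaining.append(i)

    weights = np.array([r.count(library.library_id) for r in reads],
                       dtype=np.int64)
    log_rows = [{
        "stage": "genome", "remaining_before": int(weights.sum()),
        "assigned": int(weights.sum() - weights[remaining].sum()),
        "label": labels.UNMAPPED,
    }]

    matchers = {
        labels.MIRNA: _match_mirna,
        labels.TRNA_RRNA: _match_trna_rrna,
        labels.TE_PIRNA: _match_te,
        labels.MRNA_DERIVED: _match_mrna,
    }
    for stage in stage_order:
        before = int(weights[remaining].sum())
        matched = matchers[stage](reads, remaining, ann, bundle, params)
        for i in matched:
            ann[i].label = stage
        matched_set = set(matched)
        remaining = [i for i in remaining if i not in matched_set]
        log_rows.append({
            "stage": stage, "remaining_before": before,
            "assigned": int(weights[list(matched_set)].sum()) if matched_set else 0,
            "label": stage,
        })
    for i in remaining:
        ann[i].label = labels.UNANNOTATED
    log_rows.append({
        "stage": "remainder",
        "remaining_before": int(weights[remaining].sum()),
        "assigned": int(weights[remaining].sum()),
        "label": labels.UNANNOTATED,
    })

    total = int(weights.sum())
    comp = {lab: 0.0 for lab in labels.CLASS_LABELS}
    hist: dict[tuple[int, str], int] = {}
    for i in range(n):
        lab = ann[i].label
        comp[lab] += float(weights[i])
        key = (reads[i].length, lab)
        hist[key] = hist.get(key, 0) + int(weights[i])
    composition = pd.Series(
        {lab: (100.0 * v / total if total else 0.0) for lab, v in comp.items()}
    )
    size_hist = pd.DataFrame(
        0, index=range(15, 51), columns=list(labels.CLASS_LABELS),
    )
    for (length, lab), c in hist.items():
        size_hist.loc[length, lab] += c
    return ClassificationResult(
        library=library,
        annotations=ann,
        composition=composition,
        size_histogram=size_hist,
        depletion_log=pd.DataFrame(log_rows),
    )


# -- stage matchers ----------------------------------------------------------

def _match_mirna(reads, remaining, ann, bundle, params):
    sub = [reads[i] for i in remaining]
    mat = map_reads(sub, bundle.mirna_mature, params.mirna_max_mismatches,
                    report="best")
    hp_index = bundle.hairpin_index
    matched = []
    for j, i in enumerate(remaining):
        mirna_id = None
        if mat.hits[j]:
            mirna_id = mat.hits[j][0].ref_id
        else:
            L = reads[i].length
            for h in ann[i].genome_hits:
                hp = hp_index.query_first(h.ref_id, h.start, h.start + L)
                if hp is not None:
                    mirna_id = hp
                    break
        if mirna_id is not None:
            ann[i].mirna_id = mirna_id
            matched.append(i)
    return matched


def _match_trna_rrna(reads, remaining, ann, bundle, params):
    index = bundle.gene_models.trna_rrna_index
    matched = []
    for i in remaining:
        L = reads[i].length
        found = []
        for h in ann[i].genome_hits:
            found.extend(index.query(h.ref_id, h.start, h.start + L))
        if found:
            # a read hitting both biotypes attributes to tRNA (documented
            # tie-break), then lexicographic gene id
            found.sort(key=lambda p: (p[1] != "tRNA", p[0]))
            ann[i].gene_id, ann[i].gene_biotype = found[0]
            matched.append(i)
    return matched


def _match_te(reads, remaining, ann, bundle, params):
    sub = [reads[i] for i in remaining]
    res = map_reads(sub, bundle.te, params.te_max_mismatches, report="best")
    matched = []
    for j, i in enumerate(remaining):
        if res.hits[j]:
            hit = best_te_hit(res.hits[j])
            ann[i].te_hit = hit
            ann[i].te_class = bundle.te.get(hit.ref_id).metadata["class"]
            ann[i].sense = hit.strand == "+"
            matched.append(i)
    return matched


def _match_mrna(reads, remaining, ann, bundle, params):
    index = bundle.gene_models.mrna_index
    matched = []
    for i in remaining:
        L = reads[i].length
        assigned = None
        for h in ann[i].genome_hits:
            gene_ids = index.query(h.ref_id, h.start, h.start + L)
            if gene_ids:
                gene = bundle.gene_models.get(sorted(gene_ids)[0])
                assigned = (h, gene)
                break
        if assigned is None:
            continue
        h, gene = assigned
        ann[i].gene_id = gene.gene_id
        ann[i].gene_biotype = "mRNA"
        ann[i].sense = h.strand == gene.strand
        ann[i].feature = assign_feature(h.ref_id, h.start, h.start + L, gene)
        ann[i].feature_attr = attributed_feature(
            h.ref_id, h.start, h.start + L, h.strand, gene
        )
        matched.append(i)
    return matched


# ---------------------------------------------------------------------------
# miRNA homolog discovery
# ---------------------------------------------------------------------------

@dataclass
class MirnaCandidate:
    """A putative miRNA homolog recovered from unannotated reads."""

    sequence: str
    total_reads: int
    best_match: str
    best_species: str
    mismatches: int
    homology_score: float   # percent identity 0-100 over the read length
    locus: tuple[str, int] | None = None   # (chromosome, window start)


def _best_ungapped(read: str, ref: str) -> int | None:
    """Minimum mismatch count over all ungapped full-overlap offsets.

    The shorter sequence slides along the longer; when the read is the
    longer one, its overhanging bases count as mismatches. Returns None
    for an empty reference.
    """
    if not ref:
        return None
    if len(read) <= len(ref):
        best = None
        for off in range(len(ref) - len(read) + 1):
            mm = sum(a != b for a, b in zip(read, ref[off:off + len(read)]))
            if best is None or mm < best:
                best = mm
        return best
    extra = len(read) - len(ref)
    best = None
    for off in range(extra + 1):
        mm = sum(a != b for a, b in zip(read[off:off + len(ref)], ref))
        if best is None or mm < best:
            best = mm
    return best + extra


def discover_mirna_homologs(
    reads: Iterable[CollapsedRead],
    mirna_db: ReferenceSet,
    min_reads: int = 200,
    size_range: tuple[int, int] = (20, 25),
    max_mismatches: int = 3,
    min_score: float = 80.0,
    genome: ReferenceSet | None = None,
) -> list[MirnaCandidate]:
    """Screen unannotated reads against a mature-miRNA database.

    Candidates must be in the size window (default 20-25 nt), carry
    strictly more than ``min_reads`` total reads, and align ungapped to
    some database mature with at most ``max_mismatches`` and identity
    score ``100 * (1 - mm / len)`` of at least ``min_score``. When a
    genome is supplied, the candidate locus is located by exact mapping
    and reported as (chromosome, 100-kb window start).
    """
    if len(mirna_db) == 0:
        raise ValueError("miRNA database is empty")
    lo, hi = size_range
    out: list[MirnaCandidate] = []
    for read in reads:
        if not (lo <= read.length <= hi) or read.total <= min_reads:
            continue
        best: tuple[int, str, str] | None = None
        for ref in mirna_db:
            mm = _best_ungapped(read.sequence, ref.sequence)
            if mm is not None and (best is None or mm < best[0]):
                best = (mm, ref.id, ref.metadata.get("species", ""))
        if best is None or best[0] > max_mismatches:
            continue
        score = 100.0 * (1.0 - best[0] / read.length)
        if score < min_score:
            continue
        locus = None
        if genome is not None:
            res = map_reads([read.sequence], genome, 0, "best")
            if res.hits[0]:
                h = res.hits[0][0]
                locus = (h.ref_id, (h.start // 100_000) * 100_000)
        out.append(MirnaCandidate(
            sequence=read.sequence, total_reads=read.total,
            best_match=best[1], best_species=best[2],
            mismatches=best[0], homology_score=score, locus=locus,
        ))
    out.sort(key=lambda c: (-c.total_reads, c.sequence))
    return out


# ---------------------------------------------------------------------------
# Locus quantitation / enrichment / AGO loading
# ---------------------------------------------------------------------------

def quantify_locus(
    reads: Iterable[CollapsedRead],
    genome: ReferenceSet,
    window: tuple[str, int, int],
    denominators: dict[str, int],
) -> dict[str, float]:
    """RPM of reads mapping inside a genome window, per library.

    The window sub-sequence is extracted and reads are matched exactly
    (0 mismatches, both strands) against it, mirroring quantitation
    against a retrieved locus reference.
    """
    chrom, start, end = window
    ref = genome.get(chrom)
    if not 0 <= start < end <= len(ref):
        raise ValueError(f"window {chrom}:{start}-{end} outside reference")
    sub = ReferenceSet(
        f"{chrom}:{start}-{end}", "locus",
        [Reference(f"{chrom}:{start}-{end}", ref.sequence[start:end])],
    )
    reads = list(reads)
    res = map_reads(reads, sub, 0, "all")
    totals: dict[str, int] = {lib: 0 for lib in denominators}
    for r, hits in zip(reads, res.hits):
        if not hits:
            continue
        for lib, c in r.counts.items():
            totals[lib] = totals.get(lib, 0) + c
    return {lib: rpm(totals.get(lib, 0), denom)
            for lib, denom in denominators.items()}


@dataclass
class EnrichmentCall:
    """Per-feature tissue-enrichment verdict."""

    feature_id: str
    means: dict[str, float]
    sems: dict[str, float]
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame      # group1, group2, p_adj
    enriched: str | None     # tissue, or None


def tissue_enrichment(
    values: dict[str, Sequence[float]],
    alpha: float = 0.05,
    feature_id: str = "",
) -> EnrichmentCall:
    """One-way ANOVA + Tukey HSD across tissues of replicate RPM values.

    A tissue is called enriched only when it holds the strict maximum
    mean and every pairwise Tukey comparison against it is significant at
    ``alpha``. Identical values everywhere return F=0 and no call.
    """
    tissues = sorted(values)
    if len(tissues) < 2 or any(len(values[t]) < 2 for t in tissues):
        raise ValueError("need >= 2 tissues with >= 2 replicates each")
    groups = [np.asarray(values[t], dtype=float) for t in tissues]
    means = {t: float(np.mean(g)) for t, g in zip(tissues, groups)}
    sems = {t: float(np.std(g, ddof=1) / np.sqrt(len(g)))
            for t, g in zip(tissues, groups)}
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        tukey = pd.DataFrame(columns=["group1", "group2", "p_adj"])
        return EnrichmentCall(feature_id, means, sems, 0.0, 1.0, tukey, None)
    if all(np.allclose(g, g[0]) for g in groups):
        # zero within-group variance but unequal means: infinitely strong
        f_stat, p_val = float("inf"), 0.0
        rows = [
            {"group1": a, "group2": b,
             "p_adj": 0.0 if means[a] != means[b] else 1.0}
            for ai, a in enumerate(tissues) for b in tissues[ai + 1:]
        ]
        tukey = pd.DataFrame(rows)
    else:
        f_stat, p_val = stats.f_oneway(*groups)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels_flat = np.concatenate(
            [[t] * len(g) for t, g in zip(tissues, groups)]
        )
        hsd = pairwise_tukeyhsd(flat, labels_flat, alpha=alpha)
        tukey = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0],
        )[["group1", "group2", "p-adj"]].rename(columns={"p-adj": "p_adj"})
        tukey["p_adj"] = tukey["p_adj"].astype(float)
    top = max(tissues, key=lambda t: means[t])
    is_strict_max = all(means[top] > means[t] for t in tissues if t != top)
    enriched: str | None = None
    if is_strict_max:
        involved = tukey[(tukey["group1"] == top) | (tukey["group2"] == top)]
        if len(involved) == len(tissues) - 1 and \
                (involved["p_adj"] < alpha).all():
            enriched = top
    return EnrichmentCall(feature_id, means, sems, float(f_stat),
                          float(p_val), tukey, enriched)


def cross_reference_ago(
    ago_library: Library,
    candidates: Iterable[MirnaCandidate | str],
    bundle: ReferenceBundle,
    params: CascadeParams | None = None,
) -> pd.DataFrame:
    """AGO-loading of candidate miRNAs in an immunoprecipitation library.

    For each candidate (a MirnaCandidate or a raw mature sequence), counts
    reads in the AGO library matching it exactly in the mature's own
    orientation, reports the share of the library's annotated-miRNA
    total, and ranks candidates by count. Candidates absent from the
    library get count 0 and no rank.
    """
    result = classify(ago_library, bundle, params)
    mirna_total = int(result.label_counts()[labels.MIRNA])
    cand_seqs = []
    for c in candidates:
        cand_seqs.append(c.sequence if isinstance(c, MirnaCandidate) else c)
    refset = ReferenceSet(
        "candidates", "miRNA",
        [Reference(f"cand{i}", s) for i, s in enumerate(cand_seqs)],
    )
    res = map_reads(ago_library.reads, refset, 0, "all")
    lib = ago_library.library_id
    counts = np.zeros(len(cand_seqs), dtype=np.int64)
    for r, hits in zip(ago_library.reads, res.hits):
        matched = {refset.ids.index(h.ref_id) for h in hits
                   if h.strand == "+"}
        for ref_idx in matched:
            counts[ref_idx] += r.count(lib)
    table = pd.DataFrame({
        "candidate": cand_seqs,
        "count": counts,
        "share_pct": np.where(
            mirna_total > 0, 100.0 * counts / max(mirna_total, 1), 0.0
        ),
    })
    order = table["count"].rank(method="min", ascending=False)
    table["rank"] = np.where(table["count"] > 0, order, np.nan)
    return table
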