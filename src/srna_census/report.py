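"""Tables, heatmap matrices, clustering, and the end-to-end pipeline.

``run_pipeline`` drives trim -> collapse -> cascade -> piRNA stats ->
mRNA-derived calling -> reports from a single YAML config, either over
simulated libraries (a simulation preset) or over user-supplied FASTQ +
reference paths, and writes TSV/BED outputs plus a manifest. Outputs are
byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage

from . import __version__, labels
from .cascade import CascadeParams, ClassificationResult, classify
from .io import DEFAULT_ADAPTER, load_library, prepare_library, rpm
from .mrna import call_candidates, candidates_frame
from .pirna import (
    bin_unique_reads,
    call_clusters,
    chromosome_contribution,
    clusters_to_bed,
    positional_bias,
    strand_fractions,
    te_class_breakdown,
)
from .references import ReferenceBundle
from .sim import SimConfig, build_genome, simulate_library, write_simulation


class PipelineError(RuntimeError):
    """Raised with the failing stage name in the message."""


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def composition_table(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    """Per-tissue mean +/- SEM of class percentages over replicates.

    SEM = sd / sqrt(n) with n the replicate count; a single replicate
    reports SEM 0.
    """
    rows = []
    for res in results:
        row = {"tissue": res.library.tissue,
               "library": res.library.library_id}
        row.update(res.composition.to_dict())
        rows.append(row)
    per_lib = pd.DataFrame(rows)
    if per_lib.empty:
        return per_lib
    out_rows = []
    for tissue, grp in per_lib.groupby("tissue", sort=True):
        n = len(grp)
        for stat in ("mean", "sem"):
            row = {"tissue": tissue, "stat": stat, "n_replicates": n}
            for lab in labels.CLASS_LABELS:
                vals = grp[lab].to_numpy(dtype=float)
                if stat == "mean":
                    row[lab] = float(vals.mean())
                else:
                    row[lab] = (float(vals.std(ddof=1) / np.sqrt(n))
                                if n > 1 else 0.0)
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def trna_rrna_rpm_table(results: Sequence[ClassificationResult],
                        denominator: str = "mapped") -> pd.DataFrame:
    """Per-gene RPM of tRNA/rRNA-attributed reads, libraries as columns."""
    if denominator not in ("mapped", "trimmed"):
        raise ValueError("denominator must be 'mapped' or 'trimmed'")
    cols = {}
    for res in results:
        denom = (res.mapped_total() if denominator == "mapped"
                 else res.library.total_trimmed)
        table = res.trna_rrna_table()
        per_gene = (table.groupby("gene_id")["count"].sum()
                    if not table.empty else pd.Series(dtype=np.int64))
        cols[res.library.library_id] = per_gene.map(
            lambda c: rpm(c, denom)) if denom > 0 else per_gene * 0.0
    out = pd.DataFrame(cols).fillna(0.0)
    out.index.name = "gene_id"
    return out.sort_index()


def filter_abundance(rpm_table: pd.DataFrame,
                     threshold_log10: float = 1.0) -> pd.DataFrame:
    """Keep rows whose per-row maximum RPM exceeds 10**threshold."""
    if rpm_table.empty:
        return rpm_table
    keep = rpm_table.max(axis=1) > 10.0 ** threshold_log10
    return rpm_table.loc[keep]


class HeatmapMatrix:
    """log10(RPM) matrix with row/column linkage trees and leaf orders."""

    def __init__(self, values: pd.DataFrame, row_linkage, col_linkage,
                 row_order: list, col_order: list):
        self.values = values
        self.row_linkage = row_linkage
        self.col_linkage = col_linkage
        self.row_order = row_order
        self.col_order = col_order

    def ordered(self) -> pd.DataFrame:
        return self.values.iloc[self.row_order, self.col_order]


def hierarchical_cluster(matrix: pd.DataFrame, metric: str = "euclidean",
                         method: str = "average") -> HeatmapMatrix:
    """Agglomerative clustering of rows and columns of a matrix.

    Ties are broken by input index (scipy's deterministic ordering), so
    repeated runs on the same matrix give the same tree. A single row
    (or column) yields a trivial tree.
    """
    if matrix.shape[0] < 1:
        raise ValueError("matrix must have at least one row")

    def _link(data):
        if data.shape[0] < 2:
            return None, [0] * min(1, data.shape[0]) or [0]
        lk = linkage(data, method=method, metric=metric)
        return lk, list(leaves_list(lk))

    row_linkage, row_order = _link(matrix.to_numpy(dtype=float))
    col_linkage, col_order = _link(matrix.to_numpy(dtype=float).T)
    if matrix.shape[0] == 1:
        row_order = [0]
    if matrix.shape[1] == 1:
        col_order = [0]
    return HeatmapMatrix(matrix, row_linkage, col_linkage, row_order,
                         col_order)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _build_inputs(cfg: dict, outdir: Path):
    """Resolve references + libraries from a simulation preset or paths."""
    params_cfg = cfg.get("params", {})
    adapter = params_cfg.get("adapter", DEFAULT_ADAPTER)
    if "simulate" in cfg:
        sim_cfg_dict = dict(cfg["simulate"])
        tissues = sim_cfg_dict.pop("tissues", {"OV": 3})
        n_reads = sim_cfg_dict.pop("n_reads", 20_000)
        sim = SimConfig(seed=int(cfg.get("seed", 0)), n_reads=n_reads,
                        adapter=adapter, **sim_cfg_dict)
        bundle = build_genome(sim)
        libs = []
        sim_outputs = []
        for tissue in sorted(tissues):
            for rep in range(1, int(tissues[tissue]) + 1):
                records, truth = simulate_library(bundle, tissue=tissue,
                                                  replicate=rep)
                lib_id = f"{tissue}-{rep}"
                libs.append(prepare_library(records, lib_id, tissue, rep,
                                            adapter=adapter))
                sim_outputs.append((records, truth, lib_id))
        write_simulation(bundle, outdir / "simulated", sim_outputs)
        return bundle, libs
    if "inputs" not in cfg:
        raise PipelineError("config: need a 'simulate' preset or 'inputs'")
    inputs = cfg["inputs"]
    for key, stage in [("genome", "cascade/genome"),
                       ("mirna_mature", "cascade/miRNA"),
                       ("gene_models", "cascade/gene-models"),
                       ("te", "cascade/TE")]:
        if key not in inputs:
            raise PipelineError(f"{stage}: missing input {key!r}")
        if not Path(inputs[key]).exists():
            raise PipelineError(f"{stage}: {inputs[key]} not found")
    from .references import GeneModelSet, HairpinLocus, ReferenceSet

    hairpins = []
    if inputs.get("hairpins"):
        with open(inputs["hairpins"]) as fh:
            for line in fh:
                p = line.rstrip("\n").split("\t")
                hairpins.append(HairpinLocus(p[3], p[0], int(p[1]),
                                             int(p[2])))
    bundle = ReferenceBundle(
        genome=ReferenceSet.from_fasta(inputs["genome"], "genome", "genome"),
        mirna_mature=ReferenceSet.from_fasta(inputs["mirna_mature"],
                                             "mirna_mature", "miRNA"),
        gene_models=GeneModelSet.from_gff3(inputs["gene_models"]),
        te=ReferenceSet.from_fasta(inputs["te"], "te", "TE"),
        hairpins=hairpins,
    )
    libs = []
    for spec in inputs.get("libraries", []):
        libs.append(load_library(
            spec["fastq"], spec["id"], spec.get("tissue", "other"),
            int(spec.get("replicate", 1)), adapter=adapter,
        ))
    if not libs:
        raise PipelineError("io/libraries: no libraries configured")
    return bundle, libs


def run_pipeline(config, out: str | Path | None = None,
                 stages: set[str] | None = None) -> Path:
    """Run the full analysis from a config; returns the output directory.

    ``stages`` restricts outputs to a subset of
    {classify, pirna, mrna, report}; classification always runs (it feeds
    everything downstream).
    """
    cfg = _load_config(config)
    outdir = Path(out or cfg.get("out", "census_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or {"classify", "pirna", "mrna", "report"}
    params_cfg = cfg.get("params", {})
    params = CascadeParams(
        genome_max_mismatches=int(params_cfg.get("genome_max_mismatches", 0)),
        te_max_mismatches=int(params_cfg.get("te_max_mismatches", 2)),
        alpha=float(params_cfg.get("alpha", 0.05)),
    )
    bundle, libraries = _build_inputs(cfg, outdir)

    results = []
    for lib in libraries:
        try:
            results.append(classify(lib, bundle, params))
        except KeyError as exc:
            raise PipelineError(f"cascade/{lib.library_id}: {exc}") from exc

    written: list[str] = []

    def _write(df: pd.DataFrame, name: str, index=False) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        written.append(name)

    if "classify" in stages:
        _write(composition_table(results), "composition.tsv")
        hists = []
        for res in results:
            h = res.size_histogram.copy()
            h.insert(0, "length", h.index)
            h.insert(0, "library", res.library.library_id)
            hists.append(h)
        _write(pd.concat(hists, ignore_index=True), "size_histograms.tsv")
        logs = []
        for res in results:
            log = res.depletion_log.copy()
            log.insert(0, "library", res.library.library_id)
            logs.append(log)
        _write(pd.concat(logs, ignore_index=True), "depletion_log.tsv")

    if "pirna" in stages:
        bin_size = int(params_cfg.get("cluster_bin_size", 1_000_000))
        min_share = float(params_cfg.get("min_cluster_share", 1.0))
        te_tables = [res.te_table() for res in results]
        pooled_te = (pd.concat(te_tables, ignore_index=True)
                     if te_tables else pd.DataFrame())
        if not pooled_te.empty:
            breakdown = te_class_breakdown(pooled_te)
            _write(breakdown.rename("percent").reset_index()
                   .rename(columns={"index": "te_class"}), "te_class.tsv")
            fr = strand_fractions(pooled_te)
            _write(pd.DataFrame([fr]), "te_strand.tsv")
            for length in (27, 28):
                for orient in ("sense", "antisense"):
                    pb = positional_bias(pooled_te, length, orient)
                    if pb.n_reads:
                        m = pb.matrix.copy()
                        m.insert(0, "position", m.index)
                        _write(m, f"bias_{length}nt_{orient}.tsv")
        genome_tables = [res.genome_table(labels.TE_PIRNA) for res in results]
        pooled_gt = (pd.concat(genome_tables, ignore_index=True)
                     if genome_tables else pd.DataFrame())
        if not pooled_gt.empty:
            _write(chromosome_contribution(pooled_gt), "chromosomes.tsv")
            pi_map = bin_unique_reads(pooled_gt, bin_size)
            clusters = call_clusters(pi_map, min_share)
            _write(clusters, "clusters.tsv")
            (outdir / "clusters.bed").write_text(
                clusters_to_bed(clusters, bin_size))
            written.append("clusters.bed")

    if "mrna" in stages:
        by_tissue: dict[str, list[pd.DataFrame]] = {}
        for res in results:
            by_tissue.setdefault(res.library.tissue, []).append(
                res.mrna_table())
        frames = []
        for tissue in sorted(by_tissue):
            pooled = pd.concat(by_tissue[tissue], ignore_index=True)
            cands = call_candidates(
                pooled,
                min_reads=int(params_cfg.get("mrna_min_reads", 1000)),
                min_top_fraction=float(
                    params_cfg.get("mrna_min_top_fraction", 0.10)),
            )
            frame = candidates_frame(cands)
            frame.insert(0, "tissue", tissue)
            frames.append(frame)
        _write(pd.concat(frames, ignore_index=True), "mrna_candidates.tsv")

    if "report" in stages:
        denom = params_cfg.get("rpm_denominator", "mapped")
        rpm_table = trna_rrna_rpm_table(results, denom)
        _write(rpm_table.reset_index(), "trna_rrna_rpm.tsv")
        filtered = filter_abundance(
            rpm_table, float(params_cfg.get("heatmap_log10_threshold", 1.0)))
        if filtered.shape[0] >= 1 and filtered.shape[1] >= 1:
            log_vals = np.log10(filtered.where(filtered > 0, np.nan))
            log_vals = log_vals.fillna(0.0)
            hm = hierarchical_cluster(log_vals)
            ordered = hm.ordered()
            _write(ordered.reset_index(), "heatmap_log10_rpm.tsv")

    manifest = {
        "package": "srna-census",
        "version": __version__,
        "seed": int(cfg.get("seed", 0)),
        "params": {k: params_cfg[k] for k in sorted(params_cfg)},
        "cascade_params": asdict(params),
        "libraries": sorted(lib.library_id for lib in libraries),
        "outputs": sorted(written),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
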