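"""Parameter-recovery experiments on the bundled simulator.

Each driver builds one synthetic genome, simulates replicate libraries
under the study conditions encoded in :class:`~srna_census.sim.SimConfig`
defaults, runs the full annotation path (trim -> collapse -> cascade),
and measures the statistic of interest per replicate. They back both the
validation test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import labels
from .cascade import classify
from .io import prepare_library
from .pirna import bin_unique_reads, call_clusters, strand_fractions, \
    te_class_breakdown
from .references import UTR3
from .sim import SimConfig, build_genome, simulate_library

_MOD = 2**31


def _library_seeds(seed: int, n_seeds: int) -> list[int]:
    return [(seed * 1009 + 7919 * (i + 1)) % _MOD for i in range(n_seeds)]


def _run_one(bundle, tissue, n_reads, lib_seed, class_mixture=None):
    records, _ = simulate_library(
        bundle, tissue=tissue, replicate=1, n_reads=n_reads, seed=lib_seed,
        class_mixture=class_mixture,
    )
    lib = prepare_library(records, f"{tissue}-s{lib_seed}", tissue, 1,
                          adapter=bundle.config.adapter)
    return classify(lib, bundle)


def composition_experiment(tissue: str, seed: int, n_seeds: int = 10,
                           n_reads: int = 100_000) -> pd.DataFrame:
    """Per-replicate class composition for one tissue preset.

    Returns one row per simulated replicate with the six class
    percentages as columns.
    """
    bundle = build_genome(SimConfig(seed=seed % _MOD))
    rows = []
    for lib_seed in _library_seeds(seed, n_seeds):
        res = _run_one(bundle, tissue, n_reads, lib_seed)
        rows.append(res.composition.to_dict())
    return pd.DataFrame(rows)


def te_pirna_experiment(seed: int, n_seeds: int = 10,
                        n_reads: int = 50_000) -> pd.DataFrame:
    """TE-piRNA strand, class, and multi-mapping recovery per replicate.

    Simulates pure TE-piRNA libraries and reports, per replicate: the
    antisense percentage, the per-class percentages, and the
    multi-mapping percentage of genome-mapped reads.
    """
    bundle = build_genome(SimConfig(seed=seed % _MOD))
    rows = []
    for lib_seed in _library_seeds(seed, n_seeds):
        res = _run_one(bundle, "OV", n_reads, lib_seed,
                       class_mixture={labels.TE_PIRNA: 1.0})
        tt = res.te_table()
        gt = res.genome_table(labels.TE_PIRNA)
        breakdown = te_class_breakdown(tt)
        rows.append({
            "antisense_pct": 100.0 * strand_fractions(tt)["antisense"],
            "ltr_pct": breakdown["LTR"],
            "non_ltr_pct": breakdown["non-LTR"],
            "dna_pct": breakdown["DNA"],
            "multi_pct": 100.0 * gt.loc[~gt["unique"], "count"].sum()
                         / gt["count"].sum(),
        })
    return pd.DataFrame(rows)


def cluster_experiment(seed: int, n_seeds: int = 10,
                       n_reads: int = 50_000) -> pd.DataFrame:
    """Planted piRNA-cluster share recovery per replicate.

    All TE-piRNA reads are drawn unique-mapping so that ``n_reads``
    unique mappers enter the binned genomic map; reports the top two
    called cluster shares.
    """
    cfg = SimConfig(seed=seed % _MOD, multi_fraction=0.0)
    bundle = build_genome(cfg)
    rows = []
    for lib_seed in _library_seeds(seed, n_seeds):
        res = _run_one(bundle, "OV", n_reads, lib_seed,
                       class_mixture={labels.TE_PIRNA: 1.0})
        gt = res.genome_table(labels.TE_PIRNA)
        clusters = call_clusters(
            bin_unique_reads(gt, cfg.cluster_bin_size), min_share=1.0,
        )
        rows.append({
            "top_share_pct": float(clusters["share_pct"].iloc[0]),
            "top_label": clusters["label"].iloc[0],
            "second_share_pct": float(clusters["share_pct"].iloc[1]),
            "second_label": clusters["label"].iloc[1],
        })
    return pd.DataFrame(rows)


def mrna_experiment(seed: int, n_seeds: int = 10,
                    n_reads: int = 50_000) -> pd.DataFrame:
    """3'UTR placement and sense-orientation recovery per replicate."""
    bundle = build_genome(SimConfig(seed=seed % _MOD))
    rows = []
    for lib_seed in _library_seeds(seed, n_seeds):
        res = _run_one(bundle, "FB-Ab", n_reads, lib_seed,
                       class_mixture={labels.MRNA_DERIVED: 1.0})
        mt = res.mrna_table()
        total = mt["count"].sum()
        rows.append({
            "utr3_pct": 100.0 * mt.loc[mt["feature"] == UTR3, "count"].sum()
                        / total,
            "sense_pct": 100.0 * mt.loc[mt["sense"] == True, "count"].sum()  # noqa: E712
                         / total,
        })
    return pd.DataFrame(rows)


def strand_experiment(seed: int, n_seeds: int = 10,
                      n_reads: int = 20_000) -> pd.Series:
    """Antisense-percentage recovery at the strand-analysis sample size."""
    bundle = build_genome(SimConfig(seed=seed % _MOD))
    vals = []
    for lib_seed in _library_seeds(seed, n_seeds):
        res = _run_one(bundle, "OV", n_reads, lib_seed,
                       class_mixture={labels.TE_PIRNA: 1.0})
        vals.append(100.0 * strand_fractions(res.te_table())["antisense"])
    return pd.Series(vals, name="antisense_pct")
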