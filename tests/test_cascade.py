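"""Depletion cascade, homolog discovery, enrichment, AGO loading."""

import numpy as np
import pytest

from conftest import small_config
from oracle import mutate, random_seq
from srna_census import labels
from srna_census.cascade import (
    STAGE_ORDER,
    classify,
    cross_reference_ago,
    discover_mirna_homologs,
    quantify_locus,
    tissue_enrichment,
)
from srna_census.io import CollapsedRead, Library, collapse_reads, prepare_library
from srna_census.references import (
    GeneModelSet,
    Reference,
    ReferenceBundle,
    ReferenceSet,
)
from srna_census.sim import build_genome, simulate_library


def _library(seqs, lib_id="L1", tissue="OV"):
    return Library(lib_id, tissue, 1, collapse_reads(seqs, lib_id),
                   total_raw=len(seqs), total_trimmed=len(seqs))


@pytest.fixture(scope="module")
def ambiguous_bundle():
    """A read that matches both a mature miRNA and a TE consensus."""
    rng = np.random.default_rng(33)
    mature = random_seq(rng, 22)
    te_seq = random_seq(rng, 120) + mature + random_seq(rng, 120)
    chrom = (random_seq(rng, 150) + mature + random_seq(rng, 80)
             + te_seq + random_seq(rng, 100))
    return mature, ReferenceBundle(
        genome=ReferenceSet("genome", "genome", [Reference("c1", chrom)]),
        mirna_mature=ReferenceSet("mat", "miRNA", [Reference("m1", mature)]),
        gene_models=GeneModelSet([]),
        te=ReferenceSet("te", "TE",
                        [Reference("te1", te_seq, {"class": "LTR"})]),
    )


class TestStageOrder:
    def test_mirna_wins_over_te_in_shipped_order(self, ambiguous_bundle):
        mature, bundle = ambiguous_bundle
        res = classify(_library([mature]), bundle)
        assert res.annotations[0].label == labels.MIRNA

    def test_permuted_order_changes_ambiguous_label(self, ambiguous_bundle):
        mature, bundle = ambiguous_bundle
        order = (labels.TE_PIRNA, labels.MIRNA, labels.TRNA_RRNA,
                 labels.MRNA_DERIVED)
        res = classify(_library([mature]), bundle, stage_order=order)
        assert res.annotations[0].label == labels.TE_PIRNA

    def test_unmapped_read(self, ambiguous_bundle):
        _, bundle = ambiguous_bundle
        alien = "GC" * 15
        res = classify(_library([alien]), bundle)
        assert res.annotations[0].label == labels.UNMAPPED

    def test_bad_stage_order_rejected(self, ambiguous_bundle):
        mature, bundle = ambiguous_bundle
        with pytest.raises(ValueError):
            classify(_library([mature]), bundle,
                     stage_order=(labels.MIRNA,))


@pytest.fixture(scope="module")
def recovery_run(small_bundle):
    records, truth = simulate_library(small_bundle, tissue="OV",
                                      replicate=1, n_reads=5000)
    lib = prepare_library(records, "OV-1", "OV", 1)
    return classify(lib, small_bundle), truth


class TestSimulatedRecovery:
    def test_label_agreement_with_ground_truth(self, recovery_run):
        res, truth = recovery_run
        seq2label = {r.sequence: a.label
                     for r, a in zip(res.reads, res.annotations)}
        hits = sum(
            seq2label.get(s) == labels.expected_label(c)
            for s, c in zip(truth["sequence"], truth["true_class"])
        )
        assert hits / len(truth) >= 0.99

    def test_composition_sums_to_100(self, recovery_run):
        res, _ = recovery_run
        assert res.composition.sum() == pytest.approx(100.0, abs=0.01)

    def test_label_counts_conserve_totals(self, recovery_run):
        res, _ = recovery_run
        assert int(res.label_counts().sum()) == res.library.total_trimmed

    def test_size_histogram_matches_label_counts(self, recovery_run):
        res, _ = recovery_run
        per_label = res.size_histogram.sum(axis=0)
        counts = res.label_counts()
        for lab in labels.CLASS_LABELS:
            assert per_label[lab] == counts[lab]

    def test_depletion_log_non_increasing(self, recovery_run):
        res, _ = recovery_run
        remaining = res.depletion_log["remaining_before"].to_list()
        assert remaining == sorted(remaining, reverse=True)


def test_missing_reference_names_stage(ambiguous_bundle):
    mature, bundle = ambiguous_bundle
    broken = ReferenceBundle.__new__(ReferenceBundle)
    broken.genome = bundle.genome
    broken.mirna_mature = None
    broken.gene_models = bundle.gene_models
    broken.te = bundle.te
    broken.hairpins = []
    broken._hairpin_index = None
    with pytest.raises(KeyError, match="mirna_mature"):
        classify(_library([mature]), broken)


@pytest.fixture(scope="module")
def db():
    rng = np.random.default_rng(44)
    return rng, ReferenceSet("mirbase", "miRNA", [
        Reference("dme-miR-a", random_seq(rng, 22), {"species": "dme"}),
        Reference("aae-miR-b", random_seq(rng, 21), {"species": "aae"}),
    ])


class TestHomologDiscovery:
    def test_three_mismatch_22nt_candidate_retained(self, db):
        rng, refset = db
        query = mutate(np.random.default_rng(1), refset.get("dme-miR-a").sequence, 3)
        reads = [CollapsedRead(query, {"L1": 300})]
        cands = discover_mirna_homologs(reads, refset)
        assert len(cands) == 1
        assert cands[0].mismatches == 3
        # identity score: 100 * (22 - 3) / 22
        assert cands[0].homology_score == pytest.approx(86.3636, abs=0.01)
        assert cands[0].best_match == "dme-miR-a"

    def test_low_count_candidate_excluded(self, db):
        _, refset = db
        query = mutate(np.random.default_rng(1),
                       refset.get("dme-miR-a").sequence, 3)
        assert discover_mirna_homologs(
            [CollapsedRead(query, {"L1": 150})], refset) == []

    def test_count_threshold_is_strict(self, db):
        _, refset = db
        seq = refset.get("dme-miR-a").sequence
        assert discover_mirna_homologs(
            [CollapsedRead(seq, {"L1": 200})], refset) == []
        kept = discover_mirna_homologs(
            [CollapsedRead(seq, {"L1": 201})], refset)
        assert len(kept) == 1 and kept[0].homology_score == 100.0

    def test_size_window_excludes_27nt(self, db):
        rng, refset = db
        assert discover_mirna_homologs(
            [CollapsedRead(random_seq(np.random.default_rng(2), 27),
                           {"L1": 10_000})], refset) == []

    def test_four_mismatches_excluded(self, db):
        _, refset = db
        query = mutate(np.random.default_rng(3),
                       refset.get("dme-miR-a").sequence, 4)
        assert discover_mirna_homologs(
            [CollapsedRead(query, {"L1": 500})], refset) == []

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            discover_mirna_homologs(
                [], ReferenceSet("empty", "miRNA", []))

    def test_locus_reported_when_genome_given(self, small_bundle):
        mature = small_bundle.mirna_mature.references[0]
        db = ReferenceSet("db", "miRNA",
                          [Reference("x", mature.sequence, {"species": "dme"})])
        cands = discover_mirna_homologs(
            [CollapsedRead(mature.sequence, {"L1": 500})], db,
            genome=small_bundle.genome,
        )
        assert cands[0].locus is not None
        chrom, window = cands[0].locus
        assert chrom in small_bundle.genome
        assert window % 100_000 == 0


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(55)
    chrom = random_seq(rng, 1200)
    genome = ReferenceSet("g", "genome", [Reference("c1", chrom)])
    inside = [chrom[110 + 10 * i: 130 + 10 * i] for i in range(3)]
    outside = [chrom[400 + 25 * i: 430 + 25 * i] for i in range(7)]
    reads = [CollapsedRead(s, {"L1": 1}) for s in inside + outside]
    return genome, reads


class TestQuantifyLocus:
    def test_planted_window_count(self, toy):
        genome, reads = toy
        # 3 reads inside [100, 200), 7 outside; denominator 10 reads
        out = quantify_locus(reads, genome, ("c1", 100, 200), {"L1": 10})
        assert out["L1"] == pytest.approx(3 * 1e6 / 10)

    def test_empty_window_zero(self, toy):
        genome, reads = toy
        out = quantify_locus(reads, genome, ("c1", 1000, 1100), {"L1": 10})
        assert out["L1"] == 0.0

    def test_window_outside_genome_errors(self, toy):
        genome, reads = toy
        with pytest.raises(ValueError):
            quantify_locus(reads, genome, ("c1", 900, 2000), {"L1": 10})
        with pytest.raises(KeyError):
            quantify_locus(reads, genome, ("nope", 0, 100), {"L1": 10})


class TestTissueEnrichment:
    def test_identical_values_no_enrichment(self):
        call = tissue_enrichment({t: [5.0, 5.0, 5.0]
                                  for t in ("FB-Ab", "MG", "OV", "R")})
        assert call.f_statistic == 0.0
        assert call.enriched is None

    def test_shifted_mean_enriched_and_matches_hand_anova(self):
        groups = {
            "FB-Ab": [2.0, 3.0, 4.0], "OV": [1.0, 2.0, 3.0],
            "R": [3.0, 2.0, 1.0], "MG": [52.0, 53.0, 54.0],
        }
        call = tissue_enrichment(groups, alpha=0.05)
        # textbook one-way ANOVA computed from scratch on the fixture
        all_vals = [v for g in groups.values() for v in g]
        grand = sum(all_vals) / len(all_vals)
        ss_between = sum(
            len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values()
        )
        ss_within = sum(
            (v - sum(g) / len(g)) ** 2 for g in groups.values() for v in g
        )
        f_hand = (ss_between / 3) / (ss_within / 8)
        assert call.f_statistic == pytest.approx(f_hand)
        assert call.p_value < 1e-4
        assert call.enriched == "MG"

    def test_tied_maximum_means_no_call(self):
        call = tissue_enrichment({
            "MG": [50.0, 50.0, 50.0], "OV": [50.0, 50.0, 50.0],
            "R": [1.0, 2.0, 3.0],
        })
        assert call.enriched is None

    def test_zero_variance_unequal_means(self):
        call = tissue_enrichment({
            "MG": [10.0, 10.0], "OV": [1.0, 1.0], "R": [2.0, 2.0],
        })
        assert call.p_value == 0.0
        assert call.enriched == "MG"

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            tissue_enrichment({"MG": [1.0, 2.0]})


class TestAgoLoading:
    def test_absent_candidate_zero_unranked(self, small_bundle):
        mature = small_bundle.mirna_mature.references[0].sequence
        lib = _library([mature] * 10, "AGO1", "AGO1")
        table = cross_reference_ago(lib, [mature, "GATC" * 6], small_bundle)
        present = table[table["candidate"] == mature].iloc[0]
        absent = table[table["candidate"] == "GATC" * 6].iloc[0]
        assert present["count"] == 10
        assert present["share_pct"] == pytest.approx(100.0)
        assert present["rank"] == 1
        assert absent["count"] == 0 and np.isnan(absent["rank"])

    def test_planted_share_recovered(self):
        cfg = small_config(seed=77)
        bundle = build_genome(cfg)
        target = bundle.mature_ids[0]
        cfg.mirna_weights = {target: 0.16}
        records, _ = simulate_library(
            bundle, tissue="AGO1", replicate=1, n_reads=20_000,
            class_mixture={labels.MIRNA: 1.0},
        )
        lib = prepare_library(records, "AGO1-1", "AGO1", 1)
        table = cross_reference_ago(
            lib, [bundle.mirna_mature.get(target).sequence], bundle,
        )
        assert table["share_pct"].iloc[0] == pytest.approx(16.0, abs=1.0)
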