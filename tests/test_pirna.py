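"""piRNA statistics: class breakdown, strand, signature bias, clusters."""

import numpy as np
import pandas as pd
import pytest

from oracle import random_seq
from srna_census.pirna import (
    bin_unique_reads,
    call_clusters,
    chromosome_contribution,
    positional_bias,
    signed_coverage,
    strand_fractions,
    te_class_breakdown,
    te_coverage_profile,
)
from srna_census.references import Reference, ReferenceSet
from srna_census.sequences import revcomp


def te_frame(rows):
    return pd.DataFrame(
        rows, columns=["sequence", "count", "te_id", "te_class", "strand",
                       "start", "length"],
    )


def genome_frame(rows):
    return pd.DataFrame(
        rows, columns=["sequence", "count", "chrom", "start", "strand",
                       "n_hits", "unique", "length"],
    )


SEQ27 = random_seq(np.random.default_rng(1), 27)


class TestClassBreakdown:
    def test_single_class(self):
        df = te_frame([(SEQ27, 5, "te1", "LTR", "+", 0, 27)])
        assert te_class_breakdown(df).to_dict() == {
            "LTR": 100.0, "non-LTR": 0.0, "DNA": 0.0,
        }

    def test_hand_counts(self):
        df = te_frame([
            (SEQ27, 1, "a", "LTR", "+", 0, 27),
            (SEQ27[1:] + "A", 1, "b", "LTR", "-", 3, 27),
            (SEQ27[2:] + "AC", 1, "c", "non-LTR", "+", 5, 27),
        ])
        out = te_class_breakdown(df)
        assert out["LTR"] == pytest.approx(200 / 3)
        assert out["non-LTR"] == pytest.approx(100 / 3)
        assert out["DNA"] == 0.0

    def test_count_weighting(self):
        df = te_frame([
            (SEQ27, 9, "a", "LTR", "+", 0, 27),
            ("C" + SEQ27[1:], 1, "c", "DNA", "+", 0, 27),
        ])
        assert te_class_breakdown(df)["LTR"] == pytest.approx(90.0)

    def test_missing_class_tag_errors(self):
        df = te_frame([(SEQ27, 1, "a", None, "+", 0, 27)])
        with pytest.raises(ValueError):
            te_class_breakdown(df)

    def test_totals_conserved_between_breakdown_and_strand(self):
        rng = np.random.default_rng(3)
        rows = [
            (random_seq(rng, 27), int(rng.integers(1, 9)),
             f"te{i % 4}", ["LTR", "non-LTR", "DNA"][i % 3],
             "+-"[i % 2], int(rng.integers(0, 50)), 27)
            for i in range(30)
        ]
        df = te_frame(rows)
        total = df["count"].sum()
        assert te_class_breakdown(df).sum() == pytest.approx(100.0)
        fr = strand_fractions(df)
        assert fr["sense"] + fr["antisense"] == pytest.approx(1.0)
        assert fr["sense"] * total == pytest.approx(
            df.loc[df["strand"] == "+", "count"].sum())


class TestStrandFractions:
    def test_all_antisense(self):
        df = te_frame([(SEQ27, 4, "a", "LTR", "-", 0, 27)])
        assert strand_fractions(df) == {"sense": 0.0, "antisense": 1.0}

    def test_three_to_one(self):
        df = te_frame([
            (SEQ27, 3, "a", "LTR", "+", 0, 27),
            ("A" + SEQ27[1:], 1, "a", "LTR", "-", 0, 27),
        ])
        assert strand_fractions(df) == {"sense": 0.75, "antisense": 0.25}


class TestPositionalBias:
    def test_identical_reads_give_unit_frequencies(self):
        df = te_frame([(SEQ27, 7, "a", "LTR", "+", 0, 27)])
        pb = positional_bias(df, 27, "sense")
        assert pb.n_reads == 7
        for pos, base in enumerate(SEQ27, start=1):
            rna = "U" if base == "T" else base
            assert pb.matrix.loc[pos, rna] == 1.0

    def test_hand_tabulated_frequencies(self):
        reads = ["TACG", "TGCA", "AACG", "TTTT"]
        df = te_frame([(s, 1, "a", "LTR", "+", 0, 4) for s in reads])
        pb = positional_bias(df, 4, "sense")
        assert pb.matrix.loc[1, "U"] == pytest.approx(0.75)
        assert pb.matrix.loc[1, "A"] == pytest.approx(0.25)
        assert pb.matrix.loc[2, "A"] == pytest.approx(0.5)
        assert pb.matrix.loc[4, "G"] == pytest.approx(0.5)

    def test_empty_selection(self):
        pb = positional_bias(te_frame([]), 27, "antisense")
        assert pb.n_reads == 0 and pb.matrix.empty

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(9)
        df = te_frame([
            (random_seq(rng, 28), int(rng.integers(1, 5)), "a", "LTR", "-",
             0, 28)
            for _ in range(25)
        ])
        pb = positional_bias(df, 28, "antisense")
        assert np.allclose(pb.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_revcomp_transform_maps_position_1_to_position_L(self):
        rng = np.random.default_rng(10)
        rows = [(random_seq(rng, 27), int(rng.integers(1, 6)), "a", "LTR",
                 "+", 0, 27) for _ in range(20)]
        df = te_frame(rows)
        pb = positional_bias(df, 27, "sense")
        flipped = te_frame([
            (revcomp(s), c, t, k, "-", st, ln)
            for s, c, t, k, _strand, st, ln in df.itertuples(index=False)
        ])
        pb_rc = positional_bias(flipped, 27, "antisense")
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        for base in "ACGU":
            assert pb_rc.matrix.loc[27, comp[base]] == pytest.approx(
                pb.matrix.loc[1, base])

    def test_bad_orientation_rejected(self):
        with pytest.raises(ValueError):
            positional_bias(te_frame([]), 27, "both")


@pytest.fixture(scope="module")
def te_set():
    rng = np.random.default_rng(2)
    return ReferenceSet("te", "TE", [
        Reference("te1", random_seq(rng, 100), {"class": "LTR"}),
    ])


class TestCoverage:
    def test_single_sense_read(self, te_set):
        df = te_frame([(SEQ27, 2, "te1", "LTR", "+", 0, 27)])
        track = te_coverage_profile(df, te_set, "te1")
        assert (track.loc[0:26, "sense_cov"] == 2).all()
        assert (track.loc[27:, "sense_cov"] == 0).all()
        assert track.loc[0, "sense_starts"] == 2
        assert (track["antisense_cov"] == 0).all()

    def test_overlapping_antisense_reads(self, te_set):
        df = te_frame([
            (SEQ27, 1, "te1", "LTR", "-", 10, 27),
            (SEQ27, 1, "te1", "LTR", "-", 20, 27),
        ])
        track = te_coverage_profile(df, te_set, "te1")
        # overlap [20, 37) has depth 2
        assert (track.loc[20:36, "antisense_cov"] == 2).all()
        assert track.loc[15, "antisense_cov"] == 1
        assert track.loc[40, "antisense_cov"] == 1

    def test_uniform_starts_give_flat_interior(self, te_set):
        df = te_frame([
            (SEQ27, 1, "te1", "LTR", "+", start, 27)
            for start in range(0, 74)
        ])
        track = te_coverage_profile(df, te_set, "te1")
        interior = track.loc[27:73 - 27 + 26, "sense_cov"]
        assert interior.max() <= 2 * interior.mean()

    def test_unknown_te_errors(self, te_set):
        with pytest.raises(KeyError):
            te_coverage_profile(te_frame([]), te_set, "nope")

    def test_signed_rendering_negates_antisense(self, te_set):
        df = te_frame([(SEQ27, 3, "te1", "LTR", "-", 0, 27)])
        signed = signed_coverage(te_coverage_profile(df, te_set, "te1"))
        assert signed["antisense_cov"].min() == -3
        assert (signed["sense_cov"] >= 0).all()


class TestChromosomeContribution:
    def test_single_chromosome(self):
        df = genome_frame([(SEQ27, 5, "2R", 100, "+", 1, True, 27)])
        out = chromosome_contribution(df)
        assert out["percent"].to_list() == [100.0]

    def test_hand_percentages(self):
        df = genome_frame([
            (SEQ27, 30, "c1", 0, "+", 1, True, 27),
            ("A" + SEQ27[1:], 70, "c2", 0, "+", 1, True, 27),
        ])
        out = chromosome_contribution(df).set_index("chrom")
        assert out.loc["c1", "percent"] == pytest.approx(30.0)
        assert out.loc["c2", "percent"] == pytest.approx(70.0)

    def test_empty(self):
        assert chromosome_contribution(genome_frame([])).empty

    def test_multi_mapping_reads_excluded(self):
        df = genome_frame([
            (SEQ27, 10, "c1", 0, "+", 1, True, 27),
            ("A" + SEQ27[1:], 90, "c2", 0, "+", 5, False, 27),
        ])
        out = chromosome_contribution(df)
        assert out["chrom"].to_list() == ["c1"]


class TestClusters:
    def test_single_bin_holds_everything(self):
        df = genome_frame([(SEQ27, 10, "2R", 123, "+", 1, True, 27)])
        pi_map = bin_unique_reads(df, 1_000_000)
        out = call_clusters(pi_map, 1.0)
        assert out["share_pct"].to_list() == [100.0]
        assert out["label"].to_list() == ["2R:0Mb"]

    def test_min_share_filter_hand_case(self):
        rows = []
        for share, (chrom, start) in zip(
            (40, 35, 25), (("c1", 0), ("c1", 1_000_000), ("c2", 0))
        ):
            rows.append((random_seq(np.random.default_rng(share), 27),
                         share, chrom, start + 5, "+", 1, True, 27))
        out = call_clusters(bin_unique_reads(genome_frame(rows), 1_000_000),
                            min_share=30.0)
        assert len(out) == 2
        assert out["share_pct"].to_list() == [40.0, 35.0]

    def test_bin_counts_conserve_unique_total(self):
        rng = np.random.default_rng(6)
        rows = [
            (random_seq(rng, 27), int(rng.integers(1, 9)),
             f"c{i % 3}", int(rng.integers(0, 5_000_000)), "+", 1, True, 27)
            for i in range(50)
        ]
        df = genome_frame(rows)
        pi_map = bin_unique_reads(df, 1_000_000)
        assert pi_map.bins["count"].sum() == df["count"].sum()
        assert pi_map.bins["share_pct"].sum() == pytest.approx(100.0)

    def test_invariant_to_chromosome_order(self):
        rng = np.random.default_rng(8)
        rows = [
            (random_seq(rng, 27), int(rng.integers(1, 9)),
             f"c{i % 3}", int(rng.integers(0, 3_000_000)), "+", 1, True, 27)
            for i in range(30)
        ]
        df = genome_frame(rows)
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = call_clusters(bin_unique_reads(df, 1_000_000), 1.0)
        b = call_clusters(bin_unique_reads(shuffled, 1_000_000), 1.0)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_min_share_rejected(self):
        pi_map = bin_unique_reads(genome_frame([]), 1_000_000)
        with pytest.raises(ValueError):
            call_clusters(pi_map, 0.0)
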