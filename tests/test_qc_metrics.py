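import math

import numpy as np
import pandas as pd
import pytest

from conftest import sim_to_pairs
from helpers import brute_pair_region, make_pair, make_read
from pairqc import fixtures
from pairqc.alignment_io import ReadPair
from pairqc.annotation import (
    AnnotatedJunction,
    build_index,
    extract_annotated_junctions,
)
from pairqc.counting import GeneCounter, BOOKKEEPING
from pairqc.qc_metrics import (
    CycleAccumulator,
    GcContentAccumulator,
    GeneBodyAccumulator,
    InsertSizeAccumulator,
    RegionRateAccumulator,
    StrandednessAccumulator,
    diversity_summary,
    gene_diversity_table,
    orient_read,
)
from test_annotation import make_gene


def cycle_acc(*pairs):
    acc = CycleAccumulator()
    for p in pairs:
        acc.update(p)
    return acc


class TestQualityByCycle:
    def test_constant_quality(self):
        acc = cycle_acc(make_pair({"quals": (30,) * 50}, {"quals": (30,) * 50}))
        df = acc.quality_by_cycle()
        assert (df[["min", "q1", "median", "q3", "max"]] == 30).all().all()

    def test_discrete_median(self):
        pairs = [
            make_pair({"cigar": (("M", 1),), "quals": (q,)}, {"cigar": (("M", 1),), "quals": (q,)})
            for q in (20, 30, 40)
        ]
        df = cycle_acc(*pairs).quality_by_cycle()
        r1c1 = df[(df["read"] == "R1") & (df["cycle"] == 1)].iloc[0]
        assert (r1c1["min"], r1c1["q1"], r1c1["median"], r1c1["q3"], r1c1["max"]) == (
            20, 20, 30, 40, 40,
        )

    def test_decaying_quality_fixture_recovers_generator_means(self):
        genes, _, genome = fixtures.make_annotation(n_genes=5, seed=1)
        res = fixtures.simulate_pairs(
            genes, genome, n_pairs=800, seed=2,
            qual_start=38, qual_drop=8, qual_sd=2,
        )
        df = cycle_acc(*sim_to_pairs(res)).quality_by_cycle()
        r1 = df[df["read"] == "R1"]
        for cycle in (1, 38, 75):
            expected = 38 - 8 * (cycle - 1) / 75
            got = float(r1[r1["cycle"] == cycle]["median"].iloc[0])
            assert abs(got - expected) <= 1.5


class TestNvc:
    def test_forward_read_counts_by_cycle(self):
        acc = cycle_acc(make_pair(
            {"cigar": (("M", 4),), "seq": "ACGT"},
            {"cigar": (("M", 4),), "seq": "ACGT"},
        ))
        df = acc.nvc_raw()
        r1 = df[df["read"] == "R1"].set_index("cycle")
        assert r1.loc[1, "A"] == 1 and r1.loc[2, "C"] == 1
        assert r1.loc[3, "G"] == 1 and r1.loc[4, "T"] == 1

    def test_reverse_read_is_reverse_complemented(self):
        # stored "AAAA" on the reverse strand was sequenced as "TTTT"
        acc = cycle_acc(make_pair(
            {"cigar": (("M", 4),), "seq": "AAAA", "reverse": True},
            {"cigar": (("M", 4),), "seq": "CCCC"},
        ))
        r1 = acc.nvc_raw().query("read == 'R1'").set_index("cycle")
        assert (r1["T"] == 1).all() and (r1["A"] == 0).all()

    def test_unclipped_and_clipped_variants(self):
        acc = cycle_acc(make_pair(
            {"cigar": (("S", 2), ("M", 4), ("S", 2)), "seq": "TTACGTTT"},
            {"cigar": (("M", 8),), "seq": "ACGTACGT"},
        ))
        unclipped = acc.nvc_unclipped().query("read == 'R1'")
        assert unclipped[list("ACGTN")].to_numpy().sum() == 4
        clipped = acc.nvc_clipped().query("read == 'R1'")
        assert clipped[list("ACGTN")].to_numpy().sum() == 4
        lead = clipped[clipped["side"] == "lead"]
        assert list(lead["offset"]) == [-2, -1]
        assert lead[lead["offset"] == -1]["T"].iloc[0] == 1

    def test_per_cycle_conservation(self, small_pairs):
        """Sum over A/C/G/T/N at each cycle equals reads reaching the cycle."""
        acc = cycle_acc(*small_pairs[:500])
        nvc = acc.nvc_raw()
        nr = acc.n_rate()
        merged = nvc.merge(nr[["read", "cycle", "reads"]], on=["read", "cycle"])
        assert (merged[list("ACGTN")].sum(axis=1) == merged["reads"]).all()


class TestNRate:
    def test_no_n(self):
        df = cycle_acc(make_pair()).n_rate()
        assert (df["rate"] == 0).all()

    def test_single_n(self):
        pairs = [make_pair({"cigar": (("M", 5),), "seq": "AANAA" if i == 0 else "AAAAA"},
                           {"cigar": (("M", 5),)})
                 for i in range(10)]
        df = cycle_acc(*pairs).n_rate()
        r1 = df[df["read"] == "R1"].set_index("cycle")
        assert r1.loc[3, "rate"] == pytest.approx(0.1)
        assert r1.loc[2, "rate"] == 0


class TestClippingProfile:
    def test_no_clips(self):
        df = cycle_acc(*[make_pair() for _ in range(5)]).clipping_profile()
        assert (df["rate"] == 0).all()

    def test_tail_clip_rate(self):
        pairs = [make_pair({"cigar": (("M", 45), ("S", 5),) if i == 0 else (("M", 50),)})
                 for i in range(10)]
        df = cycle_acc(*pairs).clipping_profile()
        r1 = df[df["read"] == "R1"].set_index("cycle")
        assert np.allclose(r1.loc[46:50, "rate"], 0.1)
        assert (r1.loc[1:45, "rate"] == 0).all()

    def test_reverse_strand_clip_reoriented(self):
        # leading S in alignment orientation = last sequenced cycles
        df = cycle_acc(make_pair({"cigar": (("S", 5), ("M", 45)), "reverse": True})).clipping_profile()
        r1 = df[df["read"] == "R1"].set_index("cycle")
        assert (r1.loc[46:50, "clipped"] == 1).all()
        assert (r1.loc[1:45, "clipped"] == 0).all()


class TestCigarProfile:
    def test_insertion_cycles(self):
        df = cycle_acc(make_pair({"cigar": (("M", 10), ("I", 2), ("M", 38))})).cigar_profile()
        r1 = df[df["read"] == "R1"].set_index("cycle")
        assert r1.loc[11, "I"] == 1 and r1.loc[12, "I"] == 1
        assert r1.loc[10, "I"] == 0 and r1.loc[13, "I"] == 0

    def test_skip_event_at_boundary_and_length_distribution(self):
        acc = cycle_acc(make_pair({"cigar": (("M", 20), ("N", 100), ("M", 30))}))
        r1 = acc.cigar_profile().query("read == 'R1'").set_index("cycle")
        assert r1.loc[20, "N"] == 1
        assert r1["N"].sum() == 1
        lengths = acc.cigar_length_distribution()
        row = lengths[(lengths["read"] == "R1") & (lengths["op"] == "N")]
        assert list(row["length"]) == [100] and list(row["count"]) == [1]

    def test_op_base_totals_equal_direct_summation(self, small_pairs):
        pairs = small_pairs[:300]
        acc = cycle_acc(*pairs)
        df = acc.cigar_profile()
        for op in ("M", "S"):
            expected = sum(
                n
                for p in pairs
                for r in (p.r1, p.r2)
                for o, n in r.cigar
                if o == op
            )
            assert df[op].sum() == expected


class TestGcContent:
    def test_extremes(self):
        acc = GcContentAccumulator()
        acc.update(make_pair({"cigar": (("M", 4),), "seq": "GGGG"},
                             {"cigar": (("M", 4),), "seq": "CCCC"}))
        acc.update(make_pair({"cigar": (("M", 4),), "seq": "ATAT"},
                             {"cigar": (("M", 4),), "seq": "ATAT"}))
        df = acc.table().set_index("gc_bin")
        assert df.loc[1.0, "count"] == 1 and df.loc[0.0, "count"] == 1

    def test_all_n_pair_skipped(self):
        acc = GcContentAccumulator()
        acc.update(make_pair({"cigar": (("M", 4),), "seq": "NNNN"},
                             {"cigar": (("M", 4),), "seq": "NNNN"}))
        assert acc.counts.sum() == 0 and acc.all_n_pairs == 1

    def test_fixture_mean_matches_genome_gc(self):
        genes, _, genome = fixtures.make_annotation(n_genes=6, seed=3, gc_fraction=0.4)
        res = fixtures.simulate_pairs(genes, genome, n_pairs=600, seed=4)
        acc = GcContentAccumulator()
        for p in sim_to_pairs(res):
            acc.update(p)
        assert acc.mean() == pytest.approx(0.40, abs=0.02)


class TestInsertSize:
    def test_plain_pair(self):
        acc = InsertSizeAccumulator()
        size = acc.compute(make_pair({"pos": 100, "cigar": (("M", 50),)},
                                     {"pos": 200, "cigar": (("M", 50),)}))
        assert size == 150

    def test_spliced_mate_subtracts_n(self):
        acc = InsertSizeAccumulator()
        size = acc.compute(make_pair(
            {"pos": 100, "cigar": (("M", 20), ("N", 100), ("M", 30))},
            {"pos": 260, "cigar": (("M", 40),)},
        ))
        assert size == 100

    def test_annotated_intron_in_gap_subtracted(self):
        junctions = {AnnotatedJunction("chr1", "+", 160, 260)}
        acc = InsertSizeAccumulator(junctions)
        size = acc.compute(make_pair({"pos": 100, "cigar": (("M", 50),)},
                                     {"pos": 270, "cigar": (("M", 50),)}))
        # outer span 220 minus the 100 bp intron inside the gap [150, 270)
        assert size == 120

    def test_same_strand_pair_unassignable(self):
        acc = InsertSizeAccumulator()
        pair = make_pair({"pos": 100}, {"pos": 200, "reverse": False})
        acc.update(pair)
        assert acc.unassignable == 1 and acc.counts == {}

    def test_unspliced_fixture_recovers_generator_histogram(self):
        genes, _, genome = fixtures.make_annotation(
            n_genes=5, seed=5, exon_count_range=(1, 1),
            alt_transcript_prob=0.0, with_cds=False,
        )
        res = fixtures.simulate_pairs(genes, genome, n_pairs=800, seed=6)
        acc = InsertSizeAccumulator()
        for p in sim_to_pairs(res):
            acc.update(p)
        expected = res.truth["fragment_length"].value_counts().to_dict()
        assert acc.counts == expected


@pytest.fixture(scope="module")
def annotated():
    g = make_gene(
        "G1", "chr1", "+",
        [[(1000, 1200), (1500, 1700), (2000, 2200)]],
        cds=[(1500, 1700)], utr=[(1000, 1200), (2000, 2200)],
    )
    return [g], build_index([g])


class TestRegionRates:

    def test_cds_pair(self, annotated):
        genes, idx = annotated
        acc = RegionRateAccumulator(idx)
        assert acc.classify(make_pair({"pos": 1510}, {"pos": 1560})) == "CDS"

    def test_intronic_pair(self, annotated):
        genes, idx = annotated
        acc = RegionRateAccumulator(idx)
        assert acc.classify(make_pair({"pos": 1250}, {"pos": 1300})) == "intron"

    def test_fixture_matches_per_base_oracle(self, small_dataset, small_pairs):
        genes, _, _, _ = small_dataset
        acc = RegionRateAccumulator(build_index(genes))
        for p in small_pairs[:300]:
            assert acc.classify(p) == brute_pair_region(genes, p)


class TestStrandedness:
    def run_protocol(self, protocol, seed=8):
        genes, _, genome = fixtures.make_annotation(n_genes=8, seed=7)
        res = fixtures.simulate_pairs(genes, genome, n_pairs=1500, seed=seed, protocol=protocol)
        acc = StrandednessAccumulator(build_index(genes), min_pairs=500)
        for p in sim_to_pairs(res):
            acc.update(p)
        return acc.infer()

    def test_first_strand_recovered(self):
        r, call = self.run_protocol("first_strand")
        assert r <= 0.1 and call == "first_strand"

    def test_second_strand_recovered(self):
        r, call = self.run_protocol("second_strand")
        assert r >= 0.9 and call == "second_strand"

    def test_unstranded_recovered(self):
        r, call = self.run_protocol("unstranded")
        assert 0.4 <= r <= 0.6 and call == "unstranded"

    def test_too_few_informative_pairs_is_indeterminate(self):
        g = make_gene("G1", "chr1", "+", [[(1000, 2000)]])
        acc = StrandednessAccumulator(build_index([g]), min_pairs=1000)
        acc.update(make_pair({"pos": 1100}, {"pos": 1200}))
        r, call = acc.infer()
        assert math.isnan(r) and call == "indeterminate"


class TestGeneBody:
    def test_uniform_coverage_is_flat(self):
        g = make_gene("G1", "chr1", "+", [[(1000, 1400)]])
        acc = GeneBodyAccumulator([g], n_bins=40)
        # tile the 400 bp exon with abutting 200-bp pairs at depth 1
        acc.update(make_pair({"pos": 1000, "cigar": (("M", 100),)},
                             {"pos": 1300, "cigar": (("M", 100),)}), "G1")
        acc.update(make_pair({"pos": 1100, "cigar": (("M", 100),)},
                             {"pos": 1200, "cigar": (("M", 100),)}), "G1")
        df = acc.table()
        allb = df[df["stratum"] == "all"]
        assert allb["depth_normalized"].to_numpy() == pytest.approx([1 / 40] * 40)

    def test_reverse_gene_right_end_maps_to_five_prime(self):
        g = make_gene("G1", "chr1", "-", [[(1000, 1400)]])
        acc = GeneBodyAccumulator([g], n_bins=40)
        acc.update(make_pair({"pos": 1360, "cigar": (("M", 20),)},
                             {"pos": 1380, "cigar": (("M", 20),)}), "G1")
        bins = acc.gene_bins("G1")
        assert bins[:4].sum() == 40 and bins[4:].sum() == 0

    def test_per_gene_bin_sum_equals_depth_sum(self, small_dataset, small_pairs):
        genes, _, _, _ = small_dataset
        idx = build_index(genes)
        counter = GeneCounter(idx)
        acc = GeneBodyAccumulator(genes)
        for p in small_pairs[:500]:
            a = counter.update(p)
            acc.update(p, a if a not in BOOKKEEPING else None)
        for gid, depth in acc.depth.items():
            assert acc.gene_bins(gid).sum() == depth.sum()

    def test_three_prime_bias_recovered(self):
        genes, _, genome = fixtures.make_annotation(n_genes=5, seed=9)
        res = fixtures.simulate_pairs(
            genes, genome, n_pairs=2000, seed=10, three_prime_bias=3.0
        )
        idx = build_index(genes)
        counter = GeneCounter(idx)
        acc = GeneBodyAccumulator(genes)
        for p in sim_to_pairs(res):
            a = counter.update(p)
            acc.update(p, a if a not in BOOKKEEPING else None)
        prof = acc.table().query("stratum == 'all'")["depth_normalized"].to_numpy()
        slope = np.polyfit(np.arange(40), prof, 1)[0]
        assert slope > 0


class TestGeneDiversity:
    def test_single_gene(self):
        df = gene_diversity_table({"G1": 100})
        assert list(df["cumulative_fraction"]) == [1.0]
        assert diversity_summary(df)["genes_for_50pct"] == 1

    def test_even_split(self):
        df = gene_diversity_table({"G1": 50, "G2": 50})
        assert list(df["cumulative_fraction"]) == [0.5, 1.0]
        s = diversity_summary(df)
        assert s["genes_for_50pct"] == 1 and s["genes_for_80pct"] == 2

    def test_matches_direct_computation(self, qc_run):
        import os
        from pairqc.qc_metrics import read_metric_table

        out, _ = qc_run
        curve = read_metric_table(os.path.join(out, "gene_diversity.tsv"))
        counts = pd.read_csv(
            os.path.join(out, "gene_counts.tsv"), sep="\t", header=None,
            names=["gene_id", "count"],
        )
        counts = counts[~counts["gene_id"].str.startswith("_")]
        counts = counts[counts["count"] > 0].sort_values(
            ["count", "gene_id"], ascending=[False, True]
        )
        expected = counts["count"].cumsum() / counts["count"].sum()
        assert np.allclose(curve["cumulative_fraction"], expected)

    def test_all_zero_counts(self):
        assert len(gene_diversity_table({"G1": 0})) == 0
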