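import numpy as np
import pandas as pd
import pytest

from conftest import sim_to_pairs
from helpers import brute_assign_pair, brute_read_junctions, make_pair, make_read
from pairqc import fixtures
from pairqc.alignment_io import ReadPair
from pairqc.annotation import build_index, extract_annotated_junctions
from pairqc.counting import (
    AMBIGUOUS,
    BOOKKEEPING,
    ExonPartCounter,
    GeneCounter,
    JunctionCounter,
    MalformedSpliceError,
    NO_FEATURE,
    assign_pair_union,
    compute_fpkm,
    extract_junctions,
    fragment_strand,
)
from test_annotation import make_gene


@pytest.fixture(scope="module")
def two_gene_index():
    a = make_gene("G1", "chr1", "+", [[(1000, 1500)]])
    b = make_gene("G2", "chr1", "+", [[(3000, 3500)]])
    return [a, b], build_index([a, b])


class TestUnionRule:
    def test_single_gene(self, two_gene_index):
        genes, idx = two_gene_index
        assert assign_pair_union(make_pair({"pos": 1100}, {"pos": 1200}), idx) == "G1"

    def test_mates_in_different_genes_ambiguous(self, two_gene_index):
        genes, idx = two_gene_index
        assert assign_pair_union(make_pair({"pos": 1100}, {"pos": 3100}), idx) == AMBIGUOUS

    def test_intergenic_no_feature(self, two_gene_index):
        genes, idx = two_gene_index
        assert assign_pair_union(make_pair({"pos": 2000}, {"pos": 2100}), idx) == NO_FEATURE

    def test_skipped_bases_do_not_assign(self, two_gene_index):
        # the N op spans G2's exon entirely: no aligned base touches G2
        genes, idx = two_gene_index
        pair = make_pair(
            {"pos": 1400, "cigar": (("M", 50), ("N", 2000), ("M", 50))},
            {"pos": 1400, "cigar": (("M", 50),)},
        )
        # N spans [1450, 3450); the trailing 50M lands at 3450..3500 inside G2
        assert assign_pair_union(pair, idx) == AMBIGUOUS
        pair2 = make_pair(
            {"pos": 1400, "cigar": (("M", 50), ("N", 2100), ("M", 50))},
            {"pos": 1400, "cigar": (("M", 50),)},
        )
        # now the trailing block lands beyond G2's exon end: only G1 is hit
        assert assign_pair_union(pair2, idx) == "G1"

    @pytest.mark.parametrize("strand_mode", ["unstranded", "first_strand", "second_strand"])
    def test_matches_per_base_brute_force(self, small_dataset, small_pairs, strand_mode):
        genes, _, _, _ = small_dataset
        idx = build_index(genes)
        for p in small_pairs[:400]:
            strand = fragment_strand(p, strand_mode)
            expected = brute_assign_pair(genes, p, None if strand == "." else strand)
            assert assign_pair_union(p, idx, strand_mode) == expected

    def test_conservation(self, small_dataset, small_pairs):
        genes, _, _, _ = small_dataset
        counter = GeneCounter(build_index(genes))
        for p in small_pairs:
            counter.update(p)
        total = sum(counter.counts.values())
        assert total == len(small_pairs)
        df = counter.table()
        assert list(df["gene_id"].tail(3)) == list(BOOKKEEPING)


class TestExonPartCounting:
    def test_pair_touching_two_parts(self):
        g = make_gene("G1", "chr1", "+", [[(1000, 1200)], [(1000, 1100)]])
        idx = build_index([g])
        counter = ExonPartCounter(idx)
        hit = counter.update(make_pair({"pos": 1050}, {"pos": 1090}))
        assert hit == ["G1:E001", "G1:E002"]

    def test_spliced_over_part_not_counted(self):
        g = make_gene(
            "G1", "chr1", "+", [[(1000, 1100), (2000, 2100), (3000, 3100)]]
        )
        idx = build_index([g])
        counter = ExonPartCounter(idx)
        # mate 1 splices from exon 1 directly to exon 3 over part E002
        pair = make_pair(
            {"pos": 1050, "cigar": (("M", 50), ("N", 1900), ("M", 50))},
            {"pos": 3000, "cigar": (("M", 50),)},
        )
        hit = counter.update(pair)
        assert hit == ["G1:E001", "G1:E003"]
        assert counter.counts["G1:E002"] == 0

    def test_matches_brute_force_overlap(self, small_dataset, small_pairs):
        from helpers import pair_footprint_bases

        genes, _, _, _ = small_dataset
        idx = build_index(genes)
        counter = ExonPartCounter(idx)
        parts = list(idx.parts.values())
        for p in small_pairs[:300]:
            hit = counter.update(p)
            fp = pair_footprint_bases(p)
            if len(fp) != 1:
                assert hit == []
                continue
            chrom, bases = next(iter(fp.items()))
            touched_aggs = {
                pt.aggregate_gene_id
                for pt in parts
                if pt.interval.chrom == chrom
                and any(pt.interval.start <= b < pt.interval.end for b in bases)
            }
            gene_hits = {
                g.gene_id
                for g in genes
                if g.chrom == chrom
                and any(
                    e.start <= b < e.end
                    for e in g.exon_intervals()
                    for b in bases
                )
            }
            agg_hits = {idx.aggregate_of_gene[g] for g in gene_hits}
            if len(agg_hits) != 1:
                assert hit == []
            else:
                agg = next(iter(agg_hits))
                expected = sorted(
                    pt.part_id
                    for pt in parts
                    if pt.aggregate_gene_id == agg
                    and pt.interval.chrom == chrom
                    and any(pt.interval.start <= b < pt.interval.end for b in bases)
                )
                assert hit == expected


class TestExtractJunctions:
    def test_single_skip(self):
        r = make_read(pos=1000, cigar=(("M", 10), ("N", 100), ("M", 10)))
        assert extract_junctions(r) == [("chr1", ".", 1010, 1110)]

    def test_two_skips(self):
        r = make_read(pos=0, cigar=(("M", 5), ("N", 50), ("M", 5), ("N", 40), ("M", 5)))
        assert extract_junctions(r) == [
            ("chr1", ".", 5, 55),
            ("chr1", ".", 60, 100),
        ]

    def test_terminal_n_is_malformed(self):
        r = make_read(pos=0, cigar=(("N", 50), ("M", 10)))
        with pytest.raises(MalformedSpliceError):
            extract_junctions(r)

    def test_matches_truth_table(self, small_dataset, small_pairs):
        genes, _, _, result = small_dataset
        truth = result.truth.set_index("name")
        for p in small_pairs[:300]:
            got = set()
            for r in (p.r1, p.r2):
                got |= {(c, s, e) for c, _, s, e in extract_junctions(r)}
            row = truth.loc[p.name]
            expected = set()
            for col in ("r1_junctions", "r2_junctions"):
                val = row[col]
                if isinstance(val, str) and val:
                    for tok in val.split(";"):
                        c, s, e = tok.split(":")
                        expected.add((c, int(s), int(e)))
            assert got == expected


class TestJunctionCounting:
    def test_known_high(self):
        g = make_gene("G1", "chr1", "+", [[(1000, 1100), (1200, 1300)]])
        annotated = extract_annotated_junctions([g])
        counter = JunctionCounter(annotated, high_coverage_threshold=4)
        pair = make_pair(
            {"pos": 1050, "cigar": (("M", 50), ("N", 100), ("M", 20))},
            {"pos": 1200, "cigar": (("M", 50),)},
        )
        for _ in range(10):
            counter.update(pair)
        df = counter.table()
        assert len(df) == 1
        row = df.iloc[0]
        assert row["known"] and row["count"] == 10 and row["coverage_class"] == "high"
        # the annotated strand is adopted for the unstranded observation
        assert row["strand"] == "+"

    def test_novel_low_and_unobserved_known_listed(self):
        g = make_gene("G1", "chr1", "+", [[(1000, 1100), (1200, 1300)]])
        counter = JunctionCounter(extract_annotated_junctions([g]))
        pair = make_pair(
            {"pos": 2000, "cigar": (("M", 10), ("N", 500), ("M", 10))},
            {"pos": 2500, "cigar": (("M", 20),)},
        )
        counter.update(pair)
        df = counter.table().set_index("intron_start")
        assert df.loc[2010, "known"] == False and df.loc[2010, "coverage_class"] == "low"
        assert df.loc[1100, "count"] == 0  # annotated but unobserved, still listed

    def test_pair_observing_same_junction_in_both_mates_counts_once(self):
        counter = JunctionCounter(set())
        pair = make_pair(
            {"pos": 1000, "cigar": (("M", 10), ("N", 100), ("M", 10))},
            {"pos": 1005, "cigar": (("M", 5), ("N", 100), ("M", 15))},
        )
        counter.update(pair)
        assert list(counter.counts.values()) == [1]

    def test_doubling_mate_observations_never_changes_counts(self, small_pairs):
        counter = JunctionCounter(set())
        doubled = JunctionCounter(set())
        for p in small_pairs[:300]:
            counter.update(p)
            # presenting the whole pair twice doubles counts exactly; within
            # a pair, duplicate mate evidence is already deduplicated
            doubled.update(p)
            doubled.update(p)
        assert {k: 2 * v for k, v in counter.counts.items()} == doubled.counts

    def test_summary_matches_brute_tabulation(self, small_dataset, small_pairs):
        genes, _, _, _ = small_dataset
        annotated = extract_annotated_junctions(genes)
        counter = JunctionCounter(annotated, high_coverage_threshold=4)
        brute: dict[tuple, int] = {}
        for p in small_pairs:
            counter.update(p)
            for j in brute_read_junctions(p):
                brute[j] = brute.get(j, 0) + 1
        annotated_loci = {(j.chrom, j.start, j.end) for j in annotated}
        summary = counter.summary_table().set_index("class")
        for kname, is_known in (("known", True), ("novel", False)):
            for cls, pred in (("high", lambda c: c >= 4), ("low", lambda c: c < 4)):
                expected_loci = [
                    j for j, c in brute.items()
                    if ((j in annotated_loci) == is_known) and pred(c)
                ]
                if is_known and cls == "low":
                    # unobserved annotated junctions are listed as known/low
                    expected_n = len(expected_loci) + sum(
                        1 for j in annotated_loci if j not in brute
                    )
                else:
                    expected_n = len(expected_loci)
                row = summary.loc[f"{kname}_{cls}"]
                assert row["loci"] == expected_n
                assert row["events"] == sum(brute[j] for j in expected_loci)


class TestFpkm:
    def test_closed_form(self):
        df = compute_fpkm({"G1": 1000}, {"G1": 2000})
        # single gene: assigned_total = 1000 -> 1000*1e9/(2000*1000)
        assert df["fpkm"].iloc[0] == pytest.approx(5e5)

    def test_example_values(self):
        counts = {"G1": 1000, "G2": 10_000_000 - 1000}
        lengths = {"G1": 2000, "G2": 1000}
        df = compute_fpkm(counts, lengths).set_index("gene_id")
        assert df.loc["G1", "fpkm"] == pytest.approx(
            1000 * 1e9 / (2000 * 10_000_000)
        )

    def test_zero_count_zero_fpkm(self):
        df = compute_fpkm({"G1": 0, "G2": 10}, {"G1": 500, "G2": 500}).set_index("gene_id")
        assert df.loc["G1", "fpkm"] == 0

    def test_no_assigned_pairs_all_na(self):
        df = compute_fpkm({"G1": 0}, {"G1": 500})
        assert np.isnan(df["fpkm"].iloc[0])

    def test_matches_independent_recomputation(self, qc_run):
        import os

        out, summary = qc_run
        fpkm = pd.read_csv(os.path.join(out, "fpkm.tsv"), sep="\t")
        total = fpkm["count"].sum()
        expected = fpkm["count"] * 1e9 / (fpkm["length_bp"] * total)
        assert np.allclose(fpkm["fpkm"], expected, equal_nan=True)
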