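import numpy as np
import pytest

from pairqc import fixtures
from pairqc.alignment_io import ReadPair, stream_pairs
from pairqc.pipeline import RunConfig, run_qc


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-gene annotation with overlaps plus 2000 simulated pairs."""
    genes, chrom_lengths, genome = fixtures.make_annotation(
        n_genes=12, seed=11, overlap_fraction=0.25
    )
    result = fixtures.simulate_pairs(
        genes, genome, n_pairs=2000, seed=7, clip_rate=0.05
    )
    return genes, chrom_lengths, genome, result


@pytest.fixture(scope="session")
def qc_run(tmp_path_factory, small_dataset):
    """Full pipeline run on the small dataset; yields (out_dir, summary)."""
    genes, chrom_lengths, genome, result = small_dataset
    d = tmp_path_factory.mktemp("qc_run")
    gtf, sam = str(d / "ann.gtf"), str(d / "reads.sam")
    fixtures.write_gtf(genes, gtf)
    fixtures.write_sam(result.pairs, chrom_lengths, sam)
    out = str(d / "out")
    summary = run_qc(RunConfig(sam, gtf, out))
    return out, summary


def sim_to_pairs(result) -> list[ReadPair]:
    """Lift simulator records into the alignment-io pair type directly."""
    from pairqc.alignment_io import AlignedRead

    def lift(r):
        return AlignedRead(
            name=r.name,
            is_first_in_pair=r.is_first_in_pair,
            is_reverse=r.is_reverse,
            is_secondary=False,
            is_supplementary=False,
            is_unmapped=False,
            chrom=r.chrom,
            pos=r.pos,
            mapq=r.mapq,
            cigar=tuple(r.cigar),
            seq=r.seq,
            quals=tuple(r.quals),
        )

    return [ReadPair(lift(r1), lift(r2)) for r1, r2 in result.pairs]


@pytest.fixture(scope="session")
def small_pairs(small_dataset):
    _, _, _, result = small_dataset
    return sim_to_pairs(result)


def roundtrip_pairs(result, chrom_lengths, tmpdir, sort_mode="coordinate"):
    """Write simulated pairs to SAM and read them back through pysam."""
    path = str(tmpdir / "rt.sam")
    fixtures.write_sam(result.pairs, chrom_lengths, path, sort_mode=sort_mode)
    return list(stream_pairs(path, sort_mode, min_mapq=0))
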