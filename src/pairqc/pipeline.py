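"""Single-pass per-replicate processing run.

One traversal of the alignment stream feeds every enabled accumulator:
QC metric tables, gene/exon-part/junction count files and browser tracks
all come out of the same pass. Disabling a sub-function only omits its
output files — the computation of everything else is unchanged, so the
remaining outputs are byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

from . import __version__
from .alignment_io import (
    DEFAULT_MIN_MAPQ,
    FilterTally,
    read_header_lengths,
    stream_pairs,
)
from .annotation import (
    build_index,
    extract_annotated_junctions,
    flatten_exons,
    parse_gtf,
    write_flat_annotation,
)
from .counting import (
    DEFAULT_HIGH_COVERAGE_THRESHOLD,
    BOOKKEEPING,
    ExonPartCounter,
    GeneCounter,
    JunctionCounter,
    compute_fpkm,
    fragment_strand,
)
from .qc_metrics import (
    ChromRateAccumulator,
    CycleAccumulator,
    GcContentAccumulator,
    GeneBodyAccumulator,
    InsertSizeAccumulator,
    METRIC_SCHEMAS,
    RegionRateAccumulator,
    StrandednessAccumulator,
    diversity_summary,
    drop_rate_table,
    gene_diversity_table,
    write_metric_table,
)
from .tracks import DEFAULT_WINDOW, WiggleTrack, make_junction_bed

SUBFUNCTIONS = ("metrics", "counts", "tracks")


@dataclass
class RunConfig:
    """Effective configuration of one processing run; every field has a default."""

    input_path: str = ""
    annotation_path: str = ""
    out_dir: str = "."
    sort_mode: str = "coordinate"
    min_mapq: int = DEFAULT_MIN_MAPQ
    strand_mode: str = "unstranded"
    window: int = DEFAULT_WINDOW
    high_coverage_threshold: int = DEFAULT_HIGH_COVERAGE_THRESHOLD
    gene_body_bins: int = 40
    strandedness_min_pairs: int = 1000
    drop_duplicates: bool = False
    skip: tuple[str, ...] = field(default_factory=tuple)

    def enabled(self, sub: str) -> bool:
        return sub not in self.skip


def run_qc(config: RunConfig) -> dict:
    """Execute one single-pass processing run; returns the run summary.

    The summary (also written to ``run_summary.json`` in the output
    directory) records the effective configuration, record and drop
    tallies, headline inferences and the output-file inventory.
    """
    for sub in config.skip:
        if sub not in SUBFUNCTIONS:
            raise ValueError(
                f"unknown sub-function {sub!r}; valid: {', '.join(SUBFUNCTIONS)}"
            )
    if not os.path.exists(config.input_path):
        raise FileNotFoundError(f"alignment file not found: {config.input_path}")
    if not os.path.exists(config.annotation_path):
        raise FileNotFoundError(f"annotation file not found: {config.annotation_path}")
    os.makedirs(config.out_dir, exist_ok=True)

    genes = parse_gtf(config.annotation_path)
    parts = flatten_exons(genes)
    junctions = extract_annotated_junctions(genes)
    index = build_index(genes, parts)
    chrom_lengths = read_header_lengths(config.input_path)

    tally = FilterTally()
    cycles = CycleAccumulator()
    gc = GcContentAccumulator()
    inserts = InsertSizeAccumulator(junctions)
    regions = RegionRateAccumulator(index)
    strandedness = StrandednessAccumulator(
        index, min_pairs=config.strandedness_min_pairs
    )
    gene_body = GeneBodyAccumulator(genes, n_bins=config.gene_body_bins)
    chrom_rates = ChromRateAccumulator()
    gene_counter = GeneCounter(index, config.strand_mode)
    exon_counter = ExonPartCounter(index, config.strand_mode)
    junction_counter = JunctionCounter(
        junctions, config.strand_mode, config.high_coverage_threshold
    )
    stranded_tracks = config.strand_mode != "unstranded"
    if stranded_tracks:
        wigs = {
            "+": WiggleTrack(chrom_lengths, config.window, name="coverage.fwd"),
            "-": WiggleTrack(chrom_lengths, config.window, name="coverage.rev"),
        }
    else:
        wigs = {".": WiggleTrack(chrom_lengths, config.window, name="coverage")}

    retained = 0
    for pair in stream_pairs(
        config.input_path,
        config.sort_mode,
        config.min_mapq,
        tally,
        config.drop_duplicates,
    ):
        retained += 1
        assignment = gene_counter.update(pair)
        gene_id = assignment if assignment not in BOOKKEEPING else None
        cycles.update(pair)
        gc.update(pair)
        inserts.update(pair)
        regions.update(pair)
        strandedness.update(pair)
        gene_body.update(pair, gene_id)
        chrom_rates.update(pair)
        exon_counter.update(pair)
        junction_counter.update(pair)
        strand = fragment_strand(pair, config.strand_mode)
        wigs[strand if stranded_tracks else "."].add_pair(pair)

    gene_counts = gene_counter.gene_counts()
    diversity = gene_diversity_table(gene_counts)
    inventory: list[str] = []

    def out(name: str) -> str:
        inventory.append(name)
        return os.path.join(config.out_dir, name)

    params = f"min_mapq={config.min_mapq} strand_mode={config.strand_mode}"
    if config.enabled("metrics"):
        tables = {
            "quality_by_cycle": cycles.quality_by_cycle(),
            "nvc_raw": cycles.nvc_raw(),
            "nvc_unclipped": cycles.nvc_unclipped(),
            "nvc_clipped": cycles.nvc_clipped(),
            "n_rate": cycles.n_rate(),
            "clipping_profile": cycles.clipping_profile(),
            "cigar_profile": cycles.cigar_profile(),
            "cigar_length_distribution": cycles.cigar_length_distribution(),
            "gc_content": gc.table(),
            "insert_size": inserts.table(),
            "region_rates": regions.table(),
            "strandedness": strandedness.table(),
            "gene_body": gene_body.table(),
            "gene_diversity": diversity,
            "assignment_rates": gene_counter.assignment_rate_table(),
            "chromosome_rates": chrom_rates.table(),
            "drop_rates": drop_rate_table(tally),
            "junction_summary": junction_counter.summary_table(),
        }
        for metric, df in tables.items():
            fname, _cols = METRIC_SCHEMAS[metric]
            write_metric_table(df, out(fname), params)

    if config.enabled("counts"):
        gene_counter.write(out("gene_counts.tsv"))
        exon_counter.write(out("exon_counts.tsv"))
        junction_counter.write(out("junction_counts.tsv"))
        write_flat_annotation(parts, out("flat_annotation.gff"))
        lengths = {g.gene_id: g.exonic_union_length() for g in genes}
        compute_fpkm(gene_counts, lengths).to_csv(
            out("fpkm.tsv"), sep="\t", index=False, na_rep="NA"
        )

    if config.enabled("tracks"):
        if stranded_tracks:
            wigs["+"].write(out("coverage.fwd.wig"))
            wigs["-"].write(out("coverage.rev.wig"))
        else:
            wigs["."].write(out("coverage.wig"))
        make_junction_bed(junction_counter.table(), out("junctions.bed"))

    ratio, protocol = strandedness.infer()
    summary = {
        "tool": "pairqc",
        "version": __version__,
        "config": asdict(config),
        "units_examined": tally.total(),  # pairs, orphan reads and dropped records
        "drop_tally": dict(tally.counts),
        "retained_pairs": retained,
        "assigned_pairs": gene_counter.assigned_total(),
        "inferred_protocol": protocol,
        "strandedness_ratio": None if ratio != ratio else ratio,
        "gene_diversity": diversity_summary(diversity),
        "malformed_splice_reads": junction_counter.malformed_reads,
        "inventory": sorted(inventory),
    }
    with open(os.path.join(config.out_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
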