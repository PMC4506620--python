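"""Synthetic annotation and alignment generator with known ground truth.

Emulates, at desk scale, a paired-end RNA-seq experiment: multi-exon
genes on both strands (optionally overlapping), expression-weighted
fragment sampling with a configurable fragment-length distribution,
spliced alignments with correct N ops, strand protocols, soft clipping,
optional 3' positional bias, and an injectable sequencer fault that
N-truncates a seeded fraction of one mate from a given cycle onward.

Alignments are written directly (the simulator emits SAM, it does not run
an aligner), so every record is reconstructible from the truth table. All
output is byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, TranscriptModel

__all__ = [
    "SimulatedRead",
    "SimulationResult",
    "make_annotation",
    "write_gtf",
    "simulate_pairs",
    "inject_fault",
    "write_sam",
    "make_decoder",
    "simulate_dataset",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulatedRead:
    name: str
    is_first_in_pair: bool
    is_reverse: bool
    chrom: str
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    quals: list[int]

    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in "MDN=X")

    def strand_char(self) -> str:
        return "-" if self.is_reverse else "+"

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


@dataclass
class SimulationResult:
    pairs: list[tuple[SimulatedRead, SimulatedRead]]
    truth: pd.DataFrame
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# annotation generation


def make_annotation(
    n_genes: int = 20,
    exon_count_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    chrom_names: tuple[str, ...] = ("chr1", "chr2"),
    exon_length_range: tuple[int, int] = (80, 300),
    intron_length_range: tuple[int, int] = (60, 400),
    intergenic_gap_range: tuple[int, int] = (300, 900),
    overlap_fraction: float = 0.0,
    alt_transcript_prob: float = 0.5,
    gc_fraction: float = 0.5,
    with_cds: bool = True,
) -> tuple[list[GeneModel], dict[str, int], dict[str, str]]:
    """Build a synthetic gene annotation plus a random genome.

    Returns (genes, chromosome lengths, genome sequence by chromosome).
    A fraction of consecutive same-chromosome genes can be made to
    overlap a neighbour's terminal exon on the same strand, exercising
    the aggregate-merging path of exon flattening. With
    ``alt_transcript_prob`` a gene gains a second transcript skipping one
    internal exon. When ``with_cds`` is set, interior exons are marked CDS
    and terminal exons UTR, so region-class metrics have all classes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    cursors = {c: 1000 for c in chrom_names}
    last_gene_on: dict[str, GeneModel] = {}
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        gene_id = f"G{gi + 1:03d}"
        chrom = chrom_names[gi % len(chrom_names)]
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        prev = last_gene_on.get(chrom)
        if prev is not None and rng.random() < overlap_fraction:
            strand = prev.strand
            prev_last = max(prev.exon_intervals(), key=lambda e: e.end)
            start = prev_last.end - max(1, prev_last.length // 2)
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursors[chrom] + int(
                rng.integers(intergenic_gap_range[0], intergenic_gap_range[1] + 1)
            )
        exons: list[GenomicInterval] = []
        pos = start
        for _ in range(n_exons):
            elen = int(rng.integers(exon_length_range[0], exon_length_range[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen + int(
                rng.integers(intron_length_range[0], intron_length_range[1] + 1)
            )
        tx1 = TranscriptModel(f"{gene_id}.t1", gene_id, list(exons))
        transcripts = [tx1]
        if n_exons >= 3 and rng.random() < alt_transcript_prob:
            skip = int(rng.integers(1, n_exons - 1))
            tx2 = TranscriptModel(
                f"{gene_id}.t2",
                gene_id,
                [e for i, e in enumerate(exons) if i != skip],
            )
            transcripts.append(tx2)
        cds: list[GenomicInterval] = []
        utr: list[GenomicInterval] = []
        if with_cds and n_exons >= 2:
            utr.append(exons[0])
            utr.append(exons[-1])
            cds.extend(exons[1:-1])
        gene = GeneModel(gene_id, chrom, strand, transcripts, cds, utr)
        genes.append(gene)
        cursors[chrom] = max(cursors[chrom], exons[-1].end)
        last_gene_on[chrom] = gene
    chrom_lengths = {c: cursors[c] + 1000 for c in chrom_names}
    genome = {
        c: _random_genome(rng, chrom_lengths[c], gc_fraction) for c in chrom_names
    }
    return genes, chrom_lengths, genome


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def write_gtf(genes: list[GeneModel], path: str, source: str = "pairqc_sim") -> None:
    """Write gene models as Ensembl-style GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            for tx in g.transcripts:
                for e in tx.sorted_exons():
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t"
                        f'gene_id "{g.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                    )
            for iv, feat in [(i, "CDS") for i in g.cds_intervals] + [
                (i, "UTR") for i in g.utr_intervals
            ]:
                fh.write(
                    f"{g.chrom}\t{source}\t{feat}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";\n'
                )


# ---------------------------------------------------------------------------
# transcript coordinate mapping


def _tx_blocks(tx: TranscriptModel) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in tx.sorted_exons()]


def _tx_length(tx: TranscriptModel) -> int:
    return sum(e - s for s, e in _tx_blocks(tx))


def _tx_to_genomic(
    tx: TranscriptModel, strand: str, a: int, b: int
) -> list[tuple[int, int]]:
    """Map transcript-coordinate interval [a, b) (5'->3') to genomic blocks.

    Returns ascending genomic (start, end) blocks.
    """
    blocks = _tx_blocks(tx)
    L = _tx_length(tx)
    if strand == "-":
        a, b = L - b, L - a  # flip to plus-strand transcript coordinates
    out = []
    off = 0
    for s, e in blocks:
        blen = e - s
        lo, hi = max(a, off), min(b, off + blen)
        if lo < hi:
            out.append((s + lo - off, s + hi - off))
        off += blen
    return out


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                cigar.append(("N", gap))
        cigar.append(("M", e - s))
    # merge adjacent M runs (abutting exons)
    merged: list[tuple[str, int]] = []
    for op, n in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def clip_query_bases(
    cigar: list[tuple[str, int]], pos: int, k: int, side: str
) -> tuple[list[tuple[str, int]], int]:
    """Convert k query bases at one alignment end into soft clip.

    ``side`` is 'left' or 'right' in alignment (genomic) orientation. D/N
    ops falling inside the clipped region are dropped; for left clips the
    alignment start advances by the reference bases consumed.
    """
    if k <= 0:
        return list(cigar), pos
    ops = list(cigar) if side == "left" else [(o, n) for o, n in reversed(cigar)]
    remaining = k
    ref_advance = 0
    i = 0
    while i < len(ops) and remaining > 0:
        op, n = ops[i]
        if op in "MIS=X":
            take = min(n, remaining)
            remaining -= take
            if op in "M=X":
                ref_advance += take
            if take < n:
                ops[i] = (op, n - take)
                break
            i += 1
        elif op in "DN":
            ref_advance += n
            i += 1
        else:  # H, P at the end
            i += 1
    rest = ops[i:]
    # the alignment proper must resume on an aligned block: drop D/N/P at
    # the clip boundary and fold a boundary insertion into the clip itself
    while rest and rest[0][0] in "DNPI":
        op, n = rest[0]
        if op in "DN":
            ref_advance += n
        elif op == "I":
            k += n
        rest = rest[1:]
    new = [("S", k)] + rest
    if side == "right":
        new = [(o, n) for o, n in reversed(new)]
    # merge adjacent equal ops (e.g. S followed by pre-existing S)
    merged: list[tuple[str, int]] = []
    for op, n in new:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged, pos + (ref_advance if side == "left" else 0)


# ---------------------------------------------------------------------------
# pair simulation


def simulate_pairs(
    genes: list[GeneModel],
    genome: dict[str, str],
    n_pairs: int = 10_000,
    read_length: int = 75,
    fragment_mean: float = 180.0,
    fragment_sd: float = 30.0,
    expression_weights: dict[str, float] | None = None,
    protocol: str = "unstranded",
    clip_rate: float = 0.0,
    clip_length_range: tuple[int, int] = (1, 10),
    three_prime_bias: float = 0.0,
    qual_start: float = 38.0,
    qual_drop: float = 8.0,
    qual_sd: float = 2.0,
    mapq: int = 60,
    seed: int = 0,
    name_prefix: str = "sim",
) -> SimulationResult:
    """Simulate aligned, spliced read pairs with full ground truth.

    Fragments are sampled from transcripts in proportion to
    ``expression_weights`` (uniform by default), with near-normal lengths
    clipped to [read_length, transcript length]. Under the second-strand
    protocol read 1 is sequenced from the fragment's 5' end on the
    transcript strand; under first-strand from the 3' end; unstranded
    flips a fair coin per fragment. ``three_prime_bias`` > 0 weights
    fragment start positions toward the transcript 3' end exponentially.
    Fragments longer than their transcript are resampled and tallied.
    """
    if protocol not in ("unstranded", "first_strand", "second_strand"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    if expression_weights is None:
        weights = np.ones(len(genes))
    else:
        weights = np.array([expression_weights.get(g, 0.0) for g in gene_ids])
    weights = weights / weights.sum()
    gene_by_id = {g.gene_id: g for g in genes}

    pairs: list[tuple[SimulatedRead, SimulatedRead]] = []
    truth_rows = []
    resampled = 0
    made = 0
    while made < n_pairs:
        gid = gene_ids[int(rng.choice(len(genes), p=weights))]
        gene = gene_by_id[gid]
        tx = gene.transcripts[int(rng.integers(len(gene.transcripts)))]
        L = _tx_length(tx)
        frag = int(round(rng.normal(fragment_mean, fragment_sd)))
        if frag > L:
            resampled += 1
            continue
        frag = max(frag, read_length)
        max_start = L - frag
        if three_prime_bias > 0 and max_start > 0:
            u = rng.random()
            b = three_prime_bias
            x = np.log1p(u * (np.exp(b) - 1.0)) / b
            start = int(x * max_start)
        else:
            start = int(rng.integers(0, max_start + 1))

        name = f"{name_prefix}:{made + 1:06d}"
        # fragment occupies transcript coords [start, start+frag) 5'->3'
        five_iv = (start, start + read_length)
        three_iv = (start + frag - read_length, start + frag)
        if protocol == "second_strand":
            r1_from_five = True
        elif protocol == "first_strand":
            r1_from_five = False
        else:
            r1_from_five = bool(rng.random() < 0.5)
        r1_iv, r2_iv = (five_iv, three_iv) if r1_from_five else (three_iv, five_iv)
        # the mate sequenced off the fragment 5' end reads along the
        # transcript strand; the other mate reads the opposite strand
        reads = []
        for is_first, (a, b_), from_five in (
            (True, r1_iv, r1_from_five),
            (False, r2_iv, not r1_from_five),
        ):
            blocks = _tx_to_genomic(tx, gene.strand, a, b_)
            pos = blocks[0][0]
            cigar = _blocks_to_cigar(blocks)
            read_strand = gene.strand if from_five else ("-" if gene.strand == "+" else "+")
            seq = "".join(genome[gene.chrom][s:e] for s, e in blocks)
            # as-sequenced per-cycle qualities, then flipped into alignment
            # orientation for SAM storage when the read is reverse-aligned
            cyc = np.arange(read_length)
            q = np.clip(
                np.round(
                    rng.normal(
                        qual_start - qual_drop * cyc / read_length, qual_sd
                    )
                ),
                2,
                40,
            ).astype(int)
            quals = list(q[::-1] if read_strand == "-" else q)
            if rng.random() < clip_rate:
                k = int(
                    rng.integers(clip_length_range[0], clip_length_range[1] + 1)
                )
                side = "left" if rng.random() < 0.5 else "right"
                cigar, pos = clip_query_bases(cigar, pos, k, side)
            reads.append(
                SimulatedRead(
                    name=name,
                    is_first_in_pair=is_first,
                    is_reverse=read_strand == "-",
                    chrom=gene.chrom,
                    pos=pos,
                    mapq=mapq,
                    cigar=cigar,
                    seq=seq,
                    quals=quals,
                )
            )
        r1, r2 = reads
        pairs.append((r1, r2))
        j1, j2 = (
            ";".join(f"{r.chrom}:{s}:{e}" for s, e in _read_skip_blocks(r))
            for r in (r1, r2)
        )
        truth_rows.append(
            (name, gid, tx.transcript_id, frag, r1.strand_char(), j1, j2, False)
        )
        made += 1

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "name",
            "gene_id",
            "transcript_id",
            "fragment_length",
            "r1_strand",
            "r1_junctions",
            "r2_junctions",
            "faulted",
        ],
    )
    params = {
        "n_pairs": n_pairs,
        "read_length": read_length,
        "fragment_mean": fragment_mean,
        "fragment_sd": fragment_sd,
        "protocol": protocol,
        "clip_rate": clip_rate,
        "three_prime_bias": three_prime_bias,
        "seed": seed,
        "resampled_fragments": resampled,
    }
    return SimulationResult(pairs, truth, params)


def _read_skip_blocks(r: SimulatedRead) -> list[tuple[int, int]]:
    out = []
    ref = r.pos
    for op, n in r.cigar:
        if op == "N":
            out.append((ref, ref + n))
        if op in "MDN=X":
            ref += n
    return out


# ---------------------------------------------------------------------------
# fault injection


def inject_fault(
    result: SimulationResult,
    read_index: int,
    cycle: int,
    fraction: float,
    seed: int = 0,
) -> SimulationResult:
    """N-truncate a seeded fraction of one mate from a given cycle onward.

    Emulates a sequencer-side fault: for the selected reads, every base
    from ``cycle`` (1-based, as-sequenced orientation) to the read end
    becomes N and the alignment is soft-clipped over those cycles.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be within [0, 1]")
    if read_index not in (1, 2):
        raise ValueError("read_index must be 1 or 2")
    rng = np.random.default_rng(seed)
    new_pairs = []
    faulted_names = set()
    for r1, r2 in result.pairs:
        target = r1 if read_index == 1 else r2
        if rng.random() < fraction:
            target = _truncate_read(target, cycle)
            faulted_names.add(target.name)
        new_pairs.append((target, r2) if read_index == 1 else (r1, target))
    truth = result.truth.copy()
    truth["faulted"] = truth["name"].isin(faulted_names)
    params = dict(result.params)
    params.update(
        {
            "fault_read_index": read_index,
            "fault_cycle": cycle,
            "fault_fraction": fraction,
            "fault_seed": seed,
        }
    )
    return SimulationResult(new_pairs, truth, params)


def _truncate_read(r: SimulatedRead, cycle: int) -> SimulatedRead:
    L = len(r.seq)
    if cycle > L:
        return r
    k = L - cycle + 1  # cycles c..L become N and soft clip
    if r.is_reverse:
        # as-sequenced tail = alignment-orientation head
        seq = "N" * k + r.seq[k:]
        quals = [2] * k + list(r.quals[k:])
        cigar, pos = clip_query_bases(r.cigar, r.pos, k, "left")
    else:
        seq = r.seq[: L - k] + "N" * k
        quals = list(r.quals[: L - k]) + [2] * k
        cigar, pos = clip_query_bases(r.cigar, r.pos, k, "right")
    return replace(r, seq=seq, quals=quals, cigar=cigar, pos=pos)


# ---------------------------------------------------------------------------
# SAM output


def _flags(r: SimulatedRead, mate: SimulatedRead) -> int:
    f = 0x1 | 0x2
    if r.is_reverse:
        f |= 0x10
    if mate.is_reverse:
        f |= 0x20
    f |= 0x40 if r.is_first_in_pair else 0x80
    return f


def write_sam(
    pairs: list[tuple[SimulatedRead, SimulatedRead]],
    chrom_lengths: dict[str, int],
    path: str,
    sort_mode: str = "coordinate",
) -> None:
    """Write simulated pairs as a SAM file sorted by coordinate or name."""
    order = {c: i for i, c in enumerate(chrom_lengths)}
    records: list[tuple[tuple, SimulatedRead, SimulatedRead]] = []
    for r1, r2 in pairs:
        for r, mate in ((r1, r2), (r2, r1)):
            if sort_mode == "coordinate":
                key = (order[r.chrom], r.pos, r.name, not r.is_first_in_pair)
            elif sort_mode == "name":
                key = (r.name, not r.is_first_in_pair)
            else:
                raise ValueError(f"unknown sort_mode {sort_mode!r}")
            records.append((key, r, mate))
    records.sort(key=lambda t: t[0])
    so = "coordinate" if sort_mode == "coordinate" else "queryname"
    with open(path, "w") as fh:
        fh.write(f"@HD\tVN:1.6\tSO:{so}\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for _, r, mate in records:
            lo = min(r.pos, mate.pos)
            hi = max(r.reference_end(), mate.reference_end())
            tlen = hi - lo
            if r.pos > mate.pos or (r.pos == mate.pos and r.is_reverse):
                tlen = -tlen
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(
                "\t".join(
                    [
                        r.name,
                        str(_flags(r, mate)),
                        r.chrom,
                        str(r.pos + 1),
                        str(r.mapq),
                        r.cigar_string(),
                        "=",
                        str(mate.pos + 1),
                        str(tlen),
                        r.seq,
                        qual,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# experiment decoder


def make_decoder(
    n_samples: int = 12,
    n_replicates: int = 6,
    n_groups: int = 4,
    qc_dirs: list[str] | None = None,
) -> pd.DataFrame:
    """Replicate metadata table for a multi-sample, multi-lane experiment.

    The default layout mirrors a technical-replication design: 12
    biological samples, each sequenced as 6 technical replicates (one per
    sequencer lane), with 4 biological condition groups of 3 samples each
    — 72 replicate rows in all.
    """
    rows = []
    for s in range(n_samples):
        group = f"GRP{s * n_groups // n_samples + 1}"
        for rep in range(n_replicates):
            rows.append(
                (
                    f"SAMP{s + 1:02d}_RG{rep + 1:02d}",
                    f"SAMP{s + 1:02d}",
                    f"LANE{rep + 1:02d}",
                    group,
                )
            )
    df = pd.DataFrame(rows, columns=["unique_id", "sample_id", "lane_id", "group_id"])
    df["qc_dir"] = qc_dirs if qc_dirs is not None else "."
    return df


def simulate_dataset(
    out_gtf: str,
    out_sam: str,
    out_truth: str | None = None,
    n_genes: int = 20,
    n_pairs: int = 10_000,
    seed: int = 0,
    sort_mode: str = "coordinate",
    fault: tuple[int, int, float] | None = None,
    **sim_kwargs,
) -> SimulationResult:
    """One-call fixture: annotation + simulated SAM + truth table on disk.

    ``fault`` is an optional (read_index, cycle, fraction) triple applied
    with :func:`inject_fault` before the SAM is written.
    """
    ann_kwargs = {
        k: sim_kwargs.pop(k)
        for k in list(sim_kwargs)
        if k in ("overlap_fraction", "gc_fraction", "exon_count_range", "alt_transcript_prob", "with_cds")
    }
    genes, chrom_lengths, genome = make_annotation(
        n_genes=n_genes, seed=seed, **ann_kwargs
    )
    write_gtf(genes, out_gtf)
    result = simulate_pairs(genes, genome, n_pairs=n_pairs, seed=seed + 1, **sim_kwargs)
    if fault is not None:
        read_index, cycle, fraction = fault
        result = inject_fault(result, read_index, cycle, fraction, seed=seed + 2)
    write_sam(result.pairs, chrom_lengths, out_sam, sort_mode=sort_mode)
    if out_truth:
        result.truth.to_csv(out_truth, sep="\t", index=False)
    return result
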