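"""Independent brute-force oracles used to validate the streaming code.

Everything here works base by base with linear scans over the raw
annotation — deliberately slow, with no shared logic with the package's
interval indexes or accumulators.
"""

from __future__ import annotations

import numpy as np

from pairqc.alignment_io import ReadPair
from pairqc.annotation import GeneModel


def make_read(
    name="r",
    first=True,
    reverse=False,
    chrom="chr1",
    pos=100,
    cigar=((("M", 50),)),
    seq=None,
    quals=None,
    mapq=60,
):
    from pairqc.alignment_io import AlignedRead

    qlen = sum(n for op, n in cigar if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    if quals is None:
        quals = (30,) * len(seq)
    return AlignedRead(
        name=name, is_first_in_pair=first, is_reverse=reverse,
        is_secondary=False, is_supplementary=False, is_unmapped=False,
        chrom=chrom, pos=pos, mapq=mapq, cigar=tuple(cigar), seq=seq,
        quals=tuple(quals),
    )


def make_pair(r1_kwargs=None, r2_kwargs=None, name="p"):
    k1 = {"first": True, **(r1_kwargs or {})}
    k2 = {"first": False, "reverse": True, **(r2_kwargs or {})}
    return ReadPair(make_read(name=name, **k1), make_read(name=name, **k2))


def pair_footprint_bases(pair: ReadPair) -> dict[str, set[int]]:
    """All aligned reference bases (M/=/X) of both mates, per chromosome."""
    out: dict[str, set[int]] = {}
    for r in (pair.r1, pair.r2):
        if r.is_unmapped or r.chrom is None:
            continue
        bases = out.setdefault(r.chrom, set())
        ref = r.pos
        for op, n in r.cigar:
            if op in "M=X":
                bases.update(range(ref, ref + n))
                ref += n
            elif op in "DN":
                ref += n
    return out


def brute_gene_sets(
    genes: list[GeneModel], chrom: str, bases: set[int], strand: str | None
) -> set[str]:
    """Union over bases of genes whose exons cover the base (linear scan)."""
    hit = set()
    for g in genes:
        if g.chrom != chrom:
            continue
        if strand is not None and g.strand in "+-" and g.strand != strand:
            continue
        for e in g.exon_intervals():
            if any(e.start <= b < e.end for b in bases):
                hit.add(g.gene_id)
                break
    return hit


def brute_assign_pair(
    genes: list[GeneModel], pair: ReadPair, strand: str | None
) -> str:
    fp = pair_footprint_bases(pair)
    if len(fp) != 1:
        return "_unassignable"
    chrom, bases = next(iter(fp.items()))
    hit = brute_gene_sets(genes, chrom, bases, strand)
    if not hit:
        return "_no_feature"
    if len(hit) > 1:
        return "_ambiguous"
    return next(iter(hit))


def brute_region_class(genes: list[GeneModel], chrom: str, base: int) -> str:
    """Finest region class of one base with precedence CDS > UTR > exon > intron."""
    in_cds = in_utr = in_exon = in_span = False
    for g in genes:
        if g.chrom != chrom:
            continue
        for iv in g.cds_intervals:
            if iv.start <= base < iv.end:
                in_cds = True
        for iv in g.utr_intervals:
            if iv.start <= base < iv.end:
                in_utr = True
        for iv in g.exon_intervals():
            if iv.start <= base < iv.end:
                in_exon = True
        sp = g.span
        if sp.start <= base < sp.end:
            in_span = True
    if in_cds:
        return "CDS"
    if in_utr:
        return "UTR"
    if in_exon:
        return "exon_other"
    if in_span:
        return "intron"
    return "intergenic"


def brute_pair_region(genes: list[GeneModel], pair: ReadPair) -> str:
    fp = pair_footprint_bases(pair)
    if len(fp) != 1:
        return "ambiguous_region"
    chrom, bases = next(iter(fp.items()))
    counts = {"CDS": 0, "UTR": 0, "exon_other": 0, "intron": 0, "intergenic": 0}
    for b in bases:
        counts[brute_region_class(genes, chrom, b)] += 1
    order = ("CDS", "UTR", "exon_other", "intron", "intergenic")
    return max(order, key=lambda c: (counts[c], -order.index(c)))


def brute_flatten(genes: list[GeneModel]) -> list[tuple[str, str, int, int]]:
    """Per-base exon labeling + run-length encoding, as (chrom, strand, s, e).

    A new run starts wherever the set of (gene, transcript-exon-boundary)
    membership changes. Returns segments of the exonic union split at
    every exon start/end of any member transcript, matching the flattened
    exon-part geometry. Strand '.' merges with '+'.
    """
    out = []
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        s = "+" if g.strand == "." else g.strand
        groups.setdefault((g.chrom, s), []).append(g)
    for (chrom, strand), gs in sorted(groups.items()):
        boundaries = set()
        covered = set()
        for g in gs:
            for e in g.exon_intervals():
                boundaries.add(e.start)
                boundaries.add(e.end)
                covered.update(range(e.start, e.end))
        if not covered:
            continue
        lo, hi = min(covered), max(covered) + 1
        run_start = None
        for b in range(lo, hi + 1):
            inside = b in covered
            at_boundary = b in boundaries
            if run_start is None:
                if inside:
                    run_start = b
            else:
                if not inside:
                    out.append((chrom, strand, run_start, b))
                    run_start = None
                elif at_boundary:
                    out.append((chrom, strand, run_start, b))
                    run_start = b
        assert run_start is None
    return sorted(out)


def brute_junctions(genes: list[GeneModel]) -> set[tuple[str, str, int, int]]:
    out = set()
    for g in genes:
        for tx in g.transcripts:
            ex = sorted(tx.exons, key=lambda e: e.start)
            for a, b in zip(ex[:-1], ex[1:]):
                if a.end < b.start:
                    out.add((g.chrom, g.strand, a.end, b.start))
    return out


def brute_read_junctions(pair: ReadPair) -> set[tuple[str, int, int]]:
    out = set()
    for r in (pair.r1, pair.r2):
        ref = r.pos
        for op, n in r.cigar:
            if op == "N":
                out.add((r.chrom, ref, ref + n))
            if op in "MDN=X":
                ref += n
    return out


def brute_wiggle(
    pairs: list[ReadPair], chrom_lengths: dict[str, int], window: int
) -> dict[str, np.ndarray]:
    depth = {
        c: np.zeros(length, dtype=np.int64) for c, length in chrom_lengths.items()
    }
    for p in pairs:
        for chrom, bases in pair_footprint_bases(p).items():
            for b in bases:
                depth[chrom][b] += 1
    out = {}
    for c, d in depth.items():
        n_win = -(-len(d) // window)
        padded = np.zeros(n_win * window, dtype=np.int64)
        padded[: len(d)] = d
        out[c] = padded.reshape(n_win, window).sum(axis=1)
    return out
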