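"""SAM/BAM streaming, read-pair reconstruction and the retention filter.

Records are read with pysam and converted to a light :class:`AlignedRead`
so that downstream accumulators never touch pysam objects. Pairing joins
the two primary records of a template; the retention filter drops pairs
with an unmapped, secondary, supplementary or low-MAPQ mate and tallies
every drop reason so that every input record is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

__all__ = [
    "AlignedRead",
    "ReadPair",
    "FilterTally",
    "PairingError",
    "read_alignments",
    "read_header_lengths",
    "pair_reads",
    "filter_pair",
    "stream_pairs",
    "CIGAR_OPS",
    "QUERY_CONSUMING",
    "REF_CONSUMING",
]

CIGAR_OPS = "MIDNSHP=X"
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")

DEFAULT_MIN_MAPQ = 50
DEFAULT_PAIR_CACHE_LIMIT = 2_000_000


class PairingError(RuntimeError):
    pass


@dataclass
class AlignedRead:
    """One alignment record, coordinates 0-based, sequence in alignment orientation."""

    name: str
    is_first_in_pair: bool
    is_reverse: bool
    is_secondary: bool
    is_supplementary: bool
    is_unmapped: bool
    chrom: str | None
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    quals: tuple[int, ...]
    is_duplicate: bool = False

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def read_length(self) -> int:
        if self.seq:
            return len(self.seq)
        return sum(n for op, n in self.cigar if op in QUERY_CONSUMING)

    def reference_end(self) -> int:
        """One past the rightmost reference base consumed by the alignment."""
        return self.pos + sum(n for op, n in self.cigar if op in REF_CONSUMING)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals covered by M/=/X ops (D and N excluded)."""
        blocks: list[tuple[int, int]] = []
        ref = self.pos
        for op, n in self.cigar:
            if op in "M=X":
                if blocks and blocks[-1][1] == ref:
                    blocks[-1] = (blocks[-1][0], ref + n)
                else:
                    blocks.append((ref, ref + n))
                ref += n
            elif op in "DN":
                ref += n
        return blocks

    def skip_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals spanned by N (intron skip) ops."""
        blocks = []
        ref = self.pos
        for op, n in self.cigar:
            if op == "N":
                blocks.append((ref, ref + n))
            if op in REF_CONSUMING:
                ref += n
        return blocks


@dataclass
class ReadPair:
    r1: AlignedRead
    r2: AlignedRead

    @property
    def name(self) -> str:
        return self.r1.name

    def mates(self) -> tuple[AlignedRead, AlignedRead]:
        return (self.r1, self.r2)

    def footprint(self) -> dict[str, list[tuple[int, int]]]:
        """Union of both mates' aligned reference bases, per chromosome."""
        from .annotation import merge_intervals

        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in self.mates():
            if r.is_unmapped or r.chrom is None:
                continue
            per_chrom.setdefault(r.chrom, []).extend(r.aligned_blocks())
        return {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}


FILTER_REASONS = (
    "unmapped",
    "secondary",
    "supplementary",
    "low_mapq",
    "duplicate",
    "unpaired_mate",
    "retained",
)


@dataclass
class FilterTally:
    """Pair- and record-level accounting of the retention filter."""

    counts: dict[str, int] = field(
        default_factory=lambda: dict.fromkeys(FILTER_REASONS, 0)
    )

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] += n

    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------

def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = tuple(
        (CIGAR_OPS[op], n) for op, n in (rec.cigartuples or ())
    )
    seq = rec.query_sequence or ""
    quals = tuple(rec.query_qualities) if rec.query_qualities is not None else ()
    return AlignedRead(
        name=rec.query_name,
        is_first_in_pair=bool(rec.is_read1),
        is_reverse=bool(rec.is_reverse),
        is_secondary=bool(rec.is_secondary),
        is_supplementary=bool(rec.is_supplementary),
        is_unmapped=bool(rec.is_unmapped),
        chrom=rec.reference_name if not rec.is_unmapped else rec.reference_name,
        pos=rec.reference_start if rec.reference_start is not None else -1,
        mapq=rec.mapping_quality,
        cigar=cigar,
        seq=seq,
        quals=quals,
        is_duplicate=bool(rec.is_duplicate),
    )


def read_alignments(path: str) -> Iterator[AlignedRead]:
    """Stream records from a SAM/BAM file in file order, positions 0-based."""
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for rec in fh:
                yield _from_pysam(rec)
    finally:
        pysam.set_verbosity(save)


def read_header_lengths(path: str) -> dict[str, int]:
    """Chromosome lengths declared in the alignment header."""
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            return dict(zip(fh.references, fh.lengths))
    finally:
        pysam.set_verbosity(save)


def pair_reads(
    stream: Iterable[AlignedRead],
    sort_mode: str = "name",
    tally: FilterTally | None = None,
    cache_limit: int = DEFAULT_PAIR_CACHE_LIMIT,
) -> Iterator[ReadPair]:
    """Join primary records into read pairs.

    In ``name`` mode, same-name records must be adjacent; in ``coordinate``
    mode unmatched mates are held in a bounded name-keyed cache until the
    mate arrives. Secondary and supplementary records are tallied and never
    paired; leftover single records are tallied as ``unpaired_mate``. Pairs
    are emitted exactly once, in order of completion.
    """
    if sort_mode not in ("name", "coordinate"):
        raise ValueError(f"unknown sort_mode {sort_mode!r}")
    if tally is None:
        tally = FilterTally()
    cache: dict[str, AlignedRead] = {}

    def _emit(a: AlignedRead, b: AlignedRead) -> ReadPair:
        if a.is_first_in_pair == b.is_first_in_pair:
            raise PairingError(
                f"records named {a.name!r} are not a first/second mate pair "
                "(three primary records sharing a name, or flags malformed)"
            )
        return ReadPair(a, b) if a.is_first_in_pair else ReadPair(b, a)

    for rec in stream:
        if rec.is_secondary:
            tally.add("secondary")
            continue
        if rec.is_supplementary:
            tally.add("supplementary")
            continue
        mate = cache.pop(rec.name, None)
        if mate is not None:
            yield _emit(mate, rec)
            continue
        if sort_mode == "name" and cache:
            # adjacency broken: everything cached is orphaned
            tally.add("unpaired_mate", len(cache))
            cache.clear()
        cache[rec.name] = rec
        if len(cache) > cache_limit:
            raise PairingError(
                f"mate cache exceeded {cache_limit} records; the input does "
                "not appear to be name-sorted with adjacent mates — re-sort "
                "by name or raise the cache limit"
            )
    tally.add("unpaired_mate", len(cache))


def filter_pair(
    pair: ReadPair, min_mapq: int = DEFAULT_MIN_MAPQ, drop_duplicates: bool = False
) -> tuple[bool, str]:
    """Apply the retention filter; returns (retained, reason).

    Reason precedence: unmapped > secondary > supplementary > low_mapq.
    """
    mates = pair.mates()
    if any(r.is_unmapped for r in mates):
        return False, "unmapped"
    if any(r.is_secondary for r in mates):
        return False, "secondary"
    if any(r.is_supplementary for r in mates):
        return False, "supplementary"
    if any(r.mapq < min_mapq for r in mates):
        return False, "low_mapq"
    if drop_duplicates and any(r.is_duplicate for r in mates):
        return False, "duplicate"
    return True, "retained"


def stream_pairs(
    path: str,
    sort_mode: str = "name",
    min_mapq: int = DEFAULT_MIN_MAPQ,
    tally: FilterTally | None = None,
    drop_duplicates: bool = False,
) -> Iterator[ReadPair]:
    """Read, pair and filter an alignment file; yields retained pairs only."""
    if tally is None:
        tally = FilterTally()
    for pair in pair_reads(read_alignments(path), sort_mode, tally):
        retained, reason = filter_pair(pair, min_mapq, drop_duplicates)
        tally.add(reason)
        if retained:
            yield pair
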