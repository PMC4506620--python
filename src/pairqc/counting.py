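"""Downstream-analysis count tables.

Gene-level counting follows the HTSeq "union" rule on read pairs: the
assignment set is the union, over every aligned reference base of both
mates (M/=/X ops only; D- and N-spanned bases are not aligned bases), of
the genes whose exons overlap that base. Exactly one gene retains the
pair; an empty union is ``_no_feature`` and a larger one ``_ambiguous``.
Exon-part counts (the differential-exon-usage input) increment every
flattened part of the unambiguously assigned aggregate that the pair
footprint touches. Junction counting is per pair (a junction seen by both
mates counts once) with known/novel and high/low-coverage classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .alignment_io import AlignedRead, ReadPair
from .annotation import AnnotatedJunction, FeatureIndex, GeneModel

__all__ = [
    "GeneCounter",
    "ExonPartCounter",
    "JunctionCounter",
    "assign_pair_union",
    "fragment_strand",
    "extract_junctions",
    "compute_fpkm",
    "NO_FEATURE",
    "AMBIGUOUS",
    "UNASSIGNABLE",
    "STRAND_MODES",
    "DEFAULT_HIGH_COVERAGE_THRESHOLD",
]

NO_FEATURE = "_no_feature"
AMBIGUOUS = "_ambiguous"
UNASSIGNABLE = "_unassignable"
BOOKKEEPING = (NO_FEATURE, AMBIGUOUS, UNASSIGNABLE)

STRAND_MODES = ("unstranded", "first_strand", "second_strand")
DEFAULT_HIGH_COVERAGE_THRESHOLD = 4


def fragment_strand(pair_or_read: ReadPair | AlignedRead, strand_mode: str) -> str:
    """Library-protocol-resolved strand of the originating fragment.

    Under a second-strand (forward) protocol read 1 aligns to the fragment
    strand; under first-strand (reverse, e.g. dUTP) it aligns opposite.
    Unstranded libraries carry no strand information: returns ".".
    """
    if strand_mode == "unstranded":
        return "."
    if isinstance(pair_or_read, ReadPair):
        r1 = pair_or_read.r1
        r1_strand = r1.strand
    else:
        r = pair_or_read
        r1_strand = r.strand if r.is_first_in_pair else ("-" if not r.is_reverse else "+")
    if strand_mode == "second_strand":
        return r1_strand
    if strand_mode == "first_strand":
        return "-" if r1_strand == "+" else "+"
    raise ValueError(f"unknown strand mode {strand_mode!r}")


def assign_pair_union(
    pair: ReadPair, index: FeatureIndex, strand_mode: str = "unstranded"
) -> str:
    """Union-rule gene assignment of a read pair.

    Returns a gene id, or one of the bookkeeping categories
    ``_no_feature`` / ``_ambiguous`` / ``_unassignable`` (the latter when
    the mates map to different chromosomes so no single footprint exists).
    """
    fp = pair.footprint()
    if len(fp) != 1:
        return UNASSIGNABLE
    chrom, ivs = next(iter(fp.items()))
    strand = fragment_strand(pair, strand_mode)
    genes = index.genes_overlapping(chrom, ivs, None if strand == "." else strand)
    if not genes:
        return NO_FEATURE
    if len(genes) > 1:
        return AMBIGUOUS
    return next(iter(genes))


@dataclass
class GeneCounter:
    """Union-rule gene count table with bookkeeping rows."""

    index: FeatureIndex
    strand_mode: str = "unstranded"
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid in self.index.genes:
            self.counts.setdefault(gid, 0)
        for cat in BOOKKEEPING:
            self.counts.setdefault(cat, 0)

    def update(self, pair: ReadPair) -> str:
        assignment = assign_pair_union(pair, self.index, self.strand_mode)
        self.counts[assignment] = self.counts.get(assignment, 0) + 1
        return assignment

    def gene_counts(self) -> dict[str, int]:
        return {g: c for g, c in self.counts.items() if g not in BOOKKEEPING}

    def assigned_total(self) -> int:
        return sum(self.gene_counts().values())

    def table(self) -> pd.DataFrame:
        genes = sorted(self.gene_counts())
        rows = [(g, self.counts[g]) for g in genes]
        rows += [(cat, self.counts[cat]) for cat in BOOKKEEPING]
        return pd.DataFrame(rows, columns=["gene_id", "count"])

    def assignment_rate_table(self) -> pd.DataFrame:
        rows = [
            ("assigned", self.assigned_total()),
            ("no_feature", self.counts[NO_FEATURE]),
            ("ambiguous", self.counts[AMBIGUOUS]),
            ("unassignable", self.counts[UNASSIGNABLE]),
        ]
        return pd.DataFrame(rows, columns=["category", "pairs"])

    def write(self, path: str) -> None:
        self.table().to_csv(path, sep="\t", index=False, header=False)


@dataclass
class ExonPartCounter:
    """Flattened exon-part counts for differential exon usage.

    A pair must resolve to exactly one aggregate gene under the union
    rule (at aggregate granularity); every part of that aggregate touched
    by at least one aligned base of the pair footprint gains one count.
    """

    index: FeatureIndex
    strand_mode: str = "unstranded"
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid in self.index.parts:
            self.counts.setdefault(pid, 0)

    def update(self, pair: ReadPair) -> list[str]:
        fp = pair.footprint()
        if len(fp) != 1:
            return []
        chrom, ivs = next(iter(fp.items()))
        strand = fragment_strand(pair, self.strand_mode)
        genes = self.index.genes_overlapping(
            chrom, ivs, None if strand == "." else strand
        )
        aggregates = {self.index.aggregate_of_gene[g] for g in genes}
        if len(aggregates) != 1:
            return []
        agg = next(iter(aggregates))
        hit = [
            pid
            for pid in self.index.parts_overlapping(chrom, ivs)
            if self.index.parts[pid].aggregate_gene_id == agg
        ]
        for pid in hit:
            self.counts[pid] += 1
        return sorted(hit)

    def table(self) -> pd.DataFrame:
        parts = sorted(self.counts)
        return pd.DataFrame(
            {"part_id": parts, "count": [self.counts[p] for p in parts]}
        )

    def write(self, path: str) -> None:
        self.table().to_csv(path, sep="\t", index=False, header=False)


class MalformedSpliceError(ValueError):
    pass


def extract_junctions(
    read: AlignedRead, strand: str = "."
) -> list[tuple[str, str, int, int]]:
    """Splice junctions implied by a read's N (reference-skip) CIGAR ops.

    Each N op yields one (chrom, strand, intron_start, intron_end) tuple.
    An N op with no reference-consuming aligned block on both sides is
    malformed and raises :class:`MalformedSpliceError`.
    """
    out = []
    ref = read.pos
    n_ops = len(read.cigar)
    for i, (op, n) in enumerate(read.cigar):
        if op == "N":
            before = any(o in "M=XD" for o, _ in read.cigar[:i])
            after = any(o in "M=XD" for o, _ in read.cigar[i + 1 :])
            if not (before and after):
                raise MalformedSpliceError(
                    f"read {read.name}: N op at CIGAR position {i + 1}/{n_ops} "
                    "has no flanking aligned block"
                )
            out.append((read.chrom, strand, ref, ref + n))
        if op in "MDN=X":
            ref += n
    return out


class JunctionCounter:
    """Per-pair splice-junction counts with known/novel classification.

    A junction observed by both mates of a pair counts once. An observed
    junction matching an annotated intron exactly (strand-compatible: an
    unstranded observation matches either annotated strand) is recorded
    under the annotated locus and flagged known; all annotated junctions
    are emitted even when unobserved. Loci with at least
    ``high_coverage_threshold`` supporting pairs are classed high-coverage.
    """

    def __init__(
        self,
        annotated: set[AnnotatedJunction],
        strand_mode: str = "unstranded",
        high_coverage_threshold: int = DEFAULT_HIGH_COVERAGE_THRESHOLD,
    ) -> None:
        self.strand_mode = strand_mode
        self.high_coverage_threshold = high_coverage_threshold
        self._annotated_by_locus: dict[tuple[str, int, int], list[AnnotatedJunction]] = {}
        for j in annotated:
            self._annotated_by_locus.setdefault((j.chrom, j.start, j.end), []).append(j)
        self.counts: dict[tuple[str, str, int, int], int] = {}
        self.known: dict[tuple[str, str, int, int], bool] = {}
        for j in sorted(annotated):
            key = (j.chrom, j.strand, j.start, j.end)
            self.counts[key] = 0
            self.known[key] = True
        self.malformed_reads = 0

    def _canonical(self, obs: tuple[str, str, int, int]) -> tuple[tuple[str, str, int, int], bool]:
        chrom, strand, s, e = obs
        cands = self._annotated_by_locus.get((chrom, s, e), ())
        for j in cands:
            if strand == "." or j.strand == "." or j.strand == strand:
                return (j.chrom, j.strand, j.start, j.end), True
        return obs, False

    def update(self, pair: ReadPair) -> set[tuple[str, str, int, int]]:
        strand = fragment_strand(pair, self.strand_mode)
        observed: set[tuple[str, str, int, int]] = set()
        for r in pair.mates():
            try:
                observed |= {tuple(j) for j in extract_junctions(r, strand)}
            except MalformedSpliceError:
                self.malformed_reads += 1
        canon: set[tuple[str, str, int, int]] = set()
        for obs in observed:
            key, is_known = self._canonical(obs)
            canon.add(key)
            if key not in self.counts:
                self.counts[key] = 0
                self.known[key] = is_known
        for key in canon:
            self.counts[key] += 1
        return canon

    def table(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.counts):
            chrom, strand, s, e = key
            rows.append(
                (
                    chrom,
                    strand,
                    s,
                    e,
                    self.known[key],
                    self.counts[key],
                    "high"
                    if self.counts[key] >= self.high_coverage_threshold
                    else "low",
                )
            )
        return pd.DataFrame(
            rows,
            columns=["chrom", "strand", "intron_start", "intron_end", "known", "count", "coverage_class"],
        )

    def summary_table(self) -> pd.DataFrame:
        """Distinct-locus and event (pair-observation) counts by class."""
        rows = []
        df = self.table()
        for known_flag, kname in ((True, "known"), (False, "novel")):
            for cls in ("high", "low"):
                sub = df[(df["known"] == known_flag) & (df["coverage_class"] == cls)]
                # unobserved annotated loci are listed but carry no events
                if not known_flag:
                    sub = sub[sub["count"] > 0]
                rows.append((f"{kname}_{cls}", len(sub), int(sub["count"].sum())))
        return pd.DataFrame(rows, columns=["class", "loci", "events"])

    def write(self, path: str) -> None:
        self.table().to_csv(path, sep="\t", index=False)


def compute_fpkm(
    gene_counts: dict[str, int], gene_lengths: dict[str, int]
) -> pd.DataFrame:
    """Fragments per kilobase of exonic-union length per million assigned pairs.

    FPKM(g) = count(g) * 1e9 / (length_bp(g) * assigned_total). With no
    assigned pairs every value is NA.
    """
    assigned_total = sum(gene_counts.values())
    rows = []
    for g in sorted(gene_counts):
        count = gene_counts[g]
        length = gene_lengths[g]
        if assigned_total == 0:
            fpkm = math.nan
        else:
            fpkm = count * 1e9 / (length * assigned_total)
        rows.append((g, count, length, fpkm))
    return pd.DataFrame(rows, columns=["gene_id", "count", "length_bp", "fpkm"])
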