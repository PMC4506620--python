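"""Transcript annotation: gene models, flattened exon parts, junctions, interval index.

Parses Ensembl-style GTF into :class:`GeneModel` objects, derives the
disjoint "exon part" set used for differential-exon-usage counting (same
flattening as the DEXSeq preparation step: same-strand genes with
overlapping exons are merged into one aggregate, and every exon boundary of
every member transcript induces a part boundary), extracts the set of
annotated splice junctions, and builds a per-chromosome interval index for
gene / exon-part / region-class queries.

All internal coordinates are 0-based half-open; conversion from the GTF's
1-based closed convention happens in :func:`parse_gtf` only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "FlatExonPart",
    "AnnotatedJunction",
    "FeatureIndex",
    "GtfParseError",
    "parse_gtf",
    "flatten_exons",
    "extract_annotated_junctions",
    "build_index",
    "write_flat_annotation",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand in {+, -, .}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def sorted_exons(self) -> list[GenomicInterval]:
        return sorted(self.exons, key=lambda e: e.start)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    cds_intervals: list[GenomicInterval] = field(default_factory=list)
    utr_intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for t in self.transcripts for e in t.exons]
        ends = [e.end for t in self.transcripts for e in t.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def exon_intervals(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]

    def exonic_union(self) -> list[tuple[int, int]]:
        """Merged (start, end) tuples of all exons across transcripts."""
        return merge_intervals([(e.start, e.end) for e in self.exon_intervals()])

    def exonic_union_length(self) -> int:
        return sum(e - s for s, e in self.exonic_union())


@dataclass(frozen=True)
class FlatExonPart:
    """A disjoint exonic segment within an aggregate gene.

    ``part_id`` is ``"<aggregate_gene_id>:E<k>"`` with k zero-padded and
    increasing with genomic start. ``aggregate_gene_id`` joins member gene
    ids with ``+`` when exons of distinct same-strand genes overlap.
    """

    part_id: str
    interval: GenomicInterval
    aggregate_gene_id: str
    member_gene_ids: frozenset[str]


@dataclass(frozen=True, order=True)
class AnnotatedJunction:
    """A distinct (chrom, strand, intron) locus derived from adjacent exons."""

    chrom: str
    strand: str
    start: int  # first intronic base, 0-based
    end: int  # one past last intronic base

    @property
    def intron(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


# ---------------------------------------------------------------------------
# interval helpers

def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/touching (start, end) tuples; returns sorted list."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a - b over merged interval lists."""
    out: list[tuple[int, int]] = []
    bi = 0
    b = merge_intervals(b)
    for s, e in merge_intervals(a):
        cur = s
        while bi < len(b) and b[bi][1] <= cur:
            bi += 1
        j = bi
        while j < len(b) and b[j][0] < e:
            bs, be = b[j]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap in bases between two merged interval lists."""
    total = 0
    i = j = 0
    a = merge_intervals(a)
    b = merge_intervals(b)
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


# ---------------------------------------------------------------------------
# GTF parsing

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_CONSUMED_FEATURES = {
    "exon",
    "CDS",
    "UTR",
    "five_prime_utr",
    "three_prime_utr",
}


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str) -> list[GeneModel]:
    """Parse a GTF file into gene models.

    Only ``exon``, ``CDS`` and UTR features are consumed; all other feature
    types are ignored. Exon features must carry ``gene_id`` and
    ``transcript_id`` attributes. GTF 1-based closed coordinates are
    converted to 0-based half-open.
    """
    transcripts: dict[str, TranscriptModel] = {}
    gene_info: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected >=8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame = fields[:8]
            if feature not in _CONSUMED_FEATURES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end1 < start1:
                raise GtfParseError(
                    f"{path}: line {lineno}: end ({end1}) < start ({start1})"
                )
            attrs = _parse_attributes(fields[8]) if len(fields) > 8 else {}
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing gene_id attribute"
                )
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            info = gene_info.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "cds": [], "utr": []}
            )
            if feature == "exon":
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise GtfParseError(
                        f"{path}: line {lineno}: exon missing transcript_id"
                    )
                tx = transcripts.setdefault(
                    tx_id, TranscriptModel(tx_id, gene_id, [])
                )
                if tx.exons and tx.exons[0].chrom != chrom:
                    raise GtfParseError(
                        f"{path}: line {lineno}: transcript {tx_id} spans "
                        f"chromosomes {tx.exons[0].chrom} and {chrom}"
                    )
                tx.exons.append(iv)
            elif feature == "CDS":
                info["cds"].append(iv)
            else:  # UTR variants
                info["utr"].append(iv)

    genes: dict[str, GeneModel] = {}
    for tx in transcripts.values():
        # enforce the sorted non-overlapping exon invariant: merge any
        # overlapping exon records within one transcript
        merged = merge_intervals([(e.start, e.end) for e in tx.exons])
        chrom, strand = tx.exons[0].chrom, tx.exons[0].strand
        tx.exons = [GenomicInterval(chrom, s, e, strand) for s, e in merged]
        info = gene_info[tx.gene_id]
        gene = genes.setdefault(
            tx.gene_id,
            GeneModel(
                tx.gene_id,
                info["chrom"],
                info["strand"],
                [],
                list(info["cds"]),
                list(info["utr"]),
            ),
        )
        gene.transcripts.append(tx)
    # deterministic ordering
    out = [genes[g] for g in sorted(genes)]
    for g in out:
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return out


# ---------------------------------------------------------------------------
# flattening

def _merge_strand(strand: str) -> str:
    return "+" if strand == "." else strand


def flatten_exons(genes: list[GeneModel]) -> list[FlatExonPart]:
    """Flatten gene exons into disjoint exon parts per aggregate gene.

    Same-strand genes whose exons overlap by at least one base are merged
    (transitively) into one aggregate named by joining member gene ids with
    ``+``. Within each aggregate the parts are the disjoint segments of the
    exonic union induced by every exon boundary of every member transcript.
    Unstranded (".") genes are treated as "+" for merging, with a warning.
    """
    for g in genes:
        if g.strand == ".":
            logger.warning(
                "gene %s is unstranded; treated as '+' for exon flattening",
                g.gene_id,
            )
    # group genes by chrom and merge-strand
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        groups.setdefault((g.chrom, _merge_strand(g.strand)), []).append(g)

    parts: list[FlatExonPart] = []
    for (chrom, strand), members in sorted(groups.items()):
        # transitive aggregation by exonic-union overlap: sweep over merged
        # exon intervals tagged by gene
        tagged = []
        for g in members:
            for s, e in g.exonic_union():
                tagged.append((s, e, g.gene_id))
        tagged.sort()
        # union-find over genes: two genes aggregate when any of their
        # exonic-union intervals overlap by >=1 bp (transitively)
        parent: dict[str, str] = {g.gene_id: g.gene_id for g in members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        cur_end = -1
        cur_gid: str | None = None
        for s, e, gid in tagged:
            if cur_gid is not None and s < cur_end:
                union(cur_gid, gid)
                cur_end = max(cur_end, e)
            else:
                cur_end = e
            cur_gid = gid
        components: dict[str, list[str]] = {}
        for g in members:
            components.setdefault(find(g.gene_id), []).append(g.gene_id)
        gene_by_id = {g.gene_id: g for g in members}
        for component in components.values():
            member_ids = sorted(component)
            agg_id = "+".join(member_ids)
            # boundaries from every exon of every member transcript
            bounds: set[int] = set()
            union_ivs: list[tuple[int, int]] = []
            for gid in member_ids:
                for e_iv in gene_by_id[gid].exon_intervals():
                    bounds.add(e_iv.start)
                    bounds.add(e_iv.end)
                    union_ivs.append((e_iv.start, e_iv.end))
            union = merge_intervals(union_ivs)
            sorted_bounds = sorted(bounds)
            k = 0
            for us, ue in union:
                cuts = [b for b in sorted_bounds if us < b < ue]
                edges = [us] + cuts + [ue]
                for ps, pe in zip(edges[:-1], edges[1:]):
                    k += 1
                    parts.append(
                        FlatExonPart(
                            part_id=f"{agg_id}:E{k:03d}",
                            interval=GenomicInterval(chrom, ps, pe, strand),
                            aggregate_gene_id=agg_id,
                            member_gene_ids=frozenset(member_ids),
                        )
                    )
    parts.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.part_id))
    return parts


def extract_annotated_junctions(genes: list[GeneModel]) -> set[AnnotatedJunction]:
    """One junction per distinct (chrom, strand, intron) over all transcripts."""
    out: set[AnnotatedJunction] = set()
    for g in genes:
        for tx in g.transcripts:
            exons = tx.sorted_exons()
            for up, down in zip(exons[:-1], exons[1:]):
                if up.end < down.start:
                    out.add(
                        AnnotatedJunction(g.chrom, g.strand, up.end, down.start)
                    )
    return out


# ---------------------------------------------------------------------------
# feature index

REGION_CLASSES = ("CDS", "UTR", "exon_other", "intron", "intergenic")


class FeatureIndex:
    """Per-chromosome interval index over genes, exon parts and region classes.

    Region classes are maintained as disjoint merged interval lists with
    precedence CDS > UTR > other-exon > intron > intergenic; any base not
    covered by a gene span is intergenic. Queries off annotated chromosomes
    return empty results rather than failing.
    """

    def __init__(self, genes: list[GeneModel], parts: list[FlatExonPart]):
        self.genes = {g.gene_id: g for g in genes}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._part_trees: dict[str, IntervalTree] = {}
        self.parts = {p.part_id: p for p in parts}
        self.aggregate_of_gene: dict[str, str] = {}
        self.parts_by_aggregate: dict[str, list[FlatExonPart]] = {}
        for p in parts:
            self.parts_by_aggregate.setdefault(p.aggregate_gene_id, []).append(p)
            for gid in p.member_gene_ids:
                self.aggregate_of_gene[gid] = p.aggregate_gene_id
            self._part_trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end, p
            )
        for g in genes:
            tree = self._exon_trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exonic_union():
                tree.addi(s, e, g)
        # disjoint region-class unions per chromosome
        self._regions: dict[str, dict[str, list[tuple[int, int]]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            cds = merge_intervals(
                [(iv.start, iv.end) for g in gs for iv in g.cds_intervals]
            )
            utr = merge_intervals(
                [(iv.start, iv.end) for g in gs for iv in g.utr_intervals]
            )
            exon = merge_intervals(
                [iv for g in gs for iv in g.exonic_union()]
            )
            span = merge_intervals([(g.span.start, g.span.end) for g in gs])
            utr_only = subtract_intervals(utr, cds)
            exon_other = subtract_intervals(subtract_intervals(exon, cds), utr)
            intron = subtract_intervals(span, merge_intervals(cds + utr + exon))
            self._regions[chrom] = {
                "CDS": cds,
                "UTR": utr_only,
                "exon_other": exon_other,
                "intron": intron,
            }

    # -- queries ------------------------------------------------------------
    def genes_overlapping(
        self, chrom: str, intervals: list[tuple[int, int]], strand: str | None = None
    ) -> set[str]:
        """Gene ids whose exonic union overlaps any of the query intervals.

        With ``strand`` given, only genes on that strand (or unstranded
        genes) are returned.
        """
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in intervals:
            for iv in tree.overlap(s, e):
                g = iv.data
                if strand is None or g.strand == "." or g.strand == strand:
                    hits.add(g.gene_id)
        return hits

    def parts_overlapping(
        self, chrom: str, intervals: list[tuple[int, int]]
    ) -> set[str]:
        tree = self._part_trees.get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in intervals:
            for iv in tree.overlap(s, e):
                hits.add(iv.data.part_id)
        return hits

    def region_class_lengths(
        self, chrom: str, intervals: list[tuple[int, int]]
    ) -> dict[str, int]:
        """Base counts of each region class over the query intervals."""
        intervals = merge_intervals(intervals)
        total = sum(e - s for s, e in intervals)
        out = dict.fromkeys(REGION_CLASSES, 0)
        regions = self._regions.get(chrom)
        if regions is not None:
            for cls, union in regions.items():
                out[cls] = intersect_length(intervals, union)
        out["intergenic"] = total - sum(
            out[c] for c in ("CDS", "UTR", "exon_other", "intron")
        )
        return out

    def region_class_of_base(self, chrom: str, pos: int) -> str:
        lens = self.region_class_lengths(chrom, [(pos, pos + 1)])
        for cls in REGION_CLASSES:
            if lens[cls]:
                return cls
        return "intergenic"


def build_index(
    genes: list[GeneModel], parts: list[FlatExonPart] | None = None
) -> FeatureIndex:
    if parts is None:
        parts = flatten_exons(genes)
    return FeatureIndex(genes, parts)


# ---------------------------------------------------------------------------
# flattened-annotation output

def write_flat_annotation(parts: list[FlatExonPart], path: str) -> None:
    """Write the flattened exon-part annotation as a GFF-like text file.

    One ``exonic_part`` line per part plus one ``aggregate_gene`` span line
    per aggregate; this file is the key reference for the exon count table.
    """
    by_agg: dict[str, list[FlatExonPart]] = {}
    for p in parts:
        by_agg.setdefault(p.aggregate_gene_id, []).append(p)
    with open(path, "w") as fh:
        for agg in sorted(by_agg):
            ps = sorted(by_agg[agg], key=lambda p: p.interval.start)
            chrom = ps[0].interval.chrom
            strand = ps[0].interval.strand
            lo = min(p.interval.start for p in ps)
            hi = max(p.interval.end for p in ps)
            members = ",".join(sorted(ps[0].member_gene_ids))
            fh.write(
                f"{chrom}\tpairqc\taggregate_gene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t"
                f'aggregate_gene_id "{agg}"; member_genes "{members}";\n'
            )
            for p in ps:
                fh.write(
                    f"{chrom}\tpairqc\texonic_part\t{p.interval.start + 1}\t"
                    f"{p.interval.end}\t.\t{strand}\t.\t"
                    f'part_id "{p.part_id}"; aggregate_gene_id "{agg}"; '
                    f'member_genes "{members}";\n'
                )
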