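"""Streaming per-replicate QC accumulators.

Every metric is accumulated once per retained read pair during a single
traversal of the alignment stream, then emitted as a plain-text
tab-separated table. Cycle-indexed metrics operate in *as-sequenced* cycle
space: reads aligned to the reverse strand are reverse-complemented (and
their CIGAR reversed) back to sequencer orientation before cycle indexing,
so that per-cycle artifacts line up with the machine cycle at which they
arose. Cycles are 1-based.

Quartiles of discrete per-cycle quality histograms use the lower-quantile
convention (smallest value whose cumulative count reaches ceil(q*n)),
which is exact and deterministic on integer phred scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .alignment_io import AlignedRead, FilterTally, ReadPair
from .annotation import (
    AnnotatedJunction,
    FeatureIndex,
    GeneModel,
    REGION_CLASSES,
    intersect_length,
)

__all__ = [
    "orient_read",
    "CycleAccumulator",
    "GcContentAccumulator",
    "InsertSizeAccumulator",
    "RegionRateAccumulator",
    "StrandednessAccumulator",
    "GeneBodyAccumulator",
    "ChromRateAccumulator",
    "gene_diversity_table",
    "drop_rate_table",
    "write_metric_table",
    "read_metric_table",
    "METRIC_SCHEMAS",
    "MAX_PHRED",
]

MAX_PHRED = 94
BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PROFILE_OPS = ("M", "I", "D", "N", "S", "=", "X")
# '=' is spelled EQ in column headers to stay shell/TSV friendly
_OP_COL = {"=": "EQ"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def orient_read(read: AlignedRead) -> tuple[str, tuple[int, ...], tuple[tuple[str, int], ...]]:
    """Return (seq, quals, cigar) in as-sequenced orientation.

    Reverse-strand alignments store the reverse complement of the sequenced
    read; undo that so cycle 1 is the first sequencer cycle.
    """
    if read.is_reverse:
        return (
            revcomp(read.seq),
            tuple(reversed(read.quals)),
            tuple(reversed(read.cigar)),
        )
    return read.seq, read.quals, read.cigar


# ---------------------------------------------------------------------------
# per-cycle accumulation


class _ReadIndexMatrix:
    """Grow-on-demand per-cycle counters for one read-in-pair index."""

    def __init__(self) -> None:
        self.n_cycles = 0
        cap = 160
        self.qual_hist = np.zeros((cap, MAX_PHRED), dtype=np.int64)
        self.base_counts = np.zeros((cap, len(BASES)), dtype=np.int64)
        self.unclipped_base_counts = np.zeros((cap, len(BASES)), dtype=np.int64)
        self.reads_reaching = np.zeros(cap, dtype=np.int64)
        self.op_counts = {op: np.zeros(cap, dtype=np.int64) for op in PROFILE_OPS}
        # clipped-sequence NVC, indexed by offset from the clip boundary
        self.lead_clip_counts = np.zeros((cap, len(BASES)), dtype=np.int64)
        self.tail_clip_counts = np.zeros((cap, len(BASES)), dtype=np.int64)
        self.max_lead_offset = 0
        self.max_tail_offset = 0
        self.op_lengths: dict[str, dict[int, int]] = {op: {} for op in "MIDNSHP=X"}
        self.ignored_pad_ops = 0

    def _ensure(self, n: int) -> None:
        cap = self.qual_hist.shape[0]
        if n <= cap:
            return
        new_cap = max(n, cap * 2)

        def grow(a: np.ndarray) -> np.ndarray:
            shape = (new_cap,) + a.shape[1:]
            out = np.zeros(shape, dtype=a.dtype)
            out[: a.shape[0]] = a
            return out

        self.qual_hist = grow(self.qual_hist)
        self.base_counts = grow(self.base_counts)
        self.unclipped_base_counts = grow(self.unclipped_base_counts)
        self.reads_reaching = grow(self.reads_reaching)
        self.op_counts = {op: grow(a) for op, a in self.op_counts.items()}
        self.lead_clip_counts = grow(self.lead_clip_counts)
        self.tail_clip_counts = grow(self.tail_clip_counts)

    def update(self, read: AlignedRead) -> None:
        seq, quals, cigar = orient_read(read)
        L = len(seq)
        if L == 0:
            return
        self._ensure(L)
        self.n_cycles = max(self.n_cycles, L)
        self.reads_reaching[:L] += 1
        idx = np.fromiter(
            (_BASE_INDEX.get(b, 4) for b in seq.upper()), dtype=np.int64, count=L
        )
        np.add.at(self.base_counts, (np.arange(L), idx), 1)
        if quals:
            q = np.clip(np.asarray(quals, dtype=np.int64), 0, MAX_PHRED - 1)
            np.add.at(self.qual_hist, (np.arange(L), q), 1)
        # CIGAR walk in as-sequenced orientation
        qpos = 0
        n_query_ops = sum(1 for op, _ in cigar if op in "MIS=X")
        seen_query_ops = 0
        for op, n in cigar:
            if op in "MIS=X":
                if op == "S":
                    self.op_counts["S"][qpos : qpos + n] += 1
                    if seen_query_ops == 0:
                        # lead clip: offsets count backward from the boundary
                        boundary = qpos + n
                        for i in range(n):
                            off = boundary - (qpos + i)  # 1..n
                            self.max_lead_offset = max(self.max_lead_offset, off)
                            self.lead_clip_counts[off - 1, idx[qpos + i]] += 1
                    else:
                        # tail clip: offsets count forward from the boundary
                        for i in range(n):
                            off = i + 1
                            self.max_tail_offset = max(self.max_tail_offset, off)
                            self.tail_clip_counts[off - 1, idx[qpos + i]] += 1
                else:
                    self.op_counts[op][qpos : qpos + n] += 1
                    np.add.at(
                        self.unclipped_base_counts,
                        (np.arange(qpos, qpos + n), idx[qpos : qpos + n]),
                        1,
                    )
                qpos += n
                seen_query_ops += 1
            elif op in "DN":
                # attributed to the boundary between flanking query cycles:
                # recorded at the cycle index of the preceding query base
                if qpos > 0:
                    self.op_counts[op][qpos - 1] += 1
            elif op == "P":
                self.ignored_pad_ops += 1
            if op != "P":
                self.op_lengths[op][n] = self.op_lengths[op].get(n, 0) + 1


class CycleAccumulator:
    """All cycle-indexed sequence/alignment metrics for both mates."""

    def __init__(self) -> None:
        self.mats = (_ReadIndexMatrix(), _ReadIndexMatrix())

    def update(self, pair: ReadPair) -> None:
        self.mats[0].update(pair.r1)
        self.mats[1].update(pair.r2)

    # -- emitted tables -----------------------------------------------------
    @staticmethod
    def _hist_quartiles(counts: np.ndarray) -> tuple[float, float, float, float, float]:
        n = int(counts.sum())
        if n == 0:
            return (math.nan,) * 5
        values = np.nonzero(counts)[0]
        cum = np.cumsum(counts)

        def lower_quantile(q: float) -> int:
            k = math.ceil(q * n)
            return int(np.searchsorted(cum, k))

        return (
            float(values[0]),
            float(lower_quantile(0.25)),
            float(lower_quantile(0.5)),
            float(lower_quantile(0.75)),
            float(values[-1]),
        )

    def quality_by_cycle(self) -> pd.DataFrame:
        rows = []
        for ri, mat in enumerate(self.mats, start=1):
            for c in range(mat.n_cycles):
                mn, q1, med, q3, mx = self._hist_quartiles(mat.qual_hist[c])
                rows.append((f"R{ri}", c + 1, mn, q1, med, q3, mx))
        return pd.DataFrame(
            rows, columns=["read", "cycle", "min", "q1", "median", "q3", "max"]
        )

    def _nvc_frame(self, attr: str) -> pd.DataFrame:
        rows = []
        for ri, mat in enumerate(self.mats, start=1):
            counts = getattr(mat, attr)
            for c in range(mat.n_cycles):
                rows.append((f"R{ri}", c + 1, *counts[c].tolist()))
        return pd.DataFrame(rows, columns=["read", "cycle", *BASES])

    def nvc_raw(self) -> pd.DataFrame:
        return self._nvc_frame("base_counts")

    def nvc_unclipped(self) -> pd.DataFrame:
        return self._nvc_frame("unclipped_base_counts")

    def nvc_clipped(self) -> pd.DataFrame:
        rows = []
        for ri, mat in enumerate(self.mats, start=1):
            for off in range(mat.max_lead_offset, 0, -1):
                rows.append(
                    (f"R{ri}", "lead", -off, *mat.lead_clip_counts[off - 1].tolist())
                )
            for off in range(1, mat.max_tail_offset + 1):
                rows.append(
                    (f"R{ri}", "tail", off, *mat.tail_clip_counts[off - 1].tolist())
                )
        return pd.DataFrame(rows, columns=["read", "side", "offset", *BASES])

    def n_rate(self) -> pd.DataFrame:
        rows = []
        for ri, mat in enumerate(self.mats, start=1):
            for c in range(mat.n_cycles):
                reads = int(mat.reads_reaching[c])
                n_count = int(mat.base_counts[c, _BASE_INDEX["N"]])
                rate = n_count / reads if reads else math.nan
                rows.append((f"R{ri}", c + 1, n_count, reads, rate))
        return pd.DataFrame(
            rows, columns=["read", "cycle", "n_count", "reads", "rate"]
        )

    def clipping_profile(self) -> pd.DataFrame:
        rows = []
        for ri, mat in enumerate(self.mats, start=1):
            for c in range(mat.n_cycles):
                reads = int(mat.reads_reaching[c])
                clipped = int(mat.op_counts["S"][c])
                rate = clipped / reads if reads else math.nan
                rows.append((f"R{ri}", c + 1, clipped, reads, rate))
        return pd.DataFrame(
            rows, columns=["read", "cycle", "clipped", "reads", "rate"]
        )

    def cigar_profile(self) -> pd.DataFrame:
        rows = []
        cols = [_OP_COL.get(op, op) for op in PROFILE_OPS]
        for ri, mat in enumerate(self.mats, start=1):
            for c in range(mat.n_cycles):
                reads = int(mat.reads_reaching[c])
                rows.append(
                    (
                        f"R{ri}",
                        c + 1,
                        reads,
                        *(int(mat.op_counts[op][c]) for op in PROFILE_OPS),
                    )
                )
        return pd.DataFrame(rows, columns=["read", "cycle", "reads", *cols])

    def cigar_length_distribution(self) -> pd.DataFrame:
        rows = []
        for ri, mat in enumerate(self.mats, start=1):
            for op in "MIDNSH=X":
                for length in sorted(mat.op_lengths[op]):
                    rows.append(
                        (f"R{ri}", _OP_COL.get(op, op), length, mat.op_lengths[op][length])
                    )
        return pd.DataFrame(rows, columns=["read", "op", "length", "count"])


# ---------------------------------------------------------------------------
# pair-level histograms and tallies


class GcContentAccumulator:
    """Histogram of pooled per-pair G/C fraction, bins 0.00-1.00 step 0.01."""

    def __init__(self) -> None:
        self.counts = np.zeros(101, dtype=np.int64)
        self.all_n_pairs = 0

    def update(self, pair: ReadPair) -> None:
        at = gc = 0
        for r in pair.mates():
            s = r.seq.upper()
            gc += s.count("G") + s.count("C")
            at += s.count("A") + s.count("T")
        denom = gc + at
        if denom == 0:
            self.all_n_pairs += 1
            return
        self.counts[round(100 * gc / denom)] += 1

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gc_bin": [i / 100 for i in range(101)],
                "count": self.counts.tolist(),
            }
        )

    def mean(self) -> float:
        n = self.counts.sum()
        if n == 0:
            return math.nan
        return float((np.arange(101) / 100 * self.counts).sum() / n)


class InsertSizeAccumulator:
    """Full insert-size distribution, splice-aware for annotated introns.

    The insert length is the outer distance between the mates minus any
    N-skipped reference inside either mate's alignment and minus any
    annotated intron that lies entirely within the gap between the mates.
    Mate overlap is not double-counted because the length is computed from
    the outer span, not from summed read lengths.
    """

    def __init__(self, junctions: set[AnnotatedJunction] | None = None) -> None:
        self.counts: dict[int, int] = {}
        self.unassignable = 0
        self._introns: dict[str, list[tuple[int, int]]] = {}
        for j in junctions or ():
            self._introns.setdefault(j.chrom, []).append((j.start, j.end))
        for ivs in self._introns.values():
            ivs.sort()

    def _contained_intron_bases(self, chrom: str, lo: int, hi: int) -> int:
        if hi <= lo:
            return 0
        total = 0
        seen: set[tuple[int, int]] = set()
        for s, e in self._introns.get(chrom, ()):
            if s >= hi:
                break
            if s >= lo and e <= hi and (s, e) not in seen:
                seen.add((s, e))
                total += e - s
        return total

    def compute(self, pair: ReadPair) -> int | None:
        r1, r2 = pair.mates()
        if (
            r1.chrom != r2.chrom
            or r1.chrom is None
            or r1.is_reverse == r2.is_reverse
        ):
            return None
        fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
        if fwd.pos > rev.reference_end():
            return None
        skipped = sum(e - s for r in (fwd, rev) for s, e in r.skip_blocks())
        gap_lo, gap_hi = fwd.reference_end(), rev.pos
        size = (
            rev.reference_end()
            - fwd.pos
            - skipped
            - self._contained_intron_bases(fwd.chrom, gap_lo, gap_hi)
        )
        return size

    def update(self, pair: ReadPair) -> None:
        size = self.compute(pair)
        if size is None:
            self.unassignable += 1
        else:
            self.counts[size] = self.counts.get(size, 0) + 1

    def table(self) -> pd.DataFrame:
        sizes = sorted(self.counts)
        return pd.DataFrame(
            {"insert_size": sizes, "count": [self.counts[s] for s in sizes]}
        )


class RegionRateAccumulator:
    """Pair counts by genomic region class of the pair footprint.

    The footprint (union of aligned reference bases of both mates) is
    classified by majority base class under precedence
    CDS > UTR > exon_other > intron > intergenic; ties go to the
    higher-precedence class. Pairs whose mates map to different
    chromosomes are tallied as ambiguous_region.
    """

    CLASSES = REGION_CLASSES + ("ambiguous_region",)

    def __init__(self, index: FeatureIndex) -> None:
        self.index = index
        self.counts = dict.fromkeys(self.CLASSES, 0)

    def classify(self, pair: ReadPair) -> str:
        fp = pair.footprint()
        if len(fp) != 1:
            return "ambiguous_region"
        chrom, ivs = next(iter(fp.items()))
        lens = self.index.region_class_lengths(chrom, ivs)
        best = max(REGION_CLASSES, key=lambda c: (lens[c], -REGION_CLASSES.index(c)))
        return best

    def update(self, pair: ReadPair) -> None:
        self.counts[self.classify(pair)] += 1

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(self.CLASSES), "pairs": [self.counts[c] for c in self.CLASSES]}
        )


class StrandednessAccumulator:
    """Infer the library strand protocol from single-gene pairs.

    Only pairs whose footprint overlaps exons of exactly one stranded gene
    are informative. A pair is forward-protocol-consistent when read 1
    aligns to the gene strand. With r = fwd/(fwd+rev): r >= 0.9 calls
    second-strand, r <= 0.1 first-strand, 0.4 <= r <= 0.6 unstranded,
    anything else (or too few informative pairs) indeterminate.
    """

    def __init__(
        self,
        index: FeatureIndex,
        min_pairs: int = 1000,
        stranded_hi: float = 0.9,
        stranded_lo: float = 0.1,
        unstranded_band: tuple[float, float] = (0.4, 0.6),
    ) -> None:
        self.index = index
        self.min_pairs = min_pairs
        self.stranded_hi = stranded_hi
        self.stranded_lo = stranded_lo
        self.unstranded_band = unstranded_band
        self.fwd = 0
        self.rev = 0
        self.unassignable = 0

    def update(self, pair: ReadPair) -> None:
        fp = pair.footprint()
        gene_ids: set[str] = set()
        for chrom, ivs in fp.items():
            gene_ids |= self.index.genes_overlapping(chrom, ivs)
        if len(gene_ids) != 1:
            self.unassignable += 1
            return
        gene = self.index.genes[next(iter(gene_ids))]
        if gene.strand not in "+-":
            self.unassignable += 1
            return
        if pair.r1.strand == gene.strand:
            self.fwd += 1
        else:
            self.rev += 1

    def infer(self) -> tuple[float, str]:
        informative = self.fwd + self.rev
        if informative < self.min_pairs:
            return math.nan, "indeterminate"
        r = self.fwd / informative
        if r >= self.stranded_hi:
            return r, "second_strand"
        if r <= self.stranded_lo:
            return r, "first_strand"
        lo, hi = self.unstranded_band
        if lo <= r <= hi:
            return r, "unstranded"
        return r, "indeterminate"

    def table(self) -> pd.DataFrame:
        r, call = self.infer()
        rows = [
            ("fwd_protocol_consistent", str(self.fwd)),
            ("rev_protocol_consistent", str(self.rev)),
            ("unassignable", str(self.unassignable)),
            ("ratio", "NA" if math.isnan(r) else f"{r:.6f}"),
            ("inferred_protocol", call),
        ]
        return pd.DataFrame(rows, columns=["key", "value"])


class GeneBodyAccumulator:
    """5'->3' relative-position coverage profile, stratified by expression.

    Each gene's exonic union is divided into ``n_bins`` equal-width
    relative-position bins oriented 5' to 3' (reverse-strand genes
    flipped); per-base depth from union-rule-assigned pairs accumulates
    into the bins. Genes with exonic union shorter than ``n_bins`` bases
    are excluded. Strata are assigned by gene read count among genes with
    at least one assigned pair: top quartile high, bottom quartile low,
    middle half medium.
    """

    STRATA = ("low", "medium", "high", "all")

    def __init__(self, genes: list[GeneModel], n_bins: int = 40) -> None:
        self.n_bins = n_bins
        self._union: dict[str, list[tuple[int, int]]] = {}
        self._offsets: dict[str, list[int]] = {}
        self._length: dict[str, int] = {}
        self._chrom: dict[str, str] = {}
        self._strand: dict[str, str] = {}
        self.depth: dict[str, np.ndarray] = {}
        self.gene_pairs: dict[str, int] = {}
        for g in genes:
            union = g.exonic_union()
            L = sum(e - s for s, e in union)
            self._union[g.gene_id] = union
            self._length[g.gene_id] = L
            self._chrom[g.gene_id] = g.chrom
            self._strand[g.gene_id] = g.strand
            offs, acc = [], 0
            for s, e in union:
                offs.append(acc)
                acc += e - s
            self._offsets[g.gene_id] = offs

    def update(self, pair: ReadPair, gene_id: str | None) -> None:
        if gene_id is None or gene_id not in self._union:
            return
        self.gene_pairs[gene_id] = self.gene_pairs.get(gene_id, 0) + 1
        depth = self.depth.get(gene_id)
        if depth is None:
            depth = self.depth[gene_id] = np.zeros(
                self._length[gene_id], dtype=np.int64
            )
        chrom = self._chrom[gene_id]
        fp = pair.footprint().get(chrom, ())
        union = self._union[gene_id]
        offsets = self._offsets[gene_id]
        for fs, fe in fp:
            for (us, ue), off in zip(union, offsets):
                lo, hi = max(fs, us), min(fe, ue)
                if lo < hi:
                    depth[off + lo - us : off + hi - us] += 1

    def gene_bins(self, gene_id: str) -> np.ndarray:
        """Depth summed into 5'->3' relative-position bins for one gene."""
        depth = self.depth.get(gene_id)
        if depth is None:
            depth = np.zeros(self._length[gene_id], dtype=np.int64)
        if self._strand[gene_id] == "-":
            depth = depth[::-1]
        L = len(depth)
        bin_of = np.arange(L) * self.n_bins // L
        return np.bincount(bin_of, weights=depth, minlength=self.n_bins)

    def strata_assignment(self) -> dict[str, str]:
        eligible = {
            g: c
            for g, c in self.gene_pairs.items()
            if c >= 1 and self._length[g] >= self.n_bins
        }
        if not eligible:
            return {}
        counts = np.array(sorted(eligible.values()))
        q25, q75 = np.quantile(counts, [0.25, 0.75])
        out = {}
        for g, c in eligible.items():
            if c >= q75:
                out[g] = "high"
            elif c <= q25:
                out[g] = "low"
            else:
                out[g] = "medium"
        return out

    def table(self) -> pd.DataFrame:
        strata = self.strata_assignment()
        profiles = {s: np.zeros(self.n_bins) for s in self.STRATA}
        for g, s in strata.items():
            b = self.gene_bins(g)
            profiles[s] += b
            profiles["all"] += b
        rows = []
        for s in self.STRATA:
            total = profiles[s].sum()
            for b in range(self.n_bins):
                raw = float(profiles[s][b])
                rows.append((s, b + 1, raw, raw / total if total > 0 else 0.0))
        return pd.DataFrame(
            rows, columns=["stratum", "bin", "depth", "depth_normalized"]
        )


class ChromRateAccumulator:
    """Retained-pair counts per chromosome (by read 1's chromosome)."""

    def __init__(self) -> None:
        self.counts: dict[str, int] = {}

    def update(self, pair: ReadPair) -> None:
        chrom = pair.r1.chrom or "*"
        self.counts[chrom] = self.counts.get(chrom, 0) + 1

    def table(self) -> pd.DataFrame:
        chroms = sorted(self.counts)
        return pd.DataFrame(
            {"chrom": chroms, "pairs": [self.counts[c] for c in chroms]}
        )


# ---------------------------------------------------------------------------
# derived tables


def gene_diversity_table(gene_counts: dict[str, int]) -> pd.DataFrame:
    """Cumulative fraction of gene-assigned pairs by descending gene rank.

    Ties are broken by gene id so the curve is deterministic.
    """
    nonzero = {g: c for g, c in gene_counts.items() if c > 0}
    total = sum(nonzero.values())
    order = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
    rows, cum = [], 0
    for rank, (g, c) in enumerate(order, start=1):
        cum += c
        rows.append((rank, g, c, cum / total))
    return pd.DataFrame(
        rows, columns=["rank", "gene_id", "count", "cumulative_fraction"]
    )


def diversity_summary(curve: pd.DataFrame) -> dict[str, int | None]:
    """Ranks at which the cumulative fraction first reaches 50 % and 80 %."""
    out: dict[str, int | None] = {"genes_for_50pct": None, "genes_for_80pct": None}
    for key, thresh in (("genes_for_50pct", 0.5), ("genes_for_80pct", 0.8)):
        hit = curve[curve["cumulative_fraction"] >= thresh]
        if len(hit):
            out[key] = int(hit["rank"].iloc[0])
    return out


def drop_rate_table(tally: FilterTally) -> pd.DataFrame:
    reasons = list(tally.counts)
    return pd.DataFrame(
        {"reason": reasons, "count": [tally.counts[r] for r in reasons]}
    )


# ---------------------------------------------------------------------------
# metric-table I/O shared with the report module

METRIC_SCHEMAS: dict[str, tuple[str, list[str]]] = {
    "quality_by_cycle": (
        "quality_by_cycle.tsv",
        ["read", "cycle", "min", "q1", "median", "q3", "max"],
    ),
    "nvc_raw": ("nvc_raw.tsv", ["read", "cycle", *BASES]),
    "nvc_unclipped": ("nvc_unclipped.tsv", ["read", "cycle", *BASES]),
    "nvc_clipped": ("nvc_clipped.tsv", ["read", "side", "offset", *BASES]),
    "n_rate": ("n_rate.tsv", ["read", "cycle", "n_count", "reads", "rate"]),
    "clipping_profile": (
        "clipping_profile.tsv",
        ["read", "cycle", "clipped", "reads", "rate"],
    ),
    "cigar_profile": (
        "cigar_profile.tsv",
        ["read", "cycle", "reads", "M", "I", "D", "N", "S", "EQ", "X"],
    ),
    "cigar_length_distribution": (
        "cigar_length_distribution.tsv",
        ["read", "op", "length", "count"],
    ),
    "gc_content": ("gc_content.tsv", ["gc_bin", "count"]),
    "insert_size": ("insert_size.tsv", ["insert_size", "count"]),
    "region_rates": ("region_rates.tsv", ["region", "pairs"]),
    "strandedness": ("strandedness.tsv", ["key", "value"]),
    "gene_body": ("gene_body.tsv", ["stratum", "bin", "depth", "depth_normalized"]),
    "gene_diversity": (
        "gene_diversity.tsv",
        ["rank", "gene_id", "count", "cumulative_fraction"],
    ),
    "assignment_rates": ("assignment_rates.tsv", ["category", "pairs"]),
    "chromosome_rates": ("chromosome_rates.tsv", ["chrom", "pairs"]),
    "drop_rates": ("drop_rates.tsv", ["reason", "count"]),
    "junction_summary": ("junction_summary.tsv", ["class", "loci", "events"]),
}


def write_metric_table(df: pd.DataFrame, path: str, params: str = "") -> None:
    """Write a metric table: '# generated-by' comment, header, TSV rows."""
    with open(path, "w") as fh:
        fh.write(f"# generated-by: pairqc {__version__}" + (f" ({params})" if params else "") + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_metric_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
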