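"""Genome-browser track generation.

Coverage is binned into fixed-width windows and written as fixedStep
wiggle (step = span = window size, 1-based starts); observed splice
junctions are written as BED6 with the supporting pair count as the
score; multi-sample summary tracks hold the mean of per-sample
normalized window values. Depth is pair-footprint depth: the union of
both mates' aligned reference bases, with mate overlap counted once and
N/D-spanned bases excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import ReadPair

__all__ = [
    "WiggleTrack",
    "make_junction_bed",
    "read_junction_bed",
    "make_summary_track",
    "read_wiggle",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 100


class TrackError(RuntimeError):
    pass


@dataclass
class WiggleTrack:
    """Windowed pair-footprint coverage over declared chromosomes."""

    chrom_lengths: dict[str, int]
    window: int = DEFAULT_WINDOW
    name: str = "coverage"
    values: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        self.values = {
            chrom: np.zeros(-(-length // self.window), dtype=np.float64)
            for chrom, length in self.chrom_lengths.items()
        }

    def add_pair(self, pair: ReadPair) -> None:
        for chrom, ivs in pair.footprint().items():
            arr = self.values.get(chrom)
            if arr is None:
                raise TrackError(
                    f"pair {pair.name!r} aligned to undeclared chromosome {chrom!r}"
                )
            limit = self.chrom_lengths[chrom]
            for s, e in ivs:
                if e > limit:
                    raise TrackError(
                        f"pair {pair.name!r} extends to base {e} beyond "
                        f"declared length {limit} of {chrom}"
                    )
                self._add_interval(arr, s, e)

    def _add_interval(self, arr: np.ndarray, s: int, e: int) -> None:
        w = self.window
        first, last = s // w, (e - 1) // w
        if first == last:
            arr[first] += e - s
            return
        arr[first] += (first + 1) * w - s
        arr[last] += e - last * w
        if last - first > 1:
            arr[first + 1 : last] += w

    def total(self) -> float:
        return float(sum(a.sum() for a in self.values.values()))

    def write(self, path: str, description: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(
                f'track type=wiggle_0 name="{self.name}"'
                + (f' description="{description}"' if description else "")
                + "\n"
            )
            for chrom in sorted(self.values):
                fh.write(
                    f"fixedStep chrom={chrom} start=1 step={self.window} "
                    f"span={self.window}\n"
                )
                for v in self.values[chrom]:
                    fh.write(f"{v:g}\n")


def read_wiggle(path: str) -> tuple[dict[str, np.ndarray], int]:
    """Parse a fixedStep wiggle file back into per-chromosome arrays."""
    values: dict[str, list[float]] = {}
    cur: list[float] | None = None
    step = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                step = int(fields["step"])
                cur = values.setdefault(fields["chrom"], [])
            else:
                assert cur is not None, "value line before fixedStep declaration"
                cur.append(float(line))
    return {c: np.asarray(v) for c, v in values.items()}, (step or 0)


# ---------------------------------------------------------------------------
# junction bed


def make_junction_bed(junction_table: pd.DataFrame, path: str, name: str = "junctions") -> None:
    """Write observed junction loci as BED6.

    The name field encodes known/novel (K/N prefix), the locus and the
    true pair count; the score is the count capped at 1000 for BED
    compatibility.
    """
    with open(path, "w") as fh:
        fh.write(f'track name="{name}" description="splice junction pair counts"\n')
        df = junction_table[junction_table["count"] > 0]
        df = df.sort_values(["chrom", "intron_start", "intron_end", "strand"])
        for row in df.itertuples(index=False):
            prefix = "K" if row.known else "N"
            locus = f"{row.chrom}:{row.intron_start}-{row.intron_end}"
            bed_name = f"{prefix}:{locus}:{row.count}"
            score = min(int(row.count), 1000)
            fh.write(
                f"{row.chrom}\t{row.intron_start}\t{row.intron_end}\t"
                f"{bed_name}\t{score}\t{row.strand}\n"
            )


def read_junction_bed(path: str) -> pd.DataFrame:
    """Parse an emitted junction BED back into a count table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            prefix, _locus_chrom, span, count = name.split(":")
            rows.append(
                (chrom, strand, int(start), int(end), prefix == "K", int(count))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "intron_start", "intron_end", "known", "count"]
    )


# ---------------------------------------------------------------------------
# summary tracks


def make_summary_track(
    tracks: list[WiggleTrack],
    factors: list[float] | None = None,
    name: str = "mean_normalized_coverage",
) -> WiggleTrack:
    """Mean of per-sample normalized window values across samples.

    ``factors[i]`` scales sample i before averaging; the conventional
    choice is 1e6 / (retained assigned pairs of sample i). All inputs
    must share the window size and chromosome layout.
    """
    if not tracks:
        raise ValueError("no input tracks")
    ref = tracks[0]
    if factors is None:
        factors = [1.0] * len(tracks)
    if len(factors) != len(tracks):
        raise ValueError("one normalization factor per track required")
    for t in tracks[1:]:
        if t.window != ref.window:
            raise TrackError(
                f"window mismatch: {t.window} vs {ref.window}"
            )
        if set(t.values) != set(ref.values):
            missing = set(t.values) ^ set(ref.values)
            raise TrackError(f"chromosome layout mismatch: {sorted(missing)}")
        for chrom in ref.values:
            if len(t.values[chrom]) != len(ref.values[chrom]):
                raise TrackError(
                    f"window-count mismatch on {chrom}: "
                    f"{len(t.values[chrom])} vs {len(ref.values[chrom])}"
                )
    out = WiggleTrack(dict(ref.chrom_lengths), ref.window, name=name)
    for chrom in ref.values:
        acc = np.zeros_like(ref.values[chrom])
        for t, f in zip(tracks, factors):
            acc += t.values[chrom] * f
        out.values[chrom] = acc / len(tracks)
    return out
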