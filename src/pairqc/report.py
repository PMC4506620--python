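"""Cross-replicate comparison report.

Loads the per-replicate metric tables written by the processing run,
organizes replicates through a decoder table (unique id, sample, lane,
group, metric-table directory), and renders the default battery of 34
comparison panels as a multiplot image (png/svg) and a one-plot-per-page
PDF report. Replicates sharing a level of the chosen grouping column
share a color; within a level they are distinguished by marker character
and a small horizontal offset. Rendering is pure over the metric store:
no alignment file is touched, and re-rendering with the same inputs and
tool version yields identical vector output.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from . import __version__
from .qc_metrics import METRIC_SCHEMAS, read_metric_table

__all__ = [
    "Decoder",
    "PlotSpec",
    "DEFAULT_MANIFEST",
    "load_decoder",
    "load_replicate_metrics",
    "render_battery",
]

plt.rcParams["svg.hashsalt"] = "pairqc"

_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
]
_MARKERS = "ox+s^v<>Dp*h"

DECODER_COLUMNS = ("unique_id", "sample_id", "lane_id", "group_id", "qc_dir")


class DecoderError(ValueError):
    pass


@dataclass
class Decoder:
    """Replicate metadata driving plot grouping and coloring."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        dupes = self.table["unique_id"][self.table["unique_id"].duplicated()]
        if len(dupes):
            raise DecoderError(
                f"duplicate unique_id values: {sorted(set(dupes))}"
            )

    @property
    def unique_ids(self) -> list[str]:
        return list(self.table["unique_id"])

    def grouping_values(self, grouping: str) -> dict[str, str]:
        if grouping not in self.table.columns:
            raise DecoderError(
                f"unknown grouping column {grouping!r}; valid columns: "
                f"{', '.join(c for c in self.table.columns if c != 'qc_dir')}"
            )
        return dict(zip(self.table["unique_id"], self.table[grouping].astype(str)))

    def qc_dir(self, unique_id: str) -> str:
        row = self.table[self.table["unique_id"] == unique_id]
        return str(row["qc_dir"].iloc[0])


def load_decoder(path: str, check_paths: bool = True) -> Decoder:
    """Load and validate a tab-separated decoder file.

    Requires at least a ``unique_id`` column; ``sample_id``, ``lane_id``
    and ``group_id`` default to ``unique_id`` when absent. With
    ``check_paths`` the ``qc_dir`` entries must exist.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "unique_id" not in df.columns:
        raise DecoderError(f"{path}: decoder must have a unique_id column")
    for col in ("sample_id", "lane_id", "group_id"):
        if col not in df.columns:
            df[col] = df["unique_id"]
    if "qc_dir" not in df.columns:
        raise DecoderError(f"{path}: decoder must have a qc_dir column")
    if check_paths:
        missing = [d for d in df["qc_dir"] if not os.path.isdir(d)]
        if missing:
            raise DecoderError(
                f"{path}: missing qc_dir paths: {sorted(set(missing))}"
            )
    return Decoder(df[list(DECODER_COLUMNS)].copy())


def load_replicate_metrics(
    decoder: Decoder, metrics: list[str] | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    """Load every metric table for every replicate, schema-validated.

    Returns a store keyed by (unique_id, metric name). A missing or
    schema-violating table raises, naming the replicate and the table.
    """
    if metrics is None:
        metrics = list(METRIC_SCHEMAS)
    store: dict[tuple[str, str], pd.DataFrame] = {}
    for uid in decoder.unique_ids:
        qc_dir = decoder.qc_dir(uid)
        for metric in metrics:
            fname, cols = METRIC_SCHEMAS[metric]
            path = os.path.join(qc_dir, fname)
            if not os.path.exists(path):
                raise FileNotFoundError(
                    f"replicate {uid}: missing metric table {fname} in {qc_dir}"
                )
            df = read_metric_table(path)
            missing_cols = [c for c in cols if c not in df.columns]
            if missing_cols:
                raise DecoderError(
                    f"replicate {uid}: table {fname} lacks columns {missing_cols}"
                )
            store[(uid, metric)] = df
    return store


# ---------------------------------------------------------------------------
# plot manifest


@dataclass(frozen=True)
class PlotSpec:
    """One comparison panel: which table it reads and how it is drawn."""

    plot_id: str
    title: str
    metric: str
    geometry: str  # line_by_cycle | histogram | points | profile | curve
    read: str | None = None
    options: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def opt(self, key: str, default: str | None = None) -> str | None:
        return dict(self.options).get(key, default)


def _cycle_panels() -> list[PlotSpec]:
    specs = []
    for read in ("R1", "R2"):
        specs.append(PlotSpec(f"quality_by_cycle_{read}", f"Median phred by cycle ({read})",
                              "quality_by_cycle", "line_by_cycle", read, (("y", "median"),)))
    for variant in ("raw", "unclipped"):
        for read in ("R1", "R2"):
            specs.append(PlotSpec(f"nvc_{variant}_{read}", f"NVC {variant} ({read})",
                                  f"nvc_{variant}", "nvc", read))
    for read in ("R1", "R2"):
        specs.append(PlotSpec(f"nvc_clipped_{read}", f"NVC clipped ({read})",
                              "nvc_clipped", "nvc_clipped", read))
    for read in ("R1", "R2"):
        specs.append(PlotSpec(f"n_rate_{read}", f"N rate by cycle ({read})",
                              "n_rate", "line_by_cycle", read, (("y", "rate"),)))
    for read in ("R1", "R2"):
        specs.append(PlotSpec(f"clipping_profile_{read}", f"Clipping rate by cycle ({read})",
                              "clipping_profile", "line_by_cycle", read, (("y", "rate"),)))
    for read in ("R1", "R2"):
        specs.append(PlotSpec(f"cigar_profile_{read}", f"CIGAR op rates by cycle ({read})",
                              "cigar_profile", "cigar_profile", read))
    for read in ("R1", "R2"):
        specs.append(PlotSpec(f"cigar_lengths_{read}", f"CIGAR op length distribution ({read})",
                              "cigar_length_distribution", "op_lengths", read))
    return specs


def _build_default_manifest() -> list[PlotSpec]:
    specs = _cycle_panels()
    specs.append(PlotSpec("insert_size", "Insert size distribution", "insert_size",
                          "histogram", None, (("x", "insert_size"),)))
    specs.append(PlotSpec("gc_content", "G/C content", "gc_content",
                          "histogram", None, (("x", "gc_bin"),)))
    specs.append(PlotSpec("strandedness", "Strandedness ratio", "strandedness", "strandedness"))
    specs.append(PlotSpec("region_rates", "Mapping location rates", "region_rates",
                          "points", None, (("cat", "region"), ("val", "pairs"), ("normalize", "1"))))
    for stratum in ("all", "low", "medium", "high"):
        specs.append(PlotSpec(f"gene_body_{stratum}", f"Gene-body coverage ({stratum})",
                              "gene_body", "profile", None, (("stratum", stratum),)))
    specs.append(PlotSpec("gene_diversity", "Gene diversity", "gene_diversity", "curve"))
    specs.append(PlotSpec("assignment_rates", "Gene-assignment categories", "assignment_rates",
                          "points", None, (("cat", "category"), ("val", "pairs"), ("normalize", "1"))))
    for cls in ("known_high", "known_low", "novel_high", "novel_low"):
        specs.append(PlotSpec(f"junction_loci_{cls}", f"Junction loci ({cls.replace('_', ', ')})",
                              "junction_summary", "points",
                              None, (("cat", "class"), ("val", "loci"), ("only", cls))))
    for kn in ("known", "novel"):
        specs.append(PlotSpec(f"junction_events_{kn}", f"Junction events ({kn})",
                              "junction_summary", "junction_events", None, (("which", kn),)))
    specs.append(PlotSpec("chromosome_rates", "Pairs per chromosome", "chromosome_rates",
                          "points", None, (("cat", "chrom"), ("val", "pairs"), ("normalize", "1"))))
    specs.append(PlotSpec("drop_rates", "Drop-reason rates", "drop_rates",
                          "points", None, (("cat", "reason"), ("val", "count"), ("normalize", "1"))))
    return specs


DEFAULT_MANIFEST: list[PlotSpec] = _build_default_manifest()
assert len(DEFAULT_MANIFEST) == 34


# ---------------------------------------------------------------------------
# rendering


class _Styler:
    def __init__(self, decoder: Decoder, grouping: str):
        self.groups = decoder.grouping_values(grouping)
        levels = sorted(set(self.groups.values()))
        self.color = {
            lvl: _PALETTE[i % len(_PALETTE)] for i, lvl in enumerate(levels)
        }
        self.levels = levels
        # within-level replicate rank drives marker and horizontal offset
        self.rank: dict[str, int] = {}
        seen: dict[str, int] = {}
        for uid in decoder.unique_ids:
            lvl = self.groups[uid]
            self.rank[uid] = seen.get(lvl, 0)
            seen[lvl] = self.rank[uid] + 1

    def style(self, uid: str) -> dict:
        lvl = self.groups[uid]
        r = self.rank[uid]
        return {
            "color": self.color[lvl],
            "marker": _MARKERS[r % len(_MARKERS)],
        }

    def offset(self, uid: str, width: float = 0.6) -> float:
        all_uids = list(self.rank)
        i = all_uids.index(uid)
        return -width / 2 + width * (i + 0.5) / len(all_uids)


def _render_panel(
    ax: plt.Axes,
    spec: PlotSpec,
    store: dict[tuple[str, str], pd.DataFrame],
    decoder: Decoder,
    styler: _Styler,
) -> None:
    missing = []
    for uid in decoder.unique_ids:
        df = store.get((uid, spec.metric))
        if df is None:
            missing.append(uid)
            continue
        st = styler.style(uid)
        try:
            _draw_replicate(ax, spec, df, uid, st, styler)
        except Exception:
            missing.append(uid)
    ax.set_title(spec.title, fontsize=8)
    ax.tick_params(labelsize=6)
    if missing:
        ax.text(
            0.02, 0.98, "missing: " + ",".join(missing[:3]) + ("..." if len(missing) > 3 else ""),
            transform=ax.transAxes, fontsize=5, va="top", color="red",
        )


def _draw_replicate(
    ax: plt.Axes,
    spec: PlotSpec,
    df: pd.DataFrame,
    uid: str,
    st: dict,
    styler: _Styler,
) -> None:
    geom = spec.geometry
    if geom == "line_by_cycle":
        sub = df[df["read"] == spec.read]
        ax.plot(sub["cycle"], sub[spec.opt("y")], color=st["color"], lw=0.8)
    elif geom == "nvc":
        sub = df[df["read"] == spec.read]
        totals = sub[list("ACGTN")].sum(axis=1).replace(0, np.nan)
        for base, ls in zip("ACGT", ("-", "--", ":", "-.")):
            ax.plot(sub["cycle"], sub[base] / totals, color=st["color"], lw=0.6, ls=ls)
    elif geom == "nvc_clipped":
        sub = df[df["read"] == spec.read]
        if len(sub) == 0:
            return
        totals = sub[list("ACGTN")].sum(axis=1).replace(0, np.nan)
        for base, ls in zip("ACGT", ("-", "--", ":", "-.")):
            ax.plot(sub["offset"], sub[base] / totals, color=st["color"], lw=0.6, ls=ls)
    elif geom == "cigar_profile":
        sub = df[df["read"] == spec.read]
        reads = sub["reads"].replace(0, np.nan)
        for op, ls in zip(("S", "I", "D", "N"), ("-", "--", ":", "-.")):
            ax.plot(sub["cycle"], sub[op] / reads, color=st["color"], lw=0.6, ls=ls)
    elif geom == "op_lengths":
        sub = df[(df["read"] == spec.read) & (df["op"] == "N")]
        if len(sub):
            ax.plot(sub["length"], sub["count"], color=st["color"], lw=0.6,
                    marker=st["marker"], ms=2)
        ax.set_xlabel("N op length", fontsize=6)
    elif geom == "histogram":
        x = spec.opt("x")
        total = df["count"].sum()
        if total > 0:
            ax.plot(df[x], df["count"] / total, color=st["color"], lw=0.8)
    elif geom == "points":
        cat_col, val_col = spec.opt("cat"), spec.opt("val")
        sub = df
        only = spec.opt("only")
        if only is not None:
            sub = df[df[cat_col] == only]
        cats = list(sub[cat_col])
        vals = np.asarray(sub[val_col], dtype=float)
        if spec.opt("normalize") == "1" and vals.sum() > 0:
            vals = vals / vals.sum()
        xs = np.arange(len(cats)) + styler.offset(uid)
        ax.plot(xs, vals, linestyle="none", marker=st["marker"],
                color=st["color"], ms=3)
        ax.set_xticks(np.arange(len(cats)))
        ax.set_xticklabels(cats, rotation=90, fontsize=5)
    elif geom == "junction_events":
        which = spec.opt("which")
        sub = df[df["class"].str.startswith(which)]
        total = float(sub["events"].sum())
        ax.plot([0 + styler.offset(uid)], [total], linestyle="none",
                marker=st["marker"], color=st["color"], ms=3)
        ax.set_xticks([0])
        ax.set_xticklabels([which], fontsize=6)
    elif geom == "strandedness":
        row = df[df["key"] == "ratio"]
        val = row["value"].iloc[0]
        y = float(val) if str(val) not in ("NA", "nan") else math.nan
        ax.plot([styler.offset(uid)], [y], linestyle="none",
                marker=st["marker"], color=st["color"], ms=3)
        ax.set_ylim(-0.05, 1.05)
        ax.axhline(0.5, color="grey", lw=0.4)
    elif geom == "profile":
        sub = df[df["stratum"] == spec.opt("stratum")]
        ax.plot(sub["bin"], sub["depth_normalized"], color=st["color"], lw=0.8)
    elif geom == "curve":
        ax.plot(df["rank"], df["cumulative_fraction"], color=st["color"], lw=0.8)
        ax.set_ylim(0, 1.05)
    else:  # pragma: no cover - manifest is fixed
        raise ValueError(f"unknown geometry {geom!r}")


def _legend_handles(styler: _Styler):
    from matplotlib.lines import Line2D

    return [
        Line2D([], [], color=styler.color[lvl], label=lvl) for lvl in styler.levels
    ]


def render_battery(
    store: dict[tuple[str, str], pd.DataFrame],
    decoder: Decoder,
    out_dir: str,
    grouping: str = "group_id",
    formats: tuple[str, ...] = ("png",),
    pdf: bool = True,
    manifest: list[PlotSpec] | None = None,
) -> list[str]:
    """Render the comparison battery; returns the rendered panel ids.

    Outputs a multiplot grid in each requested raster/vector format plus
    (optionally) a PDF report with a summary front page and one page per
    panel.
    """
    if manifest is None:
        manifest = DEFAULT_MANIFEST
    os.makedirs(out_dir, exist_ok=True)
    styler = _Styler(decoder, grouping)
    n = len(manifest)
    ncols = 6
    nrows = -(-n // ncols)

    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows))
    axes = np.atleast_2d(axes)
    for i, spec in enumerate(manifest):
        ax = axes[i // ncols][i % ncols]
        _render_panel(ax, spec, store, decoder, styler)
    for j in range(n, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    if len(styler.levels) > 1:
        fig.legend(handles=_legend_handles(styler), loc="lower right", fontsize=7)
    fig.suptitle(f"pairqc {__version__} — {n} QC panels, grouped by {grouping}", fontsize=10)
    fig.tight_layout(rect=(0, 0, 1, 0.97))
    for fmt in formats:
        fig.savefig(
            os.path.join(out_dir, f"multiplot.{fmt}"),
            metadata={"Date": None} if fmt == "svg" else None,
        )
    plt.close(fig)

    if pdf:
        pdf_path = os.path.join(out_dir, "report.pdf")
        with PdfPages(
            pdf_path,
            metadata={
                "Creator": f"pairqc {__version__}",
                "Producer": "pairqc",
                "CreationDate": None,
                "ModDate": None,
            },
        ) as pp:
            front, fax = plt.subplots(figsize=(8.3, 11.7))
            fax.axis("off")
            lines = [
                f"pairqc {__version__} QC report",
                f"replicates: {len(decoder.unique_ids)}",
                f"grouping: {grouping} ({len(styler.levels)} levels)",
                f"panels: {n}",
                "",
                "replicate -> group:",
            ] + [f"  {uid}: {styler.groups[uid]}" for uid in decoder.unique_ids[:40]]
            if len(decoder.unique_ids) > 40:
                lines.append(f"  ... and {len(decoder.unique_ids) - 40} more")
            fax.text(0.05, 0.97, "\n".join(lines), va="top", family="monospace", fontsize=8)
            pp.savefig(front)
            plt.close(front)
            for spec in manifest:
                f, ax = plt.subplots(figsize=(8, 6))
                _render_panel(ax, spec, store, decoder, styler)
                if len(styler.levels) > 1:
                    ax.legend(handles=_legend_handles(styler), fontsize=7)
                pp.savefig(f)
                plt.close(f)
    return [s.plot_id for s in manifest]
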