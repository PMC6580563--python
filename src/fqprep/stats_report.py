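"""Streaming run statistics and report rendering.

The report mirrors the six QC panels a preprocessing run is judged by:
per-position quality distribution, per-position base composition,
filter-reason breakdown, adapter overlap-length histogram, overall base
percentages, and the read-length distribution — each tracked before and
after processing — plus read/base totals.

Accumulation is streaming and mergeable: :func:`merge` is component-wise
addition (associative and commutative), which is what makes chunked
parallel processing produce results identical to a single pass.

Rendering targets three formats sharing one payload: an aligned
plain-text summary, a JSON document with a stable schema (see
``docs/report_schema.md``), and a self-contained HTML page that embeds
that same JSON verbatim alongside inline-SVG charts.
"""

from __future__ import annotations

import html
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .adapter_align import AdapterKind
from .fastq_io import MAX_PHRED, FastqRecord
from .trim_filter import FilterCriterion, ReadVerdict

__all__ = ["StreamPanel", "RunStats", "accumulate", "merge", "render"]

SCHEMA_VERSION = 1
BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: Key used for reads failing two or more criteria at once.
MULTI_KEY = "+"

_FILTER_KEYS = [c.value for c in FilterCriterion] + [MULTI_KEY]


class StreamPanel:
    """Per-position and per-read accumulators for one side (before/after)."""

    def __init__(self) -> None:
        self.qual_counts = np.zeros((0, MAX_PHRED + 1), dtype=np.int64)
        self.base_counts = np.zeros((0, len(BASES)), dtype=np.int64)
        self.length_hist: Counter = Counter()
        self.reads = 0
        self.bases = 0

    def _ensure_length(self, length: int) -> None:
        cur = self.qual_counts.shape[0]
        if length > cur:
            grow = length - cur
            self.qual_counts = np.vstack(
                [self.qual_counts, np.zeros((grow, MAX_PHRED + 1), dtype=np.int64)]
            )
            self.base_counts = np.vstack(
                [self.base_counts, np.zeros((grow, len(BASES)), dtype=np.int64)]
            )

    def add(self, record: FastqRecord) -> None:
        L = len(record)
        self.reads += 1
        self.bases += L
        self.length_hist[L] += 1
        if L == 0:
            return
        self._ensure_length(L)
        pos = np.arange(L)
        scores = np.fromiter(record.scores, dtype=np.int64, count=L)
        np.add.at(self.qual_counts, (pos, np.clip(scores, 0, MAX_PHRED)), 1)
        base_idx = np.fromiter(
            (_BASE_INDEX.get(b, _BASE_INDEX["N"]) for b in record.seq),
            dtype=np.int64,
            count=L,
        )
        np.add.at(self.base_counts, (pos, base_idx), 1)

    def merge(self, other: "StreamPanel") -> None:
        self._ensure_length(other.qual_counts.shape[0])
        n = other.qual_counts.shape[0]
        if n:
            self.qual_counts[:n] += other.qual_counts
            self.base_counts[:n] += other.base_counts
        self.length_hist.update(other.length_hist)
        self.reads += other.reads
        self.bases += other.bases

    # ---- derived summaries -------------------------------------------------

    def quality_summary(self) -> Dict[str, List[float]]:
        """min/Q1/median/Q3/max/mean of quality per position (1-based order).

        Quartiles use linear interpolation on the empirical distribution.
        """
        out: Dict[str, List[float]] = {
            k: [] for k in ("min", "q1", "median", "q3", "max", "mean")
        }
        for row in self.qual_counts:
            n = int(row.sum())
            if n == 0:
                for k in out:
                    out[k].append(0.0)
                continue
            nz = np.nonzero(row)[0]
            out["min"].append(float(nz[0]))
            out["max"].append(float(nz[-1]))
            q1, med, q3 = _quantiles_from_counts(row, (0.25, 0.5, 0.75))
            out["q1"].append(q1)
            out["median"].append(med)
            out["q3"].append(q3)
            out["mean"].append(float((np.arange(row.size) * row).sum() / n))
        return out

    def base_percent(self) -> Dict[str, float]:
        """Overall A/C/G/T/N percentages (sum to 100 for non-empty data)."""
        totals = self.base_counts.sum(axis=0)
        grand = int(totals.sum())
        if grand == 0:
            return {b: 0.0 for b in BASES}
        return {b: float(100.0 * totals[i] / grand) for i, b in enumerate(BASES)}

    def base_proportions_by_position(self) -> Dict[str, List[float]]:
        """Per-position base fractions (denominator: reads covering the position)."""
        depth = self.base_counts.sum(axis=1)
        out: Dict[str, List[float]] = {b: [] for b in BASES}
        for p in range(self.base_counts.shape[0]):
            d = int(depth[p])
            for i, b in enumerate(BASES):
                out[b].append(float(self.base_counts[p, i] / d) if d else 0.0)
        return out

    # ---- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reads": self.reads,
            "bases": self.bases,
            "length_histogram": {str(k): v for k, v in sorted(self.length_hist.items())},
            "per_position_quality_counts": self.qual_counts.tolist(),
            "per_position_base_counts": {
                b: self.base_counts[:, i].tolist() for i, b in enumerate(BASES)
            },
            "per_position_quality": self.quality_summary(),
            "base_percent": self.base_percent(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StreamPanel":
        panel = cls()
        panel.reads = int(d["reads"])
        panel.bases = int(d["bases"])
        panel.length_hist = Counter({int(k): int(v) for k, v in d["length_histogram"].items()})
        qc = np.asarray(d["per_position_quality_counts"], dtype=np.int64)
        panel.qual_counts = qc.reshape((-1, MAX_PHRED + 1)) if qc.size else panel.qual_counts
        npos = panel.qual_counts.shape[0]
        bc = np.zeros((npos, len(BASES)), dtype=np.int64)
        for i, b in enumerate(BASES):
            col = d["per_position_base_counts"][b]
            bc[: len(col), i] = col
        panel.base_counts = bc
        return panel

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StreamPanel):
            return NotImplemented
        return (
            self.reads == other.reads
            and self.bases == other.bases
            and self.length_hist == other.length_hist
            and _counts_equal(self.qual_counts, other.qual_counts)
            and _counts_equal(self.base_counts, other.base_counts)
        )


def _counts_equal(a: np.ndarray, b: np.ndarray) -> bool:
    n = max(a.shape[0], b.shape[0])

    def padded(x: np.ndarray) -> np.ndarray:
        if x.shape[0] == n:
            return x
        pad = np.zeros((n - x.shape[0], x.shape[1]), dtype=np.int64)
        return np.vstack([x, pad])

    return bool(np.array_equal(padded(a), padded(b)))


def _quantiles_from_counts(counts: np.ndarray, qs: Sequence[float]) -> List[float]:
    """Linear-interpolation quantiles of the value distribution given counts."""
    n = int(counts.sum())
    values = np.nonzero(counts)[0]
    cum = np.cumsum(counts[values])

    def value_at(idx: int) -> float:
        k = int(np.searchsorted(cum, idx + 1))
        return float(values[k])

    out = []
    for q in qs:
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = int(np.ceil(h))
        vlo = value_at(lo)
        vhi = value_at(hi)
        out.append(vlo + (h - lo) * (vhi - vlo))
    return out


class RunStats:
    """All run accumulators: before/after panels, adapter and filter counts."""

    def __init__(self) -> None:
        self.before = StreamPanel()
        self.after = StreamPanel()
        self.adapter_hist: Counter = Counter()
        self.filter_counts: Dict[str, int] = {k: 0 for k in _FILTER_KEYS}
        self.per_mate_totals: List[dict] = []

    # ---- accumulation ------------------------------------------------------

    def add(self, verdict: ReadVerdict, original: FastqRecord) -> None:
        self.before.add(original)
        if verdict.passed:
            self.after.add(verdict.record)
        else:
            failed = verdict.failed_criteria
            if len(failed) == 1:
                self.filter_counts[next(iter(failed)).value] += 1
            else:
                self.filter_counts[MULTI_KEY] += 1
        if verdict.adapter_match is not None:
            self.adapter_hist[verdict.adapter_match.aligned_length] += 1

    def merge_from(self, other: "RunStats") -> None:
        self.before.merge(other.before)
        self.after.merge(other.after)
        self.adapter_hist.update(other.adapter_hist)
        for k in _FILTER_KEYS:
            self.filter_counts[k] += other.filter_counts.get(k, 0)
        self.per_mate_totals.extend(other.per_mate_totals)

    # ---- derived -----------------------------------------------------------

    @property
    def reads_filtered(self) -> int:
        return self.before.reads - self.after.reads

    def totals(self) -> dict:
        return {
            "reads_in": self.before.reads,
            "reads_out": self.after.reads,
            "reads_filtered": self.reads_filtered,
            "bases_in": self.before.bases,
            "bases_out": self.after.bases,
            "reads_with_adapter": int(sum(self.adapter_hist.values())),
        }

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "totals": self.totals(),
            "per_mate_totals": list(self.per_mate_totals),
            "before": self.before.to_dict(),
            "after": self.after.to_dict(),
            "adapter_overlap_histogram": {
                str(k): v for k, v in sorted(self.adapter_hist.items())
            },
            "filter_counts": dict(self.filter_counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunStats":
        stats = cls()
        stats.before = StreamPanel.from_dict(d["before"])
        stats.after = StreamPanel.from_dict(d["after"])
        stats.adapter_hist = Counter(
            {int(k): int(v) for k, v in d["adapter_overlap_histogram"].items()}
        )
        stats.filter_counts = {k: int(d["filter_counts"].get(k, 0)) for k in _FILTER_KEYS}
        stats.per_mate_totals = list(d.get("per_mate_totals", []))
        return stats

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunStats):
            return NotImplemented
        return (
            self.before == other.before
            and self.after == other.after
            and self.adapter_hist == other.adapter_hist
            and self.filter_counts == other.filter_counts
            and self.per_mate_totals == other.per_mate_totals
        )


# ---- spec-level operation wrappers ----------------------------------------


def accumulate(stats: RunStats, verdict: ReadVerdict, original: FastqRecord) -> RunStats:
    """Fold one read's outcome into ``stats`` (mutates and returns it)."""
    stats.add(verdict, original)
    return stats


def merge(a: RunStats, b: RunStats) -> RunStats:
    """Component-wise sum of two accumulator sets (new object)."""
    out = RunStats()
    out.merge_from(a)
    out.merge_from(b)
    return out


def render(stats: RunStats, format: str, path) -> str:
    """Write the report in ``format`` ('text' | 'json' | 'html'); returns path."""
    path = str(path)
    if format == "json":
        payload = json.dumps(stats.to_dict(), indent=2, sort_keys=True)
        with open(path, "w") as fh:
            fh.write(payload + "\n")
    elif format == "text":
        with open(path, "w") as fh:
            fh.write(render_text(stats))
    elif format == "html":
        with open(path, "w") as fh:
            fh.write(render_html(stats))
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return path


# ---- text ------------------------------------------------------------------


def render_text(stats: RunStats) -> str:
    d = stats.to_dict()
    t = d["totals"]
    lines: List[str] = []
    lines.append("fqprep run report")
    lines.append("=" * 60)
    lines.append("")
    lines.append("Totals")
    lines.append("-" * 60)
    for key in ("reads_in", "reads_out", "reads_filtered", "bases_in", "bases_out",
                "reads_with_adapter"):
        lines.append(f"  {key:<22}{t[key]:>15,}")
    if t["reads_in"]:
        pct = 100.0 * t["reads_filtered"] / t["reads_in"]
        lines.append(f"  {'percent_filtered':<22}{pct:>14.2f}%")
        pa = 100.0 * t["reads_with_adapter"] / t["reads_in"]
        lines.append(f"  {'percent_with_adapter':<22}{pa:>14.2f}%")
    for mate in d["per_mate_totals"]:
        lines.append(
            "  mate {mate}: in {reads_in:,}  out {reads_out:,}  "
            "filtered {reads_filtered:,}".format(**mate)
        )
    lines.append("")

    lines.append("Reads filtered by criterion ('+' = more than one criterion)")
    lines.append("-" * 60)
    total_filtered = max(t["reads_filtered"], 1)
    for key in _FILTER_KEYS:
        n = d["filter_counts"][key]
        lines.append(
            f"  {key:<22}{n:>15,}  ({100.0 * n / max(t['reads_in'], 1):6.2f}% of input)"
        )
    lines.append("")

    for side in ("before", "after"):
        bp = d[side]["base_percent"]
        total = sum(bp.values())
        comp = "  ".join(f"{b}: {bp[b]:6.2f}%" for b in BASES)
        lines.append(f"Base composition ({side})   {comp}   (sum {total:.1f}%)")
    lines.append("")

    lines.append("Adapter overlap histogram (aligned adapter bases -> reads)")
    lines.append("-" * 60)
    if d["adapter_overlap_histogram"]:
        for k, v in d["adapter_overlap_histogram"].items():
            lines.append(f"  {k:>4}  {v:,}")
    else:
        lines.append("  (no adapters removed)")
    lines.append("")

    for side in ("before", "after"):
        lines.append(f"Read length distribution ({side})")
        lines.append("-" * 60)
        hist = d[side]["length_histogram"]
        for k, v in hist.items():
            lines.append(f"  {k:>6}  {v:,}")
        lines.append("")

    for side in ("before", "after"):
        qs = d[side]["per_position_quality"]
        if not qs["mean"]:
            continue
        lines.append(f"Per-position quality ({side})")
        lines.append("-" * 60)
        lines.append(f"  {'pos':>4} {'min':>5} {'q1':>6} {'med':>6} {'q3':>6} "
                     f"{'max':>5} {'mean':>7}")
        for p in range(len(qs["mean"])):
            lines.append(
                f"  {p + 1:>4} {qs['min'][p]:>5.0f} {qs['q1'][p]:>6.1f} "
                f"{qs['median'][p]:>6.1f} {qs['q3'][p]:>6.1f} {qs['max'][p]:>5.0f} "
                f"{qs['mean'][p]:>7.2f}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


# ---- HTML ------------------------------------------------------------------

_COLORS = {
    "A": "#2ca02c", "C": "#1f77b4", "G": "#111111", "T": "#d62728", "N": "#9467bd",
    "before": "#1f77b4", "after": "#d62728",
    "min": "#bbbbbb", "max": "#bbbbbb", "q1": "#ff7f0e", "q3": "#ff7f0e",
    "median": "#d62728", "mean": "#1f77b4",
}


def _svg_polyline(xs, ys, x0, y0, w, h, xmax, ymax, color) -> str:
    if not xs:
        return ""
    pts = []
    for x, y in zip(xs, ys):
        px = x0 + (w * x / xmax if xmax else 0)
        py = y0 + h - (h * y / ymax if ymax else 0)
        pts.append(f"{px:.1f},{py:.1f}")
    return (
        f'<polyline fill="none" stroke="{color}" stroke-width="1.5" '
        f'points="{" ".join(pts)}"/>'
    )


def _svg_chart(title: str, series: Dict[str, tuple], kind: str = "line",
               width: int = 460, height: int = 240) -> str:
    """Tiny inline-SVG chart: named series of (xs, ys) as lines or bars."""
    pad = 34
    w, h = width - 2 * pad, height - 2 * pad - 14
    xmax = max((max(xs) for xs, _ in series.values() if xs), default=1) or 1
    ymax = max((max(ys) for _, ys in series.values() if ys), default=1) or 1
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<text x="{width / 2}" y="14" text-anchor="middle" font-size="12" '
        f'font-family="sans-serif">{html.escape(title)}</text>',
        f'<rect x="{pad}" y="{pad}" width="{w}" height="{h}" fill="none" '
        f'stroke="#888"/>',
    ]
    legend_x = pad
    for name, (xs, ys) in series.items():
        color = _COLORS.get(name, "#333")
        if kind == "bar":
            bw = max(w / (xmax + 1) - 1, 1)
            for x, y in zip(xs, ys):
                bx = pad + w * x / (xmax + 1)
                bh = h * y / ymax
                parts.append(
                    f'<rect x="{bx:.1f}" y="{pad + h - bh:.1f}" width="{bw:.1f}" '
                    f'height="{bh:.1f}" fill="{color}" fill-opacity="0.7"/>'
                )
        else:
            parts.append(_svg_polyline(xs, ys, pad, pad, w, h, xmax, ymax, color))
        parts.append(
            f'<text x="{legend_x}" y="{height - 4}" font-size="10" fill="{color}" '
            f'font-family="sans-serif">{html.escape(name)}</text>'
        )
        legend_x += 9 * max(len(name), 3)
    parts.append(
        f'<text x="{pad}" y="{pad - 4}" font-size="9" fill="#666" '
        f'font-family="sans-serif">ymax {ymax:g}, xmax {xmax:g}</text>'
    )
    parts.append("</svg>")
    return "".join(parts)


def render_html(stats: RunStats) -> str:
    """Self-contained HTML report: charts + the exact JSON payload embedded."""
    d = stats.to_dict()
    payload = json.dumps(d, sort_keys=True)
    charts: List[str] = []

    for side in ("before", "after"):
        qs = d[side]["per_position_quality"]
        pos = list(range(1, len(qs["mean"]) + 1))
        charts.append(
            _svg_chart(
                f"Per-position quality ({side})",
                {k: (pos, qs[k]) for k in ("min", "q1", "median", "q3", "max", "mean")},
            )
        )
    for side in ("before", "after"):
        panel = stats.before if side == "before" else stats.after
        props = panel.base_proportions_by_position()
        pos = list(range(1, panel.base_counts.shape[0] + 1))
        charts.append(
            _svg_chart(
                f"Base proportion by position ({side})",
                {b: (pos, props[b]) for b in BASES},
            )
        )
    fc = d["filter_counts"]
    charts.append(
        _svg_chart(
            "Reads filtered by criterion",
            {k: ([i], [fc[k]]) for i, k in enumerate(_FILTER_KEYS)},
            kind="bar",
        )
    )
    ah = d["adapter_overlap_histogram"]
    xs = [int(k) for k in ah]
    charts.append(
        _svg_chart("Reads with adapter by overlap length",
                   {"overlap": (xs, [ah[str(x)] for x in xs])}, kind="bar")
    )
    bp_series = {}
    for side in ("before", "after"):
        bp = d[side]["base_percent"]
        bp_series[side] = (list(range(len(BASES))), [bp[b] for b in BASES])
    charts.append(_svg_chart("Overall base percentage (x: A C G T N)", bp_series,
                             kind="bar"))
    for side in ("before", "after"):
        hist = d[side]["length_histogram"]
        xs = [int(k) for k in hist]
        charts.append(
            _svg_chart(f"Read length distribution ({side})",
                       {side: (xs, [hist[str(x)] for x in xs])}, kind="bar")
        )

    body = "\n".join(f'<div class="panel">{c}</div>' for c in charts)
    t = d["totals"]
    return f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8"><title>fqprep report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
.panel {{ display: inline-block; margin: 6px; border: 1px solid #ddd; }}
table {{ border-collapse: collapse; }} td, th {{ padding: 2px 10px; }}
</style></head><body>
<h1>fqprep run report</h1>
<table><tr><th>reads in</th><th>reads out</th><th>filtered</th>
<th>with adapter</th><th>bases in</th><th>bases out</th></tr>
<tr><td>{t['reads_in']:,}</td><td>{t['reads_out']:,}</td>
<td>{t['reads_filtered']:,}</td><td>{t['reads_with_adapter']:,}</td>
<td>{t['bases_in']:,}</td><td>{t['bases_out']:,}</td></tr></table>
{body}
<script type="application/json" id="report-data">{payload}</script>
</body></html>
"""
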