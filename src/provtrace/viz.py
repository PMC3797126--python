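"""Charts for sentence propagation and corpus statistics.

Chart construction is split from rendering: every chart is first a
serialisable :class:`ChartSpec` (deterministic JSON, used for snapshot
testing), then rendered to SVG/PNG via matplotlib or to a standalone HTML
page embedding both the figure and the spec.

A propagation chart shows each lineage the sentence occurs in along the
X axis — labelled with *all* of its accessions, since showing only the
surviving primary would make a merge look like a removal — and release
dates up the Y axis.  Swiss-Prot points are blue, TrEMBL points red.
Release tick marks are drawn per database (Swiss-Prot on the left margin,
TrEMBL on the right), so a missing point can be read as absence only where
that database actually published a release; dates where it published
nothing carry no mark and no absence glyph (no "striping").
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.dates as mdates
import matplotlib.pyplot as plt
import pandas as pd

from .index import OccurrenceIndex
from .patterns import PropagationTrace
from .releases import Database

DB_COLOR = {Database.SWISSPROT.value: "#1f4e9c", Database.TREMBL.value: "#c22326"}

#: Propagation charts denser than this many lineages are truncated to the
#: first categories (by first appearance) with an overflow note.
MAX_CATEGORIES = 100


@dataclass(frozen=True)
class ChartSpec:
    kind: str  # "propagation" | "timeline" | "stats"
    title: str
    x_axis: tuple[str, ...]
    series: tuple[dict, ...]
    annotations: tuple[dict, ...] = ()
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "title": self.title,
            "x_axis": list(self.x_axis),
            "series": [dict(s) for s in self.series],
            "annotations": [dict(a) for a in self.annotations],
            "options": dict(self.options),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @property
    def n_points(self) -> int:
        return sum(len(s.get("points", ())) for s in self.series)


def propagation_chart(trace: PropagationTrace, index: OccurrenceIndex) -> ChartSpec:
    """Scatter of (lineage, release date) occurrences for one sentence."""
    if not trace.timeline:
        raise ValueError("empty trace")
    first_seen: dict[int, tuple[datetime.date, str]] = {}
    for rkey, lids in trace.timeline:
        date = index.calendar.get(rkey).date
        for lid in lids:
            label = "/".join(sorted(index.lineage(lid).accessions))
            if lid not in first_seen or (date, label) < first_seen[lid]:
                first_seen[lid] = (date, label)
    ordered_lids = sorted(first_seen, key=lambda lid: first_seen[lid])
    overflow = len(ordered_lids) > MAX_CATEGORIES
    shown = ordered_lids[:MAX_CATEGORIES]
    position = {lid: i for i, lid in enumerate(shown)}
    categories = tuple(first_seen[lid][1] for lid in shown)

    points_by_db: dict[str, list[dict]] = {db.value: [] for db in Database}
    for rkey, lids in trace.timeline:
        release = index.calendar.get(rkey)
        for lid in sorted(lids):
            if lid not in position:
                continue
            points_by_db[release.database.value].append(
                {
                    "x": position[lid],
                    "y": release.date.isoformat(),
                    "accessions": first_seen[lid][1],
                    "release": rkey,
                }
            )
    series = tuple(
        {
            "label": db.value,
            "color": DB_COLOR[db.value],
            "points": points_by_db[db.value],
        }
        for db in Database
        if points_by_db[db.value]
    )
    lo, hi = trace.first_date, trace.last_date
    annotations = tuple(
        {
            "side": "left" if r.database is Database.SWISSPROT else "right",
            "release": r.key,
            "date": r.date.isoformat(),
        }
        for r in index.calendar
        if lo <= r.date <= hi
    )
    options = {"sentence": index.sentence_text(trace.sentence_id)}
    if overflow:
        options["overflow"] = len(ordered_lids) - MAX_CATEGORIES
    return ChartSpec(
        kind="propagation",
        title=f"Propagation of: {index.sentence_text(trace.sentence_id)!r}",
        x_axis=categories,
        series=series,
        annotations=annotations,
        options=options,
    )


def timeline_chart(series: Mapping[str, int], index: OccurrenceIndex) -> ChartSpec:
    """Entry count over time for one sentence (step/line chart)."""
    if not series:
        raise ValueError("empty series")
    keys = sorted(series, key=lambda k: (index.calendar.get(k).date, k))
    points = [
        {"x": i, "y": series[k], "release": k, "date": index.calendar.get(k).date.isoformat()}
        for i, k in enumerate(keys)
    ]
    peak = max(points, key=lambda p: p["y"])
    return ChartSpec(
        kind="timeline",
        title="Entries containing the sentence over time",
        x_axis=tuple(keys),
        series=({"label": "entries", "color": "#1f4e9c", "points": points},),
        annotations=({"peak_release": peak["release"], "peak_value": peak["y"]},),
    )


def stats_charts(
    stats: pd.DataFrame,
    histograms: Mapping[str, Mapping[int, int]] | None = None,
) -> list[ChartSpec]:
    """Corpus-statistics chart suite from a per-release statistics table.

    One chart per metric (totals, unique/singleton counts, percentages,
    averages, unannotated percentage), each with one line per database,
    plus a log-log reuse-distribution chart per supplied histogram.
    """
    metrics = [
        ("total", "Total sentences"),
        ("unique", "Unique sentences"),
        ("singleton", "Singleton sentences"),
        ("pct_unique", "Unique sentences (%)"),
        ("pct_singleton", "Singleton sentences (%)"),
        ("avg_sentences_per_entry", "Average sentences per annotated entry"),
        ("avg_entries_per_sentence", "Average entries per sentence"),
        ("pct_unannotated", "Entries without annotation (%)"),
    ]
    table = stats.copy()
    with pd.option_context("mode.chained_assignment", None):
        table["pct_unique"] = 100.0 * table["unique"] / table["total"].where(table["total"] > 0)
        table["pct_singleton"] = (
            100.0 * table["singleton"] / table["total"].where(table["total"] > 0)
        )
    charts: list[ChartSpec] = []
    for column, title in metrics:
        series = []
        for db in Database:
            sub = table[table["database"] == db.value]
            points = [
                {"x": row["release_id"], "date": row["date"], "y": _none(row[column])}
                for _, row in sub.iterrows()
            ]
            if points:
                series.append(
                    {"label": db.value, "color": DB_COLOR[db.value], "points": points}
                )
        charts.append(
            ChartSpec(
                kind="stats",
                title=title,
                x_axis=tuple(table["release_id"].unique()),
                series=tuple(series),
                options={"metric": column},
            )
        )
    for rkey, hist in (histograms or {}).items():
        points = [{"x": k, "y": v} for k, v in sorted(hist.items())]
        charts.append(
            ChartSpec(
                kind="stats",
                title=f"Sentence reuse distribution ({rkey})",
                x_axis=(),
                series=(
                    {"label": rkey, "color": "#1f4e9c", "points": points},
                ),
                options={"metric": "reuse_histogram", "log_log": True},
            )
        )
    return charts


def _none(value):
    return None if pd.isna(value) else (float(value) if not isinstance(value, str) else value)


# ---------------------------------------------------------------------------
# rendering


def render(spec: ChartSpec, path: str | Path) -> None:
    """Render a chart spec to SVG or PNG (by file extension)."""
    fig, ax = plt.subplots(figsize=(8, 5))
    if spec.kind == "propagation":
        for s in spec.series:
            xs = [p["x"] for p in s["points"]]
            ys = [datetime.date.fromisoformat(p["y"]) for p in s["points"]]
            ax.scatter(xs, ys, s=18, color=s["color"], label=s["label"])
        ax.set_xticks(range(len(spec.x_axis)))
        ax.set_xticklabels(spec.x_axis, rotation=90, fontsize=6)
        ax.yaxis.set_major_formatter(mdates.DateFormatter("%Y-%m"))
        for ann in spec.annotations:
            date = datetime.date.fromisoformat(ann["date"])
            x = -0.4 if ann["side"] == "left" else len(spec.x_axis) - 0.6
            ax.plot([x], [date], marker="_", color="0.4", markersize=8)
        ax.set_ylabel("release date")
        ax.legend(fontsize=7)
    elif spec.kind == "timeline":
        points = spec.series[0]["points"]
        ax.step(
            range(len(points)),
            [p["y"] for p in points],
            where="mid",
            color=spec.series[0]["color"],
        )
        ax.set_xticks(range(len(points)))
        ax.set_xticklabels([p["release"] for p in points], rotation=90, fontsize=6)
        ax.set_ylabel("entries")
    else:  # stats
        log_log = spec.options.get("log_log", False)
        for s in spec.series:
            xs = [p["x"] for p in s["points"]]
            ys = [p["y"] for p in s["points"]]
            if log_log:
                ax.loglog(xs, ys, "o", color=s["color"], label=s["label"])
            else:
                ax.plot(range(len(xs)), ys, "-o", color=s["color"], label=s["label"])
                ax.set_xticks(range(len(xs)))
                ax.set_xticklabels(xs, rotation=90, fontsize=6)
        ax.legend(fontsize=7)
    ax.set_title(spec.title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title></head>
<body>
<h2>{title}</h2>
{svg}
<script type="application/json" id="chart-spec">
{spec}
</script>
</body></html>
"""


def render_html(spec: ChartSpec, path: str | Path) -> None:
    """Standalone HTML: inline SVG plus the JSON chart spec for tooling."""
    import io

    path = Path(path)
    buffer = io.StringIO()
    tmp = path.with_suffix(".tmp.svg")
    render(spec, tmp)
    svg = tmp.read_text()
    tmp.unlink()
    svg = svg[svg.index("<svg") :]
    buffer.write(_HTML_TEMPLATE.format(title=spec.title, svg=svg, spec=spec.to_json()))
    path.write_text(buffer.getvalue())


__all__: Sequence[str] = [
    "ChartSpec",
    "MAX_CATEGORIES",
    "propagation_chart",
    "timeline_chart",
    "stats_charts",
    "render",
    "render_html",
]
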