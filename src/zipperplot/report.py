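"""Summary table, cross-assay distance matrix, and self-contained HTML report."""

from __future__ import annotations

import html as _html
import json
import string
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .query import FeatureTSS, PeakHit, nearest_across_samples
from .stats import ZipperStats

__all__ = ["summary_table", "distance_matrix", "html_report", "write_tsv", "stats_json"]

SUMMARY_COLUMNS = [
    "label",
    "chrom",
    "pos",
    "strand",
    "sample_id",
    "assay",
    "peak_start",
    "peak_end",
    "distance",
    "peak_width",
    "enrichment",
]


def summary_table(
    hits: Sequence[PeakHit], tss_pvals: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """One row per feature, in input order; missing hits yield NA fields.

    ``tss_pvals`` (label -> per-TSS tissue p-value) appends a column when given.
    """
    rows = []
    for h in hits:
        f = h.feature
        row: dict[str, object] = {
            "label": f.label,
            "chrom": f.chrom,
            "pos": f.pos,
            "strand": f.strand,
            "sample_id": h.sample_id if not h.is_missing else pd.NA,
            "assay": h.peak.assay if h.peak is not None else pd.NA,
            "peak_start": h.peak.start if h.peak is not None else pd.NA,
            "peak_end": h.peak.end if h.peak is not None else pd.NA,
            "distance": h.distance if h.distance is not None else pd.NA,
            "peak_width": h.peak_width if h.peak_width is not None else pd.NA,
            "enrichment": h.enrichment if h.enrichment is not None else pd.NA,
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    for col in ("peak_start", "peak_end", "distance", "peak_width"):
        df[col] = df[col].astype("Int64")
    if tss_pvals is not None:
        df["tss_pvalue"] = [tss_pvals.get(h.feature.label, pd.NA) for h in hits]
    return df


def distance_matrix(features: Sequence[FeatureTSS], indexes: Sequence) -> pd.DataFrame:
    """|features| x |assays| matrix of best |distance| per feature per assay
    (all-samples mode); features with no eligible peak get the inf sentinel."""
    if not indexes:
        raise ValueError("distance_matrix requires at least one assay index")
    data = {}
    for index in indexes:
        col = []
        for t in features:
            hit = nearest_across_samples(t, index)
            col.append(np.inf if hit.is_missing else float(abs(hit.distance)))
        data[index.assay] = col
    labels = [t.label or f"feature_{i + 1}" for i, t in enumerate(features)]
    return pd.DataFrame(data, index=pd.Index(labels, name="label"))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", na_rep="NA", index=index)
    return path


def stats_json(stats: ZipperStats, path: str | Path | None = None) -> str:
    """Serialize the statistics block as JSON (the report sidecar)."""
    payload = json.dumps(stats.to_dict(), indent=1, sort_keys=True)
    if path is not None:
        Path(path).write_text(payload)
    return payload


_TEMPLATE = string.Template(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>$title</title>
<style>
body { font-family: sans-serif; margin: 2em; color: #222; }
h1, h2 { color: #1a3c5e; }
table { border-collapse: collapse; margin-top: 0.5em; }
th, td { border: 1px solid #bbb; padding: 3px 8px; font-size: 90%; }
th { background: #e8eef4; cursor: pointer; }
tr:nth-child(even) { background: #f6f8fa; }
dl.stats { display: grid; grid-template-columns: max-content auto; gap: 2px 14px; }
dl.stats dt { font-weight: bold; }
.plot svg, .plot img { max-width: 100%; }
</style>
</head>
<body>
<h1>$title</h1>
<h2>Zipper plot</h2>
<div class="plot">$plot</div>
<h2>Statistics</h2>
<dl class="stats">
$stats_rows
</dl>
<h2>Summary table</h2>
<p>Click a column header to sort.</p>
$table
<script>
document.querySelectorAll("th").forEach(function (th, col) {
  th.addEventListener("click", function () {
    var tbody = th.closest("table").querySelector("tbody");
    var rows = Array.from(tbody.querySelectorAll("tr"));
    var asc = th.dataset.asc !== "1";
    th.dataset.asc = asc ? "1" : "0";
    rows.sort(function (a, b) {
      var x = a.children[col].textContent, y = b.children[col].textContent;
      var nx = parseFloat(x), ny = parseFloat(y);
      var cmp = (!isNaN(nx) && !isNaN(ny)) ? nx - ny : x.localeCompare(y);
      return asc ? cmp : -cmp;
    });
    rows.forEach(function (r) { tbody.appendChild(r); });
  });
});
</script>
</body>
</html>
"""
)


def _fmt_stat(value: object) -> str:
    if value is None:
        return "not computed"
    if isinstance(value, float):
        return f"{value:.4g}"
    return str(value)


def html_report(
    plot: str | Path,
    stats: ZipperStats,
    table: pd.DataFrame,
    out: str | Path,
    title: str = "Zipper report",
    provenance: Mapping[str, object] | None = None,
) -> Path:
    """Write a single self-contained HTML report.

    Embeds the plot (SVG inlined; PNG base64-encoded), the full statistics
    block and a client-side-sortable summary table; distances print as
    integers, statistics to 4 significant digits.
    """
    plot = Path(plot)
    if plot.suffix == ".svg":
        plot_html = plot.read_text(encoding="utf-8")
        # drop the XML prolog so the SVG inlines cleanly
        if plot_html.startswith("<?xml"):
            plot_html = plot_html.split("?>", 1)[1]
    else:
        import base64

        b64 = base64.b64encode(plot.read_bytes()).decode("ascii")
        plot_html = f'<img alt="zipper plot" src="data:image/png;base64,{b64}">'

    entries = stats.to_dict()
    if provenance:
        entries.update({f"provenance: {k}": v for k, v in provenance.items()})
    stats_rows = "\n".join(
        f"<dt>{_html.escape(str(k))}</dt><dd>{_html.escape(_fmt_stat(v))}</dd>"
        for k, v in entries.items()
    )

    fmt = table.copy()
    for col in fmt.columns:
        if str(fmt[col].dtype) == "Int64":
            fmt[col] = fmt[col].astype(object)
        elif fmt[col].dtype.kind == "f":
            fmt[col] = fmt[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else pd.NA)
    table_html = fmt.to_html(index=False, na_rep="NA", border=0)

    out = Path(out)
    out.write_text(
        _TEMPLATE.substitute(
            title=_html.escape(title),
            plot=plot_html,
            stats_rows=stats_rows,
            table=table_html,
        ),
        encoding="utf-8",
    )
    return out
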