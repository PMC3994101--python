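"""Per-gene reports and a static, self-contained "CAGnome" site export.

Each report bundles, for one probe, the scatter data (CAG length versus
expression), Tukey five-number box summaries per group, and the three
statistical summaries (Pearson, Spearman, Student's t) *copied* from a
previously computed association table — never recomputed, so exported numbers
can't drift from the analysis.  The site export is one JSON file per probe
plus a JSON index and a plain HTML browse/search page with no server logic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleTable,
    align,
    GROUP_CONTROL,
    GROUP_HD,
)

__all__ = ["GeneReport", "gene_lookup", "build_gene_report", "export_site"]

PathLike = Union[str, Path]


def gene_lookup(query: str, annotation: ProbeAnnotation) -> list[str]:
    """Probe IDs for a gene symbol (case-insensitive) or a literal probe ID.

    An unknown query returns an empty list; symbols mapping to several probes
    return all of them, in annotation order.
    """
    df = annotation.frame
    q = str(query).strip()
    by_symbol = df.loc[df["gene_symbol"].str.lower() == q.lower(), "probe_id"]
    if len(by_symbol):
        return by_symbol.tolist()
    if (df["probe_id"] == q).any():
        return [q]
    return []


def _five_number(values: np.ndarray) -> dict[str, float]:
    # Tukey-style five-number summary; quartiles by linear interpolation so
    # exports are bit-stable across platforms
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "n": int(values.size),
    }


@dataclass
class GeneReport:
    probe_id: str
    gene_symbol: str
    gene_name: str
    entrez_id: str
    scatter: list[tuple[int, float]]           # (cag_long, expression) per sample
    box_hd: dict[str, float]
    box_control: dict[str, float]
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "probe": self.probe_id,
            "symbol": self.gene_symbol,
            "name": self.gene_name,
            "entrez": self.entrez_id,
            "scatter": [[int(c), float(e)] for c, e in self.scatter],
            "box": {"hd": self.box_hd, "control": self.box_control},
            "stats": self.stats,
        }


def build_gene_report(
    probe_id: str,
    expr: ExpressionMatrix,
    samples: SampleTable,
    assoc: pd.DataFrame,
    annotation: ProbeAnnotation | None = None,
) -> GeneReport:
    """Assemble the per-probe report from the matrix, panel, and association
    table.  Statistics are copied verbatim from ``assoc``."""
    if probe_id not in expr.frame.index:
        raise KeyError(f"probe {probe_id!r} not in expression matrix")
    row = assoc.loc[assoc["probe_id"] == probe_id]
    if len(row) != 1:
        raise KeyError(f"probe {probe_id!r} not in association table")
    row = row.iloc[0]

    expr = align(expr, samples)
    e = expr.frame.loc[probe_id]
    cag = samples.cag_long.loc[e.index]
    groups = samples.groups.loc[e.index]
    scatter = list(zip(cag.astype(int).tolist(), e.astype(float).tolist()))

    ann = {"gene_symbol": "", "gene_name": "", "entrez_id": ""}
    if annotation is not None:
        hit = annotation.frame.loc[annotation.frame["probe_id"] == probe_id]
        if len(hit):
            ann = hit.iloc[0][["gene_symbol", "gene_name", "entrez_id"]].to_dict()

    def _f(v):
        v = float(v)
        return v if math.isfinite(v) else None

    stats = {
        "pearson": {"r": _f(row["r"]), "p": _f(row["p_pearson"])},
        "spearman": {"rho": _f(row["rho"]), "p": _f(row["p_spearman"])},
        "ttest": {
            "t": _f(row["t_stat"]),
            "p": _f(row["p_t"]),
            "fold_change": _f(row["fold_change"]),
        },
    }
    return GeneReport(
        probe_id=probe_id,
        gene_symbol=str(ann["gene_symbol"]),
        gene_name=str(ann["gene_name"]),
        entrez_id=str(ann["entrez_id"]),
        scatter=scatter,
        box_hd=_five_number(e[groups == GROUP_HD].to_numpy()),
        box_control=_five_number(e[groups == GROUP_CONTROL].to_numpy()),
        stats=stats,
    )


_INDEX_HTML = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>CAGnome browser</title>
<style>
 body {{ font-family: sans-serif; margin: 2em; }}
 input {{ padding: 0.3em; width: 20em; }}
 table {{ border-collapse: collapse; margin-top: 1em; }}
 td, th {{ border: 1px solid #ccc; padding: 0.3em 0.8em; }}
</style>
</head>
<body>
<h1>CAGnome: CAG length-correlated expression reports</h1>
<p>Search by gene symbol or probe ID; each entry links to a JSON report with
scatter data (CAG vs expression), HD/control box summaries, and Pearson,
Spearman and t-test statistics.</p>
<input id="q" placeholder="filter symbol or probe..." onkeyup="flt()">
<table id="tbl">
<tr><th>Symbol</th><th>Gene name</th><th>Entrez</th><th>Probe</th><th>Report</th></tr>
{rows}
</table>
<script>
function flt() {{
  var q = document.getElementById('q').value.toLowerCase();
  var rows = document.getElementById('tbl').rows;
  for (var i = 1; i < rows.length; i++) {{
    var t = rows[i].textContent.toLowerCase();
    rows[i].style.display = t.indexOf(q) >= 0 ? '' : 'none';
  }}
}}
</script>
</body>
</html>
"""


def export_site(reports: list[GeneReport], outdir: PathLike) -> dict:
    """Write one JSON per probe, a JSON index, and a static browse page.

    Serialisation is deterministic (sorted keys, fixed float repr), so
    re-exporting identical input is byte-identical.  Two reports for the same
    probe ID collide and raise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "genes").mkdir(exist_ok=True)
    index_entries = []
    seen: set[str] = set()
    for rep in reports:
        fname = f"genes/{rep.probe_id}.json"
        if rep.probe_id in seen:
            raise ValueError(f"output name collision for probe {rep.probe_id!r}")
        seen.add(rep.probe_id)
        payload = json.dumps(rep.to_dict(), sort_keys=True, indent=1)
        (outdir / fname).write_text(payload + "\n")
        index_entries.append(
            {
                "symbol": rep.gene_symbol,
                "name": rep.gene_name,
                "entrez": rep.entrez_id,
                "probe": rep.probe_id,
                "file": fname,
            }
        )
    index_entries.sort(key=lambda e: (e["symbol"].lower(), e["probe"]))
    index = {"n_genes": len(index_entries), "entries": index_entries}
    (outdir / "index.json").write_text(
        json.dumps(index, sort_keys=True, indent=1) + "\n"
    )
    rows = "\n".join(
        f'<tr><td>{e["symbol"]}</td><td>{e["name"]}</td><td>{e["entrez"]}</td>'
        f'<td>{e["probe"]}</td><td><a href="{e["file"]}">{e["file"]}</a></td></tr>'
        for e in index_entries
    )
    (outdir / "index.html").write_text(_INDEX_HTML.format(rows=rows))
    return index
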