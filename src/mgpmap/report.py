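"""Minimal self-contained HTML report for an MGP analysis run."""

from __future__ import annotations

import html

import numpy as np
import pandas as pd

_STYLE = """
body { font-family: sans-serif; margin: 2em; max-width: 70em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.25em 0.6em; text-align: right; }
th { background: #eee; }
td.label { text-align: left; }
"""


def _table(df: pd.DataFrame, float_fmt: str = "{:.4g}") -> str:
    rows = ["<table>", "<tr>" + "".join(
        f"<th>{html.escape(str(c))}</th>" for c in ["" , *df.columns]) + "</tr>"]
    for idx, row in df.iterrows():
        cells = [f'<td class="label">{html.escape(str(idx))}</td>']
        for v in row:
            cells.append(
                "<td>" + (float_fmt.format(v) if isinstance(v, (int, float, np.floating))
                          else html.escape(str(v))) + "</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    rows.append("</table>")
    return "\n".join(rows)


def render_report(
    title: str,
    summary: dict,
    loadings: pd.DataFrame,
    effect: np.ndarray,
    provenance: dict,
    comparison: dict | None = None,
) -> str:
    """Assemble the run report: fit summary, per-gene founder loadings,
    the phenotypic effect vector, optional mutant comparison, and input
    provenance (config values plus file checksums)."""
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{html.escape(title)}</title><style>{_STYLE}</style></head><body>",
        f"<h1>{html.escape(title)}</h1>",
        "<h2>Fit summary</h2>",
        _table(pd.DataFrame(
            {"value": [summary[k] for k in sorted(summary)]},
            index=sorted(summary))),
        "<h2>Genetic loadings (gene x founder)</h2>",
        _table(loadings),
        "<h2>Phenotypic effect vector</h2>",
        "<p>PLS1 phenotypic loadings per landmark coordinate "
        f"({len(effect)} entries):</p>",
        _table(pd.DataFrame(
            effect.reshape(-1, 3), columns=["x", "y", "z"],
            index=[f"L{i + 1}" for i in range(len(effect) // 3)])),
    ]
    if comparison is not None:
        parts += [
            "<h2>Mutant comparison</h2>",
            _table(pd.DataFrame(
                {"value": [comparison[k] for k in sorted(comparison)]},
                index=sorted(comparison))),
        ]
    prov_df = pd.DataFrame(
        {"value": [str(provenance[k]) for k in sorted(provenance)]},
        index=sorted(provenance))
    parts += ["<h2>Provenance</h2>", _table(prov_df), "</body></html>"]
    return "\n".join(parts)
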