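"""Human-readable report tables in the field's customary layout.

One row per miRNA per cluster, with start positions collapsed to
``first÷last (n)`` and ΔG collapsed to a ``a÷b`` range when member sites
differ. The ``÷`` notation appears only here; machine outputs stay TSV.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .clusters import Cluster
from .scan import BindingSite, summarize_multisite

GENE_TABLE_COLUMNS = [
    "mirna_id", "start_of_site", "dG_kj_mol", "ratio_pct", "length_nt",
]


def _fmt_int(x: float) -> str:
    return str(int(round(x)))


def _range_cell(values: Sequence[float], fmt=_fmt_int) -> str:
    """Collapse values to one cell: single value, or ``lo÷hi`` range.

    ΔG values are negative; the range is printed closest-to-zero first
    (−123÷−127), matching how site tables are customarily laid out.
    """
    uniq = sorted(set(values))
    if len(uniq) == 1:
        return fmt(uniq[0])
    if uniq[-1] < 0:
        return f"{fmt(uniq[-1])}÷{fmt(uniq[0])}"
    return f"{fmt(uniq[0])}÷{fmt(uniq[-1])}"


def render_gene_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Per-miRNA rows for each cluster, in the customary table layout."""
    rows = []
    for cluster in clusters:
        by_mirna: dict[str, list[BindingSite]] = {}
        for s in cluster.sites:
            by_mirna.setdefault(s.mirna_id, []).append(s)
        for mid in sorted(by_mirna):
            members = by_mirna[mid]
            summary = summarize_multisite(members)
            rows.append({
                "mirna_id": mid,
                "start_of_site": summary.formatted,
                "dG_kj_mol": _range_cell([m.score.dG for m in members]),
                "ratio_pct": _range_cell(
                    [m.score.ratio_pct for m in members]),
                "length_nt": members[0].length,
            })
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def format_gene_table(table: pd.DataFrame) -> str:
    """Render the table as aligned text for terminal output."""
    if table.empty:
        return "\t".join(GENE_TABLE_COLUMNS)
    return table.to_string(index=False)
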