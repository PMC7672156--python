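"""Overlap clusters of binding sites and their compaction statistics.

A cluster is a maximal set of sites whose intervals overlap directly or
transitively (a connected component of the pairwise-overlap graph). Its
compaction degree is the summed lengths of member sites divided by the
cluster span — how many site-lengths are "stacked" into the span — rounded
half away from zero to an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError
from .scan import BindingSite, MultiSiteSummary, summarize_multisite
from .seq_model import Region, Transcript


@dataclass(frozen=True)
class SiteInterval:
    """Minimal site record for cluster-only mode (external TSV input)."""

    mirna_id: str
    transcript_id: str
    start: int
    length: int
    region: Region | None = None

    @property
    def end(self) -> int:
        return self.start + self.length - 1


Site = BindingSite | SiteInterval


@dataclass(frozen=True)
class Cluster:
    """A maximal overlap-connected set of binding sites on one transcript."""

    transcript_id: str
    sites: tuple[Site, ...]
    region: Region | None = None

    @property
    def span_start(self) -> int:
        return min(s.start for s in self.sites)

    @property
    def span_end(self) -> int:
        """Last covered nucleotide (not the last site start)."""
        return max(s.end for s in self.sites)

    @property
    def span_length(self) -> int:
        return span_length(self.span_start, self.span_end)

    @property
    def total_bs_length(self) -> int:
        return sum(s.length for s in self.sites)

    @property
    def compaction(self) -> int:
        return compaction_degree(self.total_bs_length, self.span_length)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_mirnas(self) -> int:
        return len({s.mirna_id for s in self.sites})

    @property
    def singleton(self) -> bool:
        return len(self.sites) == 1


def span_length(span_start: int, span_end: int) -> int:
    """Inclusive nucleotide length of [span_start, span_end]."""
    if span_start > span_end:
        raise ContractError(
            f"inverted span bounds: start {span_start} > end {span_end}"
        )
    return span_end - span_start + 1


def compaction_degree(total_bs_length: int, span_len: int) -> int:
    """total site length / span, rounded half away from zero."""
    if total_bs_length <= 0 or span_len <= 0:
        raise ContractError("compaction_degree: arguments must be positive")
    return math.floor(total_bs_length / span_len + 0.5)


def percent_of(part: float, whole: float, decimals: int = 1) -> float | int:
    """``part`` as a percentage of ``whole`` at the requested precision.

    decimals=0 returns an int (41.0 → 41); otherwise a float.
    """
    if whole <= 0:
        raise ContractError("percent_of: whole must be positive")
    pct = 100.0 * part / whole
    if decimals == 0:
        return math.floor(pct + 0.5)
    return round(pct, decimals)


def find_clusters(sites: Sequence[Site], min_overlap: int = 1) -> list[Cluster]:
    """Group sites on one transcript into overlap clusters.

    Clusters are the connected components of the graph in which two sites
    are joined when their intervals share at least ``min_overlap`` nt
    (computed by a sort-merge sweep, which is equivalent for interval
    graphs). Singletons are reported as clusters of size 1. Input order does
    not matter; members within a cluster are sorted by (start, mirna_id).
    """
    if not sites:
        return []
    if min_overlap < 1:
        raise ContractError("min_overlap must be >= 1")
    transcript_ids = {s.transcript_id for s in sites}
    if len(transcript_ids) != 1:
        raise ContractError(
            f"find_clusters: sites span multiple transcripts {sorted(transcript_ids)}"
        )
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.mirna_id))
    clusters: list[list[Site]] = [[ordered[0]]]
    max_end = ordered[0].end
    for site in ordered[1:]:
        # overlap with the running component is max_end - start + 1
        if site.start <= max_end - min_overlap + 1:
            clusters[-1].append(site)
        else:
            clusters.append([site])
            max_end = site.end
        max_end = max(max_end, site.end)
    tid = ordered[0].transcript_id
    out = []
    for members in clusters:
        regions = {getattr(m, "region", None) for m in members}
        region = regions.pop() if len(regions) == 1 else None
        out.append(Cluster(transcript_id=tid, sites=tuple(members),
                           region=region))
    return out


def _as_binding_like(df: pd.DataFrame) -> list[SiteInterval]:
    """External site table rows → SiteInterval records."""
    records = []
    for row in df.itertuples(index=False):
        region = None
        if hasattr(row, "region") and isinstance(row.region, str):
            region = next((r for r in Region if r.value == row.region), None)
        records.append(SiteInterval(
            mirna_id=str(row.mirna_id),
            transcript_id=str(row.transcript_id),
            start=int(row.start),
            length=int(row.length),
            region=region,
        ))
    return records


def clusters_from_table(df: pd.DataFrame, min_overlap: int = 1) -> list[Cluster]:
    """Cluster an external site table (may contain several transcripts)."""
    out: list[Cluster] = []
    for _, group in df.groupby("transcript_id", sort=True):
        out.extend(find_clusters(_as_binding_like(group), min_overlap))
    return out


def _member_summaries(cluster: Cluster) -> str:
    """Per-miRNA start summaries, ``;``-joined in miRNA-id order."""
    by_mirna: dict[str, list[Site]] = {}
    for s in cluster.sites:
        by_mirna.setdefault(s.mirna_id, []).append(s)
    parts = []
    for mid in sorted(by_mirna):
        members = by_mirna[mid]
        if isinstance(members[0], BindingSite):
            summary = summarize_multisite(members).formatted
        else:
            starts = sorted({m.start for m in members})
            summary = (str(starts[0]) if len(starts) == 1
                       else f"{starts[0]}÷{starts[-1]} ({len(starts)})")
        parts.append(f"{mid}:{summary}")
    return ";".join(parts)


CLUSTER_COLUMNS = [
    "transcript_id", "region", "span_start", "span_end", "span_length",
    "total_bs_length", "compaction", "n_mirnas", "n_sites", "singleton",
    "members",
]


def clusters_to_frame(clusters: Iterable[Cluster]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "region": str(c.region) if c.region is not None else "",
            "span_start": c.span_start,
            "span_end": c.span_end,
            "span_length": c.span_length,
            "total_bs_length": c.total_bs_length,
            "compaction": c.compaction,
            "n_mirnas": c.n_mirnas,
            "n_sites": c.n_sites,
            "singleton": c.singleton,
            "members": _member_summaries(c),
        }
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def write_clusters_tsv(clusters: Iterable[Cluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def transcript_report(transcript: Transcript, sites: Sequence[BindingSite],
                      min_overlap: int = 1,
                      percent_decimals: int = 1) -> pd.DataFrame:
    """Per-region cluster report for one transcript.

    Sites are grouped within the region of their start (clusters never
    straddle region boundaries here; use find_clusters directly for a
    whole-transcript view). One row per cluster, plus one aggregate row per
    region with Σ total_bs_length, Σ span_length and each as a percentage of
    the region length.
    """
    columns = CLUSTER_COLUMNS + ["row_type", "region_length",
                                 "total_bs_pct_of_region",
                                 "span_pct_of_region"]
    if not sites:
        return pd.DataFrame(columns=columns)
    rows = []
    for region in (Region.FIVE_UTR, Region.CDS, Region.THREE_UTR,
                   Region.UNANNOTATED):
        region_sites = [s for s in sites if s.region is region]
        if not region_sites:
            continue
        clusters = find_clusters(region_sites, min_overlap)
        frame = clusters_to_frame(clusters)
        frame["region"] = str(region)
        frame["row_type"] = "cluster"
        region_len = transcript.region_length(region)
        frame["region_length"] = region_len
        frame["total_bs_pct_of_region"] = float("nan")
        frame["span_pct_of_region"] = float("nan")
        rows.append(frame)
        total_bs = sum(c.total_bs_length for c in clusters)
        total_span = sum(c.span_length for c in clusters)
        agg = {
            "transcript_id": transcript.id,
            "region": str(region),
            "span_start": min(c.span_start for c in clusters),
            "span_end": max(c.span_end for c in clusters),
            "span_length": total_span,
            "total_bs_length": total_bs,
            "compaction": float("nan"),
            "n_mirnas": len({s.mirna_id for s in region_sites}),
            "n_sites": len(region_sites),
            "singleton": float("nan"),
            "members": "",
            "row_type": "region_total",
            "region_length": region_len,
            "total_bs_pct_of_region": (
                percent_of(total_bs, region_len, percent_decimals)
                if region_len else None),
            "span_pct_of_region": (
                percent_of(total_span, region_len, percent_decimals)
                if region_len else None),
        }
        rows.append(pd.DataFrame([agg]))
    return pd.concat(rows, ignore_index=True)[columns]
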