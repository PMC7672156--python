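"""Sliding-window binding-site scan of miRNAs over transcripts.

Every window of miRNA length is scored with the hydrogen-bond duplex model;
windows whose ΔG/ΔGm ratio passes the threshold become binding sites. All
windows are evaluated (no early stopping) and overlapping self-hits are all
reported — the data this models routinely shows same-miRNA sites 3 nt apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .duplex import DEFAULT_ENERGY_PER_BOND, DuplexScore, duplex_score
from .errors import ContractError
from .seq_model import MiRNA, Region, Transcript

logger = logging.getLogger(__name__)

#: Default reporting threshold on ΔG/ΔGm (%). Reported sites in this model
#: family typically span 85–100%.
DEFAULT_MIN_RATIO_PCT = 85.0

#: Canonical site-table columns, in output order.
SITE_COLUMNS = [
    "transcript_id", "mirna_id", "start", "end", "length", "region",
    "region_span", "bonds", "dG_kj_mol", "dGm_kj_mol", "ratio_pct",
]


@dataclass(frozen=True)
class BindingSite:
    """One accepted miRNA site on a transcript (1-based inclusive coords).

    ``region`` is the region of the start position; ``region_span`` records
    whether the site crosses a region boundary.
    """

    mirna_id: str
    transcript_id: str
    start: int
    length: int
    region: Region
    score: DuplexScore
    region_span: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def scan(mirna: MiRNA, transcript: Transcript,
         min_ratio_pct: float = DEFAULT_MIN_RATIO_PCT,
         min_abs_dg: float | None = None,
         energy_per_bond: float = DEFAULT_ENERGY_PER_BOND) -> list[BindingSite]:
    """Score every window of ``transcript`` against ``mirna`` and keep those
    with ratio_pct ≥ ``min_ratio_pct`` (and, if given, |ΔG| ≥ ``min_abs_dg``
    kJ/mole). Sites are sorted by start.

    A transcript shorter than the miRNA yields an empty result with a
    warning, not an error.
    """
    L = mirna.length
    if transcript.length < L:
        logger.warning(
            "transcript %s (%d nt) shorter than miRNA %s (%d nt); no windows",
            transcript.id, transcript.length, mirna.id, L,
        )
        return []
    sites: list[BindingSite] = []
    seq = transcript.seq
    for start in range(1, transcript.length - L + 2):
        window = seq[start - 1:start - 1 + L]
        score = duplex_score(mirna.seq, window, energy_per_bond)
        if score.ratio_pct < min_ratio_pct:
            continue
        if min_abs_dg is not None and abs(score.dG) < min_abs_dg:
            continue
        end = start + L - 1
        region = transcript.region_of(start)
        sites.append(BindingSite(
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            start=start,
            length=L,
            region=region,
            score=score,
            region_span=transcript.region_of(end) is not region,
        ))
    return sites


def scan_many(mirnas: Sequence[MiRNA], transcripts: Sequence[Transcript],
              min_ratio_pct: float = DEFAULT_MIN_RATIO_PCT,
              min_abs_dg: float | None = None,
              energy_per_bond: float = DEFAULT_ENERGY_PER_BOND,
              ) -> list[BindingSite]:
    """Batch driver: concatenation of scan() over the full cross product,
    in deterministic (transcript, miRNA, start) order."""
    if not mirnas or not transcripts:
        return []
    sites: list[BindingSite] = []
    for transcript in transcripts:
        for mirna in mirnas:
            try:
                sites.extend(scan(mirna, transcript, min_ratio_pct,
                                  min_abs_dg, energy_per_bond))
            except ContractError as exc:
                logger.error("scan %s vs %s failed: %s",
                             mirna.id, transcript.id, exc)
                raise
        logger.info("scanned %s: %d sites so far", transcript.id, len(sites))
    return sites


@dataclass(frozen=True)
class MultiSiteSummary:
    """Start positions of one miRNA's sites, in the report notation
    ``first÷last (n)`` (or the bare start when there is one site)."""

    mirna_id: str
    transcript_id: str
    first_start: int
    last_start: int
    count: int

    @property
    def formatted(self) -> str:
        if self.count == 1:
            return str(self.first_start)
        return f"{self.first_start}÷{self.last_start} ({self.count})"


def summarize_multisite(sites: Sequence[BindingSite]) -> MultiSiteSummary:
    """Summarize the sites of one miRNA on one transcript."""
    if not sites:
        raise ContractError("summarize_multisite: empty site list")
    mirna_ids = {s.mirna_id for s in sites}
    transcript_ids = {s.transcript_id for s in sites}
    if len(mirna_ids) != 1 or len(transcript_ids) != 1:
        raise ContractError(
            "summarize_multisite: sites must share one miRNA and transcript"
        )
    starts = [s.start for s in sites]
    if len(set(starts)) != len(starts):
        raise ContractError("summarize_multisite: duplicate start positions")
    return MultiSiteSummary(
        mirna_id=sites[0].mirna_id,
        transcript_id=sites[0].transcript_id,
        first_start=min(starts),
        last_start=max(starts),
        count=len(starts),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def sites_to_frame(sites: Iterable[BindingSite]) -> pd.DataFrame:
    """Site list → canonical TSV-ready DataFrame."""
    rows = [
        {
            "transcript_id": s.transcript_id,
            "mirna_id": s.mirna_id,
            "start": s.start,
            "end": s.end,
            "length": s.length,
            "region": str(s.region),
            "region_span": s.region_span,
            "bonds": s.score.bonds,
            "dG_kj_mol": s.score.dG,
            "dGm_kj_mol": s.score.dGm,
            "ratio_pct": s.score.ratio_pct,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_sites_tsv(sites: Iterable[BindingSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    """Read a site table. Accepts external tables with at least mirna_id,
    transcript_id, start, length; end is derived when absent."""
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "transcript_id", "start", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"site table missing columns: {sorted(missing)}")
    if "end" not in df.columns:
        df["end"] = df["start"] + df["length"] - 1
    return df


def write_sites_bed(sites: Iterable[BindingSite], path: str | Path) -> None:
    """BED6 export: 0-based half-open, score = round(ratio_pct)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.start - 1}\t{s.end}\t{s.mirna_id}"
                f"\t{round(s.score.ratio_pct)}\t+\n"
            )
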