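"""Oligopeptides encoded by CDS binding sites.

A binding site that overlaps the CDS covers a run of codons; translating that
run gives the oligopeptide the site "encodes", and the codons on either side
give flanking oligopeptides. Repeated dipeptide runs such as (AP)n arise when
a miRNA binds tandem repeats in the coding sequence.

Codon coverage uses ceiling semantics: a codon partially covered at either
site edge counts. Translation uses the standard genetic code; internal stops
render '*' and are flagged, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import AnnotationError, ContractError
from .scan import BindingSite
from .seq_model import Transcript


@dataclass(frozen=True)
class PeptideContext:
    """Peptide encoded by the CDS codons a site covers, with flanks.

    Codon indices are 1-based within the CDS. Flanks are truncated at CDS
    edges.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    codon_first: int
    codon_last: int
    peptide: str
    upstream_flank: str
    downstream_flank: str

    @property
    def has_stop(self) -> bool:
        return "*" in self.peptide


def covered_codons(site: BindingSite, transcript: Transcript) -> tuple[int, int]:
    """1-based CDS codon indices covered (even partially) by ``site``."""
    if not transcript.annotated:
        raise AnnotationError(
            f"transcript {transcript.id!r} has no CDS annotation"
        )
    cs, ce = transcript.cds_start, transcript.cds_end
    lo = max(site.start, cs)
    hi = min(site.end, ce)
    if lo > hi:
        raise ContractError(
            f"site {site.mirna_id}@{site.start} does not overlap the CDS"
        )
    codon_first = -(-(lo - cs + 1) // 3)  # ceil division
    codon_last = -(-(hi - cs + 1) // 3)
    return codon_first, codon_last


def _translate(rna: str) -> str:
    return str(Seq(rna).translate())


def peptide_context(site: BindingSite, transcript: Transcript,
                    flank_aa: int = 10) -> PeptideContext:
    """Translate the covered codons and up to ``flank_aa`` codons each side."""
    if flank_aa < 0:
        raise ContractError("flank_aa must be >= 0")
    cs, ce = transcript.cds_start, transcript.cds_end
    c1, c2 = covered_codons(site, transcript)
    cds_len = ce - cs + 1
    if cds_len % 3 != 0:
        raise AnnotationError(
            f"transcript {transcript.id!r}: CDS length {cds_len} not a "
            "multiple of 3"
        )
    cds = transcript.seq[cs - 1:ce]
    n_codons = cds_len // 3

    def codon_slice(first: int, last: int) -> str:
        return cds[(first - 1) * 3:last * 3]

    up_first = max(1, c1 - flank_aa)
    down_last = min(n_codons, c2 + flank_aa)
    return PeptideContext(
        mirna_id=site.mirna_id,
        transcript_id=site.transcript_id,
        site_start=site.start,
        codon_first=c1,
        codon_last=c2,
        peptide=_translate(codon_slice(c1, c2)),
        upstream_flank=_translate(codon_slice(up_first, c1 - 1)) if c1 > up_first else "",
        downstream_flank=_translate(codon_slice(c2 + 1, down_last)) if down_last > c2 else "",
    )


def repeat_run(peptide: str) -> tuple[str, int]:
    """Smallest repeating unit of ``peptide`` and its repeat count.

    "APAPAP" → ("AP", 3); a non-periodic peptide returns (peptide, 1).
    """
    if not peptide:
        raise ContractError("repeat_run: empty peptide")
    n = len(peptide)
    for unit_len in range(1, n + 1):
        if n % unit_len == 0:
            unit = peptide[:unit_len]
            if unit * (n // unit_len) == peptide:
                return unit, n // unit_len
    return peptide, 1  # pragma: no cover - unreachable, unit_len=n always matches


PEPTIDE_COLUMNS = [
    "transcript_id", "mirna_id", "site_start", "codon_first", "codon_last",
    "peptide", "upstream_flank", "downstream_flank", "has_stop",
]


def peptides_to_frame(contexts: Iterable[PeptideContext]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "mirna_id": c.mirna_id,
            "site_start": c.site_start,
            "codon_first": c.codon_first,
            "codon_last": c.codon_last,
            "peptide": c.peptide,
            "upstream_flank": c.upstream_flank,
            "downstream_flank": c.downstream_flank,
            "has_stop": c.has_stop,
        }
        for c in contexts
    ]
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def write_peptides_tsv(contexts: Iterable[PeptideContext],
                       path: str | Path) -> None:
    peptides_to_frame(contexts).to_csv(path, sep="\t", index=False)
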