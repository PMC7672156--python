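"""Sequence data model: miRNAs, transcripts, mRNA regions, and FASTA /
annotation I/O.

Coordinates are 1-based and inclusive throughout, matching how binding-site
start positions are reported in the miRNA-target literature. BED export (see
:mod:`mirsite.scan`) converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlphabetError, AnnotationError, ContractError, FastaError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: miRNA lengths accepted by the data model. Mature miRNAs are ~18-26 nt;
#: the model tolerates a slightly wider band.
MIRNA_MIN_LEN = 15
MIRNA_MAX_LEN = 30


class Region(Enum):
    """The three functional regions of an annotated mRNA, plus a marker for
    transcripts without CDS annotation."""

    FIVE_UTR = "5'UTR"
    CDS = "CDS"
    THREE_UTR = "3'UTR"
    UNANNOTATED = "unannotated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def normalize_rna(raw: str) -> str:
    """Upper-case ``raw`` and convert DNA T to RNA U.

    Raises
    ------
    AlphabetError
        If any character after normalization is outside {A, C, G, U}. The
        error message names the 1-based offending position. Ambiguity codes
        (N, R, Y, ...) are rejected, not expanded.
    """
    if not raw:
        raise AlphabetError("empty sequence")
    seq = raw.upper().replace("T", "U")
    for i, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(f"invalid character {ch!r} at position {i}")
    return seq


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, the query of every scan. ``seq`` is 5'→3' RNA."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = normalize_rna(self.seq)
        object.__setattr__(self, "seq", seq)
        if not (MIRNA_MIN_LEN <= len(seq) <= MIRNA_MAX_LEN):
            raise ContractError(
                f"miRNA {self.id!r}: length {len(seq)} outside "
                f"[{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}]"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Transcript:
    """An mRNA with optional 1-based inclusive CDS boundaries.

    When CDS bounds are given they partition the sequence into
    5'UTR = [1, cds_start-1], CDS = [cds_start, cds_end] and
    3'UTR = [cds_end+1, len]. Without annotation the whole sequence is a
    single ``UNANNOTATED`` region: scanning works, peptide extraction refuses.
    """

    id: str
    seq: str
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.id!r}: cds_start and cds_end must be "
                "given together"
            )
        if self.cds_start is not None:
            if not (1 <= self.cds_start <= self.cds_end <= len(self.seq)):
                raise AnnotationError(
                    f"transcript {self.id!r}: CDS bounds "
                    f"[{self.cds_start}, {self.cds_end}] outside sequence "
                    f"of length {len(self.seq)}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def annotated(self) -> bool:
        return self.cds_start is not None

    def region_of(self, pos: int) -> Region:
        """Region containing 1-based position ``pos``; CDS boundaries map
        to CDS."""
        if not (1 <= pos <= len(self.seq)):
            raise ContractError(
                f"position {pos} outside [1, {len(self.seq)}] "
                f"of transcript {self.id!r}"
            )
        if not self.annotated:
            return Region.UNANNOTATED
        if pos < self.cds_start:
            return Region.FIVE_UTR
        if pos <= self.cds_end:
            return Region.CDS
        return Region.THREE_UTR

    def region_bounds(self, region: Region) -> tuple[int, int] | None:
        """1-based inclusive bounds of ``region``, or None when empty."""
        if not self.annotated:
            if region is Region.UNANNOTATED:
                return (1, len(self.seq))
            return None
        table = {
            Region.FIVE_UTR: (1, self.cds_start - 1),
            Region.CDS: (self.cds_start, self.cds_end),
            Region.THREE_UTR: (self.cds_end + 1, len(self.seq)),
        }
        bounds = table.get(region)
        if bounds is None or bounds[0] > bounds[1]:
            return None
        return bounds

    def region_length(self, region: Region) -> int:
        bounds = self.region_bounds(region)
        return 0 if bounds is None else bounds[1] - bounds[0] + 1


def region_of(transcript: Transcript, pos: int) -> Region:
    """Functional form of :meth:`Transcript.region_of`."""
    return transcript.region_of(pos)


# ---------------------------------------------------------------------------
# FASTA and annotation I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) multi-record FASTA.

    Ids are preserved verbatim up to the first whitespace. Sequences are
    returned raw (not normalized); duplicate ids and empty records are
    rejected with the offending record id.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaError(f"record {rec.id!r}: empty sequence")
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]],
                path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def load_mirnas(path: str | Path) -> list[MiRNA]:
    """Read and normalize a miRNA FASTA (DNA-alphabet input is converted)."""
    out = []
    for rid, seq in read_fasta(path):
        if "T" in seq.upper():
            logger.info("miRNA %s: DNA alphabet input, converting T to U", rid)
        out.append(MiRNA(rid, seq))
    return out


def read_annotation_tsv(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read the CDS sidecar: TSV with header
    ``transcript_id  cds_start  cds_end`` (1-based inclusive)."""
    bounds: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["transcript_id", "cds_start", "cds_end"]
        if header[:3] != expected:
            raise AnnotationError(
                f"annotation header {header!r} != {expected!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"line {lineno}: expected 3 columns")
            tid, s, e = parts[0], parts[1], parts[2]
            if tid in bounds:
                raise AnnotationError(f"duplicate annotation for {tid!r}")
            try:
                bounds[tid] = (int(s), int(e))
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from exc
    return bounds


def read_annotation_gff3(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read CDS bounds from a GFF3 on the transcript coordinate system.

    Multiple CDS lines per seqid are merged to their min start / max end
    (transcript-space CDS is contiguous; no splice handling).
    """
    bounds: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            if ftype != "CDS":
                continue
            s, e = int(start), int(end)
            if seqid in bounds:
                s0, e0 = bounds[seqid]
                bounds[seqid] = (min(s, s0), max(e, e0))
            else:
                bounds[seqid] = (s, e)
    return bounds


def load_transcripts(fasta: str | Path,
                     annotation: str | Path | None = None) -> list[Transcript]:
    """Read transcripts, attaching CDS bounds from a TSV or GFF3 sidecar.

    Transcripts absent from the annotation are accepted unannotated.
    """
    bounds: dict[str, tuple[int, int]] = {}
    if annotation is not None:
        text = Path(annotation).read_text()
        if text.startswith("##gff-version") or str(annotation).endswith(
                (".gff", ".gff3")):
            bounds = read_annotation_gff3(annotation)
        else:
            bounds = read_annotation_tsv(annotation)
    out = []
    for rid, seq in read_fasta(fasta):
        cds = bounds.get(rid)
        if cds is None:
            out.append(Transcript(rid, seq))
        else:
            out.append(Transcript(rid, seq, cds_start=cds[0], cds_end=cds[1]))
    return out
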