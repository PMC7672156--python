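"""Synthetic miRNA/transcript generator with planted binding sites.

Fixtures stand in for real miRNA and transcript downloads in every test:
miRNAs are drawn at miRBase-like lengths (20–25 nt by default), transcripts
get a 5'UTR/CDS/3'UTR partition, and reverse-complement windows are planted
at known positions with a controlled number of wobble (G:U), A:C or
zero-bond mismatch substitutions. Each planted site carries a truth record
whose expected ΔG/ΔGm ratio is computed from the bond model at planting
time, so a scan can be checked against ground truth exactly.

All randomness flows through one numpy Generator; the seed is explicit in
the config and echoed into the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .duplex import duplex_score, reverse_complement
from .errors import ContractError
from .seq_model import MiRNA, Transcript, write_fasta

RNA = "ACGU"

#: substitution kinds a planted site may carry
SUB_KINDS = ("to_wobble", "to_AC", "to_mismatch")

#: default fixture dimensions: desk-size mimic of a miRNA-target screen
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_mirnas": 5,
    "n_transcripts": 4,
    "mirna_length_range": [20, 25],
    "transcript_length_range": [500, 3000],
    "gc_fraction": 0.5,
    "sites_per_transcript": 3,
    "substitution_counts": [0, 1, 2, 3],
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: window bases that give a zero-bond pair against each miRNA base
_MISMATCH_CHOICES = {"A": "AG", "C": "CU", "G": "AG", "U": "CU"}


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted site."""

    transcript_id: str
    mirna_id: str
    planted_start: int  # 1-based
    n_substitutions: int
    substitution_kinds: tuple[str, ...]
    expected_ratio_pct: float


@dataclass
class SyntheticDataset:
    mirnas: list[MiRNA]
    transcripts: list[Transcript]
    truth: list[TruthRecord]
    config: dict[str, Any]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": t.transcript_id,
                    "mirna_id": t.mirna_id,
                    "planted_start": t.planted_start,
                    "n_substitutions": t.n_substitutions,
                    "substitution_kinds": ",".join(t.substitution_kinds),
                    "expected_ratio_pct": t.expected_ratio_pct,
                }
                for t in self.truth
            ],
            columns=["transcript_id", "mirna_id", "planted_start",
                     "n_substitutions", "substitution_kinds",
                     "expected_ratio_pct"],
        )


def _rng_of(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_rna(length: int, gc_fraction: float,
               rng: np.random.Generator) -> str:
    """Random RNA with expected GC content ``gc_fraction``."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return "".join(
        rng.choice(list(RNA), size=length, p=[p_at, p_gc, p_gc, p_at])
    )


def random_transcript(length: int, gc_fraction: float = 0.5,
                      cds_bounds: tuple[int, int] | None = None,
                      seed: int | np.random.Generator = 0,
                      transcript_id: str = "tx") -> Transcript:
    """Random transcript; deterministic for a fixed seed."""
    if length < 1:
        raise ContractError("length must be >= 1")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ContractError("gc_fraction must be in [0, 1]")
    rng = _rng_of(seed)
    seq = random_rna(length, gc_fraction, rng)
    if cds_bounds is None:
        return Transcript(transcript_id, seq)
    return Transcript(transcript_id, seq, cds_start=cds_bounds[0],
                      cds_end=cds_bounds[1])


def random_mirna(length: int, gc_fraction: float = 0.5,
                 seed: int | np.random.Generator = 0,
                 mirna_id: str = "mir") -> MiRNA:
    rng = _rng_of(seed)
    return MiRNA(mirna_id, random_rna(length, gc_fraction, rng))


def _substituted_window(mirna: MiRNA, substitutions: Sequence[str],
                        rng: np.random.Generator) -> tuple[str, tuple[str, ...]]:
    """Reverse-complement window of ``mirna`` with the requested substitution
    kinds applied at seeded random (eligible) miRNA positions."""
    for kind in substitutions:
        if kind not in SUB_KINDS:
            raise ContractError(f"unknown substitution kind {kind!r}")
    L = mirna.length
    window = list(reverse_complement(mirna.seq))
    free = set(range(L))  # miRNA positions not yet substituted
    applied: list[str] = []
    for kind in substitutions:
        if kind == "to_wobble":
            eligible = [i for i in free if mirna.seq[i] in "GU"]
        elif kind == "to_AC":
            eligible = [i for i in free if mirna.seq[i] in "AC"]
        else:
            eligible = sorted(free)
        if not eligible:
            raise ContractError(
                f"no eligible position left for substitution {kind!r}"
            )
        i = int(rng.choice(eligible))
        free.discard(i)
        b = mirna.seq[i]
        j = L - 1 - i  # antiparallel partner in the window
        if kind == "to_wobble":
            window[j] = "U" if b == "G" else "G"
        elif kind == "to_AC":
            window[j] = "C" if b == "A" else "A"
        else:
            window[j] = str(rng.choice(list(_MISMATCH_CHOICES[b])))
        applied.append(kind)
    return "".join(window), tuple(applied)


def plant_site(transcript: Transcript, mirna: MiRNA, position: int,
               substitutions: Sequence[str] = (),
               seed: int | np.random.Generator = 0,
               ) -> tuple[Transcript, TruthRecord]:
    """Replace the window at ``position`` (1-based) with the miRNA's reverse
    complement carrying the requested substitutions.

    The truth record's expected ratio is the duplex score of the final
    window, so it accounts for exactly the substitutions applied.
    """
    L = mirna.length
    if not (1 <= position <= transcript.length - L + 1):
        raise ContractError(
            f"window [{position}, {position + L - 1}] outside transcript "
            f"{transcript.id!r} of length {transcript.length}"
        )
    rng = _rng_of(seed)
    window, applied = _substituted_window(mirna, substitutions, rng)
    seq = (transcript.seq[:position - 1] + window
           + transcript.seq[position - 1 + L:])
    planted = Transcript(transcript.id, seq, cds_start=transcript.cds_start,
                         cds_end=transcript.cds_end)
    record = TruthRecord(
        transcript_id=transcript.id,
        mirna_id=mirna.id,
        planted_start=position,
        n_substitutions=len(applied),
        substitution_kinds=applied,
        expected_ratio_pct=duplex_score(mirna.seq, window).ratio_pct,
    )
    return planted, record


def _choose_cds(length: int, rng: np.random.Generator) -> tuple[int, int]:
    """5'UTR/CDS/3'UTR partition with CDS length a multiple of 3."""
    utr5 = int(rng.integers(max(1, length // 10), max(2, length // 5)))
    cds_len = ((length // 2) // 3) * 3
    cds_len = max(3, cds_len)
    cds_start = utr5 + 1
    cds_end = min(length, cds_start + cds_len - 1)
    # keep divisibility after clipping
    cds_end = cds_start + ((cds_end - cds_start + 1) // 3) * 3 - 1
    return cds_start, cds_end


def _place_nonoverlapping(length: int, site_len: int,
                          taken: list[tuple[int, int]],
                          rng: np.random.Generator,
                          max_tries: int = 1000) -> int:
    for _ in range(max_tries):
        pos = int(rng.integers(1, length - site_len + 2))
        end = pos + site_len - 1
        if all(end < s or pos > e for s, e in taken):
            taken.append((pos, end))
            return pos
    raise ContractError(
        "could not place a non-overlapping site; transcript too crowded"
    )


def make_dataset(config: dict[str, Any] | None = None,
                 outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate miRNAs, transcripts and planted sites per ``config``.

    Every transcript receives ``sites_per_transcript`` non-overlapping
    planted sites, cycling over the miRNAs and over the configured
    substitution counts (substitution kinds cycle wobble → A:C → mismatch).
    With ``outdir`` set, writes mirnas.fasta, transcripts.fasta, annot.tsv,
    truth.tsv and the resolved sim_config.yaml.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    rng = np.random.default_rng(cfg["seed"])
    lo, hi = cfg["mirna_length_range"]
    mirnas = [
        MiRNA(f"mir-{i + 1:03d}",
              random_rna(int(rng.integers(lo, hi + 1)), cfg["gc_fraction"], rng))
        for i in range(cfg["n_mirnas"])
    ]
    tlo, thi = cfg["transcript_length_range"]
    transcripts: list[Transcript] = []
    truth: list[TruthRecord] = []
    sub_counts = list(cfg["substitution_counts"])
    plan_idx = 0
    for t in range(cfg["n_transcripts"]):
        length = int(rng.integers(tlo, thi + 1))
        cds = _choose_cds(length, rng)
        tx = random_transcript(length, cfg["gc_fraction"], cds, rng,
                               transcript_id=f"tx-{t + 1:03d}")
        taken: list[tuple[int, int]] = []
        for _ in range(cfg["sites_per_transcript"]):
            mirna = mirnas[plan_idx % len(mirnas)]
            n_subs = sub_counts[plan_idx % len(sub_counts)]
            kinds = tuple(SUB_KINDS[(plan_idx + k) % len(SUB_KINDS)]
                          for k in range(n_subs))
            pos = _place_nonoverlapping(length, mirna.length, taken, rng)
            tx, record = plant_site(tx, mirna, pos, kinds, rng)
            truth.append(record)
            plan_idx += 1
        transcripts.append(tx)
    dataset = SyntheticDataset(mirnas=mirnas, transcripts=transcripts,
                               truth=truth, config=cfg)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([(m.id, m.seq) for m in mirnas], outdir / "mirnas.fasta")
        write_fasta([(t.id, t.seq) for t in transcripts],
                    outdir / "transcripts.fasta")
        with open(outdir / "annot.tsv", "w") as fh:
            fh.write("transcript_id\tcds_start\tcds_end\n")
            for t in transcripts:
                fh.write(f"{t.id}\t{t.cds_start}\t{t.cds_end}\n")
        dataset.truth_frame().to_csv(outdir / "truth.tsv", sep="\t",
                                     index=False)
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return dataset
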