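"""Position frequency matrices and consensus strings for aligned ortholog
binding-site blocks.

The package consumes pre-aligned equal-length blocks (ortholog alignment is
done externally) and exports a plain count matrix consumable by standard
sequence-logo tools. No information-content scaling and no logo rendering
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlphabetError, ContractError

#: column order of the count matrix
BASES = ("A", "C", "G", "U")
GAP = "-"
_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column base counts over aligned sequences.

    ``counts`` has shape (length, 4) ordered A, C, G, U; ``gaps`` is the
    per-column gap count. counts[i].sum() + gaps[i] == n_sequences for
    every column.
    """

    counts: np.ndarray
    gaps: np.ndarray
    n_sequences: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        """counts / n_sequences; per gap-free column these sum to 1."""
        return self.counts / self.n_sequences


def build_pfm(sequences: Sequence[str]) -> PositionFrequencyMatrix:
    """Count bases per column over ≥2 aligned equal-length RNA sequences.

    Gaps ('-') are tracked separately from base counts.
    """
    if len(sequences) < 2:
        raise ContractError("build_pfm: need at least 2 sequences")
    seqs = [s.upper().replace("T", "U") for s in sequences]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ContractError("build_pfm: ragged sequence lengths")
    counts = np.zeros((L, 4), dtype=int)
    gaps = np.zeros(L, dtype=int)
    for s in seqs:
        for i, ch in enumerate(s):
            if ch == GAP:
                gaps[i] += 1
            elif ch in _INDEX:
                counts[i, _INDEX[ch]] += 1
            else:
                raise AlphabetError(
                    f"invalid character {ch!r} at column {i + 1}"
                )
    return PositionFrequencyMatrix(counts=counts, gaps=gaps,
                                   n_sequences=len(seqs))


def consensus(pfm: PositionFrequencyMatrix, min_freq: float = 0.5) -> str:
    """Per-column consensus: the most frequent base when its frequency
    (over all sequences, gaps included in the denominator) reaches
    ``min_freq``, else 'N'. Ties break alphabetically (A < C < G < U)."""
    freqs = pfm.frequencies()
    out = []
    for col in freqs:
        best = int(np.argmax(col))  # argmax takes the first = alphabetical
        out.append(BASES[best] if col[best] >= min_freq else "N")
    return "".join(out)


def pfm_to_frame(pfm: PositionFrequencyMatrix) -> pd.DataFrame:
    """Count matrix as a DataFrame (pos, A, C, G, U, gap), 1-based pos."""
    df = pd.DataFrame(pfm.counts, columns=list(BASES))
    df.insert(0, "pos", np.arange(1, pfm.length + 1))
    df["gap"] = pfm.gaps
    return df


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    pfm_to_frame(pfm).to_csv(path, sep="\t", index=False)
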