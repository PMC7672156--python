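"""Hydrogen-bond duplex model for a miRNA against an equal-length mRNA window.

The pairing model counts hydrogen bonds per base pair: the Watson-Crick pairs
G:C (3 bonds) and A:U (2 bonds), plus the tolerated non-canonical pairs —
the G:U wobble (1 bond) and A:C (1 bond). Any other combination contributes
nothing. Pair classification is symmetric: a miRNA U against an mRNA G is the
same 1-bond wobble as G against U.

The free energy of a placement is ΔG = −ε·bonds for a configurable per-bond
energy ε (kJ/mole); ΔGm = −ε·max_bonds is the energy against the perfect
reverse complement. The selection statistic is the ratio ΔG/ΔGm in percent,
which equals 100·bonds/max_bonds and is independent of ε. The model is
ungapped — every miRNA nucleotide pairs with one window nucleotide, read
antiparallel — and positionally unweighted (no seed-region bonus): the whole
miRNA sequence contributes equally.

Physical pair distances (nm) are carried as metadata only; they never enter
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import AlphabetError, ContractError

#: Default per-hydrogen-bond energy, kJ/mole. Calibration-dependent: a
#: typical 22-nt site at ~90% ratio lands near −125…−135 kJ/mole with this
#: value. All thresholding logic should prefer the ε-free ratio_pct.
DEFAULT_ENERGY_PER_BOND = 2.5


class PairKind(Enum):
    GC = "GC"
    AU = "AU"
    GU = "GU"
    AC = "AC"
    NONE = "none"


#: hydrogen bonds per pair class
HYDROGEN_BONDS: dict[PairKind, int] = {
    PairKind.GC: 3,
    PairKind.AU: 2,
    PairKind.GU: 1,
    PairKind.AC: 1,
    PairKind.NONE: 0,
}

#: physical pair distance metadata, nanometers (not used in scoring)
DISTANCE_NM: dict[PairKind, float | None] = {
    PairKind.GC: 1.03,
    PairKind.AU: 1.03,
    PairKind.GU: 1.02,
    PairKind.AC: 1.04,
    PairKind.NONE: None,
}

_PAIR_LOOKUP: dict[frozenset[str], PairKind] = {
    frozenset("GC"): PairKind.GC,
    frozenset("AU"): PairKind.AU,
    frozenset("GU"): PairKind.GU,
    frozenset("AC"): PairKind.AC,
}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class PairClass:
    """Classification of one base pair."""

    kind: PairKind
    hydrogen_bonds: int
    distance_nm: float | None


def classify_pair(mirna_base: str, mrna_base: str) -> PairClass:
    """Classify a miRNA/mRNA base pair; symmetric in its arguments."""
    for b in (mirna_base, mrna_base):
        if b not in "ACGU":
            raise AlphabetError(f"invalid base {b!r}")
    kind = _PAIR_LOOKUP.get(frozenset((mirna_base, mrna_base)), PairKind.NONE)
    return PairClass(kind, HYDROGEN_BONDS[kind], DISTANCE_NM[kind])


def pair_bonds(mirna_base: str, mrna_base: str) -> int:
    """Hydrogen-bond count of one pair (fast path used by the scanner)."""
    kind = _PAIR_LOOKUP.get(frozenset((mirna_base, mrna_base)), PairKind.NONE)
    return HYDROGEN_BONDS[kind]


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (A↔U, G↔C)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def max_bonds(seq: str) -> int:
    """Bonds of ``seq`` against its perfect reverse complement: each G or C
    contributes 3, each A or U contributes 2."""
    return sum(3 if b in "GC" else 2 for b in seq)


@dataclass(frozen=True)
class DuplexScore:
    """Score of one miRNA placement against one mRNA window.

    ``ratio_pct`` = 100·bonds/max_bonds, rounded to one decimal; it is 100.0
    iff the window is the exact reverse complement of the miRNA.
    """

    bonds: int
    max_bonds: int
    dG: float
    dGm: float
    ratio_pct: float


def duplex_score(mirna_seq: str, window: str,
                 energy_per_bond: float = DEFAULT_ENERGY_PER_BOND) -> DuplexScore:
    """Score a miRNA against an equal-length mRNA window.

    Both sequences are read 5'→3'; pairing is antiparallel, so miRNA
    position i pairs with window position L−1−i.
    """
    if len(window) != len(mirna_seq):
        raise ContractError(
            f"window length {len(window)} != miRNA length {len(mirna_seq)}"
        )
    if energy_per_bond <= 0:
        raise ContractError("energy_per_bond must be positive")
    L = len(mirna_seq)
    bonds = sum(
        pair_bonds(mirna_seq[i], window[L - 1 - i]) for i in range(L)
    )
    mb = max_bonds(mirna_seq)
    return DuplexScore(
        bonds=bonds,
        max_bonds=mb,
        dG=-energy_per_bond * bonds,
        dGm=-energy_per_bond * mb,
        ratio_pct=round(100.0 * bonds / mb, 1),
    )
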