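# Methods

## Duplex model

A miRNA of length L is placed antiparallel against each mRNA window of
length L: miRNA position i pairs with window position L−1−i, both sequences
read 5′→3′. Each pair contributes hydrogen bonds — G:C 3, A:U 2, G:U 1,
A:C 1, anything else 0 — and classification is symmetric in its two bases,
so a miRNA U against an mRNA G is the same 1-bond wobble as the reverse.
The physical pair distances (1.03 nm for G:C and A:U, 1.02 nm for G:U,
1.04 nm for A:C) are carried as metadata constants only and never enter
scoring.

Assumptions worth stating plainly:

- **Ungapped.** Every miRNA nucleotide pairs with one window nucleotide; no
  bulges or internal loops. Gapped alignment is out of scope.
- **Positionally unweighted.** No seed-region bonus; every position
  contributes equally. The model is built on the premise that the whole
  miRNA sequence matters for recognition.
- **Additive energy.** ΔG = −ε·bonds with a single per-bond energy ε. No
  nearest-neighbor (stacking) thermodynamics, no target-site accessibility
  or secondary-structure terms.

## Parameters

| parameter | default | units | meaning |
|-----------|---------|-------|---------|
| ε (`energy_per_bond`) | 2.5 | kJ/mole per H-bond | converts bond counts to ΔG; chosen so a typical 22-nt site at ~90 % ratio lands near −125…−135 kJ/mole |
| `min_ratio_pct` | 85 | % | scan reporting threshold on ΔG/ΔGm |
| `min_abs_dg` | off | kJ/mole | optional report filter on \|ΔG\| (e.g. 130); ε-dependent, hence not a scan default |
| `min_overlap` | 1 | nt | overlap required to merge sites into a cluster; abutting sites do not merge |
| `flank_aa` | 10 | aa | flanking oligopeptide length in peptide extraction |

Absolute ΔG values are calibration-dependent: ε is an artifact parameter,
and all thresholding logic prefers the ε-free ratio ΔG/ΔGm (%), which equals
100·bonds/max_bonds and is reported to one decimal. The 85 % default is the
low end of the ratio range over which sites are typically reported in this
model family; it is configurable and nothing downstream depends on it.

## Scanning and site semantics

All |transcript|−L+1 windows are evaluated; there is no early stopping and
no non-maximum suppression, so overlapping self-hits of one miRNA a few nt
apart are all reported (summaries collapse them to `first÷last (n)`).
Coordinates are 1-based inclusive everywhere except the BED6 export, which
converts to 0-based half-open. A site's region is the region of its start
position; a `region_span` flag records boundary-crossing sites. Transcripts
without CDS annotation scan normally as a single unannotated region; peptide
extraction refuses them.

## Clusters and compaction

Clusters are connected components of the interval-overlap graph, computed by
a sort-merge sweep (equivalent for intervals; tests verify against an
explicit graph-components oracle). The cluster span runs from the first
covered nucleotide to the **last covered nucleotide** (not the last site
start). Compaction degree = Σ member lengths / span length, rounded half
away from zero to an integer; region percentages use the same rounding at
integer precision and banker's-free rounding at one decimal otherwise.
Per-region reports group sites by the region of their start, so clusters
never straddle region boundaries there; whole-transcript clustering is
available directly through `find_clusters`.

Known print inconsistencies in the source material for this kind of analysis
(a compaction value that does not equal its printed total/span quotient, and
a cluster total that does not equal the sum of its listed site lengths) are
documented here and deliberately not reproduced: the implementation computes
the quotient.

## CDS oligopeptides

A site overlapping the CDS covers codons ⌈(max(start, cds_start)−cds_start+1)/3⌉
through ⌈(min(end, cds_end)−cds_start+1)/3⌉ — ceiling semantics, so a codon
partially covered at either edge counts. This interpretation is what makes a
~22-nt site encode a 13-mer oligopeptide such as (AP)₆A. Translation uses
the standard genetic code; internal stops render `*` and set a flag rather
than failing. Flanks are truncated at CDS edges, and upstream flank +
peptide + downstream flank always equals the contiguous translation of the
corresponding codon range (tested).

## Conservation matrices

Ortholog blocks are consumed pre-aligned (equal length, `-` gaps); no
aligner is embedded. The position frequency matrix counts bases per column
with gaps tracked separately; the consensus takes the most frequent base
when its frequency over all sequences reaches `min_freq` (default 0.5),
breaking ties alphabetically, else `N`. No information-content scaling — the
export is a plain count matrix any logo tool can render.

## Synthetic data

The generator emulates a desk-scale miRNA-target screen: miRNA lengths drawn
uniformly from 20–25 nt, transcripts 0.5–3 kb with a 5′UTR/CDS/3′UTR
partition (CDS length a multiple of 3, roughly half the transcript), uniform
base composition at a configurable GC fraction (default 0.5). Reverse-
complement windows are planted at non-overlapping positions with a
controlled number of substitutions of three kinds — to a G:U wobble, to an
A:C pair, or to a zero-bond mismatch — and each planted site's expected
ΔG/ΔGm ratio is computed from the final window at planting time, giving an
exactly checkable truth table. One numpy generator drives all randomness;
the seed is explicit in the config and echoed into the outputs, so fixtures
are byte-reproducible.

What the generator does **not** emulate: real transcript base composition
and repeat structure, miRNA family redundancy, expression levels, or any
concentration kinetics. Passing recovery tests therefore shows the scanner
and score are exact against the model's own ground truth — not that the
model's predictions are biologically validated.

## Numerical choices and degenerate inputs

- Rounding: ratio to one decimal; compaction and integer percentages half
  away from zero (`floor(x + 0.5)` for positive x).
- Ties in consensus break alphabetically (A < C < G < U), documented rather
  than configurable.
- A transcript shorter than the miRNA yields an empty scan with a warning,
  not an error; an empty site list yields an empty report.
- Ambiguity codes in input sequences are rejected with the offending
  position, not expanded; DNA-alphabet input is silently normalized (T→U)
  with a log line.
- Duplicate FASTA ids, inverted CDS bounds, mixed-transcript cluster input
  and duplicate start positions in a multi-site summary are contract errors.

## Problem sizes

The test suite and the reproduction script run at desk scale: oracle
equivalence over 100 random miRNA/transcript pairs (transcripts 60–160 nt),
cluster oracles up to 50 sites, full-complementarity checks over 1000 random
miRNAs, and planted-site recovery over 8 seeds × 25 sites on 0.4–1.2 kb
transcripts. These sizes exercise every code path deterministically; nothing
in the implementation is specific to them.

## Limitations

- No statistical significance for sites: the ratio threshold is a cutoff,
  not an E-value.
- The ΔG scale is a linear calibration of bond counts; it cannot reproduce
  energies computed with stacking thermodynamics, and sites of equal length
  and ratio can differ in ΔG only through base composition.
- No genome-to-transcript coordinate lifting, splicing, or GenBank parsing;
  inputs are transcript-space FASTA plus a TSV/GFF3 CDS sidecar.
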