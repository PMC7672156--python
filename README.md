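# mirsite

Discovery and analysis of miRNA binding sites on mRNA by an ungapped
hydrogen-bond duplex model.

miRNAs (~18–26 nt non-coding RNAs) repress gene expression by base-pairing
with mRNA — in the 3′UTR, but also in the 5′UTR and the coding sequence.
Seed-only prediction tools miss sites whose pairing strength is distributed
along the whole miRNA, including non-canonical pairs. `mirsite` scores every
transcript window of miRNA length with a per-pair hydrogen-bond count and
reports sites whose binding energy is close to that of the perfect duplex.
On top of the scanner it provides the downstream analyses such screens need:
overlap clusters of competing sites and their compaction degree, oligopeptides
encoded by CDS sites, and conservation matrices for aligned ortholog blocks.
A synthetic planted-site generator makes the whole pipeline exercisable
without any sequence downloads.

## The model

For a miRNA placed antiparallel against an equal-length mRNA window, each
base pair contributes hydrogen bonds:

| pair | bonds | note |
|------|-------|------|
| G:C  | 3     | Watson–Crick |
| A:U  | 2     | Watson–Crick |
| G:U  | 1     | wobble |
| A:C  | 1     | tolerated non-canonical |
| other | 0    | mismatch |

The placement's free energy is ΔG = −ε·(total bonds), with ε the per-bond
energy (default 2.5 kJ/mole); ΔGm is the energy of the miRNA against its
perfect reverse complement. The selection statistic is

    ΔG/ΔGm (%) = 100 · bonds / max_bonds,

independent of ε, equal to 100 % exactly when the window is the miRNA's
reverse complement. Sites passing a ratio threshold (default 85 %) are
reported with 1-based inclusive coordinates and their mRNA region
(5′UTR / CDS / 3′UTR).

Sites whose intervals overlap, directly or transitively, form a **cluster**;
its **compaction degree** is Σ(site lengths) / (cluster span), rounded half
away from zero — how many site-lengths are stacked into the span, a measure
of how strongly miRNAs compete for the same stretch of mRNA.

## Worked example

Cluster a site table (the kind the scanner emits, or an external one):

```python
import pandas as pd
from mirsite.clusters import clusters_from_table, clusters_to_frame

sites = pd.DataFrame({
    "mirna_id":      ["mir-a", "mir-a", "mir-a", "mir-b", "mir-c"],
    "transcript_id": ["GENE1"] * 5,
    "start":         [17, 20, 23, 16, 11],
    "length":        [22, 22, 22, 25, 25],
})
print(clusters_to_frame(clusters_from_table(sites)).to_string(index=False))
```

```
transcript_id region  span_start  span_end  span_length  total_bs_length  compaction  n_mirnas  n_sites  singleton                           members
        GENE1                 11        44           34              116           3         3        5      False mir-a:17÷23 (3);mir-b:16;mir-c:11
```

All five sites overlap into one cluster spanning positions 11–44 (34 nt).
Their summed length is 116 nt, so the compaction degree is 116/34 ≈ 3: three
site-lengths are packed into the span, and the three miRNAs compete for it.
`mir-a:17÷23 (3)` is the customary shorthand for three sites of one miRNA
starting between positions 17 and 23.

The same pipeline from the shell, on a simulated dataset with planted sites:

```sh
mirsite simulate --seed 5 -o demo/
mirsite scan --mirnas demo/mirnas.fasta --transcripts demo/transcripts.fasta \
             --annot demo/annot.tsv --min-ratio 85 -o demo/sites.tsv
mirsite clusters --sites demo/sites.tsv -o demo/clusters.tsv
```

`demo/sites.tsv` begins:

```
transcript_id  mirna_id  start  end   length  region  region_span  bonds  dG_kj_mol  dGm_kj_mol  ratio_pct
tx-001         mir-001   856    879   24      CDS     False        60     -150.0     -150.0      100.0
tx-001         mir-002   297    320   24      5'UTR   True         56     -140.0     -145.0      96.6
tx-001         mir-003   1923   1943  21      3'UTR   False        50     -125.0     -135.0      92.6
```

Every row matches a row of `demo/truth.tsv`, the generator's ground truth:
the perfect planted site scores 100.0 %, the site planted with one A:C
substitution 96.6 %, and so on. `mirsite peptides` translates the codons a
CDS site covers (with flanking oligopeptides), and `mirsite logo` exports the
position count matrix of an aligned ortholog block for logo rendering.

## Layout

- `src/mirsite/seq_model.py` — sequences, regions, FASTA / annotation I/O
- `src/mirsite/duplex.py` — the pair table and duplex score
- `src/mirsite/scan.py` — sliding-window scanner and site tables
- `src/mirsite/clusters.py` — overlap clusters, compaction, region reports
- `src/mirsite/peptides.py` — oligopeptides encoded by CDS sites
- `src/mirsite/conservation.py` — position frequency matrices, consensus
- `src/mirsite/simulate.py` — synthetic data with planted ground truth
- `src/mirsite/cli.py`, `src/mirsite/reports.py` — CLI and report tables

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
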