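# bzipkit

Detection, classification and molecular phylogenetics of **bZIP / CNC
transcription factors**.

The basic-region leucine-zipper (bZIP) superfamily is defined by a ~60–80
residue BRLZ domain: a ~21-aa basic region carrying a bipartite nuclear
localization signal, followed by a leucine zipper of heptad repeats
(positions *a*–*g*, period 7) with leucine or another bulky hydrophobic
residue at the "*d*" positions and a conserved asparagine at the third
"*a*". The CNC (cap'n'collar) subfamily — NF-E2 p45, the Nrf factors, Bach
repressors, and their basal homologs reaching back to marine bacteria —
adds a conserved CNC domain in front of the BRLZ and, in several members, an
N-terminal signal-anchor transmembrane peptide (NHB1) that tethers the
factor to the ER membrane. Turnover of these factors is governed by short
β-TrCP phosphodegrons (canonical `DSGxSL`, non-canonical `DSGxxL`).

`bzipkit` is a desk-scale, fully reproducible pipeline for this biology,
aimed at molecular evolution and transcription-factor researchers:

- **motif engine** — degenerate consensus patterns over residue classes
  (φ hydrophobic, ϕ hydrophilic, B basic, X any) with built-in BR/NLS,
  CNC-domain, CNC-flavoured basic region and degron motifs, and a
  Hamming-mismatch scanner;
- **zipper** — heptad-register detection and BRLZ domain assembly;
- **alignment** — Needleman–Wunsch/Gotoh global alignment (BLOSUM62,
  affine gaps), percent identity, progressive MSA, sequence-logo
  information content;
- **phylo** — p-distances with complete/partial gap deletion, Poisson
  correction *d* = −ln(1 − *p*), Saitou–Nei neighbor joining, column
  bootstrap, and nearest-reference subfamily assignment;
- **membrane** — Kyte–Doolittle hydropathy TM calling, n/c flank-charge
  orientation (positive-inside heuristic), NHB1/TMc classification,
  helical wheels, aliphatic index and GRAVY;
- **expression** — ±1 log2-RPKM up/down labelling of network nodes;
- **synthetic** — truth-tracked generators: planted-feature proteomes and
  families evolved on known trees under Poisson substitution.

## Worked example

Plant three BRLZ-bearing proteins and call their domains:

```bash
bzipkit simulate plant --n 3 --length 200 --features BRLZ --seed 13 --out-prefix demo
bzipkit brlz demo.fasta
```

```
record_id  br_start  br_end  lz_start  lz_end  n_repeats  d_residues  asn_third_a  cnc_flavored
syn0       59        80      87        129     6          LLLLLL      True         False
syn1       66        87      89        131     6          LLLLLL      True         False
syn2       62        83      85        127     6          LLLLLL      True         False
```

Each row is one assembled BRLZ call: the 21-aa basic-region span, the
zipper span (six heptads, all six "*d*" residues leucine, asparagine at the
third "*a*"), matching the planted truth in `demo.truth.tsv` exactly.

Build a bootstrapped NJ tree from a simulated family:

```bash
bzipkit simulate evolve --tree clades.nwk --root-fasta root.fasta --seed 4 --out-prefix fam
bzipkit tree fam.aligned.fasta -o fam.nwk --bootstrap 200 --seed 5
```

yields Newick like

```
(L2:0.099213,L3:0.089529,(((L6:0.066536,L7:0.072726)100:0.091526,...)100:0.053249);
```

with Poisson branch lengths (substitutions/site) and integer bootstrap
percentages on internal nodes.

Degron logic from the library:

```python
>>> from bzipkit import motifs
>>> from bzipkit.records import ProteinRecord
>>> [h.pattern_name for h in motifs.scan_degrons(ProteinRecord("n1", "AADSGLSLKK"))]
['DEGRON_CANONICAL']
>>> motifs.scan_degrons(ProteinRecord("mut", "AADAGLALKK"))
[]
```

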