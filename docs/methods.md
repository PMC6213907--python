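# Methods

## Consensus motifs and the scanner

Patterns are fixed-length sequences of residue-class sets. The class
alphabet is: explicit sets (`K/R`), φ = hydrophobic `{A,V,I,L,M,F,W,C}`,
ϕ = hydrophilic (the exact complement, so the two partition the 20-letter
alphabet), B = basic `{K,R,H}`, and X = any residue. Histidine is placed in
ϕ and in B, and cysteine in φ, consistent with the signs of their
Kyte–Doolittle scores; this keeps the motif classes coherent with the
membrane module. `F/φ` and `Q/ϕ` in the CNC core are set unions (equal to φ
and ϕ), kept written out for traceability to the printed consensus. CNC
core positions are relative offsets within the domain, not absolute protein
coordinates, because the domain's location varies by protein.

Scanning is per-position Hamming matching against the classes — motifs are
fixed-length consensus blocks, so no indels are allowed inside a window.
The unknown residue `X` matches only the wildcard class (conservative
handling), and is excluded from charge and hydropathy denominators.
Degron scanning reports a window matching the canonical `DSGxSL` under the
canonical name only; the non-canonical `DSGxxL` is reported where the
canonical does not also match.

## Heptad registers and BRLZ assembly

A register is a maximal run of heptads (period 7; "a" at offset 0, "d" at
offset 3) in which every "d" residue is leucine or hydrophobic and at least
`min_d_leucines` (default 3) are exactly leucine. Maximality means the run
cannot be extended by one full heptad on either side. The default
`min_repeats` is 4 rather than the canonical six because the 4th/5th
repeats of real zippers are often degraded; six-repeat calls carry a
`full` flag. The "a"-position class is reported but not enforced — it is
conserved yet variable in real families. BRLZ assembly pairs a basic-region
hit (generic or CNC-flavoured; CNC wins a span collision) with a downstream
register whose first "a" lies within `max_gap` = 10 residues of the BR end
and whose combined span is 60–80 aa. The spacer tolerance is a repository
choice — published domain extractions do not state one. When several
registers pair with one BR, the one with the most heptads, then the
smallest gap, is kept. A `--br-only` mode emits unpaired BR hits for
Skn-1-like factors that genuinely lack the zipper.

## Alignment

Pairwise alignment is global Needleman–Wunsch with Gotoh affine gaps:
BLOSUM62, gap open 10, gap extend 0.5, a length-k gap costing
`open + k·extend`. The traceback tie-break is fixed (diagonal, then gap in
the second sequence, then gap in the first) so outputs are deterministic.
Because co-optimal alignments exist for unrelated sequences, derived
per-column statistics (e.g. percent identity) are argument-order invariant
only when the optimum is unique; the score always is. Percent identity uses
residue–residue columns as its denominator (gap columns excluded) — the
most reproducible convention, and conventions converge for near-equal-length
BRLZ domains.

The multiple aligner is progressive: NJ guide tree on pairwise p-distances,
profiles merged leaf-to-root under mean-of-pairs BLOSUM62 column scoring
with the same gap penalties, no iterative refinement — determinism over
accuracy at desk scale. Logo profiles use per-column frequencies over
non-gap residues; information content is `IC_j = log2 20 + Σ f log2 f`
bits with no small-sample correction by default (available as a flag);
all-gap columns report IC 0 with a flag.

## Distances, neighbor joining, bootstrap

p-distances support complete deletion (drop any column containing a gap)
and partial deletion (keep columns present in ≥ a site-coverage fraction of
rows, default 0.95 — the conventional cutoff — then compare
pairwise-complete sites). `X` is treated as missing, like a gap. The
Poisson correction is `d = −ln(1 − p)`; a pair at `p ≥ 1` raises a
saturation error naming the pair.

Neighbor joining follows Saitou–Nei: join the pair minimising
`Q(i,j) = (n−2) d(i,j) − r_i − r_j`, branch lengths by the standard
formulas, ties broken deterministically by the sorted pair of each
cluster's smallest leaf label. Negative branch-length estimates are clamped
to zero with the deficit added to the sister branch (common practice).
Trees are emitted unrooted (rooted at a basal trifurcation). On any
additive matrix the generating topology and path lengths are recovered
exactly; this is tested against a hand-computed 4-taxon matrix and
cross-checked against scikit-bio's independent NJ implementation.

Bootstrap supports resample alignment columns with replacement (seeded
NumPy generator), rebuild the tree per replicate, and write each full-data
bipartition's replicate percentage onto the full-data tree (majority-rule
consensus is deliberately not the default). Replicates in which a pair
saturates are discarded and counted.

Subfamily assignment profile-aligns the query into the labelled reference
alignment, computes Poisson distances to every reference row, and returns
the subfamily of the nearest reference. The margin is the runner-up
subfamily's mean distance minus the assigned subfamily's mean — a
non-negative separation measure. A CNC/Nach assignment is fully supported
only when the query also carries a CNC-domain core hit; the flag is
reported separately and never overrides the nearest-neighbour label.

## Membrane segments and helix properties

TM calling is a transparent hydropathy rule rather than an HMM: mean
Kyte–Doolittle score in a 19-residue window, call threshold 1.6 (the
classic recommendation for membrane spans), maximal runs of qualifying
centers expanded to full windows and merged. Each call carries the
best-scoring 21-residue core (a canonical TM helix length), the longest
hydrophobic run (h-region), and the summed charges (K,R = +1; D,E = −1;
H = 0 by default, +0.5 optionally) of the 15-residue flanks **bracketing
the core window** — the expanded span overruns the hydrophobic stretch by
a few residues and would otherwise swallow immediately adjacent charged
flank residues. Orientation follows the positive-inside heuristic on
`Δq = n_charge − c_charge` with a ±1 dead zone mapped to "ambiguous".
Topology classes: `NHB1-type` for an N-terminal segment (start ≤ 30, a
configurable cutoff, since NHB1 is a signal anchor near the N-terminus) on
a CNC-domain-bearing factor; `TMc-type` for a segment within the last 60
residues; `internal-TM` otherwise.

GRAVY is the mean Kyte–Doolittle score (a `--scale` switch selects
Fauchère–Pliska, the scale HeliQuest uses for its "hydrophobicity"); the
aliphatic index is Ikai's `X_A + 2.9 X_V + 3.9 (X_I + X_L)` over mole
percents. The 18-residue helical wheel advances 100° per residue (five
turns); the hydrophobic arc is 360° minus the largest circular gap between
consecutive hydrophobic angles plus one 20° sector, so a fully hydrophobic
helix covers the full circle and a single hydrophobic residue one sector.

## Expression labelling

`log2_change = log2((RPKM_b + 1)/(RPKM_a + 1))`, labelled up when > +1 and
down when < −1; genes at or below the detection floor in both conditions
are `not_detected`. The pseudocount handles zeros, which the thresholding
convention itself does not address. The alternative reading — a threshold
on the per-condition log2 level rather than the between-condition ratio —
is available as `mode="level"`. No differential-expression statistics are
applied: the labelling is a fold threshold, not a test.

## Synthetic data: what it emulates and what it does not

`plant_domains` writes sampled motif instances (one residue per pattern
position), perfect zippers (leucine at every "d", asparagine at the third
"a", hydrophilic residues elsewhere so no off-phase runs arise), and
21-residue strongly hydrophobic TM cores into background sequence (uniform
by default; a Swiss-Prot-average composition and a hydrophilic-biased
control composition are options — hydrophobic-rich backgrounds would
inflate false TM calls, so negative controls use the hydrophilic one).
Flanking "d" guard positions are forced hydrophilic so planted runs are
maximal. Planted residues then mutate to a uniform random residue at the
requested per-site rate. This emulates detectability, not realism: real
domains have correlated positions, biased compositions and variable heptad
quality, so perfect recall at rate 0 demonstrates correctness of the
detectors' logic, not their sensitivity on real proteomes.

`evolve_on_tree` applies Poisson substitution along each branch
(substitution probability `1 − exp(−t)`, new residue uniform over the
other 19) with no indels, so the true alignment is trivial and pairwise
p-distance expectations are closed-form (`E[p] ≈ 1 − exp(−(t_i + t_j))` up
to coincident-substitution terms). Empirical exchangeability matrices
(WAG/LG), rate heterogeneity and indels are deliberately out of scope; MSA
behaviour under indels is tested with planted-deletion constructs instead.

## Problem sizes and determinism

The validation suite uses desk-scale sizes chosen to give tight binomial
error bars while staying instantaneous: 500 × 1000-residue sequences for
scanner/regex equivalence, 50 seeded forward simulations of 1000 sites on
an 8-leaf clock tree (t = 0.05/branch) for topology recovery, 200
simulated proteins per mutation-rate recall estimate, 200 bootstrap
replicates for the duplicate-cherry check. Every stochastic step takes an
explicit seed (NumPy `default_rng`); identical seeds reproduce outputs
bit-for-bit.

## Known limitations

- The exact aligner conventions behind published pairwise identity values
  (e.g. 87.5% between viral and human Jun BRLZ domains) are tool-specific;
  this package fixes one reproducible convention rather than emulating any
  particular desktop aligner.
- TM calling is heuristic by design; it does not model signal-peptidase
  cleavage or membrane-topology grammar, and helix-property values depend
  on the window fed to them.
- NJ tie handling differs between implementations; near-tie joins may
  legitimately differ from trees published with other software.
- Subfamily assignment is nearest-neighbour under Poisson distances, not a
  placement method; long-branch queries saturate and are reported
  unclassifiable rather than forced into a clade.
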