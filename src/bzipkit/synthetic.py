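"""Synthetic proteomes with planted, truth-tracked features, and protein
families evolved on known trees.

``plant_domains`` writes BR / LZ / CNC / TM / degron features (or a combined
BRLZ construct) into random background sequences at recorded coordinates,
optionally mutating planted residues at a per-site rate — so every detector
in the pipeline can be scored against exact truth.  ``evolve_on_tree``
simulates Poisson substitutions (no indels) along a tree whose branch
lengths are expected substitutions per site, so distance-based inference can
be tested against a known topology with closed-form expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import motifs
from .align import Alignment
from .phylo import PhyloTree
from .records import AMINO_ACIDS, HYDROPHILIC, ProteinRecord

#: Residues used to instantiate planted TM cores: strongly hydrophobic on the
#: Kyte–Doolittle scale, as in natural membrane-span h-regions.
TM_RESIDUES = "AILVFMC"

#: Swiss-Prot average amino-acid composition (percent), for the optional
#: proteome-like background.
PROTEOME_COMPOSITION = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.64, "T": 5.36, "W": 1.10, "Y": 2.92, "V": 6.86,
}

FEATURE_TYPES = (
    "BR",
    "LZ",
    "CNC",
    "TM",
    "DEGRON_CANONICAL",
    "DEGRON_NONCANONICAL",
    "BRLZ",
)

_MARGIN = 10
_HYDROPHILIC_SORTED = sorted(HYDROPHILIC)


@dataclass(frozen=True)
class PlantedFeature:
    feature_type: str
    start: int
    end: int
    phase: Optional[int] = None  # LZ only: start mod 7


@dataclass
class SyntheticTruth:
    """Machine-readable truth for one generated record."""

    record_id: str
    features: list[PlantedFeature] = field(default_factory=list)
    seed: int = 0
    mutation_rate: float = 0.0
    background: str = "uniform"


@dataclass
class TreeTruth:
    """Truth for a tree-evolved family: the generating tree and parameters."""

    newick: str
    seed: int
    root_id: str


def _background_sampler(background: str):
    if background == "uniform":
        letters, probs = list(AMINO_ACIDS), None
    elif background == "hydrophilic":
        letters, probs = _HYDROPHILIC_SORTED, None
    elif background == "proteome":
        letters = sorted(PROTEOME_COMPOSITION)
        total = sum(PROTEOME_COMPOSITION.values())
        probs = [PROTEOME_COMPOSITION[a] / total for a in letters]
    else:
        raise ValueError(f"unknown background {background!r}")
    return letters, probs


def _sample_pattern(pattern: motifs.ConsensusPattern, rng: np.random.Generator) -> str:
    return "".join(str(rng.choice(sorted(cls))) for cls in pattern.positions)


def _build_lz(n_repeats: int, rng: np.random.Generator) -> str:
    """A perfect zipper: L at every "d", N at the third "a", hydrophilic
    residues elsewhere (so no off-phase d-class runs arise)."""
    out = []
    for j in range(n_repeats):
        for offset in range(7):
            if offset == 3:
                out.append("L")
            elif offset == 0 and j == 2:
                out.append("N")
            else:
                out.append(str(rng.choice(_HYDROPHILIC_SORTED)))
    return "".join(out)


def _feature_instance(
    feature: str, rng: np.random.Generator, lz_repeats: int
) -> tuple[str, list[tuple[str, int, int, Optional[int]]]]:
    """Return (sequence, sub-features as (type, rel_start, rel_end, phase))."""
    if feature == "BR":
        seq = _sample_pattern(motifs.BR_NLS, rng)
        return seq, [("BR", 0, len(seq), None)]
    if feature == "CNC":
        seq = _sample_pattern(motifs.CNC_CORE, rng)
        return seq, [("CNC", 0, len(seq), None)]
    if feature == "LZ":
        seq = _build_lz(lz_repeats, rng)
        return seq, [("LZ", 0, len(seq), None)]
    if feature == "TM":
        seq = "".join(str(rng.choice(list(TM_RESIDUES))) for _ in range(21))
        return seq, [("TM", 0, 21, None)]
    if feature == "DEGRON_CANONICAL":
        x = str(rng.choice(list(AMINO_ACIDS)))
        return f"DSG{x}SL", [("DEGRON_CANONICAL", 0, 6, None)]
    if feature == "DEGRON_NONCANONICAL":
        x4 = str(rng.choice(list(AMINO_ACIDS)))
        x5 = str(rng.choice([a for a in AMINO_ACIDS if a != "S"]))
        return f"DSG{x4}{x5}L", [("DEGRON_NONCANONICAL", 0, 6, None)]
    if feature == "BRLZ":
        br = _sample_pattern(motifs.BR_NLS, rng)
        gap = int(rng.integers(0, 8))
        spacer = "".join(str(rng.choice(_HYDROPHILIC_SORTED)) for _ in range(gap))
        lz = _build_lz(lz_repeats, rng)
        seq = br + spacer + lz
        lz_start = len(br) + gap
        return seq, [
            ("BR", 0, len(br), None),
            ("LZ", lz_start, lz_start + len(lz), None),
        ]
    raise ValueError(f"unknown feature {feature!r}")


def plant_domains(
    n: int,
    length: int,
    features: Sequence[str],
    mutation_rate: float = 0.0,
    seed: int = 0,
    background: str = "uniform",
    lz_repeats: int = 6,
) -> tuple[list[ProteinRecord], list[SyntheticTruth]]:
    """Generate ``n`` proteins of ``length`` residues carrying the requested
    features at random non-overlapping positions with 10-residue margins.

    Planted residues are then mutated to a uniform random residue with
    probability ``mutation_rate``; truth records the exact spans (and the
    heptad phase for LZ features).
    """
    for f in features:
        if f not in FEATURE_TYPES:
            raise ValueError(f"unknown feature {f!r}")
    rng = np.random.default_rng(seed)
    letters, probs = _background_sampler(background)
    records: list[ProteinRecord] = []
    truths: list[SyntheticTruth] = []
    for idx in range(n):
        instances = [_feature_instance(f, rng, lz_repeats) for f in features]
        total = sum(len(seq) for seq, _ in instances)
        free = length - total - _MARGIN * (len(features) + 1)
        if free < 0:
            raise ValueError(
                f"length {length} cannot hold features {list(features)} "
                f"with {_MARGIN}-residue margins"
            )
        gaps = rng.multinomial(free, [1 / (len(features) + 1)] * (len(features) + 1))
        seq = [str(c) for c in rng.choice(letters, size=length, p=probs)]
        truth = SyntheticTruth(
            record_id=f"syn{idx}",
            seed=seed,
            mutation_rate=mutation_rate,
            background=background,
        )
        pos = 0
        for (feat_seq, subfeats), gap in zip(instances, gaps):
            pos += _MARGIN + int(gap)
            seq[pos : pos + len(feat_seq)] = feat_seq
            for ftype, rel_start, rel_end, _ in subfeats:
                phase = (pos + rel_start) % 7 if ftype == "LZ" else None
                truth.features.append(
                    PlantedFeature(ftype, pos + rel_start, pos + rel_end, phase)
                )
                if ftype == "LZ":
                    # guard positions: the flanking heptads' "d" residues are
                    # made non-hydrophobic so the planted run is maximal
                    for guard in (pos + rel_start - 4, pos + rel_end + 3):
                        if 0 <= guard < length and seq[guard] not in HYDROPHILIC:
                            seq[guard] = "S"
            pos += len(feat_seq)
        if mutation_rate > 0:
            for feat in truth.features:
                for i in range(feat.start, feat.end):
                    if rng.random() < mutation_rate:
                        seq[i] = str(rng.choice(list(AMINO_ACIDS)))
        records.append(ProteinRecord(id=truth.record_id, sequence="".join(seq)))
        truths.append(truth)
    return records, truths


def truth_to_frame(truths: list[SyntheticTruth]) -> pd.DataFrame:
    """Truth table as a TSV-ready DataFrame (one row per planted feature)."""
    rows = [
        {
            "record_id": t.record_id,
            "feature": f.feature_type,
            "start": f.start,
            "end": f.end,
            "phase": "" if f.phase is None else f.phase,
            "seed": t.seed,
            "mutation_rate": t.mutation_rate,
            "background": t.background,
        }
        for t in truths
        for f in t.features
    ]
    return pd.DataFrame(rows)


def truth_from_frame(df: pd.DataFrame) -> list[SyntheticTruth]:
    out: dict[str, SyntheticTruth] = {}
    for row in df.itertuples(index=False):
        t = out.setdefault(
            row.record_id,
            SyntheticTruth(
                record_id=row.record_id,
                seed=int(row.seed),
                mutation_rate=float(row.mutation_rate),
                background=str(row.background),
            ),
        )
        phase = None if row.phase in ("", None) or pd.isna(row.phase) else int(row.phase)
        t.features.append(PlantedFeature(row.feature, int(row.start), int(row.end), phase))
    return list(out.values())


def balanced_tree_newick(depth: int, branch_length: float) -> str:
    """A balanced binary clock tree with 2**depth leaves named L0, L1, ..."""
    counter = [0]

    def build(d: int) -> str:
        if d == 0:
            name = f"L{counter[0]}"
            counter[0] += 1
            return f"{name}:{branch_length}"
        return f"({build(d - 1)},{build(d - 1)}):{branch_length}"

    left, right = build(depth - 1), build(depth - 1)
    return f"({left},{right});"


def star_tree_newick(n_leaves: int, branch_length: float) -> str:
    tips = ",".join(f"L{i}:{branch_length}" for i in range(n_leaves))
    return f"({tips});"


def evolve_on_tree(
    tree: Union[str, PhyloTree],
    root_seq: ProteinRecord,
    seed: int = 0,
) -> tuple[list[ProteinRecord], Alignment, TreeTruth]:
    """Simulate Poisson substitutions along a tree.

    Along each branch of length ``t`` (expected substitutions per site) every
    site substitutes with probability 1 - exp(-t), the new residue uniform
    over the other 19.  There are no indels, so the true alignment is the
    ungapped leaf matrix.  Leaves are named by the tree's tip labels.
    """
    if isinstance(tree, str):
        from .io import parse_newick

        tree = parse_newick(tree)
    newick_text = _tree_text(tree)
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root = np.frombuffer(root_seq.sequence.encode(), dtype=np.uint8).copy()
    leaves: list[tuple[str, np.ndarray]] = []

    def walk(node, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length
            if t < 0:
                raise ValueError(f"negative branch length {t}")
            child_seq = seq.copy()
            hit = rng.random(len(child_seq)) < 1 - math.exp(-t)
            for i in np.nonzero(hit)[0]:
                choices = alphabet[alphabet != child_seq[i]]
                child_seq[i] = rng.choice(choices)
            if child.children:
                walk(child, child_seq)
            else:
                leaves.append((child.name, child_seq))

    walk(tree.root, root)
    records = [
        ProteinRecord(id=name, sequence=seq.tobytes().decode())
        for name, seq in leaves
    ]
    true_aln = Alignment(
        rows=tuple(
            ProteinRecord(r.id, r.sequence, aligned=True) for r in records
        )
    )
    return records, true_aln, TreeTruth(newick=newick_text, seed=seed, root_id=root_seq.id)


def _tree_text(tree: PhyloTree) -> str:
    from .io import format_newick

    return format_newick(tree)
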