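"""Pairwise global alignment, percent identity, progressive MSA and
column conservation profiles.

The pairwise engine is a Needleman–Wunsch / Gotoh affine-gap aligner with a
deterministic traceback (prefer diagonal, then a gap in the second sequence,
then a gap in the first).  A length-k gap costs ``gap_open + k*gap_extend``.
BLOSUM62 (from Biopython) with open 10 / extend 0.5 are the defaults.  The
multiple aligner is progressive: a neighbor-joining guide tree on pairwise
p-distances, profiles merged leaf-to-root with mean-of-pairs column scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .records import AMINO_ACIDS, ProteinRecord

NEG_INF = float("-inf")


@lru_cache(maxsize=1)
def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


@dataclass(frozen=True)
class Alignment:
    """Gap-carrying rows of equal length; stripping gaps recovers the inputs."""

    rows: tuple[ProteinRecord, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        for r in self.rows:
            if not r.aligned:
                raise ValueError(f"alignment row {r.id!r} is not flagged aligned")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(r.sequence[j] for r in self.rows)


@dataclass
class LogoProfile:
    """Per-column residue frequencies, information content and consensus."""

    frequencies: list[dict[str, float]]
    information: np.ndarray  # bits per column
    consensus: str
    all_gap: list[bool] = field(default_factory=list)


def _score_columns(col_a: tuple[str, ...], col_b: tuple[str, ...]) -> float:
    """Mean BLOSUM62 score over non-gap residue pairs between two columns."""
    table = _blosum62()
    total, count = 0.0, 0
    for a in col_a:
        if a == "-":
            continue
        for b in col_b:
            if b == "-":
                continue
            total += table[(a, b)]
            count += 1
    return total / count if count else 0.0


def _gotoh(
    cols_a: list[tuple[str, ...]],
    cols_b: list[tuple[str, ...]],
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[str]]:
    """Affine-gap global alignment of two column lists.

    Returns (score, ops) where ops are 'D' (both), 'U' (consume a, gap in b),
    'L' (consume b, gap in a).  Ties prefer D, then U, then L.
    """
    la, lb = len(cols_a), len(cols_b)
    # state matrices: M ends in a match column, U ends in a gap-in-b column,
    # L ends in a gap-in-a column
    M = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    U = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    L = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        U[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, lb + 1):
        L[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, la + 1):
        ci = cols_a[i - 1]
        for j in range(1, lb + 1):
            s = _score_columns(ci, cols_b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], U[i - 1][j - 1], L[i - 1][j - 1]) + s
            U[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                U[i - 1][j] - gap_extend,
                L[i - 1][j] - gap_open - gap_extend,
            )
            L[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                U[i][j - 1] - gap_open - gap_extend,
                L[i][j - 1] - gap_extend,
            )
    # traceback; tie preference D > U > L at every step
    ops: list[str] = []
    i, j = la, lb
    scores = {"D": M[i][j], "U": U[i][j], "L": L[i][j]}
    best = max(scores.values())
    state = next(k for k in "DUL" if scores[k] == best)
    final = best
    while i > 0 or j > 0:
        if state == "D":
            s = _score_columns(cols_a[i - 1], cols_b[j - 1])
            prev = {"D": M[i - 1][j - 1], "U": U[i - 1][j - 1], "L": L[i - 1][j - 1]}
            target = M[i][j] - s
            ops.append("D")
            i, j = i - 1, j - 1
        elif state == "U":
            prev = {
                "D": M[i - 1][j] - gap_open,
                "U": U[i - 1][j],
                "L": L[i - 1][j] - gap_open,
            }
            target = U[i][j] + gap_extend
            ops.append("U")
            i -= 1
        else:
            prev = {
                "D": M[i][j - 1] - gap_open,
                "U": U[i][j - 1] - gap_open,
                "L": L[i][j - 1],
            }
            target = L[i][j] + gap_extend
            ops.append("L")
            j -= 1
        if i == 0 and j == 0:
            break
        state = next(
            k for k in "DUL" if not math.isinf(prev[k]) and abs(prev[k] - target) < 1e-9
        )
    ops.reverse()
    return final, ops


def _merge(rows_a: list[str], rows_b: list[str], ops: list[str]) -> list[str]:
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("D", "L"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a + out_b


def align_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Global Needleman–Wunsch alignment of two unaligned records."""
    if a.aligned or b.aligned:
        raise ValueError("align_pair expects unaligned records")
    cols_a = [(ch,) for ch in a.sequence]
    cols_b = [(ch,) for ch in b.sequence]
    score, ops = _gotoh(cols_a, cols_b, gap_open, gap_extend)
    row_a, row_b = _merge([a.sequence], [b.sequence], ops)
    return Alignment(
        rows=(
            ProteinRecord(a.id, row_a, a.species, aligned=True),
            ProteinRecord(b.id, row_b, b.species, aligned=True),
        ),
        score=score,
    )


def percent_identity(aln: Alignment) -> float:
    """100 x identical columns / residue-residue columns, to 2 decimals."""
    if aln.n_rows != 2:
        raise ValueError("percent_identity requires exactly two rows")
    ra, rb = aln.rows[0].sequence, aln.rows[1].sequence
    compared = identical = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            compared += 1
            if x == y:
                identical += 1
    if compared == 0:
        raise ValueError("no residue-residue overlap columns")
    return round(100.0 * identical / compared, 2)


def _pairwise_p_distance(a: ProteinRecord, b: ProteinRecord) -> float:
    aln = align_pair(a, b)
    return 1.0 - percent_identity(aln) / 100.0


def progressive_msa(
    records: list[ProteinRecord],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Guide-tree progressive multiple alignment.

    The guide tree is neighbor joining on pairwise p-distances from global
    alignments; profiles are merged leaf-to-root under the same scoring.
    """
    if len(records) < 2:
        raise ValueError("progressive_msa requires at least 2 records")
    if len(records) == 2:
        return align_pair(records[0], records[1], gap_open, gap_extend)

    from .phylo import DistanceMatrix, nj_tree  # local import: phylo uses Alignment

    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_p_distance(records[i], records[j])
    guide = nj_tree(DistanceMatrix(tuple(r.id for r in records), d, model="p"))
    by_id = {r.id: r for r in records}

    def build(node) -> list[tuple[str, str]]:
        if not node.children:
            return [(node.name, by_id[node.name].sequence)]
        merged = build(node.children[0])
        for child in node.children[1:]:
            other = build(child)
            cols_a = [tuple(s[j] for _, s in merged) for j in range(len(merged[0][1]))]
            cols_b = [tuple(s[j] for _, s in other) for j in range(len(other[0][1]))]
            _, ops = _gotoh(cols_a, cols_b, gap_open, gap_extend)
            rows = _merge([s for _, s in merged], [s for _, s in other], ops)
            ids = [i for i, _ in merged] + [i for i, _ in other]
            merged = list(zip(ids, rows))
        return merged

    aligned = dict(build(guide.root))
    return Alignment(
        rows=tuple(
            ProteinRecord(r.id, aligned[r.id], r.species, aligned=True)
            for r in records
        )
    )


def column_profile(aln: Alignment, small_sample_correction: bool = False) -> LogoProfile:
    """Residue frequencies, information content (bits) and consensus per column.

    Frequencies are over non-gap, non-X residues.  IC_j = log2(20) + sum_r
    f_rj log2 f_rj, with 0 log 0 := 0; an all-gap column gets IC 0 and a flag.
    The optional small-sample correction subtracts 19/(2 ln2 n_j).
    """
    if aln.n_rows < 2:
        raise ValueError("column_profile requires at least 2 rows")
    max_ic = math.log2(len(AMINO_ACIDS))
    freqs: list[dict[str, float]] = []
    ics: list[float] = []
    consensus: list[str] = []
    all_gap: list[bool] = []
    for j in range(aln.n_cols):
        residues = [c for c in aln.column(j) if c not in ("-", "X")]
        if not residues:
            freqs.append({})
            ics.append(0.0)
            consensus.append("-")
            all_gap.append(True)
            continue
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        total = len(residues)
        f = {r: c / total for r, c in sorted(counts.items())}
        ic = max_ic + sum(v * math.log2(v) for v in f.values())
        if small_sample_correction:
            ic -= (len(AMINO_ACIDS) - 1) / (2 * math.log(2) * total)
        freqs.append(f)
        ics.append(max(ic, 0.0))
        consensus.append(max(f, key=lambda r: (f[r], -ord(r))))
        all_gap.append(False)
    return LogoProfile(
        frequencies=freqs,
        information=np.array(ics),
        consensus="".join(consensus),
        all_gap=all_gap,
    )


def align_to_profile(
    aln: Alignment,
    record: ProteinRecord,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Align an unaligned query record into an existing alignment (profile
    alignment); the query becomes the last row."""
    cols_a = [aln.column(j) for j in range(aln.n_cols)]
    cols_b = [(ch,) for ch in record.sequence]
    _, ops = _gotoh(cols_a, cols_b, gap_open, gap_extend)
    rows = _merge([r.sequence for r in aln.rows], [record.sequence], ops)
    new_rows = [
        ProteinRecord(r.id, s, r.species, aligned=True)
        for r, s in zip(aln.rows, rows[:-1])
    ]
    new_rows.append(ProteinRecord(record.id, rows[-1], record.species, aligned=True))
    return Alignment(rows=tuple(new_rows))
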