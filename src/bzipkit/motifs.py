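"""Degenerate consensus-pattern compiler and scanner.

Patterns are ordered lists of residue-class sets.  A class is an explicit
residue set (``K/R``), the hydrophobic class φ, the hydrophilic class ϕ
(its exact complement), the basic class B, or the wildcard X.  Scanning is
fixed-length Hamming matching of each window against the classes — no indels
inside a motif window.

The module ships the basic-region/NLS consensus of the bZIP superfamily, the
CNC-domain core and CNC-flavoured basic region of the Nrf/CNC subfamily, and
the β-TrCP phosphodegron motifs (canonical DSGxSL, non-canonical DSGxxL) plus
the DDI-protease active-site pattern DSGxQx.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .records import AMINO_ACIDS, BASIC, HYDROPHILIC, HYDROPHOBIC, ProteinRecord

WILDCARD = frozenset(AMINO_ACIDS)

_CLASS_SYMBOLS = {
    "X": WILDCARD,
    "φ": frozenset(HYDROPHOBIC),
    "ϕ": frozenset(HYDROPHILIC),
    "B": frozenset(BASIC),
}

# residue -> column index for the scanner; 'X' (unknown) gets its own column
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_RESIDUE_INDEX["X"] = len(AMINO_ACIDS)


@dataclass(frozen=True)
class ConsensusPattern:
    """A named, fixed-length degenerate pattern."""

    name: str
    positions: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError(f"pattern {self.name!r}: zero-length expansion")
        for i, cls in enumerate(self.positions):
            if not cls:
                raise ValueError(f"pattern {self.name!r}: empty class at position {i}")

    def __len__(self) -> int:
        return len(self.positions)

    def membership_matrix(self) -> np.ndarray:
        """Boolean (length, 21) matrix: does residue-column match the class?

        The last column is the unknown residue 'X', which matches only the
        wildcard class (conservative handling of unknowns).
        """
        m = np.zeros((len(self), len(AMINO_ACIDS) + 1), dtype=bool)
        for i, cls in enumerate(self.positions):
            for aa in cls:
                m[i, _RESIDUE_INDEX[aa]] = True
            if cls == WILDCARD:
                m[i, -1] = True
        return m


@dataclass(frozen=True)
class MotifHit:
    """A located match of a pattern in a record (0-based, half-open span)."""

    record_id: str
    pattern_name: str
    start: int
    end: int
    mismatches: int
    matched_seq: str


_TOKEN_RE = re.compile(r"^(?:\((?P<par>[^()]+)\)|(?P<bare>[^()\d]+))(?P<rep>\d*)$")


def _resolve_class(body: str, token: str) -> frozenset:
    """Resolve a '/'-separated alternative list into a residue set (union)."""
    result: set[str] = set()
    for alt in body.split("/"):
        if alt in _CLASS_SYMBOLS:
            result |= _CLASS_SYMBOLS[alt]
        elif len(alt) == 1 and alt in AMINO_ACIDS:
            result.add(alt)
        else:
            raise ValueError(f"unknown token {token!r} (unrecognised part {alt!r})")
    return frozenset(result)


def compile_pattern(spec: str, name: str | None = None) -> ConsensusPattern:
    """Compile a dash-delimited consensus string, e.g. ``"K/R-X3-(R/K)2"``.

    Alternatives are joined with '/', repeats are a digit suffix (``X3``,
    ``(R/K)2``), class symbols are φ (hydrophobic), ϕ (hydrophilic), B
    (basic), X (any).
    """
    positions: list[frozenset] = []
    for token in spec.strip().strip("-").split("-"):
        token = token.strip()
        if not token:
            raise ValueError(f"unknown token {token!r} (empty)")
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ValueError(f"unknown token {token!r}")
        body = m.group("par") or m.group("bare")
        repeat = int(m.group("rep")) if m.group("rep") else 1
        if repeat < 1:
            raise ValueError(f"zero-length expansion in token {token!r}")
        cls = _resolve_class(body, token)
        positions.extend([cls] * repeat)
    if not positions:
        raise ValueError("zero-length expansion")
    return ConsensusPattern(name=name or spec, positions=tuple(positions))


# -- built-in patterns -------------------------------------------------------

#: 21-aa bipartite-NLS basic region of the bZIP superfamily consensus.
BR_NLS = compile_pattern(
    "K/R-X3-(R/K)2-X-K/R-N-R/K/N-X-A/S/Y-A/V-X2-C/S-R-X-(K/R)3", name="BR_NLS"
)

#: 35-position CNC-domain core (relative offsets within the CNC domain).
#: "F/φ" and "Q/ϕ" are set unions (equal to φ and ϕ respectively, since F is
#: hydrophobic and Q hydrophilic); kept explicit for traceability.
CNC_CORE = compile_pattern(
    "φ-ϕ-I/L-P/Q-F/φ-X2-ϕ2-I/L-φ/T-ϕ-L/M-P/S-V/R-ϕ-D/E-F-N/Q-X-φ2-X4-L/F-X3-Q/ϕ-φ-X-φ-φ",
    name="CNC_CORE",
)

#: CNC-flavoured 21-aa basic region of the Nrf/CNC subfamily.
CNC_BR = compile_pattern(
    "B-D/E-φ-R3-G/S-K-N-K/R-φ-A2-Q/R-N/K-C-R-K-R-K-φ", name="CNC_BR"
)

#: Canonical β-TrCP phosphodegron.
DEGRON_CANONICAL = compile_pattern("D-S-G-X-S-L", name="DEGRON_CANONICAL")
#: Non-canonical degron (5th position relaxed).
DEGRON_NONCANONICAL = compile_pattern("D-S-G-X-X-L", name="DEGRON_NONCANONICAL")
#: DDI aspartic-protease active-site pattern, similar to the degrons.
DDI_SITE = compile_pattern("D-S-G-X-Q-X", name="DDI_SITE")

#: Lineage variants of the BR -C/S-R- peptide noted for viral MEQ / bacterial
#: Nach1 (-A-R-) and yeast Yaps (-Y/F-R-); exposed but not scanned by default.
BR_NLS_AR = compile_pattern(
    "K/R-X3-(R/K)2-X-K/R-N-R/K/N-X-A/S/Y-A/V-X2-A-R-X-(K/R)3", name="BR_NLS_AR"
)
BR_NLS_YFR = compile_pattern(
    "K/R-X3-(R/K)2-X-K/R-N-R/K/N-X-A/S/Y-A/V-X2-Y/F-R-X-(K/R)3", name="BR_NLS_YFR"
)

BUILTIN_PATTERNS: dict[str, ConsensusPattern] = {
    p.name: p
    for p in (
        BR_NLS,
        CNC_CORE,
        CNC_BR,
        DEGRON_CANONICAL,
        DEGRON_NONCANONICAL,
        DDI_SITE,
        BR_NLS_AR,
        BR_NLS_YFR,
    )
}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode residues as integer indices (X -> 20); gaps are not allowed."""
    try:
        return np.fromiter((_RESIDUE_INDEX[ch] for ch in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"cannot scan gapped/illegal residue {exc}") from exc


def scan(
    record: ProteinRecord, pattern: ConsensusPattern, max_mismatch: int = 0
) -> list[MotifHit]:
    """All windows of ``record`` matching ``pattern`` with <= ``max_mismatch``
    out-of-class positions, left to right.  Overlaps are allowed."""
    if record.aligned or "-" in record.sequence:
        raise ValueError(f"record {record.id!r}: scan requires an unaligned record")
    if max_mismatch >= len(pattern):
        raise ValueError(
            f"max_mismatch={max_mismatch} >= pattern length {len(pattern)} "
            "(degenerate query)"
        )
    n, length = len(record), len(pattern)
    if n < length:
        return []
    enc = encode_sequence(record.sequence)
    member = pattern.membership_matrix()
    windows = np.lib.stride_tricks.sliding_window_view(enc, length)
    mism = (~member[np.arange(length), windows]).sum(axis=1)
    hits = [
        MotifHit(
            record_id=record.id,
            pattern_name=pattern.name,
            start=int(s),
            end=int(s) + length,
            mismatches=int(mism[s]),
            matched_seq=record.sequence[s : s + length],
        )
        for s in np.nonzero(mism <= max_mismatch)[0]
    ]
    return hits


def scan_degrons(record: ProteinRecord, max_mismatch: int = 0) -> list[MotifHit]:
    """Canonical (DSGxSL) and non-canonical (DSGxxL) degron hits.

    A window matching the canonical motif is reported under the canonical
    name only — the canonical pattern subsumes the non-canonical one at
    that site.
    """
    canonical = scan(record, DEGRON_CANONICAL, max_mismatch)
    canonical_starts = {h.start for h in canonical}
    noncanonical = [
        h
        for h in scan(record, DEGRON_NONCANONICAL, max_mismatch)
        if h.start not in canonical_starts
    ]
    return sorted(canonical + noncanonical, key=lambda h: (h.start, h.mismatches))


def hits_to_rows(hits: Iterable[MotifHit]) -> list[dict]:
    """TSV-ready rows (columns: record_id, pattern, start, end, mismatches, match)."""
    return [
        {
            "record_id": h.record_id,
            "pattern": h.pattern_name,
            "start": h.start,
            "end": h.end,
            "mismatches": h.mismatches,
            "match": h.matched_seq,
        }
        for h in hits
    ]
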