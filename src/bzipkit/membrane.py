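"""Transmembrane segment calling and helix properties.

TM spans are called from a sliding-window Kyte–Doolittle hydropathy profile
(window 19, call threshold 1.6 — the classic recommendation for membrane
spans).  Each called span carries its best 21-residue core window, the
maximal hydrophobic (h-region) run, the summed charges of the 15-residue
n- and c-flanks, an orientation call from the positive-inside heuristic,
plus GRAVY (grand average of hydropathy) and Ikai's aliphatic index of the
core.  An 18-residue helical-wheel projection (100° per residue) summarises
the hydrophobic face.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import HYDROPHOBIC, ProteinRecord

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Fauchère–Pliska hydrophobicity (HeliQuest's scale), selectable for GRAVY.
FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.0, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

_SCALES = {"kd": KYTE_DOOLITTLE, "fp": FAUCHERE_PLISKA}

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass(frozen=True)
class TMSegment:
    """A called membrane span with its helix properties."""

    record_id: str
    span: tuple[int, int]
    core_span: tuple[int, int]
    h_region: tuple[int, int]
    n_charge: float
    c_charge: float
    delta_q: float
    orientation: str  # Ncyt | Nlum | ambiguous
    gravy: float
    aliphatic_index: float


@dataclass(frozen=True)
class WheelLayout:
    """Helical-wheel projection: residue i sits at (100 * i) mod 360 degrees."""

    residues: tuple[str, ...]
    angles: tuple[float, ...]
    hydrophobic_arc: float  # widest contiguous hydrophobic arc, degrees


def _kd_values(seq: str, scale: str = "kd") -> np.ndarray:
    table = _SCALES[scale]
    return np.array([table.get(ch, 0.0) for ch in seq])  # X contributes 0


def hydropathy_profile(
    record: ProteinRecord, window: int = 19, scale: str = "kd"
) -> np.ndarray:
    """Windowed mean hydropathy; entry i is the value at center position
    ``i + window // 2`` (positions without a full window are absent)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if len(record) < window:
        raise ValueError(f"sequence shorter than window ({len(record)} < {window})")
    vals = _kd_values(record.sequence, scale)
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def _flank_charge(seq: str, start: int, end: int) -> float:
    return sum(_CHARGE.get(ch, 0.0) for ch in seq[max(start, 0) : max(end, 0)])


def _h_region(seq: str, span: tuple[int, int]) -> tuple[int, int]:
    """Longest run of hydrophobic-class residues inside the span (first on tie)."""
    best = (span[0], span[0])
    run_start = None
    for i in range(span[0], span[1] + 1):
        inside = i < span[1] and seq[i] in HYDROPHOBIC
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            if i - run_start > best[1] - best[0]:
                best = (run_start, i)
            run_start = None
    return best


def call_tm_segments(
    record: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    flank: int = 15,
    core_len: int = 21,
    his_charge: float = 0.0,
) -> list[TMSegment]:
    """Maximal runs of window centers with mean hydropathy >= threshold,
    expanded to full windows; overlapping calls are merged."""
    n = len(record)
    if n < window:
        return []
    seq = record.sequence
    profile = hydropathy_profile(record, window)
    half = window // 2
    centers = np.nonzero(profile >= threshold)[0] + half
    if len(centers) == 0:
        return []
    # group consecutive centers, expand to windows, merge overlaps
    spans: list[list[int]] = []
    for c in centers:
        lo, hi = int(c) - half, int(c) + half + 1
        if spans and lo <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], hi)
        else:
            spans.append([lo, hi])
    charge = dict(_CHARGE)
    if his_charge:
        charge["H"] = his_charge

    def span_charge(a: int, b: int) -> float:
        return sum(charge.get(ch, 0.0) for ch in seq[max(a, 0) : max(b, 0)])

    kd = _kd_values(seq)
    segments: list[TMSegment] = []
    for lo, hi in spans:
        length = min(core_len, hi - lo)
        sums = np.convolve(kd[lo:hi], np.ones(length), mode="valid")
        best = int(np.argmax(sums))
        core = (lo + best, lo + best + length)
        # flanks bracket the core window: the window-expanded span overruns
        # the hydrophobic stretch by a few residues and would swallow
        # immediately adjacent charged flank residues
        n_charge = span_charge(core[0] - flank, core[0])
        c_charge = span_charge(core[1], core[1] + flank)
        delta_q = n_charge - c_charge
        if delta_q > 1:
            orientation = "Ncyt"
        elif delta_q < -1:
            orientation = "Nlum"
        else:
            orientation = "ambiguous"
        core_seq = seq[core[0] : core[1]]
        segments.append(
            TMSegment(
                record_id=record.id,
                span=(lo, hi),
                core_span=core,
                h_region=_h_region(seq, (lo, hi)),
                n_charge=n_charge,
                c_charge=c_charge,
                delta_q=delta_q,
                orientation=orientation,
                gravy=gravy(core_seq),
                aliphatic_index=aliphatic_index(core_seq),
            )
        )
    return segments


def classify_nhb1(
    record: ProteinRecord,
    segments: list[TMSegment],
    cnc_hits: list,
    n_terminal_cutoff: int = 30,
    c_terminal_window: int = 60,
) -> str:
    """Membrane-topology class of a bZIP factor.

    ``NHB1-type``: an N-terminal signal-anchor segment (start <= cutoff) on a
    CNC-domain-bearing factor (the Nrf1/Nrf3 arrangement); ``TMc-type``: a
    segment within the last ``c_terminal_window`` residues (the XBP1u/Nrf1D
    arrangement); ``internal-TM`` otherwise when any segment exists; else
    ``none``.
    """
    if not segments:
        return "none"
    if cnc_hits and any(s.span[0] <= n_terminal_cutoff for s in segments):
        return "NHB1-type"
    if any(s.span[0] >= len(record) - c_terminal_window for s in segments):
        return "TMc-type"
    return "internal-TM"


def helix_wheel(seq: str, allow_any_length: bool = False) -> WheelLayout:
    """Helical-wheel layout with the widest contiguous hydrophobic arc.

    Each residue occupies one sector of width 360/len; the arc is 360 minus
    the largest circular gap between consecutive hydrophobic angles plus one
    sector width, so a fully hydrophobic helix covers 360° and a single
    hydrophobic residue one sector.
    """
    if len(seq) != 18 and not allow_any_length:
        raise ValueError("helix_wheel expects an 18-mer (pass allow_any_length=True)")
    angles = tuple(float((i * 100) % 360) for i in range(len(seq)))
    sector = 360.0 / len(seq)
    hydro = sorted(a for a, ch in zip(angles, seq) if ch in HYDROPHOBIC)
    if not hydro:
        arc = 0.0
    elif len(hydro) == 1:
        arc = sector
    else:
        gaps = [b - a for a, b in zip(hydro, hydro[1:])]
        gaps.append(360.0 - hydro[-1] + hydro[0])
        arc = 360.0 - max(gaps) + sector
    return WheelLayout(residues=tuple(seq), angles=angles, hydrophobic_arc=arc)


def aliphatic_index(seq: str) -> float:
    """Ikai's aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu) with
    X_r the mole percent of residue r ('X' excluded from the denominator)."""
    residues = [ch for ch in seq if ch != "X"]
    if not residues:
        raise ValueError("aliphatic_index of empty (or all-unknown) sequence")
    n = len(residues)
    mole = {aa: 100.0 * residues.count(aa) / n for aa in "AVIL"}
    return mole["A"] + 2.9 * mole["V"] + 3.9 * (mole["I"] + mole["L"])


def gravy(seq: str, scale: str = "kd") -> float:
    """Grand average of hydropathy: mean scale value over residues, X excluded."""
    residues = [ch for ch in seq if ch != "X"]
    if not residues:
        raise ValueError("gravy of empty (or all-unknown) sequence")
    table = _SCALES[scale]
    return sum(table[ch] for ch in residues) / len(residues)


def segments_to_rows(segments: list[TMSegment], tm_class: Optional[str] = None) -> list[dict]:
    """TSV-ready rows for TM segment calls."""
    return [
        {
            "record_id": s.record_id,
            "start": s.span[0],
            "end": s.span[1],
            "core_start": s.core_span[0],
            "core_end": s.core_span[1],
            "gravy": round(s.gravy, 4),
            "aliphatic_index": round(s.aliphatic_index, 2),
            "n_charge": s.n_charge,
            "c_charge": s.c_charge,
            "delta_q": s.delta_q,
            "orientation": s.orientation,
            "class": tm_class or "",
        }
        for s in segments
    ]
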