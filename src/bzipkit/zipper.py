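"""Leucine-zipper heptad-register detection and BRLZ domain assembly.

A coiled-coil heptad repeat cycles through positions a–g with period 7; the
"a" and "d" positions form the hydrophobic dimer interface.  In bZIP zippers
the "d" positions are occupied primarily by leucine or another bulky
hydrophobic residue, and the third "a" position is conserved as asparagine.
The full bZIP-defining domain (BRLZ) is a basic region / nuclear localization
signal followed closely by the zipper, 60–80 residues in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Optional

from . import motifs
from .records import HYDROPHOBIC, ProteinRecord

#: Default "d"-position class: leucine or any hydrophobic residue.
DEFAULT_D_CLASS: FrozenSet[str] = frozenset({"L"}) | HYDROPHOBIC


@dataclass(frozen=True)
class HeptadRegister:
    """A maximal run of heptads whose "d" positions satisfy the d-class rule.

    ``start`` is the 0-based offset of the first "a" position; within each
    heptad "a" is offset 0 and "d" is offset 3.  Registers with six or more
    repeats (the canonical full bZIP zipper) are flagged ``full``.
    """

    start: int
    n_repeats: int
    a_residues: tuple[str, ...]
    d_residues: tuple[str, ...]
    d_leucine_fraction: float
    asn_at_third_a: bool

    @property
    def end(self) -> int:
        return self.start + 7 * self.n_repeats

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def full(self) -> bool:
        return self.n_repeats >= 6


@dataclass(frozen=True)
class BRLZDomain:
    """An assembled basic-region + leucine-zipper call."""

    record_id: str
    br_span: tuple[int, int]
    lz_span: tuple[int, int]
    cnc_flavored: bool
    register: HeptadRegister

    @property
    def full_span(self) -> tuple[int, int]:
        return (self.br_span[0], self.lz_span[1])

    @property
    def length(self) -> int:
        return self.full_span[1] - self.full_span[0]


def find_heptad_registers(
    record: ProteinRecord,
    min_repeats: int = 4,
    d_class: FrozenSet[str] = DEFAULT_D_CLASS,
    min_d_leucines: int = 3,
) -> list[HeptadRegister]:
    """Maximal heptad runs whose every "d" residue lies in ``d_class`` and at
    least ``min_d_leucines`` of them are exactly leucine.

    Maximality: a reported run cannot be extended by a complete heptad on
    either side without violating the d-class rule.
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    seq = record.sequence
    n = len(seq)
    registers: list[HeptadRegister] = []
    for s in range(0, n - 7 + 1):
        d0 = s + 3
        if seq[d0] not in d_class:
            continue
        # leftmost in its phase: the previous heptad must be impossible
        if s - 7 >= 0 and seq[s - 4] in d_class:
            continue
        k = 1
        while s + 7 * (k + 1) <= n and seq[s + 7 * k + 3] in d_class:
            k += 1
        if k < min_repeats:
            continue
        d_res = tuple(seq[s + 7 * j + 3] for j in range(k))
        n_leu = sum(1 for r in d_res if r == "L")
        if n_leu < min_d_leucines:
            continue
        a_res = tuple(seq[s + 7 * j] for j in range(k))
        registers.append(
            HeptadRegister(
                start=s,
                n_repeats=k,
                a_residues=a_res,
                d_residues=d_res,
                d_leucine_fraction=n_leu / k,
                asn_at_third_a=(k >= 3 and a_res[2] == "N"),
            )
        )
    return registers


def assemble_brlz(
    record: ProteinRecord,
    max_gap: int = 10,
    min_len: int = 60,
    max_len: int = 80,
    max_mismatch: int = 0,
    min_repeats: int = 4,
    br_only: bool = False,
) -> list[BRLZDomain]:
    """Pair basic-region hits with downstream heptad registers into BRLZ calls.

    A register pairs with a BR hit when its first "a" position lies at most
    ``max_gap`` residues after the BR end and the combined span length falls
    in ``[min_len, max_len]``.  When both the generic and the CNC-flavoured
    BR pattern hit the same span, the CNC call wins.  With ``br_only``
    (Skn-1-like proteins, which lack the zipper) BR hits are emitted without
    zipper pairing as zero-length-LZ domains.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    br_hits = {
        (h.start, h.end): h for h in motifs.scan(record, motifs.BR_NLS, max_mismatch)
    }
    # CNC-flavoured BR wins on span collision
    br_hits.update(
        {(h.start, h.end): h for h in motifs.scan(record, motifs.CNC_BR, max_mismatch)}
    )
    if br_only:
        return [
            BRLZDomain(
                record_id=record.id,
                br_span=(h.start, h.end),
                lz_span=(h.end, h.end),
                cnc_flavored=(h.pattern_name == "CNC_BR"),
                register=HeptadRegister(h.end, 0, (), (), 0.0, False),
            )
            for h in br_hits.values()
        ]
    if len(record) < 7 * min_repeats:
        return []
    registers = find_heptad_registers(record, min_repeats=min_repeats)
    calls: list[BRLZDomain] = []
    for br in sorted(br_hits.values(), key=lambda h: h.start):
        candidates = [
            reg
            for reg in registers
            if 0 <= reg.start - br.end <= max_gap
            and min_len <= reg.end - br.start <= max_len
        ]
        if not candidates:
            continue
        # most heptads first, then the smallest BR-LZ gap
        best = min(candidates, key=lambda r: (-r.n_repeats, r.start - br.end))
        calls.append(
            BRLZDomain(
                record_id=record.id,
                br_span=(br.start, br.end),
                lz_span=best.span,
                cnc_flavored=(br.pattern_name == "CNC_BR"),
                register=best,
            )
        )
    return calls


def brlz_to_rows(calls: list[BRLZDomain]) -> list[dict]:
    """TSV-ready rows for BRLZ calls."""
    return [
        {
            "record_id": c.record_id,
            "br_start": c.br_span[0],
            "br_end": c.br_span[1],
            "lz_start": c.lz_span[0],
            "lz_end": c.lz_span[1],
            "n_repeats": c.register.n_repeats,
            "d_residues": "".join(c.register.d_residues),
            "asn_third_a": c.register.asn_at_third_a,
            "cnc_flavored": c.cnc_flavored,
        }
        for c in calls
    ]
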