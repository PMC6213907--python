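"""Core sequence records and the amino-acid alphabet.

Every stage of the pipeline consumes and produces :class:`ProteinRecord`
objects.  Coordinates throughout the package are 0-based, half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard residues, alphabetically.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Hydrophobic class (φ).  Cysteine is hydrophobic here, consistent with its
#: positive Kyte–Doolittle score; histidine is hydrophilic for the same reason.
HYDROPHOBIC = frozenset("AVILMFWC")

#: Hydrophilic class (ϕ): the exact complement of the hydrophobic class, so the
#: two partition the 20-letter alphabet.
HYDROPHILIC = frozenset(AMINO_ACIDS) - HYDROPHOBIC

#: Basic residues (B).
BASIC = frozenset("KRH")

_VALID_UNALIGNED = frozenset(AMINO_ACIDS) | {"X"}
_VALID_ALIGNED = _VALID_UNALIGNED | {"-"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional species tag.

    ``sequence`` is upper-case over the 20 standard residues plus ``X``
    (unknown); ``-`` is permitted only when ``aligned`` is set.
    """

    id: str
    sequence: str
    species: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        valid = _VALID_ALIGNED if self.aligned else _VALID_UNALIGNED
        for pos, ch in enumerate(self.sequence):
            if ch not in valid:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> "ProteinRecord":
        """Return the record with gaps stripped (marks it unaligned)."""
        if not self.aligned:
            return self
        return ProteinRecord(
            id=self.id,
            sequence=self.sequence.replace("-", ""),
            species=self.species,
            aligned=False,
        )


@dataclass(frozen=True)
class ExpressionRow:
    """One gene's RPKM under two conditions (control vs. condition)."""

    gene: str
    rpkm_a: float
    rpkm_b: float

    def __post_init__(self) -> None:
        import math

        for name, v in (("rpkm_a", self.rpkm_a), ("rpkm_b", self.rpkm_b)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"gene {self.gene!r}: {name} must be finite and >= 0")


def check_unique_ids(records: list[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id!r}")
        seen.add(rec.id)
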