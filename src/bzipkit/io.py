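"""FASTA and Newick readers/writers plus key=value run configuration.

FASTA parsing is delegated to Biopython's SeqIO; record validation (alphabet,
uniqueness, aligned-length agreement) is applied on top.  Newick writing is
implemented here because the output contract is fixed: branch lengths to six
decimals, integer bootstrap supports as internal-node labels, no auto-quoting
of labels.  Newick parsing goes through scikit-bio.
"""

from __future__ import annotations

import io as _io
import sys
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ProteinRecord, check_unique_ids

PathLike = Union[str, Path]

_NEWICK_META = set(",():;")


def read_fasta(path: PathLike, aligned: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord`s.

    Case is normalised to upper; multi-line bodies are concatenated.  With
    ``aligned`` set, all sequences must share one length and may contain
    ``-`` gaps.  The species tag is taken from a ``species=`` key in the
    description, when present.
    """
    records: list[ProteinRecord] = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        species = ""
        for token in seq_rec.description.split():
            if token.startswith("species="):
                species = token.split("=", 1)[1]
        records.append(
            ProteinRecord(
                id=seq_rec.id,
                sequence=str(seq_rec.seq),
                species=species,
                aligned=aligned,
            )
        )
    if not records:
        raise ValueError(f"no records in {path}")
    check_unique_ids(records)
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"aligned FASTA has ragged lengths: {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"species={r.species}" if r.species else "",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta-2line")


def format_newick(tree) -> str:
    """Serialize a :class:`~bzipkit.phylo.PhyloTree` (or Clade) to Newick.

    Branch lengths are printed to 6 decimals; integer bootstrap supports
    become internal-node labels.  Leaf labels containing Newick
    metacharacters raise (no auto-quoting).
    """
    root = getattr(tree, "root", tree)

    def fmt(node, is_root: bool) -> str:
        if not node.children:
            if set(node.name or "") & _NEWICK_META:
                raise ValueError(
                    f"leaf label {node.name!r} contains Newick metacharacters"
                )
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c, False) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        if is_root:
            return f"({inner}){label}"
        return f"({inner}){label}:{node.length:.6f}"

    return fmt(root, True) + ";"


def write_newick(tree, path: PathLike) -> None:
    Path(path).write_text(format_newick(tree) + "\n")


def parse_newick(source: Union[str, PathLike]):
    """Parse Newick text (or a file path) into a :class:`~bzipkit.phylo.PhyloTree`."""
    from skbio import TreeNode

    from .phylo import Clade, PhyloTree

    text = str(source)
    if "(" not in text:  # looks like a path, not newick text
        text = Path(source).read_text()
    sk = TreeNode.read(_io.StringIO(text), format="newick")

    def convert(node) -> Clade:
        children = [convert(c) for c in node.children]
        support = None
        name = node.name
        if children and name is not None:
            # internal labels are bootstrap supports when they parse as numbers
            try:
                support = int(round(float(name)))
                name = None
            except ValueError:
                pass
        return Clade(
            name=name,
            length=float(node.length) if node.length is not None else 0.0,
            support=support,
            children=children,
        )

    return PhyloTree(root=convert(sk))


def read_config(path: PathLike) -> dict[str, str]:
    """Read a plain ``key=value`` config file; '#' starts a comment line."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def log_run(params: dict, manifest: PathLike | None = None) -> None:
    """Log tool version and parameters to stderr and optionally a manifest file."""
    from . import __version__

    lines = [f"bzipkit={__version__}"] + [f"{k}={v}" for k, v in params.items()]
    print("# " + " ".join(lines), file=sys.stderr)
    if manifest is not None:
        Path(manifest).write_text("\n".join(lines) + "\n")
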