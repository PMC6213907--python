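"""Evolutionary distances, neighbor joining, column bootstrap and subfamily
assignment.

Distances are uncorrected p-distances or Poisson-corrected distances
``d = -ln(1 - p)`` (the multiple-hit correction under a Poisson substitution
process with equal rates).  Gap treatment is either complete deletion (drop
any column with a gap) or partial deletion (keep columns present in at least
a site-coverage fraction of rows, then compare pairwise-complete sites).

Tree building is Saitou–Nei neighbor joining with a deterministic tie-break
(label-sort order on the joined pair) and negative branch-length estimates
clamped to zero with the deficit moved to the sister branch.  Bootstrap
supports are column resamples mapped onto the full-data tree's bipartitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import motifs
from .align import Alignment, align_to_profile
from .records import ProteinRecord


@dataclass
class Clade:
    """A tree node; ``length`` is the branch to the parent."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[int] = None
    children: list["Clade"] = field(default_factory=list)

    def leaves(self) -> list["Clade"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())


@dataclass
class PhyloTree:
    """An (unrooted) tree, represented rooted at a basal trifurcation."""

    root: Clade
    n_discarded_replicates: int = 0

    def leaf_names(self) -> frozenset:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the alphabetically smallest leaf."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for node in self._internal_nodes():
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def _internal_nodes(self) -> list[Clade]:
        nodes = []

        def walk(n: Clade, is_root: bool) -> None:
            if n.children and not is_root:
                nodes.append(n)
            for c in n.children:
                walk(c, False)

        walk(self.root, True)
        return nodes


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise evolutionary distances with their model tag."""

    labels: tuple[str, ...]
    d: np.ndarray
    model: str = "p"
    site_coverage: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if np.isnan(d).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(d).any():
            raise ValueError("distance matrix has non-zero diagonal")

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


def _encode_alignment(aln: Alignment) -> np.ndarray:
    """Rows as integer codes; gaps and X both count as missing (-1)."""
    mapping = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
    mapping["X"] = -1
    mapping["-"] = -1
    return np.array(
        [[mapping[c] for c in r.sequence] for r in aln.rows], dtype=np.int8
    )


def _p_matrix(
    mat: np.ndarray, labels: tuple[str, ...], deletion: str, coverage: float
) -> np.ndarray:
    n_rows, n_cols = mat.shape
    present = mat >= 0
    if deletion == "complete":
        keep = present.all(axis=0)
    elif deletion == "partial":
        keep = present.sum(axis=0) / n_rows >= coverage
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    sub = mat[:, keep]
    pres = sub >= 0
    d = np.zeros((n_rows, n_rows))
    for i in range(n_rows):
        for j in range(i + 1, n_rows):
            both = pres[i] & pres[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"pair ({labels[i]!r}, {labels[j]!r}) has no comparable sites"
                )
            diff = int((sub[i, both] != sub[j, both]).sum())
            d[i, j] = d[j, i] = diff / compared
    return d


def p_distance(
    aln: Alignment, deletion: str = "partial", coverage: float = 0.95
) -> DistanceMatrix:
    """Proportion of differing sites per pair under the chosen gap treatment."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    labels = tuple(r.id for r in aln.rows)
    d = _p_matrix(_encode_alignment(aln), labels, deletion, coverage)
    return DistanceMatrix(labels, d, model="p", site_coverage=coverage)


def poisson_correct(D: DistanceMatrix) -> DistanceMatrix:
    """Poisson multiple-hit correction, d' = -ln(1 - p), elementwise."""
    if D.model != "p":
        raise ValueError("poisson_correct expects a p-distance matrix")
    sat = np.argwhere(D.d >= 1 - 1e-12)
    if len(sat):
        i, j = sat[0]
        raise ValueError(
            f"saturated distance for pair ({D.labels[i]!r}, {D.labels[j]!r})"
        )
    return DistanceMatrix(
        D.labels, -np.log1p(-D.d), model="poisson", site_coverage=D.site_coverage
    )


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Repeatedly joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    ties are broken by the sorted pair of each cluster's smallest leaf label.
    Negative branch-length estimates are clamped to 0 with the deficit added
    to the sister branch.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("nj_tree requires at least 3 labels")
    nodes: list[Clade] = [Clade(name=l) for l in D.labels]
    reps: list[str] = list(D.labels)  # smallest leaf label per cluster
    d = D.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = Clade(children=[nodes[i], nodes[j]])
        new_idx = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    # three-point formulas for the final star resolution
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return PhyloTree(root=Clade(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_supports(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    deletion: str = "partial",
    coverage: float = 0.95,
    model: str = "poisson",
) -> PhyloTree:
    """Column bootstrap: resample columns with replacement, rebuild the tree
    each time, and write each full-data bipartition's replicate percentage
    onto the full-data tree.  Replicates with a saturated pair are discarded
    and counted on the returned tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    labels = tuple(r.id for r in aln.rows)
    mat = _encode_alignment(aln)

    def build(columns: np.ndarray) -> PhyloTree:
        d = _p_matrix(columns, labels, deletion, coverage)
        dm = DistanceMatrix(labels, d, model="p", site_coverage=coverage)
        if model == "poisson":
            dm = poisson_correct(dm)
        return nj_tree(dm)

    full = build(mat)
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    discarded = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        try:
            rep = build(mat[:, idx])
        except ValueError:
            discarded += 1
            continue
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    valid = n_reps - discarded
    all_leaves = full.leaf_names()
    ref = min(all_leaves)
    for node in full._internal_nodes():
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if side in counts and valid > 0:
            node.support = round(100 * counts[side] / valid)
    full.n_discarded_replicates = discarded
    return full


@dataclass(frozen=True)
class SubfamilyCall:
    """Nearest-reference subfamily assignment for a query BRLZ sequence."""

    label: str
    margin: float
    nearest_id: str
    nearest_distance: float
    cnc_domain: bool


def assign_subfamily(
    query: ProteinRecord,
    reference: Alignment,
    subfamilies: dict[str, str],
    cnc_max_mismatch: int = 0,
) -> SubfamilyCall:
    """Profile-align a query into a labelled reference alignment and assign
    the subfamily of the nearest reference under Poisson distances.

    ``margin`` is the runner-up subfamily's mean distance minus the assigned
    subfamily's mean distance (larger = better separated).  ``cnc_domain``
    reports whether the query carries a CNC-domain core hit — a Nach/CNC
    assignment is only fully supported when it does.
    """
    if len(set(subfamilies.values())) < 2:
        raise ValueError("reference set must contain at least 2 subfamily labels")
    merged = align_to_profile(reference, query)
    enc = _encode_alignment(merged)
    q = enc[-1]
    dists: dict[str, float] = {}
    for row, rec in zip(enc[:-1], merged.rows[:-1]):
        both = (row >= 0) & (q >= 0)
        if not both.any():
            continue
        p = float((row[both] != q[both]).sum()) / int(both.sum())
        dists[rec.id] = math.inf if p >= 1 - 1e-12 else -math.log1p(-p)
    finite = {k: v for k, v in dists.items() if math.isfinite(v)}
    if not finite:
        raise ValueError(f"query {query.id!r} is unclassifiable: saturated to every reference")
    nearest_id = min(finite, key=lambda k: (finite[k], k))
    label = subfamilies[nearest_id]
    means: dict[str, float] = {}
    for fam in set(subfamilies.values()):
        vals = [v for k, v in finite.items() if subfamilies[k] == fam]
        if vals:
            means[fam] = sum(vals) / len(vals)
    others = sorted(v for f, v in means.items() if f != label)
    margin = (others[0] - means[label]) if others else math.inf
    cnc_hits = motifs.scan(query, motifs.CNC_CORE, cnc_max_mismatch)
    return SubfamilyCall(
        label=label,
        margin=margin,
        nearest_id=nearest_id,
        nearest_distance=finite[nearest_id],
        cnc_domain=bool(cnc_hits),
    )
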