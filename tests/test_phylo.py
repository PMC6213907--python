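import math

import numpy as np
import pytest

from bzipkit import align, io, phylo, synthetic
from bzipkit.records import ProteinRecord

ADDITIVE_4TAXON = np.array(
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
)


def _aln(*id_seq_pairs):
    return align.Alignment(
        rows=tuple(ProteinRecord(i, s, aligned=True) for i, s in id_seq_pairs)
    )


class TestPDistance:
    def test_direct_count(self):
        dm = phylo.p_distance(_aln(("a", "MKV"), ("b", "MKV"), ("c", "MKL")))
        assert dm.pair("a", "b") == 0
        assert dm.pair("a", "c") == pytest.approx(1 / 3)
        assert dm.pair("b", "c") == pytest.approx(1 / 3)

    def test_complete_deletion_drops_gapped_column(self):
        dm = phylo.p_distance(
            _aln(("a", "MK-"), ("b", "MKV"), ("c", "MKL")), deletion="complete"
        )
        # column 3 dropped for every pair, so all distances are 0 over "MK"
        assert dm.d.max() == 0

    def test_partial_deletion_keeps_covered_columns(self):
        # last column present in 3/4 rows: kept at coverage 0.75, dropped at 0.95
        rows = (("a", "MKV"), ("b", "MKV"), ("c", "MKL"), ("d", "MK-"))
        kept = phylo.p_distance(_aln(*rows), deletion="partial", coverage=0.75)
        assert kept.pair("a", "c") == pytest.approx(1 / 3)
        dropped = phylo.p_distance(_aln(*rows), deletion="partial", coverage=0.95)
        assert dropped.pair("a", "c") == 0

    def test_matrix_equals_brute_force_recount(self, rng):
        letters = list("ACDEFGHIKL-")
        rows = [
            (f"s{i}", "".join(rng.choice(letters, size=60))) for i in range(10)
        ]
        dm = phylo.p_distance(_aln(*rows), deletion="partial", coverage=0.5)
        n_rows = len(rows)
        keep = [
            j
            for j in range(60)
            if sum(rows[i][1][j] != "-" for i in range(n_rows)) / n_rows >= 0.5
        ]
        for i in range(n_rows):
            for j in range(i + 1, n_rows):
                a, b = rows[i][1], rows[j][1]
                cols = [k for k in keep if a[k] != "-" and b[k] != "-"]
                expect = sum(a[k] != b[k] for k in cols) / len(cols)
                assert dm.d[i, j] == pytest.approx(expect)

    def test_no_comparable_sites_names_pair(self):
        with pytest.raises(ValueError, match="'a'.*'b'"):
            phylo.p_distance(
                _aln(("a", "MK--"), ("b", "--VL"), ("c", "MKVL")),
                deletion="partial",
                coverage=0.5,
            )

    def test_symmetry_by_construction(self, rng):
        letters = list("ACDEFG-")
        rows = [(f"s{i}", "".join(rng.choice(letters, size=40))) for i in range(6)]
        dm = phylo.p_distance(_aln(*rows), coverage=0.5)
        assert (dm.d == dm.d.T).all()


class TestPoissonCorrect:
    def test_closed_forms(self):
        d = np.array([[0, 0.5], [0.5, 0]])
        dm = phylo.poisson_correct(phylo.DistanceMatrix(("a", "b"), d))
        assert dm.pair("a", "b") == pytest.approx(0.693147, abs=1e-6)
        zero = phylo.poisson_correct(
            phylo.DistanceMatrix(("a", "b"), np.zeros((2, 2)))
        )
        assert zero.d.max() == 0

    def test_correction_dominates_p_on_grid(self):
        p = np.linspace(0, 0.95, 50)
        assert (-np.log1p(-p) >= p).all()

    def test_saturation_errors_naming_pair(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError, match="saturated"):
            phylo.poisson_correct(phylo.DistanceMatrix(("a", "b"), d))

    def test_model_tag_required(self):
        dm = phylo.DistanceMatrix(("a", "b"), np.zeros((2, 2)), model="poisson")
        with pytest.raises(ValueError):
            phylo.poisson_correct(dm)


class TestNJ:
    def test_additive_four_taxon_recovers_tree_exactly(self):
        """The additive matrix of ((A:1,B:2):1,(C:3,D:4)) must come back with
        topology AB|CD and exact branch lengths."""
        tree = phylo.nj_tree(phylo.DistanceMatrix(("A", "B", "C", "D"), ADDITIVE_4TAXON))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4}, abs=1e-9)
        internal = [n for n in tree.root.children if n.children]
        assert internal[0].length == pytest.approx(1, abs=1e-9)

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        sk_tree = sk_nj(SkDM(ADDITIVE_4TAXON, ids=["A", "B", "C", "D"]))
        ours = phylo.nj_tree(phylo.DistanceMatrix(("A", "B", "C", "D"), ADDITIVE_4TAXON))
        # canonical unrooted bipartitions from the scikit-bio tree
        tips = frozenset("ABCD")
        sk_bips = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if "A" in side:
                side = tips - side
            if 2 <= len(side) <= len(tips) - 2:
                sk_bips.add(side)
        assert ours.bipartitions() == sk_bips == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(("a", "b", "c"), d))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"a": 1, "b": 3, "c": 5}, abs=1e-9)

    def test_ultrametric_eight_taxon_topology_recovered(self):
        """Patristic distances from a balanced clock tree reproduce its
        topology."""
        tree = io.parse_newick(synthetic.balanced_tree_newick(3, 1.0))
        leaves = sorted(tree.leaf_names())
        # path lengths from the true tree
        def depth_map(node, acc, out):
            for c in node.children:
                if c.children:
                    depth_map(c, acc + [c], out)
                else:
                    out[c.name] = acc + [c]
            return out

        paths = depth_map(tree.root, [], {})
        d = np.zeros((8, 8))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    pa, pb = paths[a], paths[b]
                    shared = sum(1 for x, y in zip(pa, pb) if x is y)
                    dist = sum(n.length for n in pa[shared:]) + sum(
                        n.length for n in pb[shared:]
                    )
                    d[i, j] = d[j, i] = dist
        recovered = phylo.nj_tree(phylo.DistanceMatrix(tuple(leaves), d))
        assert recovered.bipartitions() == tree.bipartitions()

    def test_invalid_matrices_rejected(self):
        bad = ADDITIVE_4TAXON.copy()
        bad[0, 1] = 99
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(("A", "B", "C", "D"), bad)
        nan = ADDITIVE_4TAXON.copy()
        nan[0, 1] = nan[1, 0] = np.nan
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(("A", "B", "C", "D"), nan)


class TestBootstrap:
    def _family(self, seed=4):
        root = ProteinRecord("root", "ACDEFGHIKLMNPQRSTVWY" * 25)
        nwk = (
            "((a1:0.01,a2:0.01):0.3,(b1:0.01,b2:0.01):0.3,"
            "((c1:0.01,c2:0.01):0.3,(d1:0.01,d2:0.01):0.3):0.3);"
        )
        records, aln, _ = synthetic.evolve_on_tree(nwk, root, seed=seed)
        return aln

    def test_distinct_clades_have_high_support(self):
        aln = self._family()
        tree = phylo.bootstrap_supports(aln, n_reps=100, seed=7)
        supports = [n.support for n in tree._internal_nodes() if n.support is not None]
        assert supports and all(s >= 95 for s in supports)

    def test_duplicated_pair_has_support_100(self):
        rows = [
            ("x1", "ACDEFGHIKL" * 10),
            ("x2", "ACDEFGHIKL" * 10),  # exact duplicate of x1
            ("y", "MKVLWYPQRS" * 10),
            ("z", "GGHHNNDDEE" * 10),
        ]
        tree = phylo.bootstrap_supports(_aln(*rows), n_reps=50, seed=3, model="p")
        cherry = [
            n
            for n in tree._internal_nodes()
            if n.leaf_names() in ({"x1", "x2"}, {"y", "z"})
        ]
        assert cherry and all(n.support == 100 for n in cherry)

    def test_bitwise_reproducible_for_same_seed(self):
        aln = self._family()
        t1 = phylo.bootstrap_supports(aln, n_reps=60, seed=11)
        t2 = phylo.bootstrap_supports(aln, n_reps=60, seed=11)
        assert io.format_newick(t1) == io.format_newick(t2)

    def test_nreps_validation(self):
        with pytest.raises(ValueError):
            phylo.bootstrap_supports(self._family(), n_reps=0, seed=1)


class TestParameterRecovery:
    def test_poisson_pipeline_recovers_known_topology(self):
        """Forward Poisson simulation on an 8-leaf clock tree, then
        p-distance + Poisson correction + NJ, recovers the true topology in
        >= 95% of seeded runs (1000 sites, t = 0.05 per branch)."""
        nwk = synthetic.balanced_tree_newick(3, 0.05)
        true_tree = io.parse_newick(nwk)
        true_bips = true_tree.bipartitions()
        root = ProteinRecord("root", "ACDEFGHIKLMNPQRSTVWY" * 50)
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            _, aln, _ = synthetic.evolve_on_tree(nwk, root, seed=seed)
            dm = phylo.poisson_correct(phylo.p_distance(aln))
            if phylo.nj_tree(dm).bipartitions() == true_bips:
                wins += 1
        assert wins / n_runs >= 0.95


class TestAssignSubfamily:
    def _reference(self):
        rng = np.random.default_rng(99)
        base_jun = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=64))
        base_cnc = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=64))

        def mutate(seq, k):
            s = list(seq)
            for i in rng.choice(len(s), size=k, replace=False):
                s[i] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
            return "".join(s)

        rows = [
            ("jun1", base_jun),
            ("jun2", mutate(base_jun, 4)),
            ("cnc1", base_cnc),
            ("cnc2", mutate(base_cnc, 4)),
        ]
        aln = _aln(*rows)
        labels = {"jun1": "Jun", "jun2": "Jun", "cnc1": "CNC", "cnc2": "CNC"}
        return aln, labels, base_jun

    def test_identical_query_gets_zero_distance(self):
        aln, labels, base_jun = self._reference()
        call = phylo.assign_subfamily(ProteinRecord("q", base_jun), aln, labels)
        assert call.label == "Jun"
        assert call.nearest_distance == 0
        assert call.margin > 0

    def test_mutated_queries_recover_their_subfamily(self):
        aln, labels, base_jun = self._reference()
        rng = np.random.default_rng(123)
        wins = 0
        for t in range(20):
            s = list(base_jun)
            for i in np.nonzero(rng.random(len(s)) < 0.05)[0]:
                s[i] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
            call = phylo.assign_subfamily(ProteinRecord(f"q{t}", "".join(s)), aln, labels)
            wins += call.label == "Jun"
        assert wins >= 19

    def test_cnc_domain_flag_reported_without_override(self):
        """A query carrying a CNC-domain core still gets the nearest label,
        with the CNC evidence reported as a separate flag."""
        aln, labels, base_jun = self._reference()
        from bzipkit.motifs import CNC_CORE

        rng = np.random.default_rng(5)
        cnc_seq = "".join(str(rng.choice(sorted(cls))) for cls in CNC_CORE.positions)
        query = ProteinRecord("q", cnc_seq + base_jun)
        call = phylo.assign_subfamily(query, aln, labels)
        assert call.cnc_domain is True
        assert call.label == "Jun"

    def test_single_label_reference_rejected(self):
        aln, labels, base_jun = self._reference()
        with pytest.raises(ValueError):
            phylo.assign_subfamily(
                ProteinRecord("q", base_jun), aln, {k: "Jun" for k in labels}
            )
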