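"""Reference curation: coverage filter, distances, NJ tree, anchors, merging."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode

from butyragene import refdb
from butyragene.refdb import (
    ReferenceProtein,
    TooFewTaxaError,
    UndefinedDistanceError,
    UnresolvablePartitionError,
)


def ref(id="r1", seq="ACDEFGHIKL" * 10, first=1, last=100, length=100, **kw):
    return ReferenceProtein(id=id, gene_family="but", sequence=seq,
                            model_first=first, model_last=last,
                            model_length=length, **kw)


class TestModelCoverage:
    @pytest.mark.parametrize(
        "first,last,length,expected",
        [(1, 100, 100, 0.99), (4, 96, 100, 0.92), (50, 50, 100, 0.0)],
    )
    def test_formula(self, first, last, length, expected):
        assert refdb.model_coverage(ref(first=first, last=last, length=length)) == pytest.approx(expected)

    @given(first=st.integers(1, 50), span=st.integers(0, 50), k=st.integers(1, 9))
    @settings(max_examples=50, derandomize=True)
    def test_scale_free(self, first, span, k):
        length = 120
        a = ref(first=first, last=first + span, length=length)
        b = ref(first=first * k, last=(first + span) * k, length=length * k)
        assert refdb.model_coverage(a) == pytest.approx(refdb.model_coverage(b))


class TestFilterFullLength:
    def test_threshold_and_order(self):
        refs = [ref("a", first=1, last=96, length=100),   # 0.95
                ref("b", first=1, last=91, length=100)]   # 0.90
        assert [r.id for r in refdb.filter_full_length(refs)] == ["a"]

    def test_boundary_inclusive(self):
        exactly = ref("edge", first=4, last=97, length=100)  # coverage 0.93
        assert refdb.model_coverage(exactly) == pytest.approx(0.93)
        assert refdb.filter_full_length([exactly]) == [exactly]

    def test_full_span_identity(self):
        refs = [ref("a"), ref("b")]
        assert refdb.filter_full_length(refs) == refs


class TestProteinDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACDEF", "ACDEF", 0.0),
         ("ACDEF", "ACDEY", 0.2),
         ("AC-EF", "ACDEF", 0.0),            # gapped column ignored
         ("A" * 49 + "C" + "", "A" * 49 + "D", 0.02)],
    )
    def test_values(self, a, b, expected):
        assert refdb.protein_distance(a, b) == pytest.approx(expected)

    def test_no_overlap_errors(self):
        with pytest.raises(UndefinedDistanceError):
            refdb.protein_distance("AC--", "--DE")


def _random_additive_tree(rng, n):
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n)]
    while len(nodes) > 3:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        nodes.append(TreeNode(length=float(rng.uniform(0.05, 1.0)), children=[a, b]))
    return TreeNode(children=nodes)


def _bipartitions(tree):
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips(include_self=True))
        if 1 < len(side) < len(leaves) - 1:
            parts.add(min(side, leaves - side, key=sorted))
    return parts


class TestNJTree:
    def test_three_point_exact(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                            ["A", "B", "C"])
        tree = refdb.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_too_few_taxa(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["A", "B"])
        with pytest.raises(TooFewTaxaError):
            refdb.nj_tree(dm)

    def test_identical_rows_zero_cherry(self):
        m = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float)
        tree = refdb.nj_tree(DistanceMatrix(m, list("ABCD")))
        d = tree.tip_tip_distances(endpoints=["A", "B"])
        assert d["A", "B"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_additive_recovery(self, seed):
        """Path lengths of the NJ tree reproduce any additive matrix."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        true = _random_additive_tree(rng, n)
        tipd = true.tip_tip_distances()
        rec = refdb.nj_tree(DistanceMatrix(tipd.data, list(tipd.ids)))
        rd = rec.tip_tip_distances(endpoints=list(tipd.ids))
        assert np.abs(rd.data - tipd.data).max() < 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_skbio_on_additive_input(self, seed):
        """Independent cross-check: same bipartitions as scikit-bio's NJ."""
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(100 + seed)
        true = _random_additive_tree(rng, 8)
        tipd = true.tip_tip_distances()
        dm = DistanceMatrix(tipd.data, list(tipd.ids))
        assert _bipartitions(refdb.nj_tree(dm)) == _bipartitions(skbio_nj(dm))


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


class TestPartitionByAnchors:
    def test_perfect_separation(self):
        cur = refdb.partition_by_anchors(_tree("((P1,P2),(N1,N2));"),
                                         ["P1", "P2"], ["N1", "N2"])
        assert set(cur.kept) == {"P1", "P2"}
        assert set(cur.excluded) == {"N1", "N2"}

    def test_unlabeled_leaf_joins_positive_side(self):
        cur = refdb.partition_by_anchors(_tree("((P1,(P2,U)),(N1,N2));"),
                                         ["P1", "P2"], ["N1", "N2"])
        assert "U" in cur.kept

    def test_interleaved_anchors_unresolvable(self):
        with pytest.raises(UnresolvablePartitionError):
            refdb.partition_by_anchors(_tree("((((P1,N1),P2),N2),X);"),
                                       ["P1", "P2"], ["N1", "N2"])

    def test_rerooting_invariance(self):
        base = _tree("(((P1,P2),(U1,U2)),(N1,(N2,U3)));")
        expected = refdb.partition_by_anchors(base, ["P1", "P2"], ["N1", "N2"])
        for target in ("U1", "N2", "P1"):
            tree = base.copy()
            node = next(t for t in tree.tips() if t.name == target).parent
            got = refdb.partition_by_anchors(tree.root_at(node),
                                             ["P1", "P2"], ["N1", "N2"])
            assert set(got.kept) == set(expected.kept)


class TestMergeSimilar:
    def _dm(self, ids, pairs):
        n = len(ids)
        m = np.zeros((n, n))
        for (a, b), v in pairs.items():
            i, j = ids.index(a), ids.index(b)
            m[i, j] = m[j, i] = v
        return DistanceMatrix(m, ids)

    def test_simple_pair(self):
        dm = self._dm(list("ABC"), {("A", "B"): 0.01, ("A", "C"): 0.5, ("B", "C"): 0.5})
        groups = refdb.merge_similar(list("ABC"), dm)
        assert groups == {"A": ("A", "B"), "C": ("C",)}

    def test_single_linkage_chain(self):
        dm = self._dm(list("ABC"), {("A", "B"): 0.015, ("B", "C"): 0.015, ("A", "C"): 0.03})
        groups = refdb.merge_similar(list("ABC"), dm)
        assert groups == {"A": ("A", "B", "C")}

    def test_all_distant_all_singletons(self):
        dm = self._dm(list("ABC"), {("A", "B"): 0.02, ("A", "C"): 0.4, ("B", "C"): 0.4})
        groups = refdb.merge_similar(list("ABC"), dm)
        assert set(groups) == {"A", "B", "C"}  # 0.02 is NOT < 0.02

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_property_under_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        ids = [f"r{i}" for i in range(n)]
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0, 0.05, size=len(iu[0]))
        m[iu] = vals
        m += m.T
        dm = DistanceMatrix(m, ids)
        groups = refdb.merge_similar(ids, dm)
        members = [x for g in groups.values() for x in g]
        assert sorted(members) == sorted(ids)  # disjoint and covering
        perm = list(rng.permutation(ids))
        assert refdb.merge_similar(perm, dm) == groups


class TestCurate:
    def test_anchors_kept_and_decoys_excluded(self, but_curation, but_family):
        cur = but_curation.curated
        assert set(but_family.positive_anchors) <= set(cur.kept)
        assert set(but_family.decoy_ids) <= set(cur.excluded)

    def test_merge_groups_cover_kept(self, but_curation):
        cur = but_curation.curated
        members = sorted(x for g in cur.merge_groups.values() for x in g)
        assert members == sorted(cur.kept)

    def test_near_duplicate_merged(self, but_curation):
        cur = but_curation.curated
        assert any(len(g) > 1 for g in cur.merge_groups.values())

    def test_report_reason_codes(self, but_curation):
        reasons = set(but_curation.report["reason"])
        assert "coverage_below_cutoff" in reasons
        assert "outside_anchor_cluster" in reasons


class TestAlignReferences:
    def test_same_length_passthrough(self):
        seqs = {"a": "ACDEF", "b": "ACDEY"}
        assert refdb.align_references(seqs) == seqs

    def test_indel_produces_common_coordinates(self):
        seqs = {"long": "ACDEFGHIKLMNPQRSTVWY", "short": "ACDEFGHIKMNPQRSTVWY"}
        aligned = refdb.align_references(seqs)
        assert len(set(map(len, aligned.values()))) == 1
        assert aligned["short"].count("-") == 1
        # distance over shared columns is small (one residue deleted)
        assert refdb.protein_distance(aligned["long"], aligned["short"]) == pytest.approx(0.0)
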