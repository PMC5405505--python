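"""Bruvo/Jaccard distances, neighbor joining and locus-bootstrap support."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apricot_gsi.distances import (
    DistanceMatrix,
    NoSharedDataError,
    bootstrap_support,
    bruvo_distance,
    distance_matrix,
    jaccard_distance,
    neighbor_joining,
    tree_splits,
)
from apricot_gsi.germplasm import SSRMarker
from apricot_gsi.m_haplotypes import MHaplotype

PANEL = [SSRMarker(f"m{i}", 2) for i in range(7)]
BASE = (100.0, 120.0, 140.0, 160.0, 180.0, 200.0, 220.0)


def hap(label, alleles):
    return MHaplotype(label, tuple(alleles))


class TestBruvo:
    def test_identity_is_zero(self):
        a = hap("a", BASE)
        assert bruvo_distance(a, a, PANEL) == 0.0

    def test_single_repeat_step_closed_form(self):
        a = hap("a", BASE)
        b = hap("b", (102.0,) + BASE[1:])
        assert bruvo_distance(a, b, PANEL) == pytest.approx((1 - 2**-1) / 7)

    def test_monotone_and_saturating_in_repeat_difference(self):
        a = hap("a", BASE)
        prev = 0.0
        for k in range(1, 12):
            b = hap("b", (100.0 + 2 * k,) + BASE[1:])
            d = bruvo_distance(a, b, PANEL)
            assert d > prev
            assert d <= 1.0 / 7 + 1e-12
            prev = d
        assert prev == pytest.approx(1.0 / 7, abs=1e-3)  # saturates toward 1 per locus

    def test_non_integral_offset_rounds_with_warning(self):
        a = hap("a", BASE)
        b = hap("b", (103.0,) + BASE[1:])  # 1.5 repeat units
        with pytest.warns(UserWarning, match="nearest repeat"):
            d = bruvo_distance(a, b, PANEL)
        assert d == pytest.approx((1 - 2**-2) / 7)

    def test_missing_loci_averaged_over_shared(self):
        a = hap("a", (100.0, None) + BASE[2:])
        b = hap("b", (102.0, 122.0) + BASE[2:])
        assert bruvo_distance(a, b, PANEL) == pytest.approx(0.5 / 6)

    def test_no_shared_loci_is_no_data(self):
        a = hap("a", (100.0,) + (None,) * 6)
        b = hap("b", (None, 120.0) + (None,) * 5)
        with pytest.raises(NoSharedDataError):
            bruvo_distance(a, b, PANEL)

    def test_synthetic_reference_ordering_near_m0(self, haplotype_table, marker_panel):
        """m0-0's nearest neighbours among the M1 subtypes order as
        M1-2 < M1-1 < M1-0, the structure reported for the real panel."""
        by = {h.label: h for h in haplotype_table}
        d = [
            bruvo_distance(by["m0-0"], by[lab], marker_panel)
            for lab in ("M1-2", "M1-1", "M1-0")
        ]
        assert d[0] < d[1] < d[2]

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(0, 30), min_size=7, max_size=7),
        st.lists(st.integers(0, 30), min_size=7, max_size=7),
    )
    def test_metric_properties(self, ra, rb):
        a = hap("a", tuple(100.0 + 2 * r for r in ra))
        b = hap("b", tuple(100.0 + 2 * r for r in rb))
        dab = bruvo_distance(a, b, PANEL)
        dba = bruvo_distance(b, a, PANEL)
        assert dab == dba
        assert 0.0 <= dab < 1.0
        if ra == rb:
            assert dab == 0.0


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = hap("a", BASE)
        b = hap("b", tuple(x + 2 for x in BASE))
        assert jaccard_distance(a, a, PANEL) == 0.0
        assert jaccard_distance(a, b, PANEL) == 1.0

    def test_partial_overlap_closed_form(self):
        # share alleles at 3 of 7 loci: |A∩B| = 3, |A∪B| = 3 + 4 + 4 = 11
        a = hap("a", BASE)
        b = hap("b", BASE[:3] + tuple(x + 2 for x in BASE[3:]))
        assert jaccard_distance(a, b, PANEL) == pytest.approx(1 - 3 / 11)

    def test_empty_profiles_are_no_data(self):
        a = hap("a", (None,) * 7)
        with pytest.raises(NoSharedDataError):
            jaccard_distance(a, a, PANEL)


class TestDistanceMatrix:
    def test_validation_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_matrix_from_haplotypes_is_valid(self, haplotype_table, marker_panel):
        dm = distance_matrix(haplotype_table[:10], marker_panel, "bruvo")
        assert dm.values.shape == (10, 10)
        assert np.all(dm.values >= 0) and np.all(dm.values <= 1)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # branch lengths a=1, b=2, c=3 -> D = [[0,3,4],[3,0,5],[4,5,0]]
        dm = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        )
        tree = neighbor_joining(dm)
        dist = _leaf_path_lengths(tree)
        assert dist[("a", "b")] == pytest.approx(3)
        assert dist[("a", "c")] == pytest.approx(4)
        assert dist[("b", "c")] == pytest.approx(5)

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives an additive matrix
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(list("ABCD"), D)
        tree = neighbor_joining(dm)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        dist = _leaf_path_lengths(tree)
        for (i, j), expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert dist[(i, j)] == pytest.approx(expected)

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        n = 7
        coords = rng.random((n, 4))
        D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(labels, D)
        ours = neighbor_joining(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, labels))
        their_splits = set()
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n - 1:
                all_l = frozenset(labels)
                side = below if "t0" not in below else all_l - below
                their_splits.add(side)
        assert tree_splits(ours) == their_splits

    def test_divergent_classes_form_separate_clades(self, marker_panel):
        # two ancestor groups far apart; members one mutation step inside
        group_a = [hap(f"a{k}", (100.0 + 2 * k,) + BASE[1:]) for k in range(3)]
        group_b = [
            hap(f"b{k}", (140.0 + 2 * k,) + tuple(x + 20 for x in BASE[1:]))
            for k in range(3)
        ]
        dm = distance_matrix(group_a + group_b, marker_panel, "bruvo")
        splits = tree_splits(neighbor_joining(dm))
        assert frozenset({"b0", "b1", "b2"}) in splits

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 6
            # noisy, possibly non-additive matrices
            M = rng.random((n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = neighbor_joining(DistanceMatrix([f"x{i}" for i in range(n)], D))
            stack = [tree]
            while stack:
                node = stack.pop()
                assert node.length >= 0.0
                stack.extend(node.children)


class TestBootstrap:
    def test_zero_replicates_rejected(self, haplotype_table, marker_panel):
        with pytest.raises(ValueError):
            bootstrap_support(
                haplotype_table[:5], marker_panel, n_replicates=0, seed=1
            )

    def test_fixed_seed_reproducible(self, haplotype_table, marker_panel):
        runs = [
            bootstrap_support(
                haplotype_table[:8], marker_panel, n_replicates=100, seed=7
            )[1]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_concordant_loci_give_full_support(self, marker_panel):
        # identical information at all 7 loci: resampling cannot change ranks
        haps = [
            hap(lab, tuple(100.0 + off + 20 * l for l in range(7)))
            for lab, off in [("a", 0), ("b", 2), ("c", 20), ("d", 22)]
        ]
        _, support = bootstrap_support(
            haps, marker_panel, n_replicates=50, seed=3
        )
        assert support
        assert all(v == 1.0 for v in support.values())

    def test_well_separated_classes_strongly_supported(self, marker_panel):
        group_a = [hap(f"a{k}", (100.0 + 2 * k,) + BASE[1:]) for k in range(3)]
        group_b = [
            hap(f"b{k}", (160.0 + 2 * k,) + tuple(x + 30 for x in BASE[1:]))
            for k in range(3)
        ]
        _, support = bootstrap_support(
            group_a + group_b, marker_panel, n_replicates=100, seed=5
        )
        key = frozenset({"b0", "b1", "b2"})
        assert support.get(key, 0.0) >= 0.95


def _leaf_path_lengths(tree):
    """Pairwise leaf-to-leaf path lengths of a tree (brute-force oracle)."""
    import networkx as nx

    g = nx.Graph()
    counter = itertools.count()

    def walk(node):
        me = node.label if node.is_leaf else f"__{next(counter)}"
        for c in node.children:
            child = walk(c)
            g.add_edge(me, child[0], weight=child[1])
        return me, node.length

    root, _ = walk(tree)
    leaves = tree.leaves()
    out = {}
    for a, b in itertools.combinations(sorted(leaves), 2):
        out[(a, b)] = nx.shortest_path_length(g, a, b, weight="weight")
    return out
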