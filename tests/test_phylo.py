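"""Cys-anchored alignment, p-distances, NJ reconstruction, bootstrap."""

import dendropy
import numpy as np
import pytest

from cyclomine import Alignment, bootstrap, cys_anchor_align, nj_tree, p_distance
from cyclomine.annotate import CyclotideDomain
from cyclomine.phylo import read_newick

from .oracles import random_additive_matrix


def make_domain(i, pre, loops, tail):
    seq = pre + "C" + "C".join(loops) + "C" + tail
    cys = tuple(k for k, ch in enumerate(seq) if ch == "C")
    return CyclotideDomain(id=f"d{i}", seq=seq, cys_positions=cys, loops=(),
                           cyclization_residue=None)


def test_identical_domains_align_without_gaps():
    doms = [make_domain(i, "GL", ["GET", "VGGT", "STPG", "T", "SWPV"], "TRN")
            for i in range(2)]
    aln = cys_anchor_align(doms)
    assert "-" not in aln.rows[0] and aln.rows[0] == aln.rows[1]


def test_shorter_loop_padded_with_gaps():
    a = make_domain(0, "G", ["GET", "VGGT", "STP", "T", "SWPV"], "TRN")
    b = make_domain(1, "G", ["GET", "VGGT", "TVTAL", "T", "SWPV"], "TRN")
    aln = cys_anchor_align([a, b])
    assert aln.rows[0].count("-") == 2 and aln.rows[1].count("-") == 0


def test_ungapping_recovers_input(rng):
    alpha = "GAVLISTEKRQ"
    doms = []
    for i in range(6):
        loops = ["".join(alpha[j] for j in rng.integers(0, len(alpha), rng.integers(1, 7)))
                 for _ in range(5)]
        pre = "".join(alpha[j] for j in rng.integers(0, len(alpha), rng.integers(0, 4)))
        tail = "".join(alpha[j] for j in rng.integers(0, len(alpha), rng.integers(1, 5)))
        doms.append(make_domain(i, pre, loops, tail))
    aln = cys_anchor_align(doms)
    for i, d in enumerate(doms):
        assert aln.ungapped(i) == d.seq


def test_non_six_cys_domains_excluded():
    good = make_domain(0, "G", ["GET", "VGGT", "STP", "T", "SWPV"], "TRN")
    bad = CyclotideDomain(id="bad", seq="CACAC", cys_positions=(0, 2, 4), loops=())
    aln = cys_anchor_align([good, bad])
    assert aln.ids == ["d0"]


def test_p_distance_extremes():
    aln = Alignment(ids=["a", "b", "c"],
                    rows=["AAAA", "AAAA", "GGGG"])
    d = p_distance(aln)
    assert d[0, 1] == 0.0 and d[0, 2] == 1.0
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def test_p_distance_pairwise_deletion_oracle(rng):
    chars = "ACDG-"
    rows = ["".join(chars[i] for i in rng.integers(0, 5, 30)) for _ in range(5)]
    aln = Alignment(ids=[f"s{i}" for i in range(5)], rows=rows)
    d = p_distance(aln)
    for i in range(5):
        for j in range(5):
            pairs = [(x, y) for x, y in zip(rows[i], rows[j]) if "-" not in (x, y)]
            expect = (sum(x != y for x, y in pairs) / len(pairs)) if pairs else 0.0
            assert d[i, j] == pytest.approx(expect)


def test_three_taxon_closed_form():
    D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(D, ["a", "b", "c"])
    lengths = {child.name: bl for child, bl in tree.root.children}
    assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


def test_four_taxon_additive_topology_and_lengths():
    # ((A,B),(C,D)) with internal branch 0.4
    D = np.array([
        [0.0, 0.3, 1.0, 1.1],
        [0.3, 0.0, 1.1, 1.2],
        [1.0, 1.1, 0.0, 0.5],
        [1.1, 1.2, 0.5, 0.0],
    ])
    ids = ["A", "B", "C", "D"]
    # four-point condition oracle: AB|CD is the valid split
    assert D[0, 1] + D[2, 3] < D[0, 2] + D[1, 3]
    tree = nj_tree(D, ids)
    assert frozenset(["A", "B"]) in set(tree.bipartitions()) or \
        frozenset(["C", "D"]) in set(tree.bipartitions())
    D2, ids2 = tree.distance_matrix()
    order = [ids2.index(x) for x in ids]
    assert np.allclose(D, D2[np.ix_(order, order)], atol=1e-12)


def test_additive_matrices_reconstructed_exactly(rng):
    for _ in range(20):
        n = int(rng.integers(4, 9))
        D = random_additive_matrix(n, rng)
        ids = [f"t{i}" for i in range(n)]
        tree = nj_tree(D, ids)
        D2, ids2 = tree.distance_matrix()
        order = [ids2.index(x) for x in ids]
        assert np.allclose(D, D2[np.ix_(order, order)], atol=1e-8)


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])


def test_newick_round_trip_preserves_structure():
    rng = np.random.default_rng(8)
    D = random_additive_matrix(6, rng)
    ids = [f"t{i}" for i in range(6)]
    tree = nj_tree(D, ids)
    parsed = read_newick(tree.newick())
    assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(ids)
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    D2, ids2 = tree.distance_matrix()
    for i, a in enumerate(ids2):
        for j, b in enumerate(ids2):
            if i < j:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D2[i, j], abs=1e-9)


def test_bootstrap_deterministic_and_supported():
    rows = ["AAAAAAAAAA" + "GGGGGGGGGG",
            "AAAAAAAAAA" + "GGGGGGGGGT",
            "AAAAAAAAAT" + "GGGGGGGGGG",
            "TTTTTTTTTT" + "CCCCCCCCCC",
            "TTTTTTTTTT" + "CCCCCCCCCA",
            "TTTTTTTTTA" + "CCCCCCCCCC"]
    aln = Alignment(ids=list("abcdef"), rows=rows)
    t1 = bootstrap(aln, n_reps=100, seed=3)
    t2 = bootstrap(aln, n_reps=100, seed=3)
    assert t1.newick() == t2.newick()

    def supports(node, acc):
        for child, _bl in node.children:
            if not child.is_leaf:
                acc.append((frozenset(child.leaves()), child.support))
                supports(child, acc)
        return acc

    sups = dict(supports(t1.root, []))
    clade = frozenset("abc") if frozenset("abc") in sups else frozenset("def")
    assert sups[clade] >= 95.0


def test_identical_sequences_degenerate_bootstrap():
    aln = Alignment(ids=["a", "b", "c", "d"], rows=["AAAA"] * 4)
    t = bootstrap(aln, n_reps=10, seed=1)
    assert set(t.root.leaves()) == {"a", "b", "c", "d"}
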