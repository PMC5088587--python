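"""Distances, Neighbor-Joining, bootstrap supports and clade labeling.

NJ is cross-checked against scikit-bio's independent implementation and
against exact additivity (path distances of the recovered tree must equal
the input matrix).
"""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from tifykit import phylogeny as ph
from tifykit.phylogeny import DistanceMatrix, MultipleAlignment


def random_additive_tree(n_taxa, rng):
    """A random binary tree with positive branch lengths, built by
    sequential leaf attachment (independent of the NJ code under test)."""
    names = [f"t{i}" for i in range(n_taxa)]
    tree = TreeNode.read(
        [f"({names[0]}:{rng.uniform(0.1, 2.0):.6f},{names[1]}:{rng.uniform(0.1, 2.0):.6f});"]
    )
    for name in names[2:]:
        edges = list(tree.traverse(include_self=False))
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        split = TreeNode(length=target.length / 2)
        target.length /= 2
        parent.remove(target)
        split.append(target)
        split.append(TreeNode(name=name, length=float(rng.uniform(0.1, 2.0))))
        parent.append(split)
    return tree


def tree_distance_matrix(tree):
    dm = tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), dm.data)


# ---------------------------------------------------------------------------
# distances


def test_identical_rows_zero_distance():
    msa = MultipleAlignment(["a", "b"], ["MKTW", "MKTW"])
    dm = ph.pairwise_distance(msa)
    assert dm.d[0, 1] == 0.0


def test_p_distance_direct_count():
    msa = MultipleAlignment(["a", "b"], ["AAAA", "AAAT"], "dna")
    dm = ph.pairwise_distance(msa, "p_distance")
    assert dm.d[0, 1] == pytest.approx(0.25)


def test_pairwise_deletion_of_gap_columns():
    msa = MultipleAlignment(["a", "b"], ["A-AT", "AGAA"], "dna")
    dm = ph.pairwise_distance(msa)
    # 3 comparable columns, 1 mismatch
    assert dm.d[0, 1] == pytest.approx(1 / 3)


def test_no_comparable_columns_names_pair():
    msa = MultipleAlignment(["a", "b", "c"], ["A--", "-G-", "AGT"], "dna")
    with pytest.raises(ValueError, match=r"\(a, b\)"):
        ph.pairwise_distance(msa)


def test_poisson_correction_and_saturation():
    msa = MultipleAlignment(["a", "b"], ["AAAA", "AAAT"], "dna")
    dm = ph.pairwise_distance(msa, "poisson")
    assert dm.d[0, 1] == pytest.approx(-np.log(0.75))
    sat = ph.pairwise_distance(
        MultipleAlignment(["a", "b"], ["AAAA", "TTTT"], "dna"), "poisson"
    )
    assert ("a", "b") in sat.saturated
    assert np.isfinite(sat.d[0, 1])


def test_p_distance_recovers_planted_divergence(rng):
    """p of a simulated pair at planted p=0.3 over 10,000 sites is within
    binomial noise."""
    L, p = 10_000, 0.3
    a = rng.choice(list("ACGT"), L)
    b = a.copy()
    flip = rng.random(L) < p
    for i in np.where(flip)[0]:
        b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
    msa = MultipleAlignment(["a", "b"], ["".join(a), "".join(b)], "dna")
    dm = ph.pairwise_distance(msa)
    assert dm.d[0, 1] == pytest.approx(p, abs=0.02)


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_four_taxon_additive_exact():
    """Distances derived from ((A:1,B:2):1,(C:3,D:4)) are inverted exactly."""
    ids = ["A", "B", "C", "D"]
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    tree = ph.neighbor_joining(DistanceMatrix(ids, d))
    tids, td = ph.path_distances(tree)
    idx = {t: i for i, t in enumerate(tids)}
    for a, b in itertools.combinations(ids, 2):
        assert td[idx[a], idx[b]] == pytest.approx(
            d[ids.index(a), ids.index(b)], abs=1e-9
        )
    # the (A,B) cherry is recovered
    parents = {leaf.name: leaf.parent for leaf in tree.tips()}
    assert parents["A"] is parents["B"]


def test_nj_three_taxa_closed_form():
    ids = ["a", "b", "c"]
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    tree = ph.neighbor_joining(DistanceMatrix(ids, d))
    lengths = {leaf.name: leaf.length for leaf in tree.tips()}
    assert lengths["a"] == pytest.approx(0.0)  # (2+3-5)/2
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_exact_on_random_additive_matrices(n_taxa):
    """Topology and branch lengths of random positive-branch-length trees
    are recovered exactly from their additive matrices (20 seeds)."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        true_tree = random_additive_tree(n_taxa, rng)
        dm = true_tree.tip_tip_distances()
        tree = ph.neighbor_joining(DistanceMatrix(list(dm.ids), dm.data))
        assert tree.compare_rfd(true_tree) == 0.0
        tids, td = ph.path_distances(tree)
        idx = {t: i for i, t in enumerate(tids)}
        oidx = {t: i for i, t in enumerate(dm.ids)}
        for a, b in itertools.combinations(dm.ids, 2):
            assert td[idx[a], idx[b]] == pytest.approx(
                dm.data[oidx[a], oidx[b]], abs=1e-9
            )


def test_nj_matches_skbio_oracle():
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        true_tree = random_additive_tree(7, rng)
        dm = true_tree.tip_tip_distances()
        mine = ph.neighbor_joining(DistanceMatrix(list(dm.ids), dm.data))
        oracle = skbio_nj(SkDM(dm.data, dm.ids))
        assert mine.compare_rfd(oracle) == 0.0


def test_nj_tree_shape_invariants():
    rng = np.random.default_rng(5)
    true_tree = random_additive_tree(8, rng)
    dmx = true_tree.tip_tip_distances()
    tree = ph.neighbor_joining(DistanceMatrix(list(dmx.ids), dmx.data))
    leaves = {leaf.name for leaf in tree.tips()}
    assert leaves == set(dmx.ids)
    n = len(dmx.ids)
    n_edges = sum(1 for _ in tree.traverse(include_self=False))
    assert n_edges == 2 * n - 3


def test_nj_rejects_asymmetric_input():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        ph.neighbor_joining(DistanceMatrix(["a", "b", "c"], d))


def test_nj_rejects_too_few_taxa():
    with pytest.raises(ValueError, match="at least 3"):
        ph.neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# bootstrap


def _separating_msa():
    """Every column separates {A,B} from {C,D}."""
    return MultipleAlignment(
        ["A", "B", "C", "D"],
        ["A" * 40, "A" * 40, "T" * 40, "T" * 40],
        "dna",
    )


def test_bootstrap_perfect_signal_support_100():
    tree, supports, redraws = ph.bootstrap_support(
        _separating_msa(), "p_distance", n_replicates=50, seed=1
    )
    assert redraws == 0
    assert set(supports.values()) == {100.0}


def test_bootstrap_single_replicate_supports_binary(small_scenario):
    msa = small_scenario.msa
    _, supports, _ = ph.bootstrap_support(msa, "p_distance", n_replicates=1, seed=2)
    assert set(supports.values()) <= {0.0, 100.0}


def test_bootstrap_planted_split_high_support():
    """500 informative columns behind one split give support >= 95 at 100
    replicates."""
    rng = np.random.default_rng(1)
    base = rng.choice(list("ACGT"), 500)
    rows = {name: base.copy() for name in "ABCD"}
    informative = rng.random(500) < 0.5
    for name in "CD":
        rows[name] = rows[name].copy()
        rows[name][informative] = "T"
    for name in "AB":
        rows[name][informative] = "A"
    # sprinkle noise so replicates differ
    for name in "ABCD":
        noise = rng.random(500) < 0.02
        rows[name][noise] = rng.choice(list("ACGT"), noise.sum())
    msa = MultipleAlignment(list("ABCD"), ["".join(rows[n]) for n in "ABCD"], "dna")
    _, supports, _ = ph.bootstrap_support(msa, "p_distance", n_replicates=100, seed=1)
    assert max(supports.values()) >= 95.0


def test_bootstrap_invariant_under_leaf_permutation(small_scenario):
    msa = small_scenario.msa
    perm = list(reversed(range(msa.n_rows)))
    permuted = MultipleAlignment(
        [msa.ids[i] for i in perm], [msa.rows[i] for i in perm], msa.alphabet
    )
    _, s1, _ = ph.bootstrap_support(msa, "p_distance", 25, seed=3)
    _, s2, _ = ph.bootstrap_support(permuted, "p_distance", 25, seed=3)
    as_sets_1 = {frozenset(k): v for k, v in s1.items()}
    as_sets_2 = {frozenset(k): v for k, v in s2.items()}
    # compare on the shared canonicalization: each bipartition side or its
    # complement must carry the same support
    all_leaves = frozenset(msa.ids)
    norm = lambda side: min(side, all_leaves - side, key=sorted)
    n1 = {norm(k): v for k, v in as_sets_1.items()}
    n2 = {norm(k): v for k, v in as_sets_2.items()}
    assert n1 == n2


def test_newick_round_trip(tmp_path, small_scenario):
    tree, _, _ = ph.bootstrap_support(small_scenario.msa, "p_distance", 10, seed=1)
    p = tmp_path / "tree.nwk"
    ph.write_newick(tree, p)
    back = ph.read_newick(p)
    assert {t.name for t in back.tips()} == {t.name for t in tree.tips()}
    assert back.compare_rfd(tree) == 0.0


# ---------------------------------------------------------------------------
# clade labeling


def _toy_tree():
    return TreeNode.read(["((a1:1,a2:1):1,(b1:1,b2:1):1);"])


def test_label_groups_trivial_clade():
    tree = _toy_tree()
    mapping = {"a1": "Pe", "a2": "Pe", "b1": "At", "b2": "At"}
    label = ph.label_groups(tree, mapping, ["a1", "a2"])
    assert label.leaves == frozenset({"a1", "a2"})
    assert not label.spans_root
    assert label.absent_genomes == frozenset({"At"})


def test_label_groups_absent_genome_flag():
    tree = TreeNode.read(["(((p1:1,o1:1):1,p2:1):1,(x1:1,a1:1):1);"])
    mapping = {"p1": "Pe", "p2": "Pe", "o1": "Os", "x1": "Os", "a1": "At"}
    label = ph.label_groups(tree, mapping, ["p1", "o1"])
    assert "At" in label.absent_genomes  # a monocot-only clade


def test_label_groups_spanning_root_returns_all_leaves():
    tree = _toy_tree()
    mapping = {"a1": "Pe", "a2": "Pe", "b1": "At", "b2": "At"}
    label = ph.label_groups(tree, mapping, ["a1", "b1", "a2", "b2"])
    assert label.leaves == frozenset({"a1", "a2", "b1", "b2"})
    assert label.spans_root


def test_label_groups_unknown_seed_errors():
    tree = _toy_tree()
    mapping = {"a1": "Pe", "a2": "Pe", "b1": "At", "b2": "At"}
    with pytest.raises(ValueError, match="not in tree"):
        ph.label_groups(tree, mapping, ["zz"])
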