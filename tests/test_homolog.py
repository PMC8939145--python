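"""Greedy/linkage clustering, score-to-distance, UPGMA and tree dissection."""

import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from graspmine.homolog import (
    DEFAULT_DEPTH_CUTOFF,
    ClusterDistanceMatrix,
    cluster_homologs,
    cophenetic_distances,
    cross_score_matrix,
    dissect_tree,
    greedy_identity_cluster,
    linkage_identity_coverage_cluster,
    quick_identity,
    score_to_distance,
    star_align,
    upgma_tree,
)
from graspmine.seqcore import MultipleAlignment, ScoredProfile, derive_consensus
from graspmine.synth import PlantedFamilySpec, evolve_family

from conftest import random_protein


# --- independent oracle -----------------------------------------------------


def naive_upgma(labels, d):
    """Straightforward list-based average linkage; returns cophenetic
    distances and merge heights."""
    clusters = [[lab] for lab in labels]
    dist = {
        (a, b): d[i][j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def cdist(ca, cb):
        return sum(
            dist[(x, y)] if (x, y) in dist else dist[(y, x)]
            for x in ca
            for y in cb
        ) / (len(ca) * len(cb))

    coph = {}
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dd = cdist(clusters[i], clusters[j])
                if best is None or dd < best[0]:
                    best = (dd, i, j)
        dd, i, j = best
        heights.append(dd / 2)
        for x in clusters[i]:
            for y in clusters[j]:
                coph[(x, y) if x <= y else (y, x)] = dd
        merged = clusters[i] + clusters[j]
        clusters = [
            c for k, c in enumerate(clusters) if k not in (i, j)
        ] + [merged]
    return coph, sorted(heights)


def make_dm(d):
    d = np.asarray(d, dtype=float)
    n = len(d)
    return ClusterDistanceMatrix(
        cluster_ids=tuple(range(n)), s=np.ones((n, n)), d=d
    )


def random_symmetric(rng, n):
    d = rng.random((n, n)) * 5
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d


# --- greedy clustering ------------------------------------------------------


def test_greedy_identical_pair_merges():
    seqs = {"a": "MKKLLTACDE", "b": "MKKLLTACDE"}
    out = greedy_identity_cluster(seqs, 0.9)
    assert len(out) == 1 and sorted(out[0].member_ids) == ["a", "b"]


def test_greedy_half_identity_splits():
    seqs = {"a": "AAAAAAAAAA", "b": "AAAAAWWWWW"}
    out = greedy_identity_cluster(seqs, 0.9)
    assert len(out) == 2


def test_greedy_is_order_independent(rng):
    a = random_protein(rng, 40)
    c = random_protein(rng, 40)
    seqs = {"a": a, "b": a, "c": c}
    expected = None
    for order in itertools.permutations(seqs):
        out = greedy_identity_cluster({k: seqs[k] for k in order}, 0.9)
        parts = sorted(tuple(sorted(cl.member_ids)) for cl in out)
        if expected is None:
            expected = parts
        assert parts == expected
    assert expected == [("a", "b"), ("c",)]


@pytest.mark.parametrize("kernel", ["quick", "exact"])
def test_greedy_kernels_agree_on_planted_families(rng, kernel):
    fams = [
        evolve_family(
            PlantedFamilySpec(f"f{i}", 60, 0.05, 4, "ancillary"), rng
        )
        for i in range(3)
    ]
    seqs = {k: v for fam in fams for k, v in fam.items()}
    out = greedy_identity_cluster(seqs, 0.5, identity=kernel)
    parts = sorted(tuple(sorted(cl.member_ids)) for cl in out)
    expected = sorted(tuple(sorted(f)) for f in fams)
    assert parts == expected


def test_greedy_threshold_validation():
    with pytest.raises(ValueError):
        greedy_identity_cluster({"a": "MK"}, 0.0)
    assert greedy_identity_cluster({}, 0.9) == []


# --- linkage identity/coverage clustering -----------------------------------


def test_linkage_identical_pair_at_80_80(blosum62):
    seqs = {"a": "MKKLLTACDEFG", "b": "MKKLLTACDEFG"}
    comps = linkage_identity_coverage_cluster(seqs, 0.8, 0.8, blosum62)
    assert comps == [{"a", "b"}]


def test_linkage_chain_single_linkage(blosum62, rng):
    # a ~ b and b ~ c above threshold; a ~ c below: one component of 3
    base = random_protein(rng, 40)

    def mutate(s, k):
        out = list(s)
        for pos in rng.choice(len(s), size=k, replace=False):
            out[pos] = "W" if s[pos] != "W" else "Y"
        return "".join(out)

    b = base
    a = mutate(b, 5)  # ~87%
    c = mutate(b, 5)
    seqs = {"a": a, "b": b, "c": c}
    comps = linkage_identity_coverage_cluster(seqs, 0.85, 0.8, blosum62)
    assert comps == [{"a", "b", "c"}]


def test_linkage_coverage_gate(blosum62, rng):
    short = random_protein(rng, 20)
    long = short + random_protein(rng, 60)
    comps = linkage_identity_coverage_cluster(
        {"s": short, "l": long}, 0.8, 0.8, blosum62
    )
    assert sorted(map(sorted, comps)) == [["l"], ["s"]]


# --- star alignment ---------------------------------------------------------


def test_star_align_rows_degap_to_members(blosum62, rng):
    fam = evolve_family(
        PlantedFamilySpec("f", 50, 0.1, 5, "ancillary"), rng
    )
    m = star_align(fam, blosum62)
    assert set(m.member_ids) == set(fam)
    for sid in fam:
        assert m.degapped(sid) == fam[sid]


# --- score-to-distance ------------------------------------------------------


@pytest.mark.parametrize(
    "scores,expected",
    [
        ((100, 100, 100, 100), 0.0),
        ((60, 50, 100, 100), -math.log(0.6)),
        ((120, 110, 100, 100), 0.0),  # clamped
    ],
)
def test_score_to_distance_examples(scores, expected):
    assert score_to_distance(*scores) == pytest.approx(expected, abs=1e-12)


def test_score_to_distance_rejects_nonpositive():
    with pytest.raises(ValueError):
        score_to_distance(0, 1, 1, 1)


def test_score_to_distance_grid_properties():
    """Symmetry, zero diagonal analogue, non-negativity and monotonicity on
    an exhaustive grid of score quadruples."""
    grid = [1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0]
    for s_ab in grid:
        for s_ba in grid:
            for s_aa in grid:
                for s_bb in grid:
                    d = score_to_distance(s_ab, s_ba, s_aa, s_bb)
                    assert d >= 0.0
                    assert d == score_to_distance(s_ba, s_ab, s_bb, s_aa)
    # d == 0 iff cross-score reaches the smaller self-score
    assert score_to_distance(50, 10, 50, 100) == 0.0
    assert score_to_distance(49, 10, 50, 100) > 0.0
    # strictly decreasing in the maximal cross-score
    prev = None
    for s in grid:
        d = score_to_distance(s, 1.0, 1000.0, 1000.0)
        if prev is not None:
            assert d < prev
        prev = d


# --- UPGMA ------------------------------------------------------------------


def test_upgma_single_merge():
    tree = upgma_tree(make_dm([[0, 4], [4, 0]]))
    assert tree.height == pytest.approx(2.0)
    assert sorted(tree.leaves()) == ["0", "1"]


def test_upgma_three_leaves_hand_computed():
    d = [[0, 2, 8], [2, 0, 8], [8, 8, 0]]
    tree = upgma_tree(make_dm(d))
    assert tree.height == pytest.approx(4.0)
    inner = [c for c in tree.children if not c.is_leaf][0]
    assert inner.height == pytest.approx(1.0)
    assert sorted(inner.leaves()) == ["0", "1"]


def test_upgma_single_leaf():
    tree = upgma_tree(make_dm([[0.0]]))
    assert tree.is_leaf and tree.leaves() == ["0"]


def test_upgma_matches_naive_oracle(rng):
    for _ in range(150):
        n = int(rng.integers(5, 9))
        d = random_symmetric(rng, n)
        tree = upgma_tree(make_dm(d))
        coph = cophenetic_distances(tree)
        labels = [str(i) for i in range(n)]
        expected_coph, expected_heights = naive_upgma(labels, d)
        for key, val in expected_coph.items():
            assert coph[key] == pytest.approx(val, abs=1e-9)
        heights = []

        def collect(node):
            if not node.is_leaf:
                heights.append(node.height)
                for c in node.children:
                    collect(c)

        collect(tree)
        assert sorted(heights) == pytest.approx(expected_heights, abs=1e-9)


def test_upgma_matches_scipy_average_linkage(rng):
    for _ in range(25):
        n = int(rng.integers(4, 9))
        d = random_symmetric(rng, n)
        tree = upgma_tree(make_dm(d))
        coph = cophenetic_distances(tree)
        Z = linkage(squareform(d), method="average")
        sc = squareform(cophenet(Z))
        for i in range(n):
            for j in range(i + 1, n):
                assert coph[(str(i), str(j))] == pytest.approx(
                    sc[i, j], abs=1e-9
                )


def test_upgma_reproduces_ultrametric_input(rng):
    """Cophenetic distances of the UPGMA tree reproduce any ultrametric
    input exactly."""
    for _ in range(40):
        # build a random ultrametric via a random tree of merge heights
        n = 6
        d = np.zeros((n, n))
        groups = [[i] for i in range(n)]
        h = 0.0
        while len(groups) > 1:
            h += float(rng.random()) + 0.1
            i, j = sorted(rng.choice(len(groups), 2, replace=False))
            for x in groups[i]:
                for y in groups[j]:
                    d[x, y] = d[y, x] = 2 * h
            groups[i] = groups[i] + groups[j]
            del groups[j]
        tree = upgma_tree(make_dm(d))
        coph = cophenetic_distances(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert coph[(str(i), str(j))] == pytest.approx(
                    d[i, j], abs=1e-9
                )


def test_newick_round_trips_through_dendropy():
    import dendropy

    tree = upgma_tree(make_dm([[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == {"0", "1", "2"}
    # root-to-leaf path lengths all equal the root height (ultrametric)
    for leaf in t.leaf_node_iter():
        assert leaf.distance_from_root() == pytest.approx(4.0)


# --- dissection -------------------------------------------------------------


def test_dissect_three_leaf_example():
    tree = upgma_tree(make_dm([[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
    parts = dissect_tree(tree, 2.3)
    assert sorted(parts) == [["0", "1"], ["2"]]


def test_dissect_extremes(rng):
    d = random_symmetric(rng, 6) + 0.5
    np.fill_diagonal(d, 0)
    tree = upgma_tree(make_dm(d))
    assert sorted(dissect_tree(tree, 0.0)) == [[str(i)] for i in range(6)]
    assert dissect_tree(tree, tree.height) == [sorted(tree.leaves())]


def test_dissect_partitions_are_nested(rng):
    for _ in range(20):
        d = random_symmetric(rng, 7)
        tree = upgma_tree(make_dm(d))
        cuts = sorted(rng.random(3) * 4)
        parts = [dissect_tree(tree, c) for c in cuts]
        for fine, coarse in zip(parts, parts[1:]):
            blocks = [set(b) for b in coarse]
            for block in fine:
                assert any(set(block) <= b for b in blocks)


def test_default_depth_cutoff_value():
    assert DEFAULT_DEPTH_CUTOFF == pytest.approx(-math.log(0.01) / 2)
    assert round(DEFAULT_DEPTH_CUTOFF, 1) == 2.3


# --- full pipeline ----------------------------------------------------------


def test_cluster_homologs_single_sequence():
    res = cluster_homologs({"only": "MKKLLTACDEFGH"})
    assert len(res.clusters) == 1
    assert res.clusters[0].member_ids == ("only",)


def test_cluster_homologs_duplicates_share_cluster(rng):
    s = random_protein(rng, 80)
    other = random_protein(rng, 80)
    res = cluster_homologs({"a": s, "b": s, "c": other})
    labels = res.labels()
    assert labels["a"] == labels["b"]
    assert labels["a"] != labels["c"]


def test_cluster_homologs_recovers_planted_families(rng):
    from sklearn.metrics import adjusted_rand_score

    fams = {
        f"f{i}": evolve_family(
            PlantedFamilySpec(f"f{i}", 70, 0.1, 6, "ancillary"), rng
        )
        for i in range(3)
    }
    seqs = {k: v for fam in fams.values() for k, v in fam.items()}
    res = cluster_homologs(seqs)
    labels = res.labels()
    truth = [sid.rsplit("_", 1)[0] for sid in sorted(seqs)]
    pred = [labels[sid] for sid in sorted(seqs)]
    assert adjusted_rand_score(truth, pred) == 1.0


def test_cluster_homologs_invariant_to_order_and_relabeling(rng):
    fams = {
        f"f{i}": evolve_family(
            PlantedFamilySpec(f"f{i}", 60, 0.08, 4, "ancillary"), rng
        )
        for i in range(2)
    }
    seqs = {k: v for fam in fams.values() for k, v in fam.items()}

    def partition(result, names):
        labels = result.labels()
        groups = {}
        for sid in names:
            groups.setdefault(labels[sid], set()).add(sid)
        return sorted(tuple(sorted(g)) for g in groups.values())

    base = partition(cluster_homologs(seqs), seqs)
    shuffled = dict(reversed(list(seqs.items())))
    assert partition(cluster_homologs(shuffled), seqs) == base
    renamed = {f"zz_{k}": v for k, v in seqs.items()}
    got = partition(cluster_homologs(renamed), renamed)
    assert got == sorted(
        tuple(sorted(f"zz_{x}" for x in grp)) for grp in base
    )


def test_cross_score_matrix_separates_unrelated_profiles(blosum62, rng):
    """Unrelated cluster profiles end up beyond the dissection cutoff."""
    profiles, consensuses = [], []
    for i in range(3):
        fam = evolve_family(
            PlantedFamilySpec(f"f{i}", 90, 0.08, 4, "ancillary"), rng
        )
        m = star_align(fam, blosum62)
        profiles.append(ScoredProfile.from_alignment(m, blosum62))
        consensuses.append(
            derive_consensus(m, blosum62).consensus_sequence()
        )
    dm = cross_score_matrix(profiles, consensuses)
    off = dm.d[~np.eye(3, dtype=bool)]
    assert (off > DEFAULT_DEPTH_CUTOFF * 2).all()
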