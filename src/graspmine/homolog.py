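"""Homolog clustering of neighborhood proteins.

The procedure mirrors sensitive profile-based homolog detection at desk
scale: two-tier greedy identity clustering (0.9, then 0.5 on cluster
representatives), per-cluster multiple alignment and consensus derivation,
all-vs-all profile-versus-consensus cross-scoring, conversion of scores to
distances via ``d_AB = -ln(max(s_AB, s_BA) / min(s_AA, s_BB))``, UPGMA tree
construction, and dissection of the tree at a depth cutoff
(``-ln(0.01)/2 ~ 2.303`` by default) into the final clusters of homologs.

Also provides single-linkage identity/coverage clustering (BLASTCLUST-like
80/80 and 50/50 modes) used for cross-referencing against external
precursor sets.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .seqcore import (
    ConsensusProfile,
    MultipleAlignment,
    ScoredProfile,
    SubstitutionMatrix,
    align_pair,
    alignment_coverage,
    derive_consensus,
    percent_identity,
    profile_score,
)

#: default tree-dissection depth on the UPGMA tree, from the 0.01 score-ratio
#: threshold of the distance transform: -ln(0.01)/2
DEFAULT_DEPTH_CUTOFF = -math.log(0.01) / 2

#: minimum score entering the log-ratio distance (the transform needs > 0)
SCORE_FLOOR = 1.0


def _processing_order(seqs: Mapping[str, str]) -> list[str]:
    """Deterministic clustering order: length descending, then id ascending."""
    return sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))


@dataclass
class GreedyCluster:
    cluster_id: int
    representative_id: str
    member_ids: list[str]


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def quick_identity(a: str, b: str) -> float:
    """Identity of the optimal edit-distance global alignment, counted over
    all alignment columns (gaps included).

    Uses the bit-parallel aligner from edlib as the fast identity kernel
    for greedy centroid clustering.  The alignment-column denominator keeps
    a short sequence from reaching high identity against a much longer
    unrelated centroid, which a shorter-sequence denominator would allow
    under an edit-distance alignment.  The exact substitution-matrix
    identity is available through ``blosum_identity``.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches / columns if columns else 0.0


def blosum_identity(
    a: str, b: str, matrix: SubstitutionMatrix | None = None
) -> float:
    """Identity of the optimal BLOSUM global alignment (shorter denominator)."""
    return percent_identity(align_pair(a, b, matrix, "global"), "shorter")


def greedy_identity_cluster(
    seqs: Mapping[str, str],
    threshold: float,
    matrix: SubstitutionMatrix | None = None,
    identity: str = "quick",
) -> list[GreedyCluster]:
    """UCLUST-like greedy centroid clustering at an identity threshold.

    Sequences are processed longest-first (ties by id); each sequence joins
    the first existing centroid it matches at >= ``threshold`` identity
    (shorter-sequence denominator), otherwise it founds a new centroid.
    ``identity`` selects the pairwise kernel: "quick" (edit-distance based)
    or "exact" (substitution-matrix global alignment).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if identity not in ("quick", "exact"):
        raise ValueError(f"unknown identity kernel {identity!r}")
    if identity == "exact" and matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    clusters: list[GreedyCluster] = []
    for sid in _processing_order(seqs):
        seq = seqs[sid]
        for cl in clusters:
            rep = seqs[cl.representative_id]
            if identity == "quick":
                ident = 1.0 if seq == rep else quick_identity(seq, rep)
            else:
                ident = blosum_identity(seq, rep, matrix)
            if ident >= threshold:
                cl.member_ids.append(sid)
                break
        else:
            clusters.append(
                GreedyCluster(
                    cluster_id=len(clusters),
                    representative_id=sid,
                    member_ids=[sid],
                )
            )
    return clusters


def linkage_identity_coverage_cluster(
    seqs: Mapping[str, str],
    id_thr: float,
    cov_thr: float,
    matrix: SubstitutionMatrix | None = None,
) -> list[set[str]]:
    """Single-linkage components over identity/coverage-passing pairs.

    An edge joins two sequences whose global alignment reaches ``id_thr``
    identity (shorter denominator) with mutual coverage >= ``cov_thr``.
    """
    if not (0 < id_thr <= 1 and 0 < cov_thr <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    ids = sorted(seqs)
    n = len(ids)
    rows: list[int] = []
    cols: list[int] = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = align_pair(seqs[ids[i]], seqs[ids[j]], matrix, "global")
            cov_a, cov_b = alignment_coverage(pair)
            if (
                percent_identity(pair, "shorter") >= id_thr
                and cov_a >= cov_thr
                and cov_b >= cov_thr
            ):
                rows.append(i)
                cols.append(j)
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)
    out: list[set[str]] = [set() for _ in range(n_comp)]
    for sid, lab in zip(ids, labels):
        out[lab].add(sid)
    return out


# ---------------------------------------------------------------------------
# star multiple alignment


def star_align(
    seqs: Mapping[str, str],
    matrix: SubstitutionMatrix | None = None,
    reference_id: str | None = None,
) -> MultipleAlignment:
    """Multiple alignment by merging pairwise global alignments to a reference.

    The reference defaults to the longest member (ties by id).  Insertions
    relative to the reference are left-justified and padded; the merge is a
    center-star construction, adequate for within-cluster alignments of
    already-similar sequences.  A pluggable external aligner can replace
    this behind the same ``MultipleAlignment`` contract.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    ids = list(seqs)
    if len(ids) == 1:
        return MultipleAlignment.single(ids[0], seqs[ids[0]])
    if reference_id is None:
        reference_id = min(ids, key=lambda sid: (-len(seqs[sid]), sid))
    ref = seqs[reference_id].upper()
    R = len(ref)

    # per member: list of R+1 insert strings (before each ref position, plus
    # trailing) and the R aligned characters (residue or gap)
    member_parts: dict[str, tuple[list[str], list[str]]] = {}
    ins_len = [0] * (R + 1)
    for sid in ids:
        if sid == reference_id:
            continue
        pair = align_pair(seqs[sid], ref, matrix, "global")
        inserts = [""] * (R + 1)
        chars = [""] * R
        rpos = 0
        for x, y in zip(pair.aligned_a, pair.aligned_b):
            if y == "-":
                inserts[rpos] += x
            else:
                chars[rpos] = x
                rpos += 1
        member_parts[sid] = (inserts, chars)
        for k in range(R + 1):
            ins_len[k] = max(ins_len[k], len(inserts[k]))

    def build_row(inserts: list[str], chars: list[str]) -> str:
        out = []
        for k in range(R):
            out.append(inserts[k].ljust(ins_len[k], "-"))
            out.append(chars[k])
        out.append(inserts[R].ljust(ins_len[R], "-"))
        return "".join(out)

    ordered = [reference_id] + [sid for sid in ids if sid != reference_id]
    rows = []
    for sid in ordered:
        if sid == reference_id:
            rows.append(build_row([""] * (R + 1), list(ref)))
        else:
            rows.append(build_row(*member_parts[sid]))
    return MultipleAlignment(member_ids=tuple(ordered), rows=tuple(rows))


# ---------------------------------------------------------------------------
# score-to-distance and UPGMA


def score_to_distance(
    s_ab: float, s_ba: float, s_aa: float, s_bb: float
) -> float:
    """Convert cross- and self-scores of two clusters into a distance.

    d = -ln(max(s_AB, s_BA) / min(s_AA, s_BB)), clamped to 0 when the best
    cross-score exceeds the smaller self-score.
    """
    for s in (s_ab, s_ba, s_aa, s_bb):
        if s <= 0:
            raise ValueError("scores must be positive (clamp before calling)")
    ratio = max(s_ab, s_ba) / min(s_aa, s_bb)
    return max(0.0, -math.log(ratio))


@dataclass(frozen=True)
class ClusterDistanceMatrix:
    cluster_ids: tuple[int, ...]
    s: np.ndarray  # cross-score table, self-scores on the diagonal
    d: np.ndarray  # symmetric distances, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.cluster_ids)
        if self.s.shape != (n, n) or self.d.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


#: gapped BLOSUM62 Karlin-Altschul lambda used by the cross-score
#: significance gate
_KA_LAMBDA = 0.267


def cross_score_matrix(
    profiles: Sequence[ScoredProfile],
    consensuses: Sequence[str],
    cluster_ids: Sequence[int] | None = None,
    score_floor: float = SCORE_FLOOR,
    significance_margin: float | None = 2.0,
    prefilter_identity: float | None = 0.3,
) -> ClusterDistanceMatrix:
    """All-vs-all profile-versus-consensus scores and the derived distances.

    ``s[i, j]`` scores the profile of cluster i against the consensus
    sequence of cluster j (both directions are computed; the diagonal holds
    self-scores).  A local alignment of two unrelated sequences still
    reaches a score near ln(n*m)/lambda by chance; cross-scores below
    ``significance_margin`` times that random expectation are treated as
    "no hit" and clamped to ``score_floor``, playing the role the E-value
    threshold plays in a real profile search.  Pass ``None`` to disable the
    gate.  ``prefilter_identity`` skips the profile alignment altogether
    for cluster pairs whose consensus sequences fall below that quick
    global identity (such pairs would be floored by the gate regardless);
    pass ``None`` to score every pair.  All scores are clamped to
    ``score_floor`` before the log-ratio transform.
    """
    n = len(profiles)
    if len(consensuses) != n:
        raise ValueError("profiles and consensuses differ in length")
    if cluster_ids is None:
        cluster_ids = tuple(range(n))

    def gated(raw: float, i: int, j: int) -> float:
        if i != j and significance_margin is not None:
            theta = (
                significance_margin
                * math.log(max(len(profiles[i]) * len(consensuses[j]), 2))
                / _KA_LAMBDA
            )
            if raw < theta:
                raw = 0.0
        return max(raw, score_floor)

    s = np.full((n, n), score_floor)
    for i in range(n):
        s[i, i] = gated(profile_score(profiles[i], consensuses[i]), i, i)
    for i in range(n):
        for j in range(i + 1, n):
            if (
                prefilter_identity is not None
                and quick_identity(consensuses[i], consensuses[j])
                < prefilter_identity
            ):
                continue
            s[i, j] = gated(profile_score(profiles[i], consensuses[j]), i, j)
            s[j, i] = gated(profile_score(profiles[j], consensuses[i]), j, i)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = score_to_distance(
                s[i, j], s[j, i], s[i, i], s[j, j]
            )
    return ClusterDistanceMatrix(cluster_ids=tuple(cluster_ids), s=s, d=d)


@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric tree; leaves sit at height 0."""

    height: float
    children: tuple["TreeNode", ...] = ()
    leaf_name: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return str(self.leaf_name)
        parts = []
        for c in self.children:
            bl = self.height - c.height
            parts.append(f"{c._newick_inner()}:{bl:.6f}")
        return "(" + ",".join(parts) + ")"


def upgma_tree(dm: ClusterDistanceMatrix) -> TreeNode:
    """UPGMA (average-linkage) tree from a symmetric distance matrix.

    Repeatedly merges the closest pair (ties broken by the lexicographically
    smallest pair of sorted leaf-label tuples); the merged node sits at half
    the pair distance; distances to the new node are size-weighted means.
    """
    labels = [str(c) for c in dm.cluster_ids]
    n = len(labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, leaf_name=labels[i]) for i in range(n)
    }
    keys: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                dij = dist[(min(i, j), max(i, j))]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (dij, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        dij, _, i, j = best
        new = TreeNode(height=dij / 2.0, children=(nodes[i], nodes[j]))
        ni, nj = sizes[i], sizes[j]
        nodes[next_id] = new
        keys[next_id] = tuple(sorted(keys[i] + keys[j]))
        sizes[next_id] = ni + nj
        active = [k for k in active if k not in (i, j)]
        for k in active:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (
                ni * dik + nj * djk
            ) / (ni + nj)
        active.append(next_id)
        next_id += 1
    return nodes[active[0]]


def cophenetic_distances(root: TreeNode) -> dict[tuple[str, str], float]:
    """Pairwise cophenetic distances (2x the height of the lowest common
    ancestor) between all leaves."""
    out: dict[tuple[str, str], float] = {}

    def visit(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.leaf_name]
        groups = [visit(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        key = (a, b) if a <= b else (b, a)
                        out[key] = 2.0 * node.height
        return [leaf for g in groups for leaf in g]

    visit(root)
    return out


def dissect_tree(
    t: TreeNode, depth_cutoff: float = DEFAULT_DEPTH_CUTOFF
) -> list[list[str]]:
    """Cut the tree at a height threshold into leaf clusters.

    Each cluster is a maximal subtree whose root height is <= the cutoff
    (its parent, if any, exceeds it).  The partition is exhaustive and
    disjoint, and refines monotonically as the cutoff decreases.
    """
    parts: list[list[str]] = []

    def visit(node: TreeNode) -> None:
        if node.height <= depth_cutoff:
            parts.append(sorted(node.leaves()))
        else:
            for c in node.children:
                visit(c)

    visit(t)
    return parts


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class SeqCluster:
    cluster_id: int
    member_ids: tuple[str, ...]
    representative_id: str
    alignment: MultipleAlignment
    profile: ConsensusProfile

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")
        if set(self.alignment.member_ids) != set(self.member_ids):
            raise ValueError("alignment rows must cover exactly the members")


def build_cluster(
    cluster_id: int,
    members: Mapping[str, str],
    matrix: SubstitutionMatrix,
    h_consensus: float = 0.5,
) -> SeqCluster:
    alignment = star_align(members, matrix)
    profile = derive_consensus(alignment, matrix, h_consensus)
    rep = min(members, key=lambda sid: (-len(members[sid]), sid))
    return SeqCluster(
        cluster_id=cluster_id,
        member_ids=tuple(alignment.member_ids),
        representative_id=rep,
        alignment=alignment,
        profile=profile,
    )


@dataclass
class HomologClustering:
    """Result of the full clustering pipeline with per-sequence provenance."""

    clusters: list[SeqCluster]  # final clusters of homologs
    tier2_clusters: list[SeqCluster]
    tree: TreeNode | None
    distance_matrix: ClusterDistanceMatrix | None
    provenance: pd.DataFrame  # sequence_id, tier1, tier2, final

    def labels(self) -> dict[str, int]:
        return dict(
            zip(self.provenance["sequence_id"], self.provenance["final_cluster"])
        )

    def cluster_of(self, sequence_id: str) -> SeqCluster:
        lab = self.labels()[sequence_id]
        return self.clusters[lab]


def cluster_homologs(
    seqs: Mapping[str, str],
    matrix: SubstitutionMatrix | None = None,
    tier1_threshold: float = 0.9,
    tier2_threshold: float = 0.5,
    depth_cutoff: float = DEFAULT_DEPTH_CUTOFF,
    h_consensus: float = 0.5,
) -> HomologClustering:
    """Two-tier greedy clustering, profile cross-scoring, UPGMA and dissection.

    Returns the final clusters of homologs (unions of tier-2 clusters whose
    leaves share a subtree below the depth cutoff) and the provenance of
    every sequence through both greedy tiers.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()

    tier1 = greedy_identity_cluster(seqs, tier1_threshold, matrix)
    reps = {cl.representative_id: seqs[cl.representative_id] for cl in tier1}
    tier2 = greedy_identity_cluster(reps, tier2_threshold, matrix)

    rep_to_t1 = {cl.representative_id: cl for cl in tier1}
    tier2_members: list[dict[str, str]] = []
    for t2 in tier2:
        members: dict[str, str] = {}
        for rep in t2.member_ids:
            for sid in rep_to_t1[rep].member_ids:
                members[sid] = seqs[sid]
        tier2_members.append(members)

    tier2_built = [
        build_cluster(i, members, matrix, h_consensus)
        for i, members in enumerate(tier2_members)
    ]

    if len(tier2_built) == 1:
        parts = [[ "0" ]]
        tree = None
        dm = None
    else:
        profiles = [
            ScoredProfile.from_alignment(cl.alignment, matrix)
            for cl in tier2_built
        ]
        consensuses = [cl.profile.consensus_sequence() for cl in tier2_built]
        dm = cross_score_matrix(profiles, consensuses)
        tree = upgma_tree(dm)
        parts = dissect_tree(tree, depth_cutoff)

    final_clusters: list[SeqCluster] = []
    t2_to_final: dict[int, int] = {}
    for part in sorted(parts):
        t2_ids = sorted(int(lab) for lab in part)
        members = {}
        for t2_id in t2_ids:
            members.update(tier2_members[t2_id])
        fid = len(final_clusters)
        for t2_id in t2_ids:
            t2_to_final[t2_id] = fid
        if len(t2_ids) == 1:
            cl = tier2_built[t2_ids[0]]
            final_clusters.append(
                SeqCluster(
                    cluster_id=fid,
                    member_ids=cl.member_ids,
                    representative_id=cl.representative_id,
                    alignment=cl.alignment,
                    profile=cl.profile,
                )
            )
        else:
            final_clusters.append(build_cluster(fid, members, matrix, h_consensus))

    t1_of: dict[str, int] = {}
    t2_of: dict[str, int] = {}
    for cl in tier1:
        for sid in cl.member_ids:
            t1_of[sid] = cl.cluster_id
    for t2_id, members in enumerate(tier2_members):
        for sid in members:
            t2_of[sid] = t2_id
    records = [
        {
            "sequence_id": sid,
            "tier1_cluster": t1_of[sid],
            "tier2_cluster": t2_of[sid],
            "final_cluster": t2_to_final[t2_of[sid]],
        }
        for sid in sorted(seqs)
    ]
    return HomologClustering(
        clusters=final_clusters,
        tier2_clusters=tier2_built,
        tree=tree,
        distance_matrix=dm,
        provenance=pd.DataFrame.from_records(records),
    )
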