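"""Rule-based graspetide precursor prediction.

Precursor peptides of ATP-grasp (graspetide) biosynthetic gene clusters are
short proteins encoded next to the ligase.  Three sequence signals drive the
screen: a leader motif Phhx(1,2)h (P, two hydrophobics, one or two arbitrary
residues, a hydrophobic) typically within the 30 N-terminal residues; a
GG-like cleavage doublet of small residues (G, A, S, C, E); and core-peptide
patterns over the bond-forming residues S/T/D/E/K, written in a small motif
language with residue classes in brackets and variable gaps ``x(n-m)``.

Clusters of candidate proteins are classified cluster-wide: "known" when
any member co-clusters with a reference precursor (50% identity / 50%
coverage single linkage), matches a library core motif, or carries a
precursor annotation; "new" when the cluster passes the candidate filter
(majority of members <= 150 aa, encoded within two genes of an anchor) and
shows a conserved small-residue doublet; "candidate" when both the GG and
leader motifs occur within the first 30 residues; otherwise "rejected".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .homolog import SeqCluster, linkage_identity_coverage_cluster
from .seqcore import ConsensusProfile, SubstitutionMatrix

#: residues that can form lactone/lactam side-chain linkages
BOND_RESIDUES = frozenset("STDEK")
#: small residues admissible in the GG-like cleavage doublet
DEFAULT_SMALL_SET = frozenset("GASCE")
#: hydrophobic residues for the 'h' positions of the leader motif
DEFAULT_HYDROPHOBIC_SET = frozenset("ACFILMVWY")
DEFAULT_LEADER_WINDOW = 30


class PatternError(ValueError):
    """Raised when a motif pattern cannot be parsed."""


@dataclass(frozen=True)
class MotifPattern:
    """A core/leader motif over residues, classes and variable gaps.

    Grammar: an uppercase residue letter matches itself; ``x`` matches any
    residue; ``[ST]`` matches a residue class; ``x(n-m)`` (also ``x(n,m)``
    or an en dash) matches between n and m arbitrary residues.
    """

    pattern: str
    name: str = ""
    region: str = "core"
    tokens: tuple = field(init=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", _parse_pattern(self.pattern))

    @property
    def min_length(self) -> int:
        return sum(t[1] for t in self.tokens)

    @property
    def max_length(self) -> int:
        return sum(t[2] for t in self.tokens)


_GAP_RE = re.compile(r"\((\d+)[–—,-](\d+)\)")


def _parse_pattern(pattern: str) -> tuple:
    """Tokenize into (charset-or-None, min, max) items; None = any residue."""
    tokens: list[tuple[frozenset | None, int, int]] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise PatternError(f"unclosed '[' at position {i + 1} in {pattern!r}")
            members = pattern[i + 1 : j]
            if not members or not members.isalpha():
                raise PatternError(f"bad residue class {pattern[i:j + 1]!r}")
            tokens.append((frozenset(members.upper()), 1, 1))
            i = j + 1
        elif c == "x":
            m = _GAP_RE.match(pattern, i + 1)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if lo > hi:
                    raise PatternError(
                        f"variable gap {m.group(0)!r} has n > m in {pattern!r}"
                    )
                tokens.append((None, lo, hi))
                i = m.end()
            else:
                tokens.append((None, 1, 1))
                i += 1
        elif c.isalpha() and c.isupper():
            tokens.append((frozenset(c), 1, 1))
            i += 1
        else:
            raise PatternError(
                f"unrecognized token {c!r} at position {i + 1} in {pattern!r}"
            )
    if not tokens:
        raise PatternError("empty pattern")
    return tuple(tokens)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based inclusive
    end: int
    pattern_name: str
    matched: str


def _match_at(seq: str, pos: int, tokens: tuple) -> list[int]:
    """All end offsets (exclusive) of matches of ``tokens`` starting at pos."""
    ends = {pos}
    for charset, lo, hi in tokens:
        new_ends = set()
        for e in ends:
            if charset is None:
                for k in range(lo, hi + 1):
                    if e + k <= len(seq):
                        new_ends.add(e + k)
            else:
                if e + 1 <= len(seq) and seq[e] in charset:
                    new_ends.add(e + 1)
        if not new_ends:
            return []
        ends = new_ends
    return sorted(ends)


def match_core_pattern(
    seq: str, pattern: MotifPattern, sequence_id: str = ""
) -> list[MotifHit]:
    """All matches of a motif pattern, including every alternative span of
    variable gaps; overlapping matches are reported in leftmost-longest
    order."""
    seq = seq.upper()
    hits = []
    for pos in range(len(seq)):
        for end in _match_at(seq, pos, pattern.tokens):
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=pos + 1,
                    end=end,
                    pattern_name=pattern.name or pattern.pattern,
                    matched=seq[pos:end],
                )
            )
    hits.sort(key=lambda h: (h.start, -h.end))
    return hits


def leader_motif_pattern(
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC_SET,
    gap_range: tuple[int, int] = (1, 2),
) -> MotifPattern:
    h = "[" + "".join(sorted(hydrophobic_set)) + "]"
    lo, hi = gap_range
    return MotifPattern(
        pattern=f"P{h}{h}x({lo}-{hi}){h}",
        name="Phhx(1,2)h",
        region="leader",
    )


def scan_leader_motif(
    seq: str,
    window: int = DEFAULT_LEADER_WINDOW,
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC_SET,
    max_gap_range: tuple[int, int] = (1, 2),
    sequence_id: str = "",
) -> list[MotifHit]:
    """Matches of the Phhx(1,2)h leader motif starting within the N-terminal
    window."""
    pattern = leader_motif_pattern(hydrophobic_set, max_gap_range)
    return [
        h
        for h in match_core_pattern(seq, pattern, sequence_id)
        if h.start <= window
    ]


def scan_gg_motif(
    seq: str,
    small_set: frozenset = DEFAULT_SMALL_SET,
    require_gly: bool = False,
    region: tuple[int, int] | None = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Adjacent doublets of small residues (GG-like cleavage sites).

    ``region`` is a 1-based inclusive position range; with ``require_gly``
    at least one residue of the doublet must be glycine.
    """
    seq = seq.upper()
    lo, hi = region if region is not None else (1, len(seq))
    if lo < 1 or hi > len(seq):
        raise ValueError(f"region {region} outside sequence of length {len(seq)}")
    hits = []
    for pos in range(lo - 1, hi - 1):
        a, b = seq[pos], seq[pos + 1]
        if a in small_set and b in small_set:
            if require_gly and "G" not in (a, b):
                continue
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=pos + 1,
                    end=pos + 2,
                    pattern_name="GG",
                    matched=a + b,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# bundled motif library (patterns printed in this work; external reference
# motif sets are supplied through the pattern-file format)

BUNDLED_MOTIF_LIBRARY: tuple[MotifPattern, ...] = (
    MotifPattern("TxxxTxxDxxxxDD", name="salinispora_core", region="core"),
    MotifPattern("TxxxTx(6-10)Dx(1-4)D", name="branch1_core", region="core"),
    MotifPattern(
        "TxxxxDxxxTxKxPSDxD[DE]", name="chryseoviridin_core", region="core"
    ),
    MotifPattern("PFFARFL", name="microviridin_leader", region="leader"),
)


def load_pattern_file(path: str | Path) -> list[MotifPattern]:
    """Read patterns from a text file: one per line,
    ``name<TAB>region<TAB>pattern``; blank lines and '#' comments skipped."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected name<TAB>region<TAB>pattern"
            )
        name, region, pattern = parts
        out.append(MotifPattern(pattern=pattern, name=name, region=region))
    return out


# ---------------------------------------------------------------------------
# candidate filtering and classification

DEFAULT_MAX_PRECURSOR_LENGTH = 150
DEFAULT_MAX_ANCHOR_RANK = 2
DEFAULT_LENGTH_MAJORITY = 0.5


@dataclass(frozen=True)
class CandidateEvidence:
    cluster_id: int
    short_fraction: float
    min_anchor_rank: int | None  # smallest |rank| of any member near an anchor
    passed: bool


def candidate_filter(
    clusters: Sequence[SeqCluster],
    seqs: Mapping[str, str],
    member_ranks: Mapping[str, int],
    max_len: int = DEFAULT_MAX_PRECURSOR_LENGTH,
    max_rank: int = DEFAULT_MAX_ANCHOR_RANK,
    majority: float = DEFAULT_LENGTH_MAJORITY,
) -> dict[int, CandidateEvidence]:
    """Initial precursor candidate screen over clusters of homologs.

    A cluster is kept when strictly more than ``majority`` of its members
    are <= ``max_len`` residues AND at least one member lies within
    ``max_rank`` genes of an anchor.  ``member_ranks`` maps a protein id to
    the smallest absolute neighbor rank of a gene encoding it (members
    missing from the map are treated as far from any anchor).
    """
    out: dict[int, CandidateEvidence] = {}
    for cl in clusters:
        short = sum(1 for sid in cl.member_ids if len(seqs[sid]) <= max_len)
        frac = short / len(cl.member_ids)
        ranks = [
            abs(member_ranks[sid]) for sid in cl.member_ids if sid in member_ranks
        ]
        min_rank = min(ranks) if ranks else None
        passed = frac > majority and min_rank is not None and min_rank <= max_rank
        out[cl.cluster_id] = CandidateEvidence(
            cluster_id=cl.cluster_id,
            short_fraction=frac,
            min_anchor_rank=min_rank,
            passed=passed,
        )
    return out


@dataclass(frozen=True)
class PrecursorCall:
    cluster_id: int
    status: str  # known | new | candidate | rejected
    reference_overlap: bool
    motif_match: bool
    annotation_flag: bool
    passed_filter: bool
    conserved_doublet: bool
    gg_and_leader_n30: bool
    leader_hits: tuple[MotifHit, ...] = ()
    gg_hits: tuple[MotifHit, ...] = ()
    core_hits: tuple[MotifHit, ...] = ()
    bond_candidates: tuple[tuple[int, str], ...] = ()
    thioether_candidates: tuple[int, ...] = ()


def resolve_status(
    known_evidence: bool,
    passed_filter: bool,
    conserved_doublet: bool,
    gg_and_leader: bool,
) -> str:
    """Pure decision table mapping evidence flags to a cluster status."""
    if known_evidence:
        return "known"
    if passed_filter and conserved_doublet:
        return "new"
    if gg_and_leader:
        return "candidate"
    return "rejected"


def conserved_small_doublet(
    profile: ConsensusProfile,
    small_set: frozenset = DEFAULT_SMALL_SET,
    min_homog: float = 0.5,
) -> bool:
    """A pair of adjacent alignment columns, each with homogeneity >=
    ``min_homog`` and a small-residue consensus, operationalizes the
    conserved cleavage doublet at cluster level.

    A singleton cluster cannot exhibit conservation (every column is
    trivially homogeneous), so single-member profiles never qualify;
    singletons are picked up by the GG-plus-leader "candidate" route
    instead."""
    if profile.source.n_members < 2:
        return False
    cons = profile.consensus
    hom = profile.homogeneity
    for j in range(len(cons) - 1):
        if (
            cons[j] in small_set
            and cons[j + 1] in small_set
            and hom[j] >= min_homog
            and hom[j + 1] >= min_homog
        ):
            return True
    return False


def map_bond_residues(
    profile: ConsensusProfile,
    core_region: tuple[int, int] | None = None,
    min_homog: float = 0.5,
) -> tuple[list[tuple[int, str]], list[int]]:
    """Conserved bond-forming and thioether-donor positions in the consensus.

    Positions (1-based, within ``core_region`` if given) whose consensus
    residue is in S/T/D/E/K with homogeneity >= ``min_homog`` are lactone/
    lactam bond candidates; conserved cysteines are thioether (sulfur
    donor) candidates.  Masked ('x') and gap positions are never reported.
    """
    cons = profile.consensus
    lo, hi = core_region if core_region is not None else (1, len(cons))
    bonds: list[tuple[int, str]] = []
    thio: list[int] = []
    for pos in range(lo, hi + 1):
        c = cons[pos - 1]
        if c in ("x", "-") or profile.homogeneity[pos - 1] < min_homog:
            continue
        if c in BOND_RESIDUES:
            bonds.append((pos, c))
        elif c == "C":
            thio.append(pos)
    return bonds, thio


def core_region_after_doublet(
    profile: ConsensusProfile, small_set: frozenset = DEFAULT_SMALL_SET
) -> tuple[int, int]:
    """Alignment columns after the last conserved GG-like doublet; the full
    profile when no doublet is found (the leader/core boundary sits at the
    cleavage site)."""
    cons = profile.consensus
    last = None
    for j in range(len(cons) - 1):
        if (
            cons[j] in small_set
            and cons[j + 1] in small_set
            and profile.homogeneity[j] >= profile.h_consensus
            and profile.homogeneity[j + 1] >= profile.h_consensus
        ):
            last = j + 1  # 0-based index of second doublet residue
    if last is None or last + 2 > len(cons):
        return (1, len(cons))
    return (last + 2, len(cons))


def classify_precursor(
    cluster: SeqCluster,
    seqs: Mapping[str, str],
    evidence: CandidateEvidence,
    reference_sets: Mapping[str, str] | None = None,
    motif_library: Sequence[MotifPattern] | None = None,
    annotations: Iterable[str] | None = None,
    matrix: SubstitutionMatrix | None = None,
    small_set: frozenset = DEFAULT_SMALL_SET,
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC_SET,
    leader_window: int = DEFAULT_LEADER_WINDOW,
    reference_id_thr: float = 0.5,
    reference_cov_thr: float = 0.5,
) -> PrecursorCall:
    """Classify one cluster of candidate precursors, cluster-wide.

    Evidence gathered per member: overlap with reference precursors under
    50/50 identity-coverage single linkage, perfect matches to library core
    motifs, precursor annotation flags, and leader/GG motifs in the
    N-terminal window.  Cluster-level evidence: a conserved small-residue
    doublet in the alignment.  The status follows ``resolve_status``.
    """
    if motif_library is None:
        motif_library = BUNDLED_MOTIF_LIBRARY
    annotations = set(annotations or ())
    members = {sid: seqs[sid] for sid in cluster.member_ids}

    reference_overlap = False
    if reference_sets:
        pool = dict(members)
        for rid, rseq in reference_sets.items():
            pool[f"__ref__{rid}"] = rseq
        for comp in linkage_identity_coverage_cluster(
            pool, reference_id_thr, reference_cov_thr, matrix
        ):
            has_ref = any(s.startswith("__ref__") for s in comp)
            has_member = any(not s.startswith("__ref__") for s in comp)
            if has_ref and has_member:
                reference_overlap = True
                break

    core_hits: list[MotifHit] = []
    for sid, seq in members.items():
        for pat in motif_library:
            core_hits.extend(match_core_pattern(seq, pat, sid))
    motif_match = bool(core_hits)

    annotation_flag = any(sid in annotations for sid in members)

    leader_hits: list[MotifHit] = []
    gg_hits: list[MotifHit] = []
    gg_and_leader = False
    for sid, seq in members.items():
        lh = scan_leader_motif(
            seq, leader_window, hydrophobic_set, sequence_id=sid
        )
        region_hi = min(leader_window, len(seq) - 1) if len(seq) > 1 else None
        gh = (
            scan_gg_motif(
                seq, small_set, region=(1, region_hi + 1), sequence_id=sid
            )
            if region_hi
            else []
        )
        gh = [h for h in gh if h.start <= leader_window]
        leader_hits.extend(lh)
        gg_hits.extend(gh)
        if lh and gh:
            gg_and_leader = True

    doublet = conserved_small_doublet(cluster.profile, small_set)

    known = reference_overlap or motif_match or annotation_flag
    status = resolve_status(known, evidence.passed, doublet, gg_and_leader)

    region = core_region_after_doublet(cluster.profile, small_set)
    bonds, thio = map_bond_residues(cluster.profile, region)

    return PrecursorCall(
        cluster_id=cluster.cluster_id,
        status=status,
        reference_overlap=reference_overlap,
        motif_match=motif_match,
        annotation_flag=annotation_flag,
        passed_filter=evidence.passed,
        conserved_doublet=doublet,
        gg_and_leader_n30=gg_and_leader,
        leader_hits=tuple(leader_hits),
        gg_hits=tuple(gg_hits),
        core_hits=tuple(core_hits),
        bond_candidates=tuple(bonds),
        thioether_candidates=tuple(thio),
    )
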