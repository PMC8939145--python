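"""Sequence scoring primitives.

Pairwise affine-gap alignment (global and local), percent identity and
coverage, multiple-alignment handling, BLOSUM62-based consensus and
per-column homogeneity, alignment column filtering, and position-specific
profile-to-sequence scoring.

The alignment engine is a Gotoh dynamic program with an affine gap model
(a gap of length ``k`` costs ``open + k * extend``; BLAST-style defaults
11/1) and a deterministic traceback that prefers diagonal over up over
left moves on ties.  The same matrix-fill core drives both
residue-vs-residue and profile-vs-residue alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: index of the "unknown" symbol X in the extended alphabet
_X_INDEX = 20
_AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_TO_INDEX["X"] = _X_INDEX

GAP = "-"

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

_NEG = np.iinfo(np.int64).min // 4


class SequenceInputError(ValueError):
    """Raised for empty sequences or symbols outside the amino-acid alphabet."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a protein sequence to integer indices (X and unknowns handled).

    Unknown residue symbol 'X' maps to a dedicated index whose substitution
    score against everything is 0.  Any other non-alphabet character is an
    error naming the offending symbol.
    """
    if not seq:
        raise SequenceInputError("empty sequence")
    seq = seq.upper()
    try:
        return np.array([_AA_TO_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise SequenceInputError(
            f"non-alphabet character {exc.args[0]!r} in sequence"
        ) from None


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 integer substitution matrix over the standard alphabet.

    ``scores`` is indexed by the alphabetical residue order ``ACDEFGHIKLMNPQRSTVWY``.
    An extended 21x21 copy with a zero-scoring X row/column is kept for
    alignment of sequences containing unknown residues.
    """

    scores: np.ndarray
    name: str = "custom"
    extended: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.int64)
        if s.shape != (20, 20):
            raise ValueError(f"expected a 20x20 matrix, got {s.shape}")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        ext = np.zeros((21, 21), dtype=np.int64)
        ext[:20, :20] = s
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "extended", ext)

    def score(self, a: str, b: str) -> int:
        return int(self.extended[_AA_TO_INDEX[a.upper()], _AA_TO_INDEX[b.upper()]])

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return cls.from_biopython("BLOSUM62")

    @classmethod
    def from_biopython(cls, name: str) -> "SubstitutionMatrix":
        arr = substitution_matrices.load(name)
        alpha = arr.alphabet
        idx = [alpha.index(aa) for aa in AMINO_ACIDS]
        scores = np.asarray(arr)[np.ix_(idx, idx)].astype(np.int64)
        return cls(scores=scores, name=name)

    @classmethod
    def from_ncbi_file(cls, path: str | Path) -> "SubstitutionMatrix":
        """Load a matrix from an NCBI-format substitution matrix text file."""
        with open(path) as handle:
            arr = substitution_matrices.read(handle)
        alpha = arr.alphabet
        idx = [alpha.index(aa) for aa in AMINO_ACIDS]
        scores = np.asarray(arr)[np.ix_(idx, idx)].astype(np.int64)
        return cls(scores=scores, name=Path(path).stem)


@dataclass(frozen=True)
class AlignedPair:
    """Result of a pairwise alignment: the gapped rows and the optimal score."""

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: int
    mode: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


def _fill_dp(
    S: np.ndarray,
    gap_open: int,
    gap_extend: int,
    local: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gotoh fill over a precomputed (n x m) pairwise score matrix ``S``.

    Returns H, M, Ix, Iy of shape (n+1, m+1).  Ix holds alignments ending
    with a gap in the column sequence (vertical move), Iy with a gap in the
    row sequence (horizontal move).
    """
    n, m = S.shape
    H = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)

    H[0, 0] = 0
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    if local:
        H[0, :] = 0
        H[:, 0] = 0
    else:
        H[0, 1:] = -(gap_open + j_idx * gap_extend)
        Iy[0, 1:] = H[0, 1:]
        i_col = np.arange(1, n + 1, dtype=np.int64)
        H[1:, 0] = -(gap_open + i_col * gap_extend)
        Ix[1:, 0] = H[1:, 0]

    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        M[i, 1:] = H[i - 1, :-1] + S[i - 1, :]
        Ix[i, 1:] = np.maximum(Ix[i - 1, 1:] - gap_extend, H[i - 1, 1:] - open_cost)
        # Horizontal gaps always open from a non-horizontal state; a prefix
        # max over A[k] + k*extend yields Iy for the whole row at once.
        A = np.maximum(M[i, :], Ix[i, :])
        if not local:
            A[0] = H[i, 0]
        else:
            A = np.maximum(A, 0)
        P = np.maximum.accumulate(A[:-1] + np.arange(m, dtype=np.int64) * gap_extend)
        Iy[i, 1:] = P - open_cost - (j_idx - 1) * gap_extend
        H[i, 1:] = np.maximum(np.maximum(M[i, 1:], Ix[i, 1:]), Iy[i, 1:])
        if local:
            H[i, 1:] = np.maximum(H[i, 1:], 0)
    return H, M, Ix, Iy


def _traceback(
    H: np.ndarray,
    M: np.ndarray,
    Ix: np.ndarray,
    Iy: np.ndarray,
    a: str,
    b: str,
    gap_open: int,
    gap_extend: int,
    local: bool,
) -> tuple[str, str, int, int]:
    """Deterministic traceback; tie-break diagonal > up > left.

    Returns (aligned_a, aligned_b, start_i, start_j) where the start indices
    are 0-based offsets of the first aligned residue (local mode).
    """
    def pick_state(ii: int, jj: int) -> str:
        h = H[ii, jj]
        if M[ii, jj] == h:
            return "M"
        if Ix[ii, jj] == h:
            return "Ix"
        return "Iy"

    if local:
        best = int(H.max())
        if best <= 0:
            return "", "", 0, 0
        i, j = (int(v) for v in np.argwhere(H == best)[0])
    else:
        i, j = H.shape[0] - 1, H.shape[1] - 1
    state = pick_state(i, j)

    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if local and H[i, j] <= 0:
            break
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
            if local and H[i, j] == 0:
                break  # the consumed match restarted the local alignment here
            state = pick_state(i, j)
        elif state == "Ix":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            from_extend = Ix[i, j] == Ix[i - 1, j] - gap_extend
            i -= 1
            state = "Ix" if from_extend else pick_state(i, j)
        else:  # Iy
            out_a.append(GAP)
            out_b.append(b[j - 1])
            from_extend = Iy[i, j] == Iy[i, j - 1] - gap_extend
            j -= 1
            state = "Iy" if from_extend else pick_state(i, j)
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def align_pair(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    mode: str = "global",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignedPair:
    """Optimal pairwise alignment under an affine gap model.

    mode="global" is Needleman-Wunsch with end gaps penalized;
    mode="local" is Smith-Waterman (an all-negative score yields the empty
    alignment with score 0).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    ea = encode_sequence(a)
    eb = encode_sequence(b)
    S = matrix.extended[np.ix_(ea, eb)]
    local = mode == "local"
    H, M, Ix, Iy = _fill_dp(S, gap_open, gap_extend, local)
    if local:
        score = int(max(H.max(), 0))
    else:
        score = int(H[-1, -1])
    aligned_a, aligned_b, _, _ = _traceback(
        H, M, Ix, Iy, a.upper(), b.upper(), gap_open, gap_extend, local
    )
    return AlignedPair(
        seq_a=a.upper(),
        seq_b=b.upper(),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        mode=mode,
    )


def percent_identity(pair: AlignedPair, convention: str = "shorter") -> float:
    """Fraction of identical aligned positions.

    convention="shorter": identical positions / length of the shorter input
    (BLASTCLUST-like).  convention="columns": identical positions / number
    of columns where both rows are non-gap.
    """
    ident = sum(
        x == y and x != GAP for x, y in zip(pair.aligned_a, pair.aligned_b)
    )
    if convention == "shorter":
        denom = min(len(pair.seq_a), len(pair.seq_b))
    elif convention == "columns":
        denom = sum(
            x != GAP and y != GAP for x, y in zip(pair.aligned_a, pair.aligned_b)
        )
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if denom == 0:
        raise ZeroDivisionError("zero-length denominator in percent identity")
    return ident / denom


def alignment_coverage(pair: AlignedPair) -> tuple[float, float]:
    """Mutually aligned residues as a fraction of each full sequence length."""
    both = sum(
        x != GAP and y != GAP for x, y in zip(pair.aligned_a, pair.aligned_b)
    )
    return both / len(pair.seq_a), both / len(pair.seq_b)


# ---------------------------------------------------------------------------
# multiple alignments


@dataclass(frozen=True)
class MultipleAlignment:
    member_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("empty alignment")
        if len(self.member_ids) != len(self.rows):
            raise ValueError("member_ids and rows differ in length")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("duplicate member ids")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def n_members(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def degapped(self, member_id: str) -> str:
        row = self.rows[self.member_ids.index(member_id)]
        return row.replace(GAP, "")

    def select_columns(self, indices: Sequence[int]) -> "MultipleAlignment":
        rows = tuple("".join(row[j] for j in indices) for row in self.rows)
        return MultipleAlignment(member_ids=self.member_ids, rows=rows)

    @classmethod
    def single(cls, member_id: str, seq: str) -> "MultipleAlignment":
        return cls(member_ids=(member_id,), rows=(seq.upper(),))


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-column consensus letter and homogeneity for a multiple alignment.

    Columns whose homogeneity falls below ``h_consensus`` carry the masked
    letter 'x'; all-gap columns carry '-' with homogeneity 0.
    """

    consensus: str
    homogeneity: np.ndarray
    source: MultipleAlignment
    h_consensus: float = 0.5

    def __post_init__(self) -> None:
        if len(self.consensus) != self.source.column_count:
            raise ValueError("consensus length != alignment columns")
        if len(self.homogeneity) != len(self.consensus):
            raise ValueError("homogeneity length != consensus length")

    def consensus_sequence(self) -> str:
        """The consensus with all-gap columns removed ('x' kept as X)."""
        return "".join(
            "X" if c == "x" else c for c in self.consensus if c != GAP
        )


def _column_counts(m: MultipleAlignment) -> np.ndarray:
    """(columns x 21) residue counts; gaps excluded."""
    counts = np.zeros((m.column_count, 21), dtype=np.int64)
    for row in m.rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, _AA_TO_INDEX[c.upper()]] += 1
    return counts


def column_homogeneity(
    counts_row: np.ndarray, k_star: int, matrix: SubstitutionMatrix
) -> float:
    """Homogeneity of one column given its residue counts and consensus index.

    H = clip((mean score of consensus vs column - expected random score) /
             (self score - expected random score), 0, 1).
    The random expectation is the consensus residue's mean score against a
    uniform residue distribution; a uniformly conserved column scores 1 and
    a random column scores ~0.
    """
    n = int(counts_row.sum())
    if n == 0:
        return 0.0
    if k_star == _X_INDEX:
        return 0.0
    row = matrix.extended[k_star]
    s_bar = float(row[:21] @ counts_row) / n
    s_self = float(matrix.scores[k_star, k_star])
    s_rand = float(matrix.scores[k_star, :].mean())
    if s_self <= s_rand:
        return 0.0
    return float(np.clip((s_bar - s_rand) / (s_self - s_rand), 0.0, 1.0))


def derive_consensus(
    m: MultipleAlignment,
    matrix: SubstitutionMatrix | None = None,
    h_consensus: float = 0.5,
) -> ConsensusProfile:
    """Per-column consensus residue and homogeneity.

    The consensus residue maximizes the sum of substitution scores against
    all non-gap residues in the column (ties broken alphabetically); columns
    below the homogeneity threshold are masked as 'x', all-gap columns as '-'.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    counts = _column_counts(m)
    # candidate consensus residues are the 20 standard amino acids
    sums = counts @ matrix.extended[:, :20]  # (columns x 20)
    k_star = np.argmax(sums, axis=1)  # first max = alphabetical tie-break
    letters = []
    homog = np.zeros(m.column_count, dtype=float)
    for j in range(m.column_count):
        n = counts[j].sum()
        if n == 0:
            letters.append(GAP)
            homog[j] = 0.0
            continue
        k = int(k_star[j])
        homog[j] = column_homogeneity(counts[j], k, matrix)
        letters.append("x" if homog[j] < h_consensus else AMINO_ACIDS[k])
    return ConsensusProfile(
        consensus="".join(letters),
        homogeneity=homog,
        source=m,
        h_consensus=h_consensus,
    )


@dataclass(frozen=True)
class FilteredAlignment:
    alignment: MultipleAlignment
    kept_columns: tuple[int, ...]
    empty: bool


def filter_alignment(
    m: MultipleAlignment,
    profile: ConsensusProfile,
    max_gap: float = 0.5,
    min_homog: float = 0.1,
) -> FilteredAlignment:
    """Retain columns with gap fraction < max_gap and homogeneity > min_homog.

    Column order is preserved and the index map back into the source
    alignment is returned.  An empty result sets a warning flag rather than
    raising.
    """
    if profile.source is not m and profile.source.rows != m.rows:
        raise ValueError("profile was not derived from this alignment")
    n = m.n_members
    kept = []
    for j in range(m.column_count):
        gaps = sum(row[j] == GAP for row in m.rows)
        if gaps / n < max_gap and profile.homogeneity[j] > min_homog:
            kept.append(j)
    empty = not kept
    if empty:
        warnings.warn("alignment filtering removed every column", stacklevel=2)
        alignment = m
    else:
        alignment = m.select_columns(kept)
    return FilteredAlignment(
        alignment=alignment, kept_columns=tuple(kept), empty=empty
    )


# ---------------------------------------------------------------------------
# position-specific profiles


@dataclass(frozen=True)
class ScoredProfile:
    """Position-specific scores derived from a multiple alignment.

    ``position_scores[i, r]`` is the mean substitution score of residue
    ``r`` against the non-gap residues in retained column ``i`` (all-gap
    columns are dropped at construction).  The mean, rather than the sum,
    keeps profile-vs-consensus scores on a comparable scale across clusters
    of different sizes, which matters for the score-ratio distances
    downstream.
    """

    position_scores: np.ndarray  # (L x 21) float
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        if self.position_scores.ndim != 2 or self.position_scores.shape[1] != 21:
            raise ValueError("position_scores must be (L x 21)")

    def __len__(self) -> int:
        return self.position_scores.shape[0]

    @classmethod
    def from_alignment(
        cls,
        m: MultipleAlignment,
        matrix: SubstitutionMatrix | None = None,
        gap_open: int = DEFAULT_GAP_OPEN,
        gap_extend: int = DEFAULT_GAP_EXTEND,
    ) -> "ScoredProfile":
        if matrix is None:
            matrix = SubstitutionMatrix.blosum62()
        counts = _column_counts(m)
        n = counts.sum(axis=1)
        keep = n > 0
        with np.errstate(invalid="ignore"):
            scores = (counts @ matrix.extended.T) / n[:, None]
        return cls(
            position_scores=scores[keep],
            gap_open=gap_open,
            gap_extend=gap_extend,
        )


def profile_score(p: ScoredProfile, s: str) -> float:
    """Best local profile-to-sequence alignment score under affine gaps."""
    if len(p) == 0:
        raise ValueError("empty profile")
    es = encode_sequence(s)
    S = p.position_scores[:, es]
    # integerize at 1e-6 resolution so the shared integer DP core applies
    S_int = np.rint(S * 1_000_000).astype(np.int64)
    H, _, _, _ = _fill_dp(S_int, p.gap_open * 1_000_000, p.gap_extend * 1_000_000, True)
    return max(float(H.max()), 0.0) / 1_000_000


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    """Write sequences as FASTA wrapped at 60 columns, ids verbatim."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in records.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(recs, handle, "fasta")


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    records = read_fasta(path)
    return MultipleAlignment(
        member_ids=tuple(records), rows=tuple(records.values())
    )


def write_alignment_fasta(path: str | Path, m: MultipleAlignment) -> None:
    write_fasta(path, dict(zip(m.member_ids, m.rows)))
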