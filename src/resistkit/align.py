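"""Exact global protein alignment with affine gap costs, and its two uses:
three-row (susceptible / resistant / reference) alignment construction and
best-hit reference-ortholog assignment.

The aligner is a Gotoh-style dynamic program over three states (match,
gap-in-b, gap-in-a) with a fixed, documented traceback tie-break so that the
whole pipeline is deterministic. A gap run of length L costs
``gap_open + gap_extend * (L - 1)``; terminal gaps are charged like internal
ones, which is deliberate: annotation-transfer truncations must surface as
low-scoring terminal gap runs for the downstream artifact filter to see.

Scores are integers throughout (BLOSUM-type matrices, integer gap costs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .core import ALPHABET, GAP, ProteinRecord, StrainProteome

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "TripleAlignment",
    "global_align",
    "global_align_score",
    "build_triple",
    "assign_reference_ortholog",
]

_NEG = np.int32(-(2**30))

# state codes used by the DP and its traceback
_M, _GB, _GA = 0, 1, 2  # diagonal, gap-in-b (consume a), gap-in-a (consume b)


def _blosum62_matrix() -> np.ndarray:
    """21x21 integer BLOSUM62 over ``ALPHABET``, with 'X' scoring 0 vs all.

    Unknown residues cannot evidence a shared (or differing) state, so 'X'
    is neutral rather than the mildly negative BLOSUM default.
    """
    raw = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0
            else:
                mat[i, j] = int(raw[a, b])
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    ``gap_open`` is the cost of the first gap column of a run and
    ``gap_extend`` the cost of each additional column.
    """

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        m = np.asarray(self.matrix)
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError(f"matrix must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")


_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows and the optimal global score."""

    row_a: str
    row_b: str
    score: int

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == GAP and cb == GAP:
                raise ValueError("all-gap column in pairwise alignment")


@dataclass(frozen=True)
class TripleAlignment:
    """Susceptible / resistant / reference rows over shared columns.

    With ``reference_present=False`` the reference row is all gaps and
    column classification treats the triple as two-way only.
    """

    transcript_id: str
    susceptible: str
    resistant: str
    reference: str
    reference_present: bool = True

    def __post_init__(self) -> None:
        if not (len(self.susceptible) == len(self.resistant) == len(self.reference)):
            raise ValueError("triple rows must have equal length")
        for cs, cr, cf in zip(self.susceptible, self.resistant, self.reference):
            if cs == cr == cf == GAP:
                raise ValueError("all-gap column in triple alignment")

    @property
    def n_columns(self) -> int:
        return len(self.susceptible)


@njit(cache=True)
def _fill_affine(a, b, S, o, e):  # pragma: no cover - exercised via global_align
    n, m = a.shape[0], b.shape[0]
    NEG = -(2**30)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    GB = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    GA = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pB = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pA = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        GB[i, 0] = -(o + e * (i - 1))
        pB[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        GA[0, j] = -(o + e * (j - 1))
        pA[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = S[ai, b[j - 1]]
            # diagonal state: predecessor priority M > GB > GA
            best = M[i - 1, j - 1]
            ptr = 0
            if GB[i - 1, j - 1] > best:
                best = GB[i - 1, j - 1]
                ptr = 1
            if GA[i - 1, j - 1] > best:
                best = GA[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            # gap-in-b state (consume a[i-1])
            best = M[i - 1, j] - o
            ptr = 0
            if GB[i - 1, j] - e > best:
                best = GB[i - 1, j] - e
                ptr = 1
            if GA[i - 1, j] - o > best:
                best = GA[i - 1, j] - o
                ptr = 2
            GB[i, j] = best
            pB[i, j] = ptr
            # gap-in-a state (consume b[j-1])
            best = M[i, j - 1] - o
            ptr = 0
            if GB[i, j - 1] - o > best:
                best = GB[i, j - 1] - o
                ptr = 1
            if GA[i, j - 1] - e > best:
                best = GA[i, j - 1] - e
                ptr = 2
            GA[i, j] = best
            pA[i, j] = ptr
    score = M[n, m]
    state = 0
    if GB[n, m] > score:
        score = GB[n, m]
        state = 1
    if GA[n, m] > score:
        score = GA[n, m]
        state = 2
    return score, state, pM, pB, pA


@njit(cache=True)
def _score_affine(a, b, S, o, e):  # pragma: no cover - exercised via callers
    """Score-only affine DP with linear memory (for best-hit search)."""
    n, m = a.shape[0], b.shape[0]
    NEG = -(2**30)
    M = np.full(m + 1, NEG, dtype=np.int64)
    GB = np.full(m + 1, NEG, dtype=np.int64)
    GA = np.full(m + 1, NEG, dtype=np.int64)
    M[0] = 0
    for j in range(1, m + 1):
        GA[j] = -(o + e * (j - 1))
    for i in range(1, n + 1):
        ai = a[i - 1]
        diagM, diagB, diagA = M[0], GB[0], GA[0]
        M[0] = NEG
        GB[0] = -(o + e * (i - 1))
        GA[0] = NEG
        for j in range(1, m + 1):
            upM, upB, upA = M[j], GB[j], GA[j]
            s = S[ai, b[j - 1]]
            best = diagM
            if diagB > best:
                best = diagB
            if diagA > best:
                best = diagA
            newM = best + s
            best = upM - o
            if upB - e > best:
                best = upB - e
            if upA - o > best:
                best = upA - o
            newB = best
            best = M[j - 1] - o
            if GB[j - 1] - o > best:
                best = GB[j - 1] - o
            if GA[j - 1] - e > best:
                best = GA[j - 1] - e
            newA = best
            diagM, diagB, diagA = upM, upB, upA
            M[j], GB[j], GA[j] = newM, newB, newA
    score = M[m]
    if GB[m] > score:
        score = GB[m]
    if GA[m] > score:
        score = GA[m]
    return score


def global_align(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Traceback ties resolve diagonal first, then gap-in-b (gap character in
    ``row_b``), then gap-in-a, making the reported alignment unique.
    Either side may be empty, producing an all-gap row.
    """
    scheme = scheme or default_scheme()
    if not a and not b:
        return PairwiseAlignment(row_a="", row_b="", score=0)
    if not a:
        return PairwiseAlignment(
            row_a=GAP * len(b), row_b=b,
            score=-(scheme.gap_open + scheme.gap_extend * (len(b) - 1)),
        )
    if not b:
        return PairwiseAlignment(
            row_a=a, row_b=GAP * len(a),
            score=-(scheme.gap_open + scheme.gap_extend * (len(a) - 1)),
        )
    ea, eb = _encode(a), _encode(b)
    score, state, pM, pB, pA = _fill_affine(
        ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    ptrs = (pM, pB, pA)
    while i > 0 or j > 0:
        prev = int(ptrs[state][i, j])
        if state == _M:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == _GB:
            ra.append(a[i - 1])
            rb.append(GAP)
            i -= 1
        else:
            ra.append(GAP)
            rb.append(b[j - 1])
            j -= 1
        state = prev
    return PairwiseAlignment(row_a="".join(reversed(ra)), row_b="".join(reversed(rb)),
                             score=int(score))


def global_align_score(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> int:
    """Optimal global alignment score only (linear memory)."""
    scheme = scheme or default_scheme()
    if not a or not b:
        return global_align(a, b, scheme).score
    return int(
        _score_affine(_encode(a), _encode(b), scheme.matrix, scheme.gap_open, scheme.gap_extend)
    )


_DEFAULT: list[ScoringScheme] = []


def default_scheme() -> ScoringScheme:
    """The package-wide default scheme: BLOSUM62 with gap open 11, extend 1."""
    if not _DEFAULT:
        _DEFAULT.append(ScoringScheme())
    return _DEFAULT[0]


def _merge_on_anchor(
    anchor_res: str, other_res: str, anchor_ref: str, other_ref: str
) -> tuple[str, str, str]:
    """Merge two pairwise alignments sharing the anchor (susceptible) sequence.

    Columns where one alignment opened an anchor gap get a gap inserted into
    the non-participating row; when both alignments insert at the same anchor
    position, the resistant-side insertion is emitted first (deterministic).
    """
    sus: list[str] = []
    res: list[str] = []
    ref: list[str] = []
    i = j = 0
    la, lb = len(anchor_res), len(anchor_ref)
    while i < la or j < lb:
        if i < la and anchor_res[i] == GAP:
            sus.append(GAP)
            res.append(other_res[i])
            ref.append(GAP)
            i += 1
        elif j < lb and anchor_ref[j] == GAP:
            sus.append(GAP)
            res.append(GAP)
            ref.append(other_ref[j])
            j += 1
        else:
            sus.append(anchor_res[i])
            res.append(other_res[i])
            ref.append(other_ref[j])
            i += 1
            j += 1
    return "".join(sus), "".join(res), "".join(ref)


def build_triple(
    susceptible: str,
    resistant: str,
    reference: Optional[str],
    scheme: Optional[ScoringScheme] = None,
    transcript_id: str = "",
) -> TripleAlignment:
    """Three-row alignment anchored on the susceptible sequence.

    Resistant and (when present) reference are each globally aligned to the
    susceptible anchor, then merged on anchor positions. With no reference
    the third row is all gaps and ``reference_present`` is False.
    """
    if not susceptible:
        raise ValueError("susceptible anchor sequence must be non-empty")
    scheme = scheme or default_scheme()
    aln_res = global_align(susceptible, resistant, scheme)
    if reference is None:
        return TripleAlignment(
            transcript_id=transcript_id,
            susceptible=aln_res.row_a,
            resistant=aln_res.row_b,
            reference=GAP * len(aln_res.row_a),
            reference_present=False,
        )
    aln_ref = global_align(susceptible, reference, scheme)
    sus, res, ref = _merge_on_anchor(aln_res.row_a, aln_res.row_b, aln_ref.row_a, aln_ref.row_b)
    return TripleAlignment(
        transcript_id=transcript_id,
        susceptible=sus,
        resistant=res,
        reference=ref,
        reference_present=True,
    )


def assign_reference_ortholog(
    query: ProteinRecord,
    candidates: StrainProteome,
    scheme: Optional[ScoringScheme] = None,
    min_score: int = 0,
) -> Optional[str]:
    """Best-hit ortholog: candidate with the maximum global alignment score.

    Ties break to the lexicographically smallest transcript ID; returns None
    for an empty candidate set or when the best score is <= ``min_score``.
    """
    scheme = scheme or default_scheme()
    best_id: Optional[str] = None
    best_score = None
    for tid in candidates.ids():
        s = global_align_score(query.sequence, candidates[tid].sequence, scheme)
        if best_score is None or s > best_score:
            best_id, best_score = tid, s
    if best_id is None or best_score <= min_score:
        return None
    return best_id
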