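"""Deterministic global pairwise alignment with affine gaps.

This is the geometric substrate for signature reading: every signature call
starts from a true global (end-gap penalized) Needleman--Wunsch alignment of a
query against the designated reference, after which reference coordinates are
mapped onto the query through the alignment columns.

Conventions (fixed for bit-reproducibility):

* a gap of length L costs ``gap_open + (L - 1) * gap_extend`` (both negative);
* end gaps are penalized — fragments are handled downstream through the
  covered/deleted/uncovered distinction, not through score leniency;
* traceback precedence is diagonal > up (gap in query) > left (gap in ref).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import ProteinRecord

__all__ = [
    "AlignParams",
    "Alignment",
    "PositionEvidence",
    "global_align",
    "map_reference_positions",
    "percent_identity",
]

_NEG = -1e30


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global alignment.

    Either a named builtin substitution matrix (default BLOSUM62) or a simple
    match/mismatch scheme (set ``matrix=None``). Gap scores are negative; a
    length-L gap costs ``gap_open + (L-1) * gap_extend``.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -11.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment between a reference and a query."""

    ref_id: str
    query_id: str
    ref_aln: str
    query_aln: str
    score: float
    identity: float
    aligned_pairs: int

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.query_aln):
            raise ValueError("aligned strings differ in length")


@dataclass(frozen=True)
class PositionEvidence:
    """What the query shows at one 1-based reference position.

    ``covered``   — the query has a residue aligned to the position;
    ``deleted``   — the position falls inside the query's aligned span but the
                    query has a gap there (internal deletion);
    ``uncovered`` — the position lies outside the query's aligned span
                    (fragment truncation).
    """

    ref_position: int
    status: Literal["covered", "uncovered", "deleted"]
    observed_residue: str | None = None

    def __post_init__(self) -> None:
        if (self.observed_residue is not None) != (self.status == "covered"):
            raise ValueError("observed_residue must be set iff status is 'covered'")


@lru_cache(maxsize=8)
def _scoring(params: AlignParams) -> tuple[str, np.ndarray]:
    """Return (alphabet, score matrix) for a parameter set."""
    if params.matrix is not None:
        m = substitution_matrices.load(params.matrix)
        return str(m.alphabet), np.asarray(m, dtype=np.float64)
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    n = len(alphabet)
    s = np.full((n, n), params.mismatch, dtype=np.float64)
    np.fill_diagonal(s, params.match)
    return alphabet, s


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(alphabet)}
    try:
        return np.array([lut[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in scoring alphabet") from exc


@njit(cache=False)
def _affine_dp(a, b, S, open_, ext):  # pragma: no cover - exercised via global_align
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in query: consumes ref (up)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in ref: consumes query (left)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, X[i, j - 1] + open_, Y[i, j - 1] + ext)
    return M, X, Y


def _traceback(a: str, b: str, M, X, Y, open_: float, ext: float) -> tuple[str, str]:
    """Reconstruct one optimal alignment, precedence diagonal > up > left."""
    i, j = len(a), len(b)
    # state: 0 = M (diag), 1 = X (up, gap in query), 2 = Y (left, gap in ref)
    vals = (M[i, j], X[i, j], Y[i, j])
    state = 0 if vals[0] >= vals[1] and vals[0] >= vals[2] else (1 if vals[1] >= vals[2] else 2)
    ra: list[str] = []
    qa: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ra.append(a[i - 1])
            qa.append(b[j - 1])
            i, j = i - 1, j - 1
            prev = (M[i, j], X[i, j], Y[i, j])
            best = max(prev)
            state = 0 if prev[0] == best else (1 if prev[1] == best else 2)
        elif state == 1:
            ra.append(a[i - 1])
            qa.append("-")
            v = X[i, j]
            i -= 1
            if M[i, j] + open_ == v:
                state = 0
            elif X[i, j] + ext == v:
                state = 1
            else:
                state = 2
        else:
            ra.append("-")
            qa.append(b[j - 1])
            v = Y[i, j]
            j -= 1
            if M[i, j] + open_ == v:
                state = 0
            elif Y[i, j] + ext == v:
                state = 2
            else:
                state = 1
    return "".join(reversed(ra)), "".join(reversed(qa))


def global_align(
    ref: ProteinRecord, query: ProteinRecord, params: AlignParams = AlignParams()
) -> Alignment:
    """Optimal global alignment of ``query`` against ``ref``.

    True global alignment under affine gap penalties with end gaps penalized;
    the traceback is deterministic (diagonal > up > left among co-optimal
    moves). Raises ``ValueError`` for empty sequences.
    """
    if not ref.sequence or not query.sequence:
        raise ValueError("cannot align empty sequences")
    alphabet, S = _scoring(params)
    a = _encode(ref.sequence, alphabet)
    b = _encode(query.sequence, alphabet)
    M, X, Y = _affine_dp(a, b, S, params.gap_open, params.gap_extend)
    n, m = len(a), len(b)
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    ra, qa = _traceback(ref.sequence, query.sequence, M, X, Y,
                        params.gap_open, params.gap_extend)
    pairs = sum(1 for x, y in zip(ra, qa) if x != "-" and y != "-")
    ident = sum(1 for x, y in zip(ra, qa) if x != "-" and x == y)
    identity = 100.0 * ident / pairs if pairs else float("nan")
    return Alignment(
        ref_id=ref.id,
        query_id=query.id,
        ref_aln=ra,
        query_aln=qa,
        score=score,
        identity=identity,
        aligned_pairs=pairs,
    )


def percent_identity(aln: Alignment) -> float:
    """100 x identical columns / aligned (residue-residue) columns."""
    if aln.aligned_pairs < 1:
        raise ValueError(
            f"no aligned residue pairs between {aln.ref_id!r} and {aln.query_id!r}"
        )
    ident = sum(
        1 for x, y in zip(aln.ref_aln, aln.query_aln) if x != "-" and x == y
    )
    return 100.0 * ident / aln.aligned_pairs


def map_reference_positions(
    aln: Alignment, positions: Sequence[int]
) -> list[PositionEvidence]:
    """Locate 1-based reference positions in the alignment and read the query.

    A position is ``covered`` when the query has a residue in its column,
    ``deleted`` when the query gaps it inside its aligned span, ``uncovered``
    when the column lies outside the query's first..last residue columns.
    """
    ref_len = sum(1 for c in aln.ref_aln if c != "-")
    col_of: dict[int, int] = {}
    pos = 0
    for col, c in enumerate(aln.ref_aln):
        if c != "-":
            pos += 1
            col_of[pos] = col
    q_cols = [col for col, c in enumerate(aln.query_aln) if c != "-"]
    first_q = q_cols[0] if q_cols else None
    last_q = q_cols[-1] if q_cols else None

    out: list[PositionEvidence] = []
    for p in positions:
        if not 1 <= p <= ref_len:
            raise ValueError(f"reference position {p} out of range 1..{ref_len}")
        col = col_of[p]
        q = aln.query_aln[col]
        if q != "-":
            out.append(PositionEvidence(ref_position=p, status="covered", observed_residue=q))
        elif first_q is not None and first_q <= col <= last_q:
            out.append(PositionEvidence(ref_position=p, status="deleted"))
        else:
            out.append(PositionEvidence(ref_position=p, status="uncovered"))
    return out
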