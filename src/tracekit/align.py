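"""Affine-gap dynamic programming over nucleotide profiles.

A profile is a columns x 6 weight matrix over (A, C, G, T, N, gap); a plain
sequence is the special case of one-hot columns.  Alignment uses the Gotoh
three-state recursion (match/mismatch, gap in the first row, gap in the
second row) with an affine gap cost ``gap_open + k * gap_extend`` for a gap
of length k.  Three end-gap policies are supported:

global
    end gaps penalized in both rows.
semiglobal
    leading/trailing overhangs of the *second* input (the reference or the
    growing MSA) are free; the first input must align end to end.
overlap
    overhangs free on both inputs (dovetail alignment of reads).

Column-vs-column substitution score is the weight-weighted expectation of
the base-vs-base scores; 'N' scores 0 against everything, and gap mass
contributes nothing to substitution but scales the gap penalties of the
column it sits in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .iupac import BASES, expand_iupac, iupac_code, is_iupac

NEG = -1.0e18
_ROW_ORDER = "ACGTN-"
_ROW_INDEX = {b: i for i, b in enumerate(_ROW_ORDER)}


@dataclass(frozen=True)
class Scoring:
    """Substitution and affine gap parameters (EDNAFULL-like defaults)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def base_matrix(self) -> np.ndarray:
        """5x5 score matrix over (A, C, G, T, N); N is neutral (0)."""
        m = np.full((5, 5), self.mismatch)
        np.fill_diagonal(m, self.match)
        m[4, :] = 0.0
        m[:, 4] = 0.0
        return m


class Profile:
    """Per-column nucleotide weight matrix over (A, C, G, T, N, gap)."""

    def __init__(self, weights: np.ndarray):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 6 or w.shape[0] < 1:
            raise AlignmentError("profile must be a columns x 6 matrix")
        if np.any(w < 0):
            raise AlignmentError("profile weights must be non-negative")
        sums = w.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise AlignmentError("profile columns must sum to 1")
        self.weights = w

    def __len__(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_sequence(cls, seq: str) -> "Profile":
        """One-hot profile from a sequence (ambiguity letters split equally)."""
        if not seq:
            raise AlignmentError("empty alignment input")
        w = np.zeros((len(seq), 6))
        for i, ch in enumerate(seq.upper()):
            if ch in _ROW_INDEX and ch != "-":
                w[i, _ROW_INDEX[ch]] = 1.0
            elif is_iupac(ch):
                bases = expand_iupac(ch)
                w[i, [_ROW_INDEX[b] for b in bases]] = 1.0 / len(bases)
            else:
                raise AlignmentError(f"invalid sequence symbol {ch!r}")
        return cls(w)

    @classmethod
    def from_basecalls(cls, result, trim) -> "Profile":
        """Profile over the kept basecalls; weight split across the bases
        encoded by each consensus IUPAC call ('N' -> 0.25 on each base)."""
        if trim.empty:
            raise AlignmentError("empty profile")
        cols = []
        for i in range(trim.keep_start, trim.keep_end):
            c = result.consensus[i]
            w = np.zeros(6)
            if c == "N":
                w[:4] = 0.25
            else:
                bases = expand_iupac(c)
                w[[_ROW_INDEX[b] for b in bases]] = 1.0 / len(bases)
            cols.append(w)
        return cls(np.array(cols))

    @classmethod
    def from_msa_rows(cls, rows) -> "Profile":
        """Column frequencies of a gapped MSA (rows of equal length)."""
        if not rows or not rows[0]:
            raise AlignmentError("empty alignment input")
        L = len(rows[0])
        w = np.zeros((L, 6))
        for row in rows:
            if len(row) != L:
                raise AlignmentError("MSA rows must have equal length")
            for i, ch in enumerate(row.upper()):
                if ch == "-":
                    w[i, 5] += 1.0
                elif ch == "N":
                    w[i, :4] += 0.25
                elif ch in _ROW_INDEX:
                    w[i, _ROW_INDEX[ch]] += 1.0
                else:
                    bases = expand_iupac(ch)
                    for b in bases:
                        w[i, _ROW_INDEX[b]] += 1.0 / len(bases)
        w /= w.sum(axis=1, keepdims=True)
        return cls(w)

    def reverse_complement(self) -> "Profile":
        w = self.weights[::-1][:, [3, 2, 1, 0, 4, 5]].copy()
        return Profile(w)

    def consensus_letters(self, tol: float = 0.01) -> str:
        """One IUPAC letter (or '-') per column for textual rendering."""
        out = []
        for w in self.weights:
            bases = {BASES[k] for k in range(4) if w[k] > tol}
            if bases:
                out.append(iupac_code(bases))
            elif w[4] > tol:
                out.append("N")
            else:
                out.append("-")
        return "".join(out)


@dataclass
class PairwiseAlignment:
    """Result of a pairwise (profile) alignment.

    ``path`` lists one (i, j) pair per alignment column; ``None`` marks a
    gap in that row.  ``rows`` are the rendered gapped strings.
    """

    rows: tuple
    score: float
    mode: str
    path: list
    start1: int = 0
    end1: int = 0
    start2: int = 0
    end2: int = 0

    def __len__(self):
        return len(self.path)

    def identity_columns(self) -> str:
        """Clustal-style match line ('*' where the two rows agree)."""
        return "".join("*" if a == b and a != "-" else " "
                       for a, b in zip(*self.rows))


def _affine_dp(Wp: np.ndarray, Wq: np.ndarray, scoring: Scoring, mode: str):
    """Gotoh DP between two weight matrices; returns (score, path)."""
    if mode not in ("global", "semiglobal", "overlap"):
        raise AlignmentError(f"unknown alignment mode {mode!r}")
    m, n = Wp.shape[0], Wq.shape[0]
    B5 = scoring.base_matrix()
    Ssub = Wp[:, :5] @ B5 @ Wq[:, :5].T

    wp = Wp[:, :5].sum(axis=1)
    wq = Wq[:, :5].sum(axis=1)
    go_p = (scoring.gap_open + scoring.gap_extend) * wp  # open at p column i
    ge_p = scoring.gap_extend * wp
    go_q = (scoring.gap_open + scoring.gap_extend) * wq
    ge_q = scoring.gap_extend * wq
    Gq = np.concatenate(([0.0], np.cumsum(ge_q)))  # cumulative extension cost

    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in q row (consuming p)
    Y = np.full((m + 1, n + 1), NEG)  # gap in p row (consuming q)

    M[0, 0] = 0.0
    if mode in ("semiglobal", "overlap"):
        M[0, :] = 0.0
    if mode == "overlap":
        M[:, 0] = 0.0
    if mode == "global":
        # boundary gap states
        for i in range(1, m + 1):
            X[i, 0] = (M[i - 1, 0] + go_p[i - 1]) if i == 1 else X[i - 1, 0] + ge_p[i - 1]
        y = 0.0
        for j in range(1, n + 1):
            y = (M[0, 0] + go_q[j - 1]) if j == 1 else y + ge_q[j - 1]
            Y[0, j] = y
    elif mode == "semiglobal":
        for i in range(1, m + 1):
            X[i, 0] = (M[i - 1, 0] + go_p[i - 1]) if i == 1 else X[i - 1, 0] + ge_p[i - 1]

    for i in range(1, m + 1):
        pm, px, py = M[i - 1], X[i - 1], Y[i - 1]
        X[i, 1:] = np.maximum(np.maximum(pm[1:], py[1:]) + go_p[i - 1],
                              px[1:] + ge_p[i - 1])
        M[i, 1:] = Ssub[i - 1] + np.maximum.reduce([pm[:-1], px[:-1], py[:-1]])
        # horizontal gap state via prefix-max scan:
        # Y[i,j] = max_{k<=j} (opening value at k + extensions over (k, j])
        cand = np.empty(n + 1)
        cand[0] = Y[i, 0]
        cand[1:] = np.maximum(M[i, :-1], X[i, :-1]) + go_q
        Y[i, 1:] = Gq[1:] + np.maximum.accumulate(cand - Gq)[1:]

    # endpoint selection
    if mode == "global":
        i0, j0 = m, n
        state = _best_state(M[m, n], X[m, n], Y[m, n])
        score = (M[m, n], X[m, n], Y[m, n])[state]
        trailing = []
    elif mode == "semiglobal":
        row_best = np.maximum.reduce([M[m], X[m], Y[m]])
        j0 = int(n - np.argmax(row_best[::-1]))  # prefer largest j on ties
        state = _best_state(M[m, j0], X[m, j0], Y[m, j0])
        score = row_best[j0]
        i0 = m
        trailing = [(None, j) for j in range(j0, n)]
    else:  # overlap
        row_best = np.maximum.reduce([M[m], X[m], Y[m]])
        col_best = np.maximum.reduce([M[:, n], X[:, n], Y[:, n]])
        jr = int(n - np.argmax(row_best[::-1]))
        ic = int(m - np.argmax(col_best[::-1]))
        if row_best[jr] >= col_best[ic]:
            i0, j0 = m, jr
            trailing = [(None, j) for j in range(jr, n)]
        else:
            i0, j0 = ic, n
            trailing = [(i, None) for i in range(ic, m)]
        state = _best_state(M[i0, j0], X[i0, j0], Y[i0, j0])
        score = max(row_best[jr], col_best[ic])

    path = _traceback(M, X, Y, Ssub, go_p, ge_p, go_q, ge_q, mode,
                      i0, j0, state)
    path.extend(trailing)
    return float(score), path


def _best_state(vm, vx, vy):
    """0=M (diagonal), 1=X (up), 2=Y (left); earlier wins ties."""
    best = max(vm, vx, vy)
    for s, v in enumerate((vm, vx, vy)):
        if v >= best - 1e-9:
            return s
    return 0


def _traceback(M, X, Y, Ssub, go_p, ge_p, go_q, ge_q, mode, i, j, state):
    rev = []
    while True:
        if state == 0:  # M
            if i == 0 and j == 0:
                break
            if i == 0:  # free leading q columns (semiglobal/overlap)
                rev.extend((None, jj) for jj in range(j - 1, -1, -1))
                break
            if j == 0:  # free leading p columns (overlap)
                rev.extend((ii, None) for ii in range(i - 1, -1, -1))
                break
            rev.append((i - 1, j - 1))
            state = _best_state(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
        elif state == 1:  # X: gap in q row, consumed p column i-1
            rev.append((i - 1, None))
            cm = M[i - 1, j] + go_p[i - 1]
            cx = X[i - 1, j] + ge_p[i - 1]
            cy = Y[i - 1, j] + go_p[i - 1]
            state = _best_state(cm, cx, cy)
            i -= 1
        else:  # Y: gap in p row, consumed q column j-1
            rev.append((None, j - 1))
            cm = M[i, j - 1] + go_q[j - 1]
            cx = X[i, j - 1] + go_q[j - 1]
            cy = Y[i, j - 1] + ge_q[j - 1]
            state = _best_state(cm, cx, cy)
            j -= 1
    rev.reverse()
    return rev


def _render(path, letters1, letters2):
    r1 = "".join("-" if i is None else letters1[i] for i, _ in path)
    r2 = "".join("-" if j is None else letters2[j] for _, j in path)
    return r1, r2


def _offsets(path):
    i_cons = [i for i, _ in path if i is not None]
    j_cons = [j for _, j in path if j is not None]
    s1, e1 = (i_cons[0], i_cons[-1] + 1) if i_cons else (0, 0)
    s2, e2 = (j_cons[0], j_cons[-1] + 1) if j_cons else (0, 0)
    return s1, e1, s2, e2


def align_profile_to_sequence(p: Profile, s: str, mode: str = "global",
                              scoring: Scoring = Scoring()) -> PairwiseAlignment:
    """Align a profile (first row) to a plain sequence (second row)."""
    if len(p) == 0 or not s:
        raise AlignmentError("empty alignment input")
    q = Profile.from_sequence(s)
    score, path = _affine_dp(p.weights, q.weights, scoring, mode)
    rows = _render(path, p.consensus_letters(), s.upper())
    aln = PairwiseAlignment(rows, score, mode, path, *_offsets(path))
    return aln


def align_profile_to_profile(p: Profile, q: Profile, mode: str = "global",
                             scoring: Scoring = Scoring()) -> PairwiseAlignment:
    """Align two profiles (e.g. a trace against a growing MSA)."""
    if len(p) == 0 or len(q) == 0:
        raise AlignmentError("empty alignment input")
    score, path = _affine_dp(p.weights, q.weights, scoring, mode)
    rows = _render(path, p.consensus_letters(), q.consensus_letters())
    return PairwiseAlignment(rows, score, mode, path, *_offsets(path))


def align_sequences(a: str, b: str, mode: str = "global",
                    scoring: Scoring = Scoring()) -> PairwiseAlignment:
    """Plain sequence-to-sequence alignment (one-hot profiles)."""
    aln = align_profile_to_sequence(Profile.from_sequence(a), b, mode, scoring)
    r2 = aln.rows[1]
    r1 = "".join("-" if i is None else a.upper()[i] for i, _ in aln.path)
    aln.rows = (r1, r2)
    return aln
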