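"""Independent reference implementations used as test oracles.

These are deliberately written in a different style from the package code
(top-down memoized recursion over edit operations, end-freedom by explicit
clipping, plus a full enumeration of alignments at tiny lengths) so that
agreement with the package's vectorized Gotoh DP is meaningful.
"""

from __future__ import annotations

from functools import lru_cache


def _global_recursive(a: str, b: str, match, mismatch, gap_open, gap_extend):
    @lru_cache(maxsize=None)
    def best(i, j, last):
        # optimal score aligning a[:i] with b[:j]; `last` is the operation
        # of the column immediately to the right (affine continuation)
        if i == 0 and j == 0:
            return 0.0
        cands = []
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            cands.append(best(i - 1, j - 1, "D") + s)
        if i > 0:
            step = gap_extend if last == "U" else gap_open + gap_extend
            cands.append(best(i - 1, j, "U") + step)
        if j > 0:
            step = gap_extend if last == "L" else gap_open + gap_extend
            cands.append(best(i, j - 1, "L") + step)
        return max(cands)

    return best(len(a), len(b), None)


def affine_score_recursive(a: str, b: str, mode: str,
                           match=5.0, mismatch=-4.0,
                           gap_open=-10.0, gap_extend=-1.0) -> float:
    """Optimal affine-gap score; end freedom realized by explicit clipping.

    global     — both sequences consumed end to end, all gaps charged.
    semiglobal — b's overhangs free: max over global(a, b[j0:j1]).
    overlap    — overhangs free on both (never clipping both sequences at
                 the same end, which an optimal overlap never needs).
    """
    args = (match, mismatch, gap_open, gap_extend)
    la, lb = len(a), len(b)
    if mode == "global":
        return _global_recursive(a, b, *args)
    if mode == "semiglobal":
        return max(_global_recursive(a, b[j0:j1], *args)
                   for j0 in range(lb + 1) for j1 in range(j0, lb + 1))
    if mode == "overlap":
        best = float("-inf")
        for i0 in range(la + 1):
            for i1 in range(i0, la + 1):
                for j0 in range(lb + 1):
                    for j1 in range(j0, lb + 1):
                        if i0 > 0 and j0 > 0:
                            continue
                        if i1 < la and j1 < lb:
                            continue
                        best = max(best, _global_recursive(
                            a[i0:i1], b[j0:j1], *args))
        return best
    raise ValueError(mode)


def enumerate_alignments_best(a: str, b: str,
                              match=5.0, mismatch=-4.0,
                              gap_open=-10.0, gap_extend=-1.0) -> float:
    """Global score by explicit enumeration of every alignment (tiny inputs).

    An alignment is a sequence of columns (D/U/L, no gap-in-both) scored
    with affine gap runs.  Exponential — keep len(a), len(b) <= 4.
    """
    best = [float("-inf")]

    def walk(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, "D", score + s)
        if i < len(a):
            step = gap_extend if last == "U" else gap_open + gap_extend
            walk(i + 1, j, "U", score + step)
        if j < len(b):
            step = gap_extend if last == "L" else gap_open + gap_extend
            walk(i, j + 1, "L", score + step)

    walk(0, 0, None, 0.0)
    return best[0]


def naive_locate(text: str, pattern: str):
    """All 0-based occurrences of pattern in text by scanning."""
    hits = []
    start = 0
    while True:
        k = text.find(pattern, start)
        if k < 0:
            return hits
        hits.append(k)
        start = k + 1


def left_align_shift(refseq: str, pos0: int, ref: str, alt: str):
    """Left-align an anchored variant by exhaustive single-base shifting."""
    pos, r, a = pos0, ref, alt
    while True:
        if len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        elif r[-1] == a[-1] and len(r) != len(a) and pos > 0:
            prev = refseq[pos - 1]
            r, a = prev + r[:-1], prev + a[:-1]
            pos -= 1
        else:
            return pos, r, a
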