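"""Deconvolution of mixed diploid chromatograms and variant calling.

A heterozygous indel desynchronizes the two alleles of a PCR product: from
the edit onward every basecall interval carries two superimposed peaks, one
from each allele, visible as a dense run of secondary basecalls.  The
decomposition threads the reference through the primary/secondary calls at
every candidate indel offset d (negative = deletion): at offset d, trace
basecall i is compared with the reference base shifted by -d, and the
fraction of positions where *neither* call matches is the decomposition
error.  Threading at the true offset of either allele consumes a matching
call almost everywhere, so the error curve has local minima exactly at the
allele indel sizes (0 for a reference-length allele).  The two
smallest-error local minima pick the two alleles; the reference-consistent
calls form allele 1 and the remaining calls allele 2.  Allelic fractions
are recovered by a constrained least-squares reconstruction of the observed
peak heights from the two allele base patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import PairwiseAlignment, Scoring, align_sequences
from .basecalling import BasecallResult
from .chromatogram import Chromatogram
from .errors import DecompositionError
from .iupac import BASES, expand_iupac
from .trace_alignment import AlignedTrace
from .variants import VariantRecord, call_variants, normalize_variant, write_vcf

BREAKPOINT_WINDOW = 15
BREAKPOINT_HIGH = 0.4  # het fraction inside the window
BREAKPOINT_LOW = 0.1   # het fraction allowed before the breakpoint
MIN_POST_BREAKPOINT = 10
MIN_THREAD_POSITIONS = 10


def find_breakpoint(result: BasecallResult, aligned: AlignedTrace,
                    window: int = BREAKPOINT_WINDOW,
                    high: float = BREAKPOINT_HIGH,
                    low: float = BREAKPOINT_LOW):
    """First basecall index where dense secondary calls begin, or None.

    Looks for the smallest b whose forward window of `window` calls is more
    than `high` heterozygous while the prefix before b stays below `low` —
    the signature of a heterozygous indel, as opposed to isolated het SNVs.
    """
    het = result.het_mask().astype(float)
    B = len(het)
    if B < window:
        return None
    cum = np.concatenate(([0.0], np.cumsum(het)))
    for b in range(0, B - window + 1):
        frac_win = (cum[b + window] - cum[b]) / window
        frac_pre = cum[b] / b if b > 0 else 0.0
        if frac_win > high and frac_pre < low:
            return b
    return None


@dataclass
class DecompositionResult:
    """Two inferred alleles plus the evidence that selected them."""

    allele1: str
    allele2: str
    error_curve: dict           # indel offset (bp) -> error fraction
    selected_offsets: list      # up to 2 offsets, allele1's first
    breakpoint: int | None
    degenerate: bool = False
    fractions: tuple | None = None
    aln_allele1_ref: PairwiseAlignment | None = None
    aln_allele2_ref: PairwiseAlignment | None = None
    aln_allele1_allele2: PairwiseAlignment | None = None
    reference_window: str = ""
    window_start: int = 0       # window-local coord of reference_window[0]
    basecall_index: np.ndarray | None = None  # basecall per allele position

    @property
    def indel_offset(self):
        """The non-zero selected offset, or 0 when both alleles are
        reference-length."""
        nz = [d for d in self.selected_offsets if d != 0]
        return nz[0] if nz else 0


def _accept_sets(result: BasecallResult):
    """Per basecall, the set of bases supported by primary or secondary."""
    acc = np.zeros((result.n_basecalls, 4), dtype=bool)
    for i, (p, s) in enumerate(zip(result.primary, result.secondary)):
        if p in BASES:
            acc[i, BASES.index(p)] = True
        for b in expand_iupac(s) if s != p else ():
            acc[i, BASES.index(b)] = True
    return acc


def _ref_pos_of_breakpoint(aligned: AlignedTrace, b: int) -> int:
    """Window-local reference coordinate of basecall b (extrapolated when
    the basecall itself is unaligned)."""
    mapped = aligned.basecall_to_ref()
    idx = np.flatnonzero(mapped >= 0)
    if len(idx) == 0:
        raise DecompositionError("trace not aligned to reference")
    before = idx[idx <= b]
    anchor = int(before[-1]) if len(before) else int(idx[0])
    return int(mapped[anchor]) + (b - anchor)


def decompose_trace(result: BasecallResult, aligned: AlignedTrace,
                    reference_window: str, maxindel: int = 1000,
                    window_start: int = 0) -> DecompositionResult:
    """Split a mixed trace into two alleles via the decomposition-error curve.

    ``reference_window`` must cover the aligned trace plus up to ``maxindel``
    of flank where the reference provides it; ``window_start`` gives the
    window-local coordinate (in ``aligned.reference_seq`` space) of
    ``reference_window[0]`` (negative when the window extends left of the
    aligned region).
    """
    reference_window = reference_window.upper()
    B = result.n_basecalls
    acc = _accept_sets(result)
    het = result.het_mask()
    bp = find_breakpoint(result, aligned)

    if bp is None:
        return _decompose_snv_only(result, aligned, reference_window,
                                   window_start, acc, het)

    if B - bp < MIN_POST_BREAKPOINT:
        raise DecompositionError("insufficient signal after breakpoint")

    r_b = _ref_pos_of_breakpoint(aligned, bp)

    # --- error curve -------------------------------------------------
    RW = np.frombuffer(reference_window.encode(), dtype=np.uint8)
    base_code = np.full(256, -1, dtype=np.int64)
    for c, b_ in enumerate(BASES):
        base_code[ord(b_)] = c
    rw_codes = base_code[RW]  # -1 for N/other: matches nothing

    pos = np.arange(bp, B)
    offsets = np.arange(-maxindel, maxindel + 1)
    # window-local index of the reference base compared with basecall i at
    # offset d: r_b + (i - bp) - d, expressed in reference_window coords
    ridx = (r_b + (pos - bp))[:, None] - offsets[None, :] - window_start
    valid = (ridx >= 0) & (ridx < len(RW))
    codes = rw_codes[np.clip(ridx, 0, len(RW) - 1)]
    acc_post = acc[bp:]  # (n_positions, 4)
    match = acc_post[np.arange(len(pos))[:, None], np.clip(codes, 0, 3)]
    match &= codes >= 0
    n_valid = valid.sum(axis=0)
    n_mis = (valid & ~match).sum(axis=0)
    usable = n_valid >= MIN_THREAD_POSITIONS
    err = n_mis / np.maximum(n_valid, 1)

    curve = {int(d): float(e)
             for d, e, u in zip(offsets, err, usable) if u}
    if not curve:
        raise DecompositionError("insufficient signal after breakpoint")

    selected = _select_minima(curve)
    d1, d2 = selected[0], (selected[1] if len(selected) > 1 else selected[0])

    allele1, allele2 = _thread_alleles(result, aligned, reference_window,
                                       window_start, acc, het, bp, r_b, d1, d2)
    res = DecompositionResult(
        allele1=allele1, allele2=allele2, error_curve=curve,
        selected_offsets=list(dict.fromkeys([d1, d2])), breakpoint=bp,
        degenerate=(allele1 == allele2),
        reference_window=reference_window, window_start=window_start,
        basecall_index=np.arange(B),
    )
    _align_alleles(res)
    return res


def _decompose_snv_only(result, aligned, reference_window, window_start,
                        acc, het):
    """No indel signature: both alleles are reference-length; het SNVs are
    phased by giving the reference-matching base to allele 1."""
    B = result.n_basecalls
    mapped = aligned.basecall_to_ref()
    a1, a2 = [], []
    mismatches = 0
    compared = 0
    for i in range(B):
        ref_b = None
        j = int(mapped[i]) - window_start
        if mapped[i] >= 0 and 0 <= j < len(reference_window):
            ref_b = reference_window[j]
        b1, b2 = _split_call(result, acc, i, ref_b, ref_b)
        a1.append(b1)
        a2.append(b2)
        if ref_b in BASES:
            compared += 1
            if not (ref_b == b1 or ref_b == b2):
                mismatches += 1
    err0 = mismatches / compared if compared else 1.0
    res = DecompositionResult(
        allele1="".join(a1), allele2="".join(a2),
        error_curve={0: err0}, selected_offsets=[0], breakpoint=None,
        degenerate=("".join(a1) == "".join(a2)),
        reference_window=reference_window, window_start=window_start,
        basecall_index=np.arange(B),
    )
    _align_alleles(res)
    return res


def _split_call(result, acc, i, ref1, ref2):
    """Distribute the calls at basecall i to the two alleles.

    The reference-matching base goes to allele 1; allele 2 takes the
    remaining call (preferring a match to its own reference base ref2).
    """
    bases = {BASES[c] for c in range(4) if acc[i, c]}
    p = result.primary[i]
    if not bases:
        return p, p
    b1 = ref1 if ref1 in bases else (p if p in bases else sorted(bases)[0])
    remaining = (bases - {b1}) or bases
    b2 = ref2 if ref2 in remaining else sorted(remaining)[0]
    return b1, b2


def _thread_alleles(result, aligned, RW, window_start, acc, het, bp, r_b,
                    d1, d2):
    B = result.n_basecalls
    mapped = aligned.basecall_to_ref()
    a1, a2 = [], []
    for i in range(bp):
        ref_b = None
        j = int(mapped[i]) - window_start
        if mapped[i] >= 0 and 0 <= j < len(RW):
            ref_b = RW[j]
        b1, b2 = _split_call(result, acc, i, ref_b, ref_b)
        a1.append(b1)
        a2.append(b2)
    for i in range(bp, B):
        j1 = r_b + (i - bp) - d1 - window_start
        j2 = r_b + (i - bp) - d2 - window_start
        ref1 = RW[j1] if 0 <= j1 < len(RW) else None
        ref2 = RW[j2] if 0 <= j2 < len(RW) else None
        b1, b2 = _split_call(result, acc, i, ref1, ref2)
        a1.append(b1)
        a2.append(b2)
    return "".join(a1), "".join(a2)


def _select_minima(curve: dict):
    """Offsets of the two smallest-error local minima of the curve."""
    ds = sorted(curve)
    errs = [curve[d] for d in ds]
    minima = []
    for k, d in enumerate(ds):
        left_ok = k == 0 or errs[k] <= errs[k - 1]
        right_ok = k == len(ds) - 1 or errs[k] <= errs[k + 1]
        if left_ok and right_ok:
            minima.append(d)
    minima.sort(key=lambda d: (curve[d], abs(d)))
    chosen = minima[:2]
    chosen.sort(key=lambda d: (abs(d), curve[d]))  # allele1 = most reference-like
    return chosen


def _align_alleles(res: DecompositionResult, scoring: Scoring = Scoring()):
    res.aln_allele1_ref = align_sequences(res.allele1, res.reference_window,
                                          "semiglobal", scoring)
    res.aln_allele2_ref = align_sequences(res.allele2, res.reference_window,
                                          "semiglobal", scoring)
    res.aln_allele1_allele2 = align_sequences(res.allele1, res.allele2,
                                              "global", scoring)


def estimate_allelic_fractions(trace: Chromatogram, result: BasecallResult,
                               d: DecompositionResult):
    """Constrained least squares for the allele mixture weights (f1, f2).

    Reconstructs the per-basecall channel peaks as
    A_i * (f1 * onehot(allele1[i]) + f2 * onehot(allele2[i])) with
    f1 + f2 = 1, using the interval maxima A_i; closed form on the simplex.
    Positions where the alleles agree carry no information and are skipped.
    """
    if d.allele1 == d.allele2:
        d.degenerate = True
        d.fractions = (0.5, 0.5)
        return d.fractions
    start = d.breakpoint if d.breakpoint is not None else 0
    num = 0.0
    den = 0.0
    for k in range(start, min(len(d.allele1), len(d.allele2))):
        b1, b2 = d.allele1[k], d.allele2[k]
        if b1 == b2 or b1 not in BASES or b2 not in BASES:
            continue
        i = int(d.basecall_index[k])
        obs = result.peak_values[i].astype(float)
        A = obs.max()
        if A <= 0:
            continue
        u = np.zeros(4)
        v = np.zeros(4)
        u[BASES.index(b1)] = 1.0
        v[BASES.index(b2)] = 1.0
        num += A * (u - v) @ (obs - A * v)
        den += A * A * ((u - v) @ (u - v))
    if den == 0:
        d.degenerate = True
        d.fractions = (0.5, 0.5)
        return d.fractions
    f1 = float(np.clip(num / den, 0.0, 1.0))
    d.fractions = (f1, 1.0 - f1)
    return d.fractions


def decompose(trace: Chromatogram, reference, maxindel: int = 1000,
              peak_ratio: float = 0.33, scoring: Scoring = Scoring()):
    """End-to-end deconvolution pipeline.

    Aligns the trace (any reference kind), extracts a reference window with
    up to ``maxindel`` of flank, decomposes it, estimates allelic fractions
    and calls variants.  Returns (aligned, decomposition, variants).
    """
    from .genome_index import FMIndex
    from .trace_alignment import align_trace

    aligned = align_trace(trace, reference, peak_ratio, scoring)
    if isinstance(reference, FMIndex):
        rec = aligned.reference_name
        g0 = max(0, aligned.reference_start - maxindel)
        g1 = min(reference.record_length(rec),
                 aligned.reference_start + len(aligned.reference_seq) + maxindel)
        window = reference.sequence(rec, g0, g1)
        window_start = g0 - aligned.reference_start
    else:
        window = aligned.reference_seq
        window_start = 0
    res = decompose_trace(aligned.basecalls, aligned, window,
                          maxindel=maxindel, window_start=window_start)
    estimate_allelic_fractions(aligned.trace, aligned.basecalls, res)
    variants = call_variants(res, aligned)
    return aligned, res, variants
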