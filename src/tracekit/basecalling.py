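"""Peak-ratio basecalling, quality re-estimation and quality trimming.

Basecalling re-reads the four dye signals inside each basecall interval (the
window between the midpoints to the neighbouring peaks).  A channel counts as
"above threshold" when its interval maximum reaches ``peak_ratio`` times the
tallest channel in the same interval — a relative signal-to-noise cut, so a
uniformly weak but clean trace calls just as well as a bright one.  The
primary call is the tallest peak ('N' when nothing is above threshold), the
secondary call summarises every other above-threshold channel as one IUPAC
letter ('N' when all four are up), and the consensus merges primary and
secondary.  A heterozygous position is therefore simply one where secondary
differs from primary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromatogram import Chromatogram
from .errors import TraceKitError
from .iupac import BASES, expand_iupac, iupac_code

QUALITY_FLOOR_ERROR = 1e-4  # error floor -> quality cap Q40
QUALITY_MIN, QUALITY_MAX = 1, 40


@dataclass
class BasecallResult:
    """Re-called bases for one chromatogram.

    All per-basecall arrays/strings have equal length B.  ``peak_values`` is
    the (B, 4) matrix of per-channel interval maxima in channel order
    A, C, G, T.
    """

    primary: str
    secondary: str
    consensus: str
    qualities: np.ndarray
    peak_values: np.ndarray
    peak_positions: np.ndarray
    peak_ratio_used: float
    # channel values sampled exactly at the peak position; free of the
    # neighbour-peak bleed that the interval maxima pick up, hence used for
    # quality estimation when available
    peak_point_values: np.ndarray | None = None

    def __post_init__(self):
        B = len(self.primary)
        if not (len(self.secondary) == len(self.consensus)
                == len(self.qualities) == len(self.peak_values)
                == len(self.peak_positions) == B):
            raise ValueError("per-basecall fields must have equal length")

    @property
    def n_basecalls(self) -> int:
        return len(self.primary)

    def het_mask(self) -> np.ndarray:
        """Boolean mask of positions where secondary differs from primary."""
        return np.array([s != p for p, s in zip(self.primary, self.secondary)])


@dataclass
class TrimWindow:
    """Half-open basecall range [keep_start, keep_end) surviving trimming."""

    keep_start: int
    keep_end: int

    def __post_init__(self):
        if not 0 <= self.keep_start <= self.keep_end:
            raise ValueError("invalid trim window")

    def __len__(self):
        return self.keep_end - self.keep_start

    @property
    def empty(self) -> bool:
        return self.keep_start == self.keep_end


def _interval_bounds(peaks: np.ndarray, n_samples: int):
    """Basecall interval boundaries: midpoints between adjacent peaks."""
    mids = (peaks[:-1] + peaks[1:]) // 2
    lo = np.concatenate(([0], mids + 1))
    hi = np.concatenate((mids + 1, [n_samples]))
    return lo, hi


def call_bases(trace: Chromatogram, peak_ratio: float = 0.33) -> BasecallResult:
    """Re-call bases from the trace signal at the given peak-ratio threshold."""
    if not 0 < peak_ratio <= 1:
        raise TraceKitError("invalid peak ratio")
    if trace.n_basecalls < 1:
        raise TraceKitError("trace has no basecall intervals")

    peaks = trace.peak_positions
    lo, hi = _interval_bounds(peaks, trace.n_samples)
    B = trace.n_basecalls

    peak_values = np.empty((B, 4), dtype=np.int64)
    for i in range(B):
        peak_values[i] = trace.signal[:, lo[i]:hi[i]].max(axis=1)

    primary, secondary, consensus = [], [], []
    for i in range(B):
        pv = peak_values[i]
        top = pv.max()
        threshold = peak_ratio * top
        above = (pv >= threshold) & (pv > 0)
        if not above.any():
            primary.append("N")
            secondary.append("N")
            consensus.append("N")
            continue
        p = BASES[int(pv.argmax())]
        n_above = int(above.sum())
        if n_above == 1:
            s = p
        elif n_above == 4:
            s = "N"
        else:
            others = {BASES[c] for c in range(4) if above[c] and BASES[c] != p}
            s = iupac_code(others)
        if s == p:
            c = p
        else:
            c = iupac_code({p} | set(expand_iupac(s)))
        primary.append(p)
        secondary.append(s)
        consensus.append(c)

    result = BasecallResult(
        primary="".join(primary),
        secondary="".join(secondary),
        consensus="".join(consensus),
        qualities=np.zeros(B, dtype=np.int64),
        peak_values=peak_values,
        peak_positions=peaks.copy(),
        peak_ratio_used=float(peak_ratio),
        peak_point_values=trace.signal[:, peaks].T.copy(),
    )
    result.qualities = estimate_qualities(result)
    return result


def estimate_qualities(result: BasecallResult) -> np.ndarray:
    """Phred qualities from the signal share of the non-primary channels.

    The basecall error is estimated as the fraction of signal not carried
    by the primary channel, floored at 1e-4; qualities are clamped to
    [1, 40].  Channel values sampled at the peak position are preferred
    over interval maxima (which include bleed from neighbouring peaks).
    """
    values = result.peak_point_values
    if values is None:
        values = result.peak_values
    totals = values.sum(axis=1).astype(float)
    prim_idx = values.argmax(axis=1)
    prim = values[np.arange(len(prim_idx)), prim_idx].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.where(totals > 0, (totals - prim) / np.where(totals > 0, totals, 1), 1.0)
    err = np.maximum(err, QUALITY_FLOOR_ERROR)
    q = np.rint(-10.0 * np.log10(err)).astype(np.int64)
    return np.clip(q, QUALITY_MIN, QUALITY_MAX)


def quality_trim(result: BasecallResult, window: int = 10,
                 min_mean_quality: float = 20.0) -> TrimWindow:
    """Sliding-window quality trim.

    Keeps from the first basecall whose forward window of ``window`` calls
    averages at least ``min_mean_quality`` through the end of the last such
    window.  Returns the empty window [0, 0) when no window qualifies.
    """
    if window < 1:
        raise TraceKitError("window must be >= 1")
    q = np.asarray(result.qualities, dtype=float)
    B = len(q)
    if B < window:
        return TrimWindow(0, 0)
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    ok = np.flatnonzero(means >= min_mean_quality)
    if len(ok) == 0:
        return TrimWindow(0, 0)
    return TrimWindow(int(ok[0]), int(ok[-1]) + window)
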