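"""In-memory chromatogram model and the trace simulator.

A Sanger chromatogram is represented by four per-dye signal curves sampled at
regular time points, plus the sampling index of each basecall peak and the
basecalls/qualities stored by the instrument's own basecaller.  The simulator
renders one or two allele sequences into such a trace: each base contributes a
Gaussian peak (height scaled by the allele's mixture fraction) on its dye
channel, so a 50/50 heterozygous indel produces the characteristic overlay of
shifted peaks downstream of the edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .iupac import BASES, iupac_code

MAX_SIGNAL = 65535  # both ABIF and SCF store 16-bit samples

_CHANNEL_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class Chromatogram:
    """Four-channel trace signal with basecall peak annotations.

    Parameters
    ----------
    signal : (4, S) array of non-negative ints, channel order A, C, G, T.
    peak_positions : strictly increasing 0-based sampling indices, one per
        basecall.
    stored_bases : IUPAC string, one letter per basecall.
    stored_qualities : phred integers in [0, 93], one per basecall.
    source_format : one of ``{"abi", "scf", "synthetic"}``.
    name : free-text identifier.
    """

    signal: np.ndarray
    peak_positions: np.ndarray
    stored_bases: str
    stored_qualities: np.ndarray
    source_format: str = "synthetic"
    name: str = "trace"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.int64)
        self.peak_positions = np.asarray(self.peak_positions, dtype=np.int64)
        self.stored_qualities = np.asarray(self.stored_qualities, dtype=np.int64)
        if self.signal.ndim != 2 or self.signal.shape[0] != 4:
            raise ValueError("signal must be a 4 x S matrix")
        if self.signal.shape[1] < 1:
            raise ValueError("signal must have at least one sampling point")
        if np.any(self.signal < 0):
            raise ValueError("signal values must be non-negative")
        B = len(self.peak_positions)
        if len(self.stored_bases) != B or len(self.stored_qualities) != B:
            raise ValueError("peak_positions, stored_bases and stored_qualities "
                             "must have equal length")
        if B and (self.peak_positions.min() < 0
                  or self.peak_positions.max() >= self.signal.shape[1]):
            raise ValueError("peak positions out of sampling range")
        if B > 1 and np.any(np.diff(self.peak_positions) <= 0):
            raise ValueError("peak positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_basecalls(self) -> int:
        return len(self.peak_positions)

    def reverse_complement(self) -> "Chromatogram":
        """Trace as it would read from the opposite strand.

        Channels are swapped (A<->T, C<->G) and the time axis reversed.
        """
        from .iupac import reverse_complement as rc

        S = self.n_samples
        sig = self.signal[[3, 2, 1, 0], ::-1].copy()
        peaks = (S - 1 - self.peak_positions)[::-1].copy()
        quals = self.stored_qualities[::-1].copy()
        return Chromatogram(sig, peaks, rc(self.stored_bases), quals,
                            self.source_format, self.name)

    def __eq__(self, other):
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return (np.array_equal(self.signal, other.signal)
                and np.array_equal(self.peak_positions, other.peak_positions)
                and self.stored_bases == other.stored_bases
                and np.array_equal(self.stored_qualities, other.stored_qualities))


@dataclass
class SimulationSpec:
    """Parameters for rendering one or two allele sequences into a trace.

    ``peak_spacing`` is the mean number of sampling points per base;
    ``peak_sigma`` the Gaussian peak width (must be below the spacing so that
    adjacent peaks stay resolvable); ``noise_sd`` the standard deviation of
    the additive noise, truncated at zero.
    """

    allele_sequences: tuple
    allele_fractions: tuple = (1.0,)
    peak_spacing: int = 12
    peak_sigma: float = 3.0
    peak_amplitude: float = 1000.0
    noise_sd: float = 10.0
    seed: int = 0
    name: str = "sim"

    def __post_init__(self):
        if isinstance(self.allele_sequences, str):
            self.allele_sequences = (self.allele_sequences,)
        self.allele_sequences = tuple(s.upper() for s in self.allele_sequences)
        self.allele_fractions = tuple(float(f) for f in self.allele_fractions)
        if not 1 <= len(self.allele_sequences) <= 2:
            raise SimulationError("one or two allele sequences required")
        if len(self.allele_fractions) != len(self.allele_sequences):
            raise SimulationError("invalid fractions: one weight per allele required")
        if any(f < 0 for f in self.allele_fractions):
            raise SimulationError("invalid fractions: weights must be non-negative")
        if abs(sum(self.allele_fractions) - 1.0) > 1e-9:
            raise SimulationError("invalid fractions: weights must sum to 1")
        if self.peak_spacing < 3:
            raise SimulationError("peak_spacing must be at least 3 samples")
        if not self.peak_sigma < self.peak_spacing:
            raise SimulationError("peak_sigma must be smaller than peak_spacing")
        for s in self.allele_sequences:
            if not s or set(s) - set(BASES):
                raise SimulationError("allele sequences must be non-empty A/C/G/T strings")


def synthesize_chromatogram(spec: SimulationSpec) -> Chromatogram:
    """Render the alleles of `spec` into a synthetic chromatogram.

    Basecall peaks are laid out every ``peak_spacing`` samples (jittered by
    ±1 sample); both alleles share the same peak grid, so after a
    heterozygous indel the two allele sequences superimpose base-for-base,
    exactly as the shifted dye signals do in a real mixed trace.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_bases = max(len(s) for s in spec.allele_sequences)
    spacing = int(spec.peak_spacing)
    S = spacing * (n_bases + 2)

    # ±1 jitter never breaks monotonicity because spacing >= 2
    jitter = rng.integers(-1, 2, size=n_bases)
    peaks = spacing + spacing * np.arange(n_bases) + jitter

    x = np.arange(S, dtype=float)
    signal = np.zeros((4, S), dtype=float)
    for seq, frac in zip(spec.allele_sequences, spec.allele_fractions):
        if frac == 0.0:
            continue
        amp = spec.peak_amplitude * frac
        for i, base in enumerate(seq):
            c = _CHANNEL_INDEX[base]
            p = peaks[i]
            lo = max(0, p - 4 * int(np.ceil(spec.peak_sigma)))
            hi = min(S, p + 4 * int(np.ceil(spec.peak_sigma)) + 1)
            signal[c, lo:hi] += amp * np.exp(
                -0.5 * ((x[lo:hi] - p) / spec.peak_sigma) ** 2)

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=signal.shape)
    signal = np.clip(np.rint(signal), 0, MAX_SIGNAL).astype(np.int64)

    # store the mixture consensus as the instrument basecalls
    bases = []
    for i in range(n_bases):
        contrib = {seq[i] for seq, f in zip(spec.allele_sequences,
                                            spec.allele_fractions)
                   if f > 0 and i < len(seq)}
        bases.append(iupac_code(contrib))
    quals = np.full(n_bases, 40, dtype=np.int64)

    return Chromatogram(signal, peaks, "".join(bases), quals,
                        source_format="synthetic", name=spec.name)
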