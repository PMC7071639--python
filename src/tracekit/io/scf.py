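"""SCF v3 trace reading and writing (Staden format, big-endian).

Only version 3 with 16-bit samples is supported.  Sample curves are stored
twice-differenced ("delta-delta") per channel; decoding is two cumulative
sums modulo 2^16.
"""

from __future__ import annotations

import struct

import numpy as np

from ..chromatogram import MAX_SIGNAL, Chromatogram
from ..errors import TraceFormatError

_MAGIC = b".scf"
_HEADER = struct.Struct(">4sIIIIIIII4sIII")  # through private_offset
_HEADER_SIZE = 128


def _delta_decode(values: np.ndarray) -> np.ndarray:
    v = values.astype(np.uint32)
    v = np.cumsum(v, dtype=np.uint32) & 0xFFFF
    v = np.cumsum(v, dtype=np.uint32) & 0xFFFF
    return v.astype(np.int64)


def _delta_encode(values: np.ndarray) -> np.ndarray:
    v = values.astype(np.int64)
    d1 = np.diff(v, prepend=0)
    d2 = np.diff(d1, prepend=0)
    return (d2 & 0xFFFF).astype(np.uint16)


def read_scf(raw: bytes) -> Chromatogram:
    """Parse SCF v3 bytes into a :class:`Chromatogram`."""
    if len(raw) < _HEADER_SIZE or raw[:4] != _MAGIC:
        raise TraceFormatError("not an SCF file")
    (magic, n_samples, samples_offset, n_bases, _lclip, _rclip, bases_offset,
     comments_size, comments_offset, version, sample_size, _code_set,
     _private_size) = _HEADER.unpack_from(raw, 0)
    if not version.startswith(b"3"):
        raise TraceFormatError("unsupported SCF version")
    if sample_size != 2:
        raise TraceFormatError("unsupported SCF sample size")

    need = samples_offset + 4 * 2 * n_samples
    if len(raw) < need:
        raise TraceFormatError("truncated file")
    samples = np.frombuffer(raw, dtype=">u2", count=4 * n_samples,
                            offset=samples_offset)
    signal = np.empty((4, n_samples), dtype=np.int64)
    for c in range(4):  # stored channel order A, C, G, T
        signal[c] = _delta_decode(samples[c * n_samples:(c + 1) * n_samples])

    # bases section: uint32 peak indices, then 4 x uint8 per-channel probs,
    # then the calls, then 3 spare bytes per base
    need = bases_offset + n_bases * (4 + 4 + 1 + 3)
    if len(raw) < need:
        raise TraceFormatError("truncated file")
    off = bases_offset
    peaks = np.frombuffer(raw, dtype=">u4", count=n_bases, offset=off).astype(np.int64)
    off += 4 * n_bases
    probs = np.frombuffer(raw, dtype=np.uint8, count=4 * n_bases,
                          offset=off).reshape(4, n_bases)
    off += 4 * n_bases
    bases = raw[off:off + n_bases].decode("ascii").upper()
    quals = np.empty(n_bases, dtype=np.int64)
    chan = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(bases):
        quals[i] = probs[chan[b], i] if b in chan else probs[:, i].max()
    return Chromatogram(signal, peaks, bases, np.clip(quals, 0, 93),
                        source_format="scf", name="scf")


def write_scf(trace: Chromatogram, comment: str = "tracekit") -> bytes:
    """Serialize a chromatogram as SCF v3 bytes; exact inverse of read_scf."""
    if trace.signal.max(initial=0) > MAX_SIGNAL:
        raise TraceFormatError("signal overflow")
    n_samples = trace.n_samples
    n_bases = trace.n_basecalls
    comments = comment.encode("ascii") + b"\0"

    samples_offset = _HEADER_SIZE
    bases_offset = samples_offset + 4 * 2 * n_samples
    comments_offset = bases_offset + n_bases * 12

    header = _HEADER.pack(_MAGIC, n_samples, samples_offset, n_bases, 0, 0,
                          bases_offset, len(comments), comments_offset,
                          b"3.00", 2, 0, 0)
    header += b"\0" * (_HEADER_SIZE - len(header))

    out = [header]
    for c in range(4):
        out.append(_delta_encode(trace.signal[c]).astype(">u2").tobytes())
    out.append(trace.peak_positions.astype(">u4").tobytes())
    chan = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.zeros((4, n_bases), dtype=np.uint8)
    for i, b in enumerate(trace.stored_bases):
        q = int(min(trace.stored_qualities[i], 255))
        if b in chan:
            probs[chan[b], i] = q
        else:
            probs[:, i] = q
    out.append(probs.tobytes())
    out.append(trace.stored_bases.encode("ascii"))
    out.append(b"\0" * (3 * n_bases))
    out.append(comments)
    return b"".join(out)
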