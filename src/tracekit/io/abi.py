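"""ABIF (.ab1/.abi) chromatogram reading.

ABIF is a big-endian tagged container: a 128-byte header points at a table
of 28-byte directory entries, each naming a (tag, number) pair with an
element type, count and either an inline value (data <= 4 bytes) or a file
offset.  We read the processed signal channels DATA9-DATA12, the peak
locations (PLOC), basecalls (PBAS) and qualities (PCON), preferring tag
entry 2 (basecaller output) over entry 1, and resolve the channel order
from the filter-wheel order tag FWO_1 (default "GATC").
"""

from __future__ import annotations

import struct

import numpy as np

from ..chromatogram import Chromatogram
from ..errors import TraceFormatError

_DIR_ENTRY = struct.Struct(">4sihhii4si")

# element type -> numpy dtype for array data
_ETYPE = {1: np.dtype("u1"), 2: np.dtype("S1"), 4: np.dtype(">i2"),
          5: np.dtype(">u2"), 7: np.dtype(">f4"), 13: np.dtype(">i4")}


def _read_entries(raw: bytes):
    if len(raw) < 34 or raw[:4] != b"ABIF":
        raise TraceFormatError("not an ABIF file")
    # header: magic, version, then one directory entry describing the table
    tag, num, etype, esize, nelem, dsize, doff_raw, _ = _DIR_ENTRY.unpack_from(raw, 6)
    if tag != b"tdir":
        raise TraceFormatError("malformed ABIF: tdir")
    table_offset = struct.unpack(">i", doff_raw)[0]
    entries = {}
    for k in range(nelem):
        off = table_offset + 28 * k
        if off + 28 > len(raw):
            raise TraceFormatError("truncated file")
        name, number, et, es, ne, ds, draw, _ = _DIR_ENTRY.unpack_from(raw, off)
        entries[(name.decode("ascii", "replace"), number)] = (et, es, ne, ds, draw)
    return entries


def _entry_data(raw: bytes, entry):
    etype, esize, nelem, dsize, draw = entry
    if dsize <= 4:
        payload = draw[:dsize]
    else:
        offset = struct.unpack(">i", draw)[0]
        if offset + dsize > len(raw):
            raise TraceFormatError("truncated file")
        payload = raw[offset:offset + dsize]
    if etype in (2, 18, 19):  # char / pString / cString
        if etype == 18:
            payload = payload[1:1 + payload[0]]
        elif etype == 19:
            payload = payload.rstrip(b"\0")
        return payload
    dt = _ETYPE.get(etype)
    if dt is None:
        raise TraceFormatError(f"malformed ABIF: unsupported element type {etype}")
    return np.frombuffer(payload, dtype=dt, count=nelem)


def _get(raw, entries, tag, numbers):
    for n in numbers:
        if (tag, n) in entries:
            return _entry_data(raw, entries[(tag, n)])
    raise TraceFormatError(f"malformed ABIF: {tag}")


def read_abi(raw: bytes) -> Chromatogram:
    """Parse ABIF bytes into a :class:`Chromatogram`."""
    entries = _read_entries(raw)

    try:
        fwo = _get(raw, entries, "FWO_", [1]).decode("ascii").upper()
    except TraceFormatError:
        fwo = "GATC"
    if sorted(fwo) != list("ACGT"):
        raise TraceFormatError("malformed ABIF: FWO_")

    channels = {}
    for i, data_num in enumerate((9, 10, 11, 12)):
        vals = np.asarray(_get(raw, entries, "DATA", [data_num]), dtype=np.int64)
        channels[fwo[i]] = np.maximum(vals, 0)
    lengths = {len(v) for v in channels.values()}
    if len(lengths) != 1:
        raise TraceFormatError("malformed ABIF: DATA")
    signal = np.stack([channels[b] for b in "ACGT"])

    peaks = np.asarray(_get(raw, entries, "PLOC", [2, 1]), dtype=np.int64)
    bases = _get(raw, entries, "PBAS", [2, 1]).decode("ascii").upper()
    pcon = _get(raw, entries, "PCON", [2, 1])
    if isinstance(pcon, (bytes, bytearray)):  # stored as char in some files
        pcon = np.frombuffer(bytes(pcon), dtype=np.uint8)
    quals = np.clip(np.asarray(pcon, dtype=np.int64), 0, 93)
    peaks = np.clip(peaks, 0, signal.shape[1] - 1)
    return Chromatogram(signal, peaks, bases, quals,
                        source_format="abi", name="abi")
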