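"""Trace file I/O: ABIF and SCF readers, SCF writer, basecall reports."""

from .abi import read_abi
from .reports import REPORT_FORMATS, write_trace_report
from .scf import read_scf, write_scf

__all__ = ["read_abi", "read_scf", "write_scf", "write_trace_report",
           "REPORT_FORMATS"]


def read_trace(path) -> "Chromatogram":
    """Read a trace file, sniffing ABIF vs SCF from the magic bytes."""
    from ..errors import TraceFormatError

    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[:4] == b"ABIF":
        trace = read_abi(raw)
    elif raw[:4] == b".scf":
        trace = read_scf(raw)
    else:
        raise TraceFormatError(f"unrecognized trace format: {path}")
    import os
    trace.name = os.path.splitext(os.path.basename(str(path)))[0]
    return trace
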