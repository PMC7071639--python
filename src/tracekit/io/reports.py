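"""Basecall report writers: JSON, TSV, FASTA, FASTQ.

JSON and TSV carry the full trace (four signal values at every sampling
position) plus one row per basecall with its peak position, primary,
secondary and consensus calls and quality.  FASTA/FASTQ carry only the
primary basecall string, FASTQ with phred+33 qualities.
"""

from __future__ import annotations

import json

from ..basecalling import BasecallResult
from ..chromatogram import Chromatogram
from ..errors import UnsupportedFormatError

REPORT_FORMATS = ("json", "tsv", "fasta", "fastq")


def write_trace_report(result: BasecallResult, trace: Chromatogram,
                       format: str = "json") -> str:
    if format not in REPORT_FORMATS:
        raise UnsupportedFormatError(f"unsupported format: {format!r}")

    if format == "fasta":
        return f">{trace.name}\n{result.primary}\n"

    if format == "fastq":
        quals = "".join(chr(int(q) + 33) for q in result.qualities)
        return f"@{trace.name}\n{result.primary}\n+\n{quals}\n"

    peaks = [
        {
            "pos": int(result.peak_positions[i]),
            "primary": result.primary[i],
            "secondary": result.secondary[i],
            "consensus": result.consensus[i],
            "qual": int(result.qualities[i]),
        }
        for i in range(result.n_basecalls)
    ]

    if format == "json":
        doc = {
            "meta": {
                "name": trace.name,
                "source_format": trace.source_format,
                "peakRatio": result.peak_ratio_used,
                "nSamples": trace.n_samples,
                "nBasecalls": result.n_basecalls,
            },
            "peaks": peaks,
            "traceA": trace.signal[0].tolist(),
            "traceC": trace.signal[1].tolist(),
            "traceG": trace.signal[2].tolist(),
            "traceT": trace.signal[3].tolist(),
        }
        return json.dumps(doc)

    # tsv: a trace block (one row per sampling position) then a basecall block
    lines = ["#trace\tsample\tA\tC\tG\tT"]
    for s in range(trace.n_samples):
        lines.append("trace\t%d\t%d\t%d\t%d\t%d"
                     % (s, trace.signal[0, s], trace.signal[1, s],
                        trace.signal[2, s], trace.signal[3, s]))
    lines.append("#basecall\tindex\tpos\tprimary\tsecondary\tconsensus\tqual")
    for i, p in enumerate(peaks):
        lines.append("basecall\t%d\t%d\t%s\t%s\t%s\t%d"
                     % (i + 1, p["pos"], p["primary"], p["secondary"],
                        p["consensus"], p["qual"]))
    return "\n".join(lines) + "\n"
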