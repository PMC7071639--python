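"""Aligning a single chromatogram to a reference.

Three reference kinds are supported:

* an FM-indexed genome — classical three-step mapping: (1) seed-anchor the
  trace, (2) semiglobal alignment of the quality-trimmed profile to the
  anchored window to fix a reliable core, (3) semiglobal alignment of the
  full untrimmed profile to the core window extended by the trace length;
* a short FASTA sequence — direct semiglobal profile-to-sequence alignment;
* a wildtype chromatogram — profile-to-profile semiglobal alignment.

Both orientations are always attempted and the better-scoring one kept; a
reverse hit reverse-complements the trace so that all downstream work (and
reporting) happens on the forward reference strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .align import (PairwiseAlignment, Profile, Scoring,
                    align_profile_to_profile, align_profile_to_sequence)
from .basecalling import BasecallResult, TrimWindow, call_bases, quality_trim
from .chromatogram import Chromatogram
from .errors import UnsupportedFormatError
from .genome_index import FMIndex, GenomeAnchor, anchor_trace

POOR_ALIGNMENT_FRACTION = 0.3  # of the maximum attainable score


@dataclass
class AlignedTrace:
    """A chromatogram placed against a reference.

    ``trace``/``basecalls`` are in the alignment orientation (i.e. already
    reverse-complemented when ``orientation == "reverse"``).  The reference
    window ``reference_seq`` starts at forward-strand coordinate
    ``reference_start`` of ``reference_name``.
    """

    alignment: PairwiseAlignment
    trace: Chromatogram
    basecalls: BasecallResult
    trim: TrimWindow
    orientation: str
    reference_name: str
    reference_start: int
    reference_seq: str
    anchor: GenomeAnchor | None = None
    poor_alignment: bool = False
    original_trace: Chromatogram | None = None

    padded_signal: np.ndarray = field(init=False)
    provenance: list = field(init=False)

    def __post_init__(self):
        L = len(self.alignment.path)
        sig = np.zeros((L, 4), dtype=np.int64)
        prov = []
        for col, (i, j) in enumerate(self.alignment.path):
            if i is not None:
                sig[col] = self.basecalls.peak_values[i]
                prov.append("trace" if j is not None else "reference-gap")
            else:
                prov.append("trace-gap")
        self.padded_signal = sig
        self.provenance = prov

    def basecall_to_ref(self) -> np.ndarray:
        """Window-local reference index per basecall (-1 where unaligned)."""
        out = np.full(self.basecalls.n_basecalls, -1, dtype=np.int64)
        for i, j in self.alignment.path:
            if i is not None and j is not None:
                out[i] = j
        return out

    def original_basecall_index(self, i: int) -> int:
        """Map an oriented basecall index back to the input trace."""
        if self.orientation == "reverse":
            return self.basecalls.n_basecalls - 1 - i
        return i

    def original_signal_position(self, i: int) -> int:
        src = self.original_trace if self.original_trace is not None else self.trace
        if self.orientation == "reverse":
            return int(src.n_samples - 1
                       - self.trace.peak_positions[i])
        return int(self.trace.peak_positions[i])


def _full_trim(bc: BasecallResult) -> TrimWindow:
    return TrimWindow(0, bc.n_basecalls)


def _prepare(trace: Chromatogram, peak_ratio: float):
    bc = call_bases(trace, peak_ratio)
    trim = quality_trim(bc)
    if trim.empty:  # very short or uniformly poor trace: keep everything
        trim = _full_trim(bc)
    return bc, trim


def align_trace(trace: Chromatogram, reference, peak_ratio: float = 0.33,
                scoring: Scoring = Scoring(), k: int = 15,
                flank: int = 50) -> AlignedTrace:
    """Align a chromatogram to a genome index, a sequence, or a wildtype trace."""
    if isinstance(reference, FMIndex):
        return _align_genome(trace, reference, peak_ratio, scoring, k, flank)
    if isinstance(reference, Chromatogram):
        return _align_wildtype(trace, reference, peak_ratio, scoring)
    return _align_fasta(trace, str(reference), peak_ratio, scoring,
                        name="ref")


def _finalize(aln, trace, oriented, bc, trim, orientation, ref_name,
              ref_start, ref_seq, scoring, anchor=None):
    max_score = scoring.match * bc.n_basecalls
    poor = aln.score < POOR_ALIGNMENT_FRACTION * max_score
    return AlignedTrace(aln, oriented, bc, trim, orientation, ref_name,
                        ref_start, ref_seq, anchor=anchor,
                        poor_alignment=poor, original_trace=trace)


def _align_fasta(trace, seq, peak_ratio, scoring, name="ref"):
    seq = seq.upper()
    best = None
    for orientation in ("forward", "reverse"):
        oriented = trace if orientation == "forward" else trace.reverse_complement()
        bc, trim = _prepare(oriented, peak_ratio)
        prof = Profile.from_basecalls(bc, _full_trim(bc))
        aln = align_profile_to_sequence(prof, seq, "semiglobal", scoring)
        if best is None or aln.score > best[0].score:
            best = (aln, oriented, bc, trim, orientation)
    aln, oriented, bc, trim, orientation = best
    return _finalize(aln, trace, oriented, bc, trim, orientation,
                     name, 0, seq, scoring)


def _align_wildtype(trace, wildtype, peak_ratio, scoring):
    wt_bc, wt_trim = _prepare(wildtype, peak_ratio)
    wt_prof = Profile.from_basecalls(wt_bc, _full_trim(wt_bc))
    wt_seq = wt_bc.consensus
    best = None
    for orientation in ("forward", "reverse"):
        oriented = trace if orientation == "forward" else trace.reverse_complement()
        bc, trim = _prepare(oriented, peak_ratio)
        prof = Profile.from_basecalls(bc, _full_trim(bc))
        aln = align_profile_to_profile(prof, wt_prof, "semiglobal", scoring)
        if best is None or aln.score > best[0].score:
            best = (aln, oriented, bc, trim, orientation)
    aln, oriented, bc, trim, orientation = best
    return _finalize(aln, trace, oriented, bc, trim, orientation,
                     wildtype.name, 0, wt_seq, scoring)


def _align_genome(trace, idx, peak_ratio, scoring, k, flank):
    bc, trim = _prepare(trace, peak_ratio)
    anchor = anchor_trace(idx, bc, trim, k=k, flank=flank)

    orientation = anchor.strand
    oriented = trace if orientation == "forward" else trace.reverse_complement()
    if orientation == "reverse":
        bc, trim = _prepare(oriented, peak_ratio)

    window = idx.sequence(anchor.record, anchor.start, anchor.end)
    # step 2: trimmed profile fixes the core region inside the window
    core_prof = Profile.from_basecalls(bc, trim)
    core = align_profile_to_sequence(core_prof, window, "semiglobal", scoring)
    core_start = anchor.start + core.start2
    core_end = anchor.start + core.end2
    # step 3: full untrimmed profile against the core extended by the trace
    B = bc.n_basecalls
    ext_start = max(0, core_start - B)
    ext_end = min(idx.record_length(anchor.record), core_end + B)
    ext_seq = idx.sequence(anchor.record, ext_start, ext_end)
    full_prof = Profile.from_basecalls(bc, _full_trim(bc))
    aln = align_profile_to_sequence(full_prof, ext_seq, "semiglobal", scoring)
    return _finalize(aln, trace, oriented, bc, trim, orientation,
                     anchor.record, ext_start, ext_seq, scoring, anchor=anchor)


def emit_alignment_report(at: AlignedTrace, format: str = "json") -> str:
    """Render an aligned trace as JSON (with padded signals) or ClustalW."""
    if format == "clustal":
        return _clustal(at)
    if format == "json":
        doc = {
            "meta": {
                "trace": at.trace.name,
                "reference": at.reference_name,
                "referenceStart": at.reference_start,
                "orientation": at.orientation,
                "score": at.alignment.score,
                "poorAlignment": at.poor_alignment,
            },
            "traceRow": at.alignment.rows[0],
            "referenceRow": at.alignment.rows[1],
            "provenance": at.provenance,
            "paddedSignal": at.padded_signal.tolist(),
        }
        return json.dumps(doc)
    raise UnsupportedFormatError(f"unsupported format: {format!r}")


def _clustal(at: AlignedTrace, width: int = 60) -> str:
    name1 = (at.trace.name or "trace")[:14]
    name2 = (at.reference_name or "ref")[:14]
    row1, row2 = at.alignment.rows
    stars = at.alignment.identity_columns()
    lines = ["CLUSTAL W multiple sequence alignment", ""]
    for start in range(0, len(row1), width):
        chunk1 = row1[start:start + width]
        chunk2 = row2[start:start + width]
        chunk_s = stars[start:start + width]
        lines.append(f"{name1:<16}{chunk1}")
        lines.append(f"{name2:<16}{chunk2}")
        lines.append(" " * 16 + chunk_s)
        lines.append("")
    return "\n".join(lines)
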