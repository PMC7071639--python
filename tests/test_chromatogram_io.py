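"""Trace file I/O and simulator behaviour."""

import json
import struct

import numpy as np
import pytest

from conftest import random_seq, simulate
from tracekit.basecalling import call_bases
from tracekit.chromatogram import Chromatogram, SimulationSpec, synthesize_chromatogram
from tracekit.errors import SimulationError, TraceFormatError, UnsupportedFormatError
from tracekit.io import read_abi, read_scf, write_scf, write_trace_report


# --------------------------------------------------------------------------
# independent ABIF writer built directly from the published container layout
# --------------------------------------------------------------------------

def make_abif(channels, peaks, bases, quals, fwo="GATC", omit=()):
    """channels: dict base -> int16 list; directory laid out by hand."""
    data_blobs = []
    entries = []

    def add(name, number, etype, esize, nelem, payload):
        if (name, number) in omit:
            return
        if len(payload) <= 4:
            draw = payload.ljust(4, b"\0")
            entries.append((name, number, etype, esize, nelem, len(payload),
                            draw, True))
        else:
            entries.append((name, number, etype, esize, nelem, len(payload),
                            payload, False))

    for i, data_num in enumerate((9, 10, 11, 12)):
        vals = channels[fwo[i]]
        add(b"DATA", data_num, 4, 2, len(vals),
            b"".join(struct.pack(">h", v) for v in vals))
    add(b"FWO_", 1, 2, 1, 4, fwo.encode())
    add(b"PLOC", 2, 4, 2, len(peaks),
        b"".join(struct.pack(">h", p) for p in peaks))
    add(b"PBAS", 2, 2, 1, len(bases), bases.encode())
    add(b"PCON", 2, 1, 1, len(quals), bytes(int(q) for q in quals))

    out = bytearray()
    out += b"ABIF" + struct.pack(">h", 101)
    header_dir_at = len(out)
    out += b"\0" * 28
    out += b"\0" * (128 - len(out))

    placed = []
    for name, number, etype, esize, nelem, dsize, payload, inline in entries:
        if inline:
            placed.append((name, number, etype, esize, nelem, dsize, payload))
        else:
            off = len(out)
            out += payload
            placed.append((name, number, etype, esize, nelem, dsize,
                           struct.pack(">i", off)))
    dir_off = len(out)
    for name, number, etype, esize, nelem, dsize, draw in placed:
        out += struct.pack(">4sihhii4si", name, number, etype, esize, nelem,
                           dsize, draw, 0)
    tdir = struct.pack(">4sihhii4si", b"tdir", 1, 1023, 28, len(placed),
                       28 * len(placed), struct.pack(">i", dir_off), 0)
    out[header_dir_at:header_dir_at + 28] = tdir
    return bytes(out)


def abif_from_trace(trace, fwo="GATC"):
    order = {b: i for i, b in enumerate("ACGT")}
    channels = {b: trace.signal[order[b]].tolist() for b in "ACGT"}
    return make_abif(channels, trace.peak_positions.tolist(),
                     trace.stored_bases, trace.stored_qualities.tolist(),
                     fwo=fwo)


class TestAbif:
    def test_round_trip_from_independent_writer(self):
        trace = simulate(random_seq(40, 7), noise_sd=5, seed=7)
        got = read_abi(abif_from_trace(trace))
        assert got == trace

    @pytest.mark.parametrize("fwo", ["GATC", "ACGT", "TGCA"])
    def test_filter_wheel_order_resolves_channels(self, fwo):
        # distinct constant signal per base channel, regardless of file order
        channels = {b: [100 * (i + 1)] * 8 for i, b in enumerate("ACGT")}
        raw = make_abif(channels, [2, 5], "AC", [30, 30], fwo=fwo)
        trace = read_abi(raw)
        for i, b in enumerate("ACGT"):
            assert trace.signal[i, 0] == 100 * (i + 1), b

    def test_bad_magic(self):
        with pytest.raises(TraceFormatError, match="not an ABIF file"):
            read_abi(b"XXXX" + b"\0" * 200)

    @pytest.mark.parametrize("tag", [b"PBAS", b"PLOC", b"PCON", b"DATA"])
    def test_missing_mandatory_tag(self, tag):
        trace = simulate(random_seq(10, 1), noise_sd=0, seed=1)
        omit = {(tag, n) for n in (2, 9)}
        raw_parts = abif_from_trace(trace)
        channels = {b: trace.signal["ACGT".index(b)].tolist() for b in "ACGT"}
        raw = make_abif(channels, trace.peak_positions.tolist(),
                        trace.stored_bases, trace.stored_qualities.tolist(),
                        omit=omit)
        with pytest.raises(TraceFormatError,
                           match=f"malformed ABIF: {tag.decode()}"):
            read_abi(raw)

    def test_truncated_file(self):
        raw = abif_from_trace(simulate(random_seq(10, 2), seed=2))
        with pytest.raises(TraceFormatError, match="truncated"):
            read_abi(raw[:140])


class TestScf:
    def test_write_read_write_byte_identical(self):
        trace = simulate(random_seq(30, 3), noise_sd=8, seed=3)
        raw = write_scf(trace)
        again = write_scf(read_scf(raw))
        assert raw == again

    @pytest.mark.parametrize("seed", range(25))
    def test_round_trip_equals_fieldwise(self, seed):
        trace = simulate(random_seq(20 + seed * 7 % 90, seed),
                         noise_sd=float(seed % 4) * 5, seed=seed)
        assert read_scf(write_scf(trace)) == trace

    def test_bad_magic(self):
        with pytest.raises(TraceFormatError, match="not an SCF file"):
            read_scf(b"GARBAGE!" + b"\0" * 200)

    def test_v2_rejected(self):
        trace = simulate("ACGTACGTAC", noise_sd=0, seed=0)
        raw = bytearray(write_scf(trace))
        raw[36:40] = b"2.00"  # version field
        with pytest.raises(TraceFormatError, match="unsupported SCF version"):
            read_scf(bytes(raw))

    def test_signal_overflow(self):
        sig = np.zeros((4, 10), dtype=np.int64)
        sig[0, 5] = 70000
        trace = Chromatogram(sig, [5], "A", [30])
        with pytest.raises(TraceFormatError, match="signal overflow"):
            write_scf(trace)


class TestReports:
    @pytest.fixture
    def called(self):
        trace = simulate(random_seq(25, 11), noise_sd=5, seed=11)
        return call_bases(trace), trace

    def test_fasta_single_base(self):
        trace = simulate("A", noise_sd=0, seed=0)
        bc = call_bases(trace)
        text = write_trace_report(bc, trace, "fasta")
        lines = text.strip().split("\n")
        assert lines[0].startswith(">") and len(lines[1]) == 1

    def test_fasta_matches_primary(self, called):
        bc, trace = called
        text = write_trace_report(bc, trace, "fasta")
        assert text.strip().split("\n")[1] == bc.primary

    def test_json_row_counts(self, called):
        bc, trace = called
        doc = json.loads(write_trace_report(bc, trace, "json"))
        for ch in "ACGT":
            assert len(doc[f"trace{ch}"]) == trace.n_samples
        assert len(doc["peaks"]) == bc.n_basecalls

    def test_tsv_row_counts(self, called):
        bc, trace = called
        lines = write_trace_report(bc, trace, "tsv").strip().split("\n")
        assert sum(l.startswith("trace\t") for l in lines) == trace.n_samples
        assert sum(l.startswith("basecall\t") for l in lines) == bc.n_basecalls

    def test_fastq_quality_round_trip(self, called):
        bc, trace = called
        lines = write_trace_report(bc, trace, "fastq").strip().split("\n")
        decoded = [ord(c) - 33 for c in lines[3]]
        assert decoded == list(bc.qualities)

    def test_unknown_format(self, called):
        bc, trace = called
        with pytest.raises(UnsupportedFormatError, match="unsupported format"):
            write_trace_report(bc, trace, "xml")


class TestSimulator:
    def test_deterministic(self):
        spec = dict(allele_sequences=("ACGTAGGCAT",), allele_fractions=(1.0,),
                    noise_sd=12.0, seed=99)
        t1 = synthesize_chromatogram(SimulationSpec(**spec))
        t2 = synthesize_chromatogram(SimulationSpec(**spec))
        assert t1 == t2

    def test_noiseless_recovery(self):
        trace = simulate("ACGT", noise_sd=0, seed=0)
        assert call_bases(trace, 0.33).primary == "ACGT"

    def test_peak_positions_are_signal_maxima(self):
        seq = random_seq(50, 5)
        trace = simulate(seq, noise_sd=0, seed=5)
        for i, base in enumerate(seq):
            c = "ACGT".index(base)
            p = trace.peak_positions[i]
            window = trace.signal[c, max(0, p - 6):p + 7]
            top = int(np.argmax(window)) + max(0, p - 6)
            assert abs(top - p) <= 1

    def test_het_snv_equal_peaks(self):
        a1 = "ACGTACGTACGTACGTACGT"
        a2 = a1[:10] + "A" + a1[11:]
        assert a1[10] != "A"
        trace = simulate((a1, a2), (0.5, 0.5), noise_sd=0, seed=0)
        bc = call_bases(trace)
        pv = bc.peak_values[10]
        c1, c2 = "ACGT".index(a1[10]), "ACGT".index("A")
        assert abs(int(pv[c1]) - int(pv[c2])) <= 1

    def test_invalid_fractions(self):
        with pytest.raises(SimulationError, match="invalid fractions"):
            SimulationSpec(("ACGT", "ACGT"), (0.5, 0.6))

    def test_unresolvable_peaks_rejected(self):
        with pytest.raises(SimulationError):
            SimulationSpec(("ACGT",), (1.0,), peak_spacing=4, peak_sigma=5.0)
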