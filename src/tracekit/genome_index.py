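"""FM-index over a FASTA reference, with k-mer seed anchoring of traces.

The index is a Burrows-Wheeler transform of the concatenated reference
records (separated by sentinels) with a C-array, a checkpointed occurrence
table (default every 64 BWT positions) and a sampled suffix array (default
every 32th suffix).  Backward search gives exact pattern counts; locations
are recovered by LF-stepping to the nearest suffix-array sample.  'N' in
the reference is a real symbol that no A/C/G/T pattern matches, so traces
never anchor into assembly gaps.

``anchor_trace`` places a basecalled trace in the reference by voting:
every k-mer of the quality-trimmed primary sequence (and of its reverse
complement) is located, and each hit votes for a (record, strand, diagonal)
bin, where diagonal = hit offset - k-mer start.  The winning bin defines
the anchor window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .errors import AmbiguousAnchorError, AnchorError, TraceKitError
from .iupac import reverse_complement

# symbol codes: 0 = terminal sentinel, 1 = record separator,
# 2..6 = A, C, G, N, T (alphabetical keeps backward search simple)
_CODE = {"A": 2, "C": 3, "G": 4, "N": 5, "T": 6}
_NSYM = 7
_FILE_MAGIC = "tracekit-fmindex-v1"


def _suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), pure numpy)."""
    n = len(text)
    rank = text.astype(np.int64)
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        tmp[order[0]] = 0
        prev = order[:-1]
        cur = order[1:]
        newer = (rank[cur] != rank[prev]) | (key2[cur] != key2[prev])
        tmp[cur] = np.cumsum(newer)
        rank = tmp.copy()
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


@dataclass
class GenomeAnchor:
    """Seed-voted placement of a trace on the reference."""

    record: str
    strand: str  # "forward" | "reverse"
    start: int   # 0-based half-open window on the forward strand
    end: int
    seed_count: int


class FMIndex:
    """FM-index of one or more reference sequences."""

    def __init__(self, names, seqs, occ_rate: int = 64, sa_rate: int = 32):
        if not names:
            raise TraceKitError("no sequences")
        self.names = list(names)
        self.seqs = [s.upper() for s in seqs]
        self.lengths = np.array([len(s) for s in self.seqs], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths + 1)))[:-1]
        self.occ_rate = int(occ_rate)
        self.sa_rate = int(sa_rate)
        self._build()

    # -- construction -------------------------------------------------
    def _build(self):
        chunks = []
        for s in self.seqs:
            codes = np.fromiter((_CODE.get(c, 5) for c in s), dtype=np.int64,
                                count=len(s))
            chunks.append(codes)
            chunks.append(np.array([1], dtype=np.int64))
        text = np.concatenate(chunks)
        text[-1] = 0  # unique terminal sentinel replaces last separator
        self.text = text
        n = len(text)
        sa = _suffix_array(text)
        self.bwt = text[(sa - 1) % n]
        counts = np.bincount(text, minlength=_NSYM)
        self.C = np.concatenate(([0], np.cumsum(counts)))[:_NSYM]
        # checkpointed occurrence counts every occ_rate positions
        onehot = (self.bwt[:, None] == np.arange(_NSYM)[None, :]).astype(np.int64)
        cum = np.cumsum(onehot, axis=0)
        self._occ_cum = cum  # helper for checkpoints; sliced below
        self.occ_checkpoints = cum[self.occ_rate - 1::self.occ_rate].copy()
        del self._occ_cum
        # sampled suffix array: keep SA values at sampled BWT rows
        mask = sa % self.sa_rate == 0
        self.sa_sample_rows = np.flatnonzero(mask).astype(np.int64)
        self.sa_sample_vals = sa[mask].astype(np.int64)
        self._sa_marked = np.zeros(n, dtype=bool)
        self._sa_marked[self.sa_sample_rows] = True
        self._sa_lookup = np.full(n, -1, dtype=np.int64)
        self._sa_lookup[self.sa_sample_rows] = self.sa_sample_vals

    @classmethod
    def from_fasta(cls, path, occ_rate: int = 64, sa_rate: int = 32) -> "FMIndex":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append("".join(c if c in "ACGT" else "N"
                                for c in str(rec.seq).upper()))
        if not names:
            raise TraceKitError("no sequences")
        return cls(names, seqs, occ_rate, sa_rate)

    # -- core queries --------------------------------------------------
    def _occ(self, sym: int, pos: int) -> int:
        """Number of `sym` in bwt[:pos]."""
        if pos <= 0:
            return 0
        cp = pos // self.occ_rate - 1
        base = int(self.occ_checkpoints[cp, sym]) if cp >= 0 else 0
        start = (cp + 1) * self.occ_rate
        if start < pos:
            base += int(np.count_nonzero(self.bwt[start:pos] == sym))
        return base

    def _backward_search(self, pattern: str):
        lo, hi = 0, len(self.bwt)
        for ch in reversed(pattern.upper()):
            sym = _CODE.get(ch)
            if sym is None or ch == "N":
                raise TraceKitError("invalid pattern")
            lo = int(self.C[sym]) + self._occ(sym, lo)
            hi = int(self.C[sym]) + self._occ(sym, hi)
            if lo >= hi:
                return 0, 0
        return lo, hi

    def count(self, pattern: str) -> int:
        lo, hi = self._backward_search(pattern)
        return hi - lo

    def _sa_value(self, row: int) -> int:
        steps = 0
        while not self._sa_marked[row]:
            sym = int(self.bwt[row])
            row = int(self.C[sym]) + self._occ(sym, row)
            steps += 1
        return (int(self._sa_lookup[row]) + steps) % len(self.bwt)

    def locate(self, pattern: str):
        """Sorted (record_name, 0-based offset) of all exact occurrences."""
        if not pattern:
            raise TraceKitError("invalid pattern")
        lo, hi = self._backward_search(pattern)
        out = []
        for row in range(lo, hi):
            gpos = self._sa_value(row)
            rec = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
            off = gpos - int(self.offsets[rec])
            if off + len(pattern) <= int(self.lengths[rec]):
                out.append((self.names[rec], off))
        out.sort(key=lambda t: (self.names.index(t[0]), t[1]))
        return out

    def sequence(self, record: str, start: int = 0, end: int | None = None) -> str:
        seq = self.seqs[self.names.index(record)]
        return seq[start:end if end is not None else len(seq)]

    def record_length(self, record: str) -> int:
        return int(self.lengths[self.names.index(record)])

    # -- persistence ---------------------------------------------------
    def save(self, path):
        meta = "\n".join([_FILE_MAGIC, str(self.occ_rate), str(self.sa_rate)]
                         + self.names)
        with open(path, "wb") as fh:
            np.savez(fh,
                     meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                     lengths=self.lengths,
                     text=self.text.astype(np.uint8))

    @classmethod
    def load(cls, path) -> "FMIndex":
        with np.load(str(path)) as z:
            meta = bytes(z["meta"]).decode().split("\n")
            if meta[0] != _FILE_MAGIC:
                raise TraceKitError("not a tracekit index file")
            occ_rate, sa_rate = int(meta[1]), int(meta[2])
            names = meta[3:]
            lengths = z["lengths"]
            text = z["text"].astype(np.int64)
        inv = {v: k for k, v in _CODE.items()}
        seqs = []
        for name, ln, off in zip(names, lengths,
                                 np.concatenate(([0], np.cumsum(lengths + 1)))):
            seqs.append("".join(inv[int(c)] for c in text[off:off + ln]))
        return cls(names, seqs, occ_rate, sa_rate)


def build_index(fasta_path, occ_rate: int = 64, sa_rate: int = 32) -> FMIndex:
    """Build an FM-index from a FASTA file (non-ACGT symbols become N)."""
    return FMIndex.from_fasta(fasta_path, occ_rate, sa_rate)


def anchor_trace(idx: FMIndex, basecalls, trim, k: int = 15,
                 flank: int = 50) -> GenomeAnchor:
    """Anchor a trace in the indexed reference by k-mer diagonal voting."""
    primary = basecalls.primary[trim.keep_start:trim.keep_end] \
        if not trim.empty else basecalls.primary
    if len(primary) < k:
        raise AnchorError("trace too short to anchor")
    trace_len = basecalls.n_basecalls

    votes: dict = {}
    for strand, seq in (("forward", primary),
                        ("reverse", reverse_complement(primary))):
        for start in range(0, len(seq) - k + 1):
            kmer = seq[start:start + k]
            if "N" in kmer:
                continue
            try:
                hits = idx.locate(kmer)
            except TraceKitError:
                continue
            for rec, off in hits:
                key = (rec, strand, off - start)
                votes[key] = votes.get(key, 0) + 1

    if not votes:
        raise AnchorError("trace not anchored")
    best = max(votes.values())
    winners = [key for key, v in votes.items() if v == best]
    if len(winners) > 1:
        raise AmbiguousAnchorError("ambiguous anchor", winners)
    rec, strand, diag = winners[0]
    rec_len = idx.record_length(rec)
    start = max(0, diag - flank)
    end = min(rec_len, diag + trace_len + flank)
    if start >= end:
        raise AnchorError("trace not anchored")
    return GenomeAnchor(rec, strand, start, end, best)
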