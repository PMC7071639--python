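"""Multi-trace assembly: reference-guided and de novo progressive MSA.

Reference-guided mode aligns every trace to the reference in both
orientations (profile-to-sequence), ranks traces by best score, then grows
an MSA by profile-to-profile alignment, with the growing MSA's overhangs
free so each trace dovetails into it.  De novo mode scores all pairwise
trace overlaps, converts scores to distances, builds a UPGMA guide tree and
progressively merges sub-alignments from the leaves to the root.

Consensus classification per column follows the patching semantics:
``consensus`` (all covering traces agree, and match the reference if one is
present), ``mismatch`` (traces agree on a different base than the
reference), ``conflict`` (traces disagree), ``no_information`` (no trace
covers the column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy

from .align import Profile, Scoring, align_profile_to_profile, align_profile_to_sequence
from .basecalling import call_bases, quality_trim, TrimWindow
from .chromatogram import Chromatogram
from .errors import TraceKitError, UnsupportedFormatError
from .iupac import BASES, iupac_code
from .trace_alignment import POOR_ALIGNMENT_FRACTION

CONSENSUS = "consensus"
MISMATCH = "mismatch"
CONFLICT = "conflict"
NO_INFORMATION = "no_information"


@dataclass
class TraceMSA:
    """Gapped multiple alignment of traces (optionally with a reference row)."""

    rows: list                 # gapped strings, equal length
    names: list
    orientations: list         # "forward"/"reverse" per row ("" for reference)
    is_reference: list         # bool per row
    row_signals: list          # (L, 4) int arrays per row (None for reference)
    guide_tree: str | None = None   # newick (de novo mode)
    skipped: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def has_reference(self) -> bool:
        return any(self.is_reference)

    def trace_rows(self):
        return [r for r, isref in zip(self.rows, self.is_reference) if not isref]

    def reference_row(self):
        for r, isref in zip(self.rows, self.is_reference):
            if isref:
                return r
        return None

    def _spans(self):
        """Covered column span [first, last] per trace row."""
        spans = []
        for row in self.trace_rows():
            nz = [k for k, ch in enumerate(row) if ch != "-"]
            spans.append((nz[0], nz[-1]) if nz else (1, 0))
        return spans

    def consensus(self) -> str:
        """Majority consensus over trace rows (ties -> IUPAC ambiguity)."""
        rows = self.trace_rows()
        spans = self._spans()
        out = []
        for c in range(self.n_columns):
            votes = {}
            for row, (s, e) in zip(rows, spans):
                if s <= c <= e:
                    votes[row[c]] = votes.get(row[c], 0) + 1
            if not votes:
                continue
            top = max(votes.values())
            winners = sorted(ch for ch, n in votes.items() if n == top)
            if winners == ["-"]:
                continue
            winners = [w for w in winners if w != "-"]
            if len(winners) == 1:
                out.append(winners[0])
            else:
                bases = set()
                for w in winners:
                    bases |= set(w) & set(BASES) or {"N"}
                bases &= set(BASES)
                out.append(iupac_code(bases) if bases else "N")
        return "".join(out)


class _Sub:
    """A sub-alignment during assembly (rows + per-row metadata)."""

    def __init__(self, rows, names, orientations, is_reference, signals):
        self.rows = rows
        self.names = names
        self.orientations = orientations
        self.is_reference = is_reference
        self.signals = signals

    @classmethod
    def from_trace(cls, letters, name, orientation, peak_values):
        return cls([letters], [name], [orientation], [False],
                   [np.asarray(peak_values, dtype=np.int64)])

    @classmethod
    def from_reference(cls, seq, name="reference"):
        return cls([seq.upper()], [name], [""], [True], [None])

    def profile(self) -> Profile:
        return Profile.from_msa_rows(self.rows)

    def apply_path(self, path, side):
        """Re-gap rows according to an alignment path; side 0 = p, 1 = q."""
        new_rows = [[] for _ in self.rows]
        keep = []
        for col in path:
            idx = col[side]
            keep.append(idx)
            for r, row in enumerate(self.rows):
                new_rows[r].append("-" if idx is None else row[idx])
        self.rows = ["".join(r) for r in new_rows]
        new_signals = []
        for sig in self.signals:
            if sig is None:
                new_signals.append(None)
                continue
            out = np.zeros((len(path), 4), dtype=np.int64)
            for k, idx in enumerate(keep):
                if idx is not None:
                    out[k] = sig[idx]
            new_signals.append(out)
        self.signals = new_signals

    def absorb(self, other):
        self.rows += other.rows
        self.names += other.names
        self.orientations += other.orientations
        self.is_reference += other.is_reference
        self.signals += other.signals


def _prepare_trace(trace: Chromatogram, peak_ratio: float):
    """Basecalled, trimmed representations in both orientations."""
    out = {}
    for orientation in ("forward", "reverse"):
        t = trace if orientation == "forward" else trace.reverse_complement()
        bc = call_bases(t, peak_ratio)
        trim = quality_trim(bc)
        if trim.empty:
            trim = TrimWindow(0, bc.n_basecalls)
        prof = Profile.from_basecalls(bc, trim)
        letters = bc.consensus[trim.keep_start:trim.keep_end]
        pv = bc.peak_values[trim.keep_start:trim.keep_end]
        out[orientation] = (prof, letters, pv)
    return out


def _finish(sub: _Sub, guide_tree=None, skipped=()):
    # drop all-gap columns defensively
    L = len(sub.rows[0])
    keep = [c for c in range(L) if any(row[c] != "-" for row in sub.rows)]
    if len(keep) != L:
        sub.rows = ["".join(row[c] for c in keep) for row in sub.rows]
        sub.signals = [None if s is None else s[keep] for s in sub.signals]
    return TraceMSA(sub.rows, sub.names, sub.orientations, sub.is_reference,
                    sub.signals, guide_tree=guide_tree, skipped=list(skipped))


def assemble_reference_guided(traces, reference: str,
                              scoring: Scoring = Scoring(),
                              peak_ratio: float = 0.33) -> TraceMSA:
    """Assemble traces against a reference sequence.

    Traces are incorporated from highest to lowest alignment score in their
    best-scoring orientation; traces below the poor-alignment floor are
    skipped (listed in ``skipped``).
    """
    if not traces:
        raise TraceKitError("at least one trace required")
    reference = reference.upper()
    ranked = []
    skipped = []
    for t in traces:
        reps = _prepare_trace(t, peak_ratio)
        best = None
        for orientation, (prof, letters, pv) in reps.items():
            aln = align_profile_to_sequence(prof, reference, "semiglobal",
                                            scoring)
            if best is None or aln.score > best[0]:
                best = (aln.score, orientation, prof, letters, pv)
        score, orientation, prof, letters, pv = best
        if score < POOR_ALIGNMENT_FRACTION * scoring.match * len(prof):
            skipped.append(t.name)
            continue
        ranked.append((score, letters, t.name, orientation, prof, pv))
    if not ranked:
        raise TraceKitError("no trace aligned to the reference")
    # order key: score desc, then content (keeps input order irrelevant)
    ranked.sort(key=lambda r: (-r[0], r[1], r[2]))

    msa = _Sub.from_reference(reference)
    for score, letters, name, orientation, prof, pv in ranked:
        new = _Sub.from_trace(letters, name, orientation, pv)
        aln = align_profile_to_profile(prof, msa.profile(), "semiglobal",
                                       scoring)
        new.apply_path(aln.path, 0)
        msa.apply_path(aln.path, 1)
        msa.absorb(new)
    return _finish(msa, skipped=skipped)


def assemble_denovo(traces, scoring: Scoring = Scoring(),
                    peak_ratio: float = 0.33) -> TraceMSA:
    """Assemble traces without a reference via a UPGMA guide tree."""
    if len(traces) < 2:
        raise TraceKitError("de novo assembly requires at least two traces")
    reps = [_prepare_trace(t, peak_ratio) for t in traces]
    n = len(traces)

    # orientation resolution: greedy propagation along strongest overlaps
    same = np.zeros((n, n))
    diff = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = reps[i]["forward"][0]
            same[i, j] = same[j, i] = align_profile_to_profile(
                pi, reps[j]["forward"][0], "overlap", scoring).score
            diff[i, j] = diff[j, i] = align_profile_to_profile(
                pi, reps[j]["reverse"][0], "overlap", scoring).score
    best_pair = np.maximum(same, diff)
    orientations = [None] * n
    orientations[0] = "forward"
    placed = {0}
    while len(placed) < n:
        cand = [(best_pair[i, j], i, j) for i in placed for j in range(n)
                if j not in placed]
        _, i, j = max(cand)
        flip = diff[i, j] > same[i, j]
        oi = orientations[i]
        orientations[j] = ("reverse" if oi == "forward" else "forward") if flip \
            else oi
        placed.add(j)

    profs, letters, pvs = [], [], []
    for r, o in zip(reps, orientations):
        p, l, v = r[o]
        profs.append(p)
        letters.append(l)
        pvs.append(v)

    self_scores = np.array([scoring.match * len(p) for p in profs])
    score = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = align_profile_to_profile(profs[i], profs[j], "overlap",
                                         scoring).score
            score[i, j] = score[j, i] = s
    lonely = [i for i in range(n)
              if all(score[i, j] <= 0 for j in range(n) if j != i)]
    keep = [i for i in range(n) if i not in lonely]
    if len(keep) < 2:
        raise TraceKitError("traces share no overlap")

    dist = np.zeros((len(keep), len(keep)))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            if a < b:
                d = 1.0 - score[i, j] / max(self_scores[i], self_scores[j])
                dist[a, b] = dist[b, a] = max(d, 0.0)
    condensed = dist[np.triu_indices(len(keep), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    root = hierarchy.to_tree(Z)

    def build(node):
        if node.is_leaf():
            i = keep[node.id]
            sub = _Sub.from_trace(letters[i], traces[i].name,
                                  orientations[i], pvs[i])
            return sub, traces[i].name
        left, nl = build(node.left)
        right, nr = build(node.right)
        aln = align_profile_to_profile(left.profile(), right.profile(),
                                       "overlap", scoring)
        left.apply_path(aln.path, 0)
        right.apply_path(aln.path, 1)
        left.absorb(right)
        return left, f"({nl},{nr})"

    sub, newick = build(root)
    skipped = [traces[i].name for i in lonely]
    return _finish(sub, guide_tree=newick + ";", skipped=skipped)


def classify_consensus(msa: TraceMSA, reference_present: bool | None = None):
    """Per-column labels: consensus / mismatch / conflict / no_information."""
    if reference_present is None:
        reference_present = msa.has_reference
    ref_row = msa.reference_row() if reference_present else None
    rows = msa.trace_rows()
    spans = msa._spans()
    labels = []
    for c in range(msa.n_columns):
        chars = [row[c] for row, (s, e) in zip(rows, spans) if s <= c <= e]
        if not chars:
            labels.append(NO_INFORMATION)
            continue
        if len(set(chars)) > 1:
            labels.append(CONFLICT)
            continue
        ch = chars[0]
        if ref_row is None or ch == ref_row[c]:
            labels.append(CONSENSUS)
        else:
            labels.append(MISMATCH)
    return labels


def write_msa(msa: TraceMSA, format: str = "fasta_horizontal") -> str:
    """Render an assembly as horizontal/vertical FASTA or JSON."""
    if format == "fasta_horizontal":
        recs = []
        for name, row in zip(msa.names, msa.rows):
            recs.append(f">{name}\n{row}")
        return "\n".join(recs) + "\n"
    if format == "fasta_vertical":
        lines = ["".join(row[c] for row in msa.rows)
                 for c in range(msa.n_columns)]
        return "\n".join(lines) + "\n"
    if format == "json":
        doc = {
            "meta": {
                "nRows": len(msa.rows),
                "nColumns": msa.n_columns,
                "hasReference": msa.has_reference,
                "guideTree": msa.guide_tree,
                "skipped": msa.skipped,
            },
            "rows": [
                {
                    "name": name,
                    "orientation": orientation,
                    "isReference": isref,
                    "alignment": row,
                    "paddedSignal": None if sig is None else sig.tolist(),
                }
                for name, orientation, isref, row, sig in zip(
                    msa.names, msa.orientations, msa.is_reference, msa.rows,
                    msa.row_signals)
            ],
            "labels": classify_consensus(msa),
        }
        return json.dumps(doc)
    raise UnsupportedFormatError(f"unsupported format: {format!r}")
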