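"""Variant extraction from allele alignments, normalization, VCF output.

Each mismatch or gap run in the allele-versus-reference alignments becomes
a candidate variant; a candidate supported by both alleles is homozygous,
by one allele heterozygous.  Indels are converted to the VCF anchor-base
convention and left-aligned (shifted to the smallest possible reference
coordinate), so calls can be intersected directly with NGS call sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import VcfError
from .trace_alignment import AlignedTrace

VARIANT_QUALITY_CAP = 60


@dataclass(frozen=True)
class VariantRecord:
    """One normalized variant with its trace provenance.

    ``pos`` is 1-based on the forward reference strand; ``basecall_pos`` is
    the 1-based basecall index and ``signal_pos`` the 0-based sampling
    index in the *original* (as-input) trace.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    quality: int
    basecall_pos: int
    signal_pos: int

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def normalize_variant(pos0: int, ref: str, alt: str, refseq: str):
    """Left-align a variant against `refseq` (0-based pos0); idempotent."""
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif len(ref) != len(alt) and ref[-1] == alt[-1] and pos0 > 0:
            prev = refseq[pos0 - 1]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos0 -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def _raw_candidates(aln, refwin):
    """(pos0, ref, alt, allele_index_of_first_base) tuples from one
    allele-vs-reference alignment (window-local, unnormalized)."""
    path = aln.path
    # restrict to the aligned span (exclude free end gap columns)
    cols = [k for k, (i, j) in enumerate(path) if i is not None]
    if not cols:
        return []
    first, last = cols[0], cols[-1]
    out = []
    k = first
    allele_row, ref_row = aln.rows
    while k <= last:
        i, j = path[k]
        if i is not None and j is not None:
            a, r = allele_row[k], ref_row[k]
            if a != r and a in "ACGT" and r in "ACGT":
                out.append((j, r, a, i))
            k += 1
        elif j is None:  # insertion run in the allele
            run = []
            while k <= last and path[k][1] is None:
                run.append(path[k][0])
                k += 1
            prev_j = _prev_ref(path, k - len(run))
            if prev_j is not None:
                anchor = refwin[prev_j]
                ins = "".join(allele_row[kk] for kk in
                              range(k - len(run), k))
                out.append((prev_j, anchor, anchor + ins, run[0]))
        else:  # deletion run in the allele
            start_k = k
            while k <= last and path[k][0] is None:
                k += 1
            j_start = path[start_k][1]
            j_end = path[k - 1][1]
            prev_j = j_start - 1
            if prev_j >= 0:
                anchor = refwin[prev_j]
                deleted = refwin[j_start:j_end + 1]
                i_anchor = _prev_allele(path, start_k)
                out.append((prev_j, anchor + deleted, anchor,
                            i_anchor if i_anchor is not None else 0))
    return out


def _prev_ref(path, k):
    for kk in range(k - 1, -1, -1):
        if path[kk][1] is not None:
            return path[kk][1]
    return None


def _prev_allele(path, k):
    for kk in range(k - 1, -1, -1):
        if path[kk][0] is not None:
            return path[kk][0]
    return None


def call_variants(d, aligned: AlignedTrace, max_quality: int = VARIANT_QUALITY_CAP):
    """Genotyped, left-aligned variants from a decomposition result.

    The trace was oriented to the forward reference strand before
    decomposition, so coordinates and alleles are already forward-stranded;
    basecall/signal positions are mapped back to the input trace.
    """
    refwin = d.reference_window
    chrom = aligned.reference_name
    # global 0-based coordinate of reference_window[0]
    window_origin = aligned.reference_start + d.window_start

    per_allele = []
    for aln in (d.aln_allele1_ref, d.aln_allele2_ref):
        cands = {}
        for pos0, ref, alt, a_idx in _raw_candidates(aln, refwin):
            npos, nref, nalt = normalize_variant(pos0, ref, alt, refwin)
            key = (npos, nref, nalt)
            if key not in cands:
                cands[key] = a_idx
        per_allele.append(cands)

    bc = aligned.basecalls
    records = []
    seen = set()
    for which, cands in enumerate(per_allele):
        for key, a_idx in cands.items():
            if key in seen:
                continue
            seen.add(key)
            genotype = "hom" if key in per_allele[1 - which] else "het"
            npos, nref, nalt = key
            span = max(len(nref), len(nalt))
            i0 = int(d.basecall_index[min(a_idx, len(d.basecall_index) - 1)])
            idxs = [min(i0 + t, bc.n_basecalls - 1) for t in range(span)]
            qual = int(min(max_quality,
                           round(float(np.mean([bc.qualities[i] for i in idxs])))))
            records.append(VariantRecord(
                chrom=chrom,
                pos=window_origin + npos + 1,
                ref=nref,
                alt=nalt,
                genotype=genotype,
                quality=qual,
                basecall_pos=aligned.original_basecall_index(i0) + 1,
                signal_pos=aligned.original_signal_position(i0),
            ))
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


def write_vcf(variants, contigs, sample: str = "SAMPLE") -> str:
    """Render records as VCF 4.2 text.

    ``contigs`` maps contig name -> length.  Records must be sorted by
    (chrom, pos).
    """
    order = [(r.chrom, r.pos) for r in variants]
    if order != sorted(order):
        raise VcfError("records not sorted")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=tracekit",
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={int(length)}>")
    lines += [
        '##INFO=<ID=BASEPOS,Number=1,Type=Integer,'
        'Description="Basecall position in the trace (1-based)">',
        '##INFO=<ID=SIGNALPOS,Number=1,Type=Integer,'
        'Description="Signal (sampling) position in the trace (0-based)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for r in variants:
        gt = "1/1" if r.genotype == "hom" else "0/1"
        info = f"BASEPOS={r.basecall_pos};SIGNALPOS={r.signal_pos}"
        lines.append("\t".join([
            r.chrom, str(r.pos), ".", r.ref, r.alt, str(r.quality), "PASS",
            info, "GT:GQ", f"{gt}:{r.quality}",
        ]))
    return "\n".join(lines) + "\n"
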