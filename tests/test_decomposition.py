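"""Allele deconvolution, fraction estimation, variant calling and VCF."""

import random

import numpy as np
import pytest

from conftest import het_reads, random_seq, simulate
from oracles import left_align_shift
from tracekit.basecalling import call_bases
from tracekit.decomposition import (DecompositionResult, decompose,
                                    decompose_trace, estimate_allelic_fractions,
                                    find_breakpoint)
from tracekit.errors import DecompositionError, VcfError
from tracekit.iupac import reverse_complement
from tracekit.trace_alignment import align_trace
from tracekit.variants import (VariantRecord, call_variants, normalize_variant,
                               write_vcf)

TEMPLATE = random_seq(800, 20250)


def run_decompose(a1, a2=None, fractions=(0.5, 0.5), noise=10, seed=0,
                  maxindel=30, reference=None):
    trace = simulate((a1,) if a2 is None else (a1, a2),
                     (1.0,) if a2 is None else fractions,
                     noise_sd=noise, seed=seed)
    return decompose(trace, reference if reference is not None else TEMPLATE,
                     maxindel=maxindel)


class TestBreakpoint:
    def test_homozygous_trace_has_none(self):
        trace = simulate(TEMPLATE[:200], noise_sd=5, seed=1)
        at = align_trace(trace, TEMPLATE)
        assert find_breakpoint(at.basecalls, at) is None

    def test_het_deletion_breakpoint_near_edit(self):
        a1, a2 = het_reads(TEMPLATE, 250, 120, "del", 7)
        trace = simulate((a1, a2), (0.5, 0.5), noise_sd=10, seed=2)
        at = align_trace(trace, TEMPLATE)
        bp = find_breakpoint(at.basecalls, at)
        assert bp is not None and abs(bp - 120) <= 5

    def test_isolated_het_snvs_no_breakpoint(self):
        a1 = TEMPLATE[:250]
        a2 = list(a1)
        for p in (60, 130, 200):
            a2[p] = "A" if a1[p] != "A" else "G"
        trace = simulate((a1, "".join(a2)), (0.5, 0.5), noise_sd=5, seed=3)
        at = align_trace(trace, TEMPLATE)
        assert find_breakpoint(at.basecalls, at) is None


class TestErrorCurve:
    def test_homozygous_single_minimum_at_zero(self):
        _, res, _ = run_decompose(TEMPLATE[:200], noise=0)
        assert res.selected_offsets == [0]
        assert res.error_curve[0] == 0.0

    @pytest.mark.parametrize("kind,size,expected", [
        ("del", 7, -7),
        ("ins", 3, +3),
        ("del", 15, -15),
    ])
    def test_het_indel_minima(self, kind, size, expected):
        arg = size if kind == "del" else random_seq(size, 999)
        a1, a2 = het_reads(TEMPLATE, 250, 120, kind, arg)
        _, res, _ = run_decompose(a1, a2, noise=10, seed=4)
        assert sorted(res.selected_offsets) == sorted([0, expected])

    def test_error_floor_at_true_offset(self):
        # noiseless: threading error at the true offsets beats +-2 neighbours
        for size in (2, 5, 11):
            a1, a2 = het_reads(TEMPLATE, 250, 120, "del", size)
            _, res, _ = run_decompose(a1, a2, noise=0, seed=5)
            for d0 in (0, -size):
                for dd in (-2, -1, 1, 2):
                    d = d0 + dd
                    if d in res.error_curve and d not in (0, -size):
                        assert res.error_curve[d0] <= res.error_curve[d]

    def test_curve_spans_requested_range(self):
        a1, a2 = het_reads(TEMPLATE, 250, 120, "del", 7)
        _, res, _ = run_decompose(a1, a2, maxindel=25, seed=6)
        offs = sorted(res.error_curve)
        assert offs[0] <= -20 and offs[-1] >= 20

    def test_insufficient_post_breakpoint_signal(self):
        # divergence starts 5 bases before the end of the read
        a1, a2 = het_reads(TEMPLATE, 250, 245, "del", 7)
        trace = simulate((a1, a2), (0.5, 0.5), noise_sd=0, seed=7)
        at = align_trace(trace, TEMPLATE)
        bp = find_breakpoint(at.basecalls, at)
        if bp is not None:  # breakpoint found this close to the end
            with pytest.raises(DecompositionError,
                               match="insufficient signal after breakpoint"):
                decompose_trace(at.basecalls, at, TEMPLATE, maxindel=30)


class TestAlleles:
    def test_deletion_allele_reconstructed(self):
        a1, a2 = het_reads(TEMPLATE, 250, 120, "del", 7)
        _, res, _ = run_decompose(a1, a2, noise=0, seed=8)
        assert res.allele1 == a1
        assert res.allele2 == a2

    def test_degenerate_hom_trace(self):
        _, res, _ = run_decompose(TEMPLATE[:200], noise=0)
        assert res.degenerate
        assert res.allele1 == res.allele2 == TEMPLATE[:200]


class TestFractions:
    def _fit(self, true_f, seed, kind="del", size=5):
        a1, a2 = het_reads(TEMPLATE, 250, 120, kind, size)
        _, res, _ = run_decompose(a1, a2, fractions=(true_f, 1 - true_f),
                                  noise=10, seed=seed)
        return res.fractions

    def test_balanced_mixture(self):
        f1, f2 = self._fit(0.5, seed=9)
        assert abs(f1 - 0.5) <= 0.05 and abs(f1 + f2 - 1) < 1e-6

    def test_skewed_mixture(self):
        f1, f2 = self._fit(0.7, seed=10)
        assert abs(f1 - 0.7) <= 0.1

    def test_pure_allele_fit(self):
        # fit known distinct alleles against a single-allele trace
        a1, a2 = het_reads(TEMPLATE, 250, 120, "del", 7)
        trace = simulate(a1, noise_sd=10, seed=11)
        bc = call_bases(trace)
        d = DecompositionResult(
            allele1=a1, allele2=a2, error_curve={0: 0.0},
            selected_offsets=[0, -7], breakpoint=120,
            basecall_index=np.arange(len(a1)))
        f1, f2 = estimate_allelic_fractions(trace, bc, d)
        assert f1 >= 0.95

    def test_identical_alleles_degenerate(self):
        a1 = TEMPLATE[:100]
        trace = simulate(a1, noise_sd=0, seed=12)
        bc = call_bases(trace)
        d = DecompositionResult(allele1=a1, allele2=a1, error_curve={0: 0.0},
                                selected_offsets=[0], breakpoint=None,
                                basecall_index=np.arange(len(a1)))
        assert estimate_allelic_fractions(trace, bc, d) == (0.5, 0.5)
        assert d.degenerate


class TestNormalization:
    def test_repeat_deletion_left_aligned(self):
        # deleting one A of "CAAAT" must report at the leftmost A, anchor C
        refseq = "GGCAAATGG"
        pos, ref, alt = normalize_variant(4, "AA", "A", refseq)
        assert (pos, ref, alt) == (2, "CA", "C")

    def test_matches_exhaustive_shifting(self):
        rng = random.Random(13)
        refseq = "".join(rng.choice("ACGT") for _ in range(300))
        for _ in range(200):
            p = rng.randint(1, 290)
            L = rng.randint(1, 4)
            if rng.random() < 0.5:  # deletion
                ref, alt = refseq[p - 1:p + L], refseq[p - 1]
            else:  # insertion
                ins = "".join(rng.choice("ACGT") for _ in range(L))
                ref, alt = refseq[p - 1], refseq[p - 1] + ins
            got = normalize_variant(p - 1, ref, alt, refseq)
            exp = left_align_shift(refseq, p - 1, ref, alt)
            assert got == exp

    def test_idempotent(self):
        refseq = "GGCAAATGG"
        first = normalize_variant(4, "AA", "A", refseq)
        assert normalize_variant(*first, refseq) == first


class TestVariantCalling:
    def test_het_snv(self):
        a1 = TEMPLATE[:250]
        a2 = a1[:100] + ("T" if a1[100] != "T" else "G") + a1[101:]
        _, _, variants = run_decompose(a1, a2, noise=5, seed=14)
        assert len(variants) == 1
        v = variants[0]
        assert (v.pos, v.ref, v.alt, v.genotype) == \
            (101, a1[100], a2[100], "het")
        assert v.basecall_pos == 101

    def test_hom_snv(self):
        mutated = list(TEMPLATE[:250])
        mutated[130] = "C" if TEMPLATE[130] != "C" else "A"
        _, _, variants = run_decompose("".join(mutated), noise=5, seed=15)
        assert [(v.pos, v.genotype) for v in variants] == [(131, "hom")]

    def test_het_deletion_left_aligned(self):
        a1, a2 = het_reads(TEMPLATE, 250, 120, "del", 7)
        _, _, variants = run_decompose(a1, a2, noise=10, seed=16)
        indels = [v for v in variants if v.is_indel]
        assert len(indels) == 1
        v = indels[0]
        exp_pos, exp_ref, exp_alt = left_align_shift(
            TEMPLATE, 119, TEMPLATE[119:127], TEMPLATE[119])
        assert (v.pos - 1, v.ref, v.alt) == (exp_pos, exp_ref, exp_alt)
        assert v.genotype == "het"

    def test_reverse_trace_reports_forward_strand(self):
        a1 = TEMPLATE[:250]
        a2 = a1[:100] + ("T" if a1[100] != "T" else "G") + a1[101:]
        fwd = simulate((a1, a2), (0.5, 0.5), noise_sd=5, seed=17)
        rev = fwd.reverse_complement()
        _, _, v_fwd = decompose(fwd, TEMPLATE, maxindel=30)
        _, _, v_rev = decompose(rev, TEMPLATE, maxindel=30)
        assert [(v.pos, v.ref, v.alt, v.genotype) for v in v_fwd] == \
            [(v.pos, v.ref, v.alt, v.genotype) for v in v_rev]


class TestVcf:
    CONTIGS = {"ref": 800}

    def _parse(self, text, tmp_path):
        import pysam
        path = tmp_path / "out.vcf"
        path.write_text(text)
        return list(pysam.VariantFile(str(path)))

    def test_header_only_is_valid(self, tmp_path):
        text = write_vcf([], self.CONTIGS)
        assert self._parse(text, tmp_path) == []

    def test_het_snv_line(self, tmp_path):
        v = VariantRecord("ref", 101, "C", "T", "het", 42, 101, 1210)
        text = write_vcf([v], self.CONTIGS)
        recs = self._parse(text, tmp_path)
        assert len(recs) == 1
        r = recs[0]
        assert (r.pos, r.ref, r.alts[0]) == (101, "C", "T")
        assert r.samples[0]["GT"] == (0, 1)
        assert r.info["BASEPOS"] == 101 and r.info["SIGNALPOS"] == 1210

    def test_round_trip_called_variants(self, tmp_path):
        a1, a2 = het_reads(TEMPLATE, 250, 120, "del", 7)
        _, _, variants = run_decompose(a1, a2, noise=10, seed=18)
        text = write_vcf(variants, self.CONTIGS)
        recs = self._parse(text, tmp_path)
        assert [(r.pos, r.ref, r.alts[0]) for r in recs] == \
            [(v.pos, v.ref, v.alt) for v in variants]

    def test_unsorted_rejected(self):
        vs = [VariantRecord("ref", 50, "A", "T", "het", 30, 50, 600),
              VariantRecord("ref", 10, "C", "G", "hom", 30, 10, 120)]
        with pytest.raises(VcfError, match="records not sorted"):
            write_vcf(vs, self.CONTIGS)
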