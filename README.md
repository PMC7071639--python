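# tracekit

Basecalling, alignment, assembly and allele deconvolution of Sanger
(capillary) sequencing chromatograms, as a Python library and command-line
toolkit.

Sanger sequencing remains the workhorse for validating NGS variant calls and
for confirming CRISPR/Cas9-engineered mutations. Both use cases hit the same
wall: a PCR product from a diploid sample mixes the two alleles in a single
trace, and a heterozygous insertion or deletion desynchronizes them — every
peak downstream of the edit is a superposition of two bases, unreadable by
eye or by a naive basecaller. tracekit automates the whole path from raw
trace files to normalized VCF: it re-calls bases with an explicit
signal-to-noise model, anchors traces in arbitrarily large FM-indexed
references, separates mixed traces into their two constituent alleles,
genotypes the differences, and assembles multiple traces into a consensus.

## What it computes

**Basecalling.** For each basecall interval the four dye signals A, C, G, T
are compared against a peak-ratio threshold *r* (default 0.33): channel *c*
is "above" iff its peak ≥ *r* · max<sub>c'</sub> peak(c'). The primary call
is the tallest peak (or `N` if nothing is above), the secondary call is the
IUPAC code of the remaining above-threshold channels, and primary ≠ secondary
marks a heterozygous position. Qualities are re-estimated as
Q = −10·log₁₀(e) with e the non-primary share of the peak signal.

**Alignment.** All alignments are affine-gap dynamic programming (Gotoh
three-state recursion; defaults match 5, mismatch −4, gap open −10, gap
extend −1) over *profiles* — per-column weight matrices on
{A, C, G, T, N, gap} — in global, semiglobal (reference overhangs free) or
overlap (dovetail) mode. Genome-scale placement uses an FM-index
(BWT + sampled suffix array) with exact k-mer seeds voted on
(record, strand, diagonal) bins.

**Deconvolution.** For every candidate indel offset d ∈ [−maxindel,
+maxindel] the reference is threaded through the primary/secondary calls
downstream of the breakpoint; the decomposition error e(d) is the fraction
of positions where neither call matches the shifted reference. The two
smallest local minima of e(d) are the allele offsets (0 = reference-length
allele; −k = k bp deletion; +k = k bp insertion) — indels up to 1000 bp are
recoverable. Allelic fractions f₁ + f₂ = 1 are estimated by constrained
least-squares reconstruction of the observed peak heights from the two
allele base patterns. Variants are called by aligning each allele back to
the reference, genotyped (both alleles → hom, one → het), left-aligned and
written as VCF 4.2 with the originating basecall and signal positions.

**Assembly.** Reference-guided: traces are ranked by alignment score and
folded into a growing MSA by profile-to-profile alignment. De novo:
pairwise overlap scores → UPGMA guide tree → progressive alignment. Columns
are classified as consensus / mismatch / conflict / no-information for
sequence-patching workflows.

A chromatogram simulator (Gaussian peaks per base, mixture weights per
allele, truncated additive noise) generates every test input, so the whole
pipeline is testable without instrument data.

## Worked example

Simulate a 50/50 heterozygous 7 bp deletion at position 120 of a 250 bp
read, then deconvolute it against the template:

```sh
$ tracekit simulate --length 250 --seed 4 --edit del:120:7 -o mix
$ tracekit decompose mix.scf -g ref.fa --maxindel 30 -o dec
$ grep -v '^##' dec.vcf
#CHROM  POS  ID  REF       ALT  QUAL  FILTER  INFO                        FORMAT  mix
ref     120  .   CGCATTTA  C    12    PASS    BASEPOS=120;SIGNALPOS=1440  GT:GQ   0/1:12
```

The JSON report shows how the call was made:

```
selectedOffsets: [0, -7]
breakpoint: 116
fractions: [0.501, 0.499]
error(0)=0.000  error(-7)=0.022  error(-15)=0.567
```

The error curve has local minima at offset 0 (the reference-length allele)
and at −7 (the deletion allele); threading at any other offset mismatches
more than half the calls. The dense run of secondary basecalls begins at
basecall 116, the mixture is recovered as essentially 50/50, and the
deletion is reported left-aligned with its anchor base (`CGCATTTA→C` at
position 120), linked back to basecall 120 / sampling point 1440 of the
trace. `dec.json` also carries the full error curve, both allele sequences
and all three pairwise alignments (allele1–reference, allele2–reference,
allele1–allele2).

## Layout

| module | contents |
| --- | --- |
| `tracekit.chromatogram` | trace container, simulator |
| `tracekit.io` | ABIF/SCF readers, SCF writer, JSON/TSV/FASTA/FASTQ reports |
| `tracekit.basecalling` | peak-ratio calls, quality re-estimation, trimming |
| `tracekit.genome_index` | FM-index build/save/load, locate, seed anchoring |
| `tracekit.align` | profiles and affine-gap DP (global/semiglobal/overlap) |
| `tracekit.trace_alignment` | three reference modes, ClustalW/JSON reports |
| `tracekit.decomposition` | breakpoint, error curve, alleles, fractions |
| `tracekit.variants` | variant extraction, left-alignment, VCF 4.2 |
| `tracekit.assembly` | reference-guided and de novo MSA, classification |
| `tracekit.cli` | `tracekit index/basecall/align/decompose/assemble/simulate` |
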