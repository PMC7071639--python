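# Methods

This note documents the models, algorithms and numerical choices behind
tracekit, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Trace model and simulator

A chromatogram is a 4 × S matrix of non-negative 16-bit dye intensities
(channel order A, C, G, T) plus, per basecall, a peak sampling position,
the instrument's stored base and a phred quality. ABIF input reads the
processed channels DATA9–DATA12 (not the raw DATA1–4), resolves channel
order through the filter-wheel tag FWO_1 (default `GATC` when absent), and
prefers directory entry 2 of PLOC/PBAS/PCON over entry 1 — entry 2 is
conventionally the basecaller's output; files carrying only entry 1 still
load. SCF support is version 3 only (16-bit samples, delta-delta
decoding); the writer emits canonical v3 that round-trips byte-identically.

The simulator renders each allele as a train of Gaussian peaks: base *i* of
an allele adds amplitude · fraction · exp(−(x−p·i)²/2σ²) on its channel,
with one peak every `peak_spacing` samples (default 12, jittered ±1 sample)
and σ = `peak_sigma` (default 3). Both alleles share the same peak grid, so
a heterozygous indel makes the allele sequences superimpose base-for-base
downstream of the edit — the same phenomenon a real mixed PCR product
shows, where both alleles migrate at the same rate. Additive Gaussian
noise (default sd 10 ≈ 1% of the default amplitude 1000) is truncated at
zero. What the simulator does *not* model: peak-width growth and signal
decay along the read, dye mobility shifts, primer artefacts, and
polymerase slippage; passing tests therefore demonstrate algorithmic
correctness under idealized peak geometry, not robustness to every failure
mode of real capillary data.

## Basecalling

Basecall intervals are bounded by the midpoints between adjacent peak
positions. Per interval, `peak_values[c]` is the maximum of channel c; a
channel is above threshold iff its peak ≥ `peak_ratio` × the tallest
channel *in the same interval* (a relative, signal-to-noise style cut) and
is strictly positive. Primary = tallest channel, or `N` when nothing is
above. Secondary = IUPAC code of the other above-threshold channels; `N`
when all four are up; equal to the primary when it is alone (which makes
het detection a simple primary ≠ secondary test). Consensus = IUPAC union
of primary and secondary.

Qualities use Q = round(−10·log₁₀(max(e, 10⁻⁴))) clamped to [1, 40], with
e the non-primary share of the four channel values. One deliberate choice:
e is measured on the channel values **sampled at the peak position**, not
on the interval maxima. With peaks σ = 3 spaced 12 samples apart, the
interval maximum of a neighbouring base's channel picks up that peak's
tail (≈ 13% of its height at the interval boundary), so interval maxima
would put even a perfectly clean trace at e ≈ 0.21 (Q7) and the default
trimmer would discard everything. Sampling at the peak centre removes the
bleed while keeping genuine co-peaks (het positions) fully visible. The
threshold logic, by contrast, deliberately keeps interval maxima, so
slightly displaced secondary peaks are still caught.

Quality trimming slides a `window` (default 10) across the quality string
and keeps from the first window whose mean ≥ `min_mean_quality` (default
20) through the end of the last such window. On traces shorter than the
window, or with no qualifying window, the trim is empty; pipeline entry
points then fall back to the full basecall range rather than failing.

## Genome index and anchoring

The FM-index stores the BWT of the concatenated reference records (unique
terminal sentinel, one separator symbol between records; suffix array by
prefix doubling), the C-array, occurrence checkpoints every 64 BWT rows
and suffix-array samples every 32 text positions — a memory/speed balance
adequate for desk-scale genomes. `N` is a first-class text symbol that no
A/C/G/T pattern matches, so assembly gaps can never attract seeds.
Patterns are restricted to A/C/G/T. The index file is a versioned NumPy
container holding the text and metadata; the structure is rebuilt on load
(it is not interoperable with other tools' index formats).

Anchoring takes every k-mer (default k = 15) of the quality-trimmed
primary sequence and of its reverse complement, locates all exact hits,
and lets each hit vote for a (record, strand, diagonal = offset − k-mer
start) bin. The winning bin defines the anchor window, the diagonal ± a
flank (default 50) clipped to the record. No hits on either strand raises
"trace not anchored"; two bins tied at the maximal vote count raise
"ambiguous anchor" with both candidates attached.

## Alignment engine

All alignments are Gotoh three-state affine DP (states: substitution, gap
in row 1, gap in row 2; a gap of length k costs open + k·extend), with
scores match 5, mismatch −4, gap open −10, gap extend −1 — EDNAFULL-like
DNA defaults; no substitution matrix is imposed by the data model. `N`
scores 0 against everything so unreadable peaks neither help nor hurt.

Profile columns weight {A, C, G, T, N, gap}; substitution score of two
columns is the weight-weighted expectation of base scores, and gap mass
contributes nothing to substitution but scales the gap penalty of the
column it sits in (inserting a mostly-gap MSA column is nearly free; the
plausible alternative — flat penalties regardless of gap mass — over-
penalizes sparse MSA columns). End-gap policy: `global` charges both
rows' ends; `semiglobal` frees the second row's overhangs (used whenever a
trace is contained in a reference or MSA); `overlap` frees both (used for
read dovetailing and de novo assembly). Traceback prefers diagonal, then
gap-in-row-2, then gap-in-row-1, making alignments deterministic.

The row-wise recursion is vectorized in NumPy; the in-row horizontal gap
state, which carries a sequential dependency, is computed exactly by a
prefix-max scan over cumulative extension costs.

## Trace-to-reference alignment

Genome mode follows a three-step scheme: (1) seed-anchor, (2) semiglobal
alignment of the *trimmed* profile to the anchored window to fix a
reliable core, (3) semiglobal alignment of the *full* profile to the core
extended by one full trace length on both sides (bounding DP cost while
guaranteeing the whole trace fits). Short-FASTA mode aligns the full
profile directly; wildtype mode aligns profile-to-profile against another
trace. Both orientations are always evaluated and the reverse-complement
trace is physically re-oriented on a reverse hit, so all downstream
coordinates live on the forward reference strand. A score below 30% of
the maximum attainable (5 × basecalls) sets a `poor_alignment` warning
flag rather than failing, so batch runs continue.

ClustalW output renders one consensus IUPAC letter per trace position (the
format cannot carry signal data); the JSON report carries the
alignment-padded per-column 4-channel signals, with zero signal in columns
where the trace has a gap.

## Deconvolution

The breakpoint detector scans for the smallest basecall index b where the
fraction of het calls in the window [b, b+15) exceeds 0.4 while the
prefix before b stays below 0.1 — dense enough to exclude isolated het
SNVs, which produce no downstream shift. The thresholds are conventions;
the phenomenon itself (a wall of secondary calls after a het indel) is
robust to their exact values.

For each offset d in [−maxindel, +maxindel] (default and maximum 1000),
threading compares basecall i ≥ b with reference base r_b + (i−b) − d; a
position errs when neither the primary nor any base of the secondary's
IUPAC expansion matches. Offsets with fewer than 10 comparable positions
are dropped; the error curve is reported in full. Local minima (≤ both
neighbours) are ranked by (error, |offset|) and the two best selected;
allele 1 is the more reference-like offset. A single minimum at 0 means
both alleles are reference-length. Degenerate inputs are well-defined: no
breakpoint and no het SNVs yields allele1 = allele2 = primary with a
one-point error curve; fewer than 10 basecalls after the breakpoint is an
error ("insufficient signal after breakpoint").

Allele construction: before the breakpoint, het SNVs are phased by giving
the reference-matching base to allele 1 (true phase is unknowable from a
single trace; this rule is deterministic and conservative). After the
breakpoint, allele 1 takes the call matching its shifted reference,
allele 2 the remaining call, preferring agreement with its own shifted
reference.

Fractions (f₁, f₂ = 1 − f₁) minimize Σᵢ Σ_c (obsᵢ(c) − Aᵢ·(f₁·1[a₁ᵢ = c] +
f₂·1[a₂ᵢ = c]))² over post-breakpoint basecalls with distinct allele
bases, Aᵢ = tallest channel peak at i; the minimizer is closed-form,
clipped to [0, 1]. Using per-basecall peak maxima rather than full curve
shapes is a simplification that is robust to peak-width variation.
Identical alleles return (0.5, 0.5) with a degeneracy flag.

Variant calling aligns each allele to the reference window (semiglobal),
turns mismatch and gap runs into candidates, normalizes indels to
anchor-base form, left-aligns (idempotently), genotypes (candidate in
both alleles → hom, one → het), and writes VCF 4.2 with INFO fields
BASEPOS/SIGNALPOS pointing back into the original trace and GT:GQ per
sample. Genotype quality is the mean basecall quality over the variant's
basecalls, capped at 60 — a pragmatic proxy; no calibrated genotype
likelihood model is attempted.

## Assembly

Reference-guided: each trace is aligned in both orientations
(profile-to-sequence, semiglobal), ranked by best score (ties broken by
row content so input order is irrelevant), and folded into the growing
MSA by profile-to-profile alignment with the MSA's overhangs free. Traces
under the poor-alignment floor are skipped and reported. De novo:
orientations are propagated greedily along the strongest pairwise
overlaps, distances d(i,j) = 1 − score(i,j)/max(selfᵢ, selfⱼ) feed UPGMA
(average linkage — deterministic, and adequate for the shallow trees of
trace assembly), and sub-alignments merge progressively in overlap mode;
traces overlapping nothing (all pairwise scores ≤ 0) are excluded with a
warning. Pairwise overlap scoring uses quality-trimmed profiles.

Per-column consensus is the majority over covering trace rows (a row
covers the columns between its first and last non-gap character; internal
gaps count as deletion votes), ties resolved to IUPAC ambiguity codes.
Classification against an optional reference row: no coverage →
`no_information`; all covering rows agree and match the reference (or no
reference) → `consensus`; all agree but differ → `mismatch`; disagreement
→ `conflict`. The interactive "edited" state of patching GUIs has no
meaning in batch assembly and is not emitted.

## Problem sizes and determinism

The test and acceptance workloads run on simulated data at desk scale:
references up to tens of kilobases for anchoring, reads of 250–800 bases,
100-replicate sweeps for indel-size (1–30 bp) and fraction (0.3–0.7)
recovery, a 1.5 kb six-trace assembly, and the 1000 bp deletion
deconvolution at maxindel 1000. Every stochastic component (simulator
noise, fixture generation) is seeded; identical seeds give bit-identical
traces and byte-identical CLI outputs.

## Known limitations

- At most two alleles; mosaic mixtures and >2-allele deconvolution are out
  of scope, as are guide-RNA-aware editing-efficiency scores.
- Pre-breakpoint het SNV phasing is conventional, not inferred.
- The quality model is a signal-share heuristic, not a calibrated error
  probability; trimming defaults assume it.
- SCF v2 is read-rejected and never written; ZTR and raw ABIF channels are
  unsupported; no mobility-shift correction.
- The index file format is tool-specific.
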