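# Methods

`squigtail` analyses poly(A) tails of therapeutic mRNAs at raw nanopore
signal level. This note documents the models, the synthetic data they are
validated on, the numerical choices, and the limits of what the validation
shows.

## Why signal space

Direct RNA sequencing (DRS) reads a molecule 3' end first, recording
picoampere current as each k-mer occupies the pore. Therapeutic mRNAs
substitute every uridine with N1-methyl-pseudouridine (mPsi), which
perturbs the recorded current and degrades basecalling, so sequence-space
mapping misses a large share of vaccine reads. The package therefore works
directly on the raw trace: reads are identified by matching the expected
squiggle of the vaccine body to the signal, and tails are measured by
segmenting the trace, with no alignment requirement.

Two vaccine tail architectures drive the design:

* **mRNA-1273**: a ~100-nt poly(A) tract terminated by an mPsiCmPsiAG
  pentamer (a restriction-site residue; written UCUAG here). Its presence
  marks an unprocessed 3' end; its loss is the first step of decay, so the
  pentamer flag splits intact from processed molecules.
* **BNT162b2**: a composite tail of 30 A, a 10-nt non-A linker, then 70 A.

## Pore model and simulator

The shipped pore model is a synthetic 5-mer Gaussian table drawn once from
a fixed seed (`scripts/make_pore_model.py`), not a vendor chemistry table:
the algorithms must not depend on any particular chemistry, and a
self-contained model lets every test carry exact ground truth. Two
conventions keep it on a realistic DRS scale: the homopolymer-A level is
pinned at 108.9 pA and the sequencing adapter is a distinct constant level
(76 pA). mPsi is modelled as an additive shift (default +4 pA) on every
U-containing k-mer; the magnitude and sign of the real shift are not
established, so this is an explicitly free parameter, and setting it to 0
recovers the unmodified model exactly. The generation script enforces, at
build time, that all pentamer/linker junction k-mers sit >= 5 pA from the
poly(A) level, so segmentation is identifiable in principle.

The simulator emits, for each nucleotide, the level of the 5-mer window
ending at that base (clamped at the 5' start). This convention puts all
junction blur on the 5'-ward segment: the terminal pentamer occupies
exactly five distinct non-A states, and every junction into a poly(A)
segment hides exactly k-1 = 4 translocation steps inside the neighbouring
segment's levels — a deterministic footprint the decoder corrects (below).
Ground-truth sample boundaries follow per-nucleotide architecture labels,
so with dwell dispersion 0 a 100-nt tail at 3012 Hz / 70 nt/s spans exactly
round(100 x 3012/70) = 4303 samples.

Defaults (all configurable, chosen as plausible RNA002-scale values, never
asserted as measured): sampling 3012 Hz, translocation 70 nt/s, Gaussian
current noise sd 1.5 pA, per-nt dwell Gamma-distributed with CV 0.3
(dispersion 0 means deterministic cumulative-rounded dwells; dwells are
always >= 1 sample). Cohort presets fix the study conditions: crude
mRNA-1273 carries the pentamer on 80% of reads (~20% lacking); the
re-adenylated preset elongates the tail by 24 A with most reads lacking
the pentamer; spike-in ladder standards cycle deterministically through
10/15/30/45/60/90/120 A; transcript bodies are fixed 300-nt (150-nt for
the ladder) synthetic random sequences. Desk-scale bodies keep traces
around 15-20k samples; nothing in the algorithms depends on body length
beyond the read-rate estimate.

## Read identification (subsequence DTW)

The query is the expected squiggle of the vaccine body's 5'-most 500
k-mer states, reversed into capture order; the target is the read signal
collapsed by fixed-window averaging (window = half the mean dwell, ~21
samples) and z-normalised (mean 0, population sd 1). Subsequence DTW finds
the minimum-cost alignment of the full query to any contiguous target
span: free start and end in the target, symmetric step pattern (diagonal /
horizontal / vertical, unit weights), absolute-difference local cost. Ties
for the end column resolve to the rightmost minimum so an exact
subsequence match reports its full span.

A read matches when cost per alignment step falls below a threshold.
The default (0.32) is the midpoint between simulated positive
(matching-body, ~0.16/step) and negative (unrelated-body, ~0.48/step)
cohorts at default noise. Event averaging blends samples across state
boundaries, which leaves a structural cost floor of about 0.16/step even
for noiseless matching reads — the match statistic separates classes
cleanly but does not approach zero.

## Tail segmentation (Viterbi)

The trace is decoded with a left-to-right HMM in capture order:

    adapter -> [pentamer] -> polyA -> [linker -> polyA2] -> transcript

with pentamer (mode `pentamer`) and linker/polyA2 (mode `composite`)
optional and skippable. Emissions are Gaussian mixtures with one component
per constituent k-mer level: poly(A) is the single homopolymer level,
pentamer the five junction k-mers, linker its fourteen junction k-mers,
and the transcript body sixteen quantile bins of the whole level table.
Mixtures matter: a single broad Gaussian for heterogeneous states lets the
linker state absorb transcript stretches of single-tail reads, producing
spurious composite calls. Component sds combine the table sd with the
noise sd and 30% inflation against model mismatch. All emission parameters
derive from the shipped pore model — never from per-read ground truth.
Self-transitions are geometric with means set by expected segment
durations; likelihood ties prefer the higher-index predecessor, which
places ambiguous boundaries as early in the trace as possible.

Two corrections make the calls unbiased:

* **Junction footprint.** A 5-mer pore reports the pure homopolymer level
  for only T-(k-1) of a T-nt tail; each decoded transition out of a
  poly(A) state is therefore shifted (k-1) mean dwells later in time.
  After the shift, noiseless dispersion-0 boundaries match ground truth
  exactly, and segment lengths are unbiased. At default dispersion the
  poly(A)/transcript edge still carries the stochastic dwell of those
  hidden k-1 nucleotides (sd ~26 samples), an irreducible truth-side
  uncertainty of roughly half a nucleotide per read.
* **Read rate.** Lengths are durations x rate, with the per-read rate
  estimated from the transcript-body span (body length + k - 1 effective
  steps, because the raw body span absorbs the footprint). Rates outside
  [35, 140] nt/s fall back to the cohort median; RATE_FAIL is set only
  when no fallback exists. Reads too short for an adapter get NO_ADAPTER,
  reads without a decodable tail NO_POLYA; every read receives exactly one
  QC tag and lengths are reported (flagged) even on QC failure.

The pentamer flag requires a decoded pentamer span of at least 20 samples
(minimum segment durations: adapter 100, poly(A) 50, pentamer/linker 20
samples). In composite mode the linker/polyA2 structure must additionally
beat the single-tail topology by >= 500 log-likelihood units (model
comparison); spurious composite gains on simulated single-tail reads
measure ~100-210 while true composite tails gain > 1500, so the margin
sits far from both. A decoded linker below its minimum duration merges the
flanking poly(A) spans into one segment. Composite calls report segment
lengths 5'->3' (proximal polyA, linker, distal polyA); single tails report
the linker and second segment as 0.

## Sequence space and statistics

For basecalled data, the pentamer is TCTAG at the 3' end immediately after
a run of >= 10 A (exact match by default; substitutions configurable), and
per-read tail lengths come from the `pt:i` tag of primary SAM records
(secondary/supplementary skipped; missing or negative tags excluded and
counted). The 3'-RACE composition counter trims the RACE adapter, requires
a >= 6-T poly(A) signature, reverse-complements, keeps post-tail inserts
of length 0-10, prepends four A for the tail context (included in the
counts) and tallies per-position bases.

Tail distributions are summarised by the median (lengths are far from
normal). The mRNA-1273 convention summarises the pentamer-lacking
(processed) subset when flags are present; BNT162b2 uses all reads.
Shortened/elongated fractions use fixed thresholds near the 0.2/0.8
quantiles of crude vaccine RNA; the shipped presets are (85, 115) and
(95, 125) nt for DRS mRNA-1273/BNT162b2 and (80, 110) / (50, 80) for the
cDNA pipeline (which reports only the last poly(A) segment and runs
shorter); `estimate_thresholds` recomputes quantile thresholds
(linear-interpolation, "type 7") from any crude distribution. Per-transcript
comparisons use tie-corrected Kruskal-Wallis (chi-square approximation;
exact small-sample p-values out of scope) restricted to transcripts with
>= 20 reads in every condition, with Benjamini-Hochberg adjustment over the
tested transcripts only and significance at adjusted p < 0.05. Absolute
quantification is plain arithmetic: mass/molar-mass x Avogadro (50 ag of a
1321.81 kDa mRNA ~ 22.8 molecules — reported exactly, without rounding to
a round figure), and a log10(copies)-vs-Ct linear fit inverts qPCR
standard curves, flagging extrapolation; copies-per-cell is a division
with 100%-recovery assumptions stated, no hidden corrections.

## What the validation does and does not show

The recovery experiments (tests and `scripts/acceptance.py`) simulate
cohorts of 300-1000 reads under the presets above and check that the full
pipeline returns the design values: median intact tail 100 +/- 5 nt,
composite 30/10/70 +/- 3 nt, 20 +/- 3% pentamer-lacking, ladder standards
within max(3 nt, 5%), re-adenylation contrast 24 +/- 3 nt. Dynamic
programs are checked against brute-force enumeration oracles (subsequence
DTW on all monotone paths, Viterbi on all legal state sequences, BH
against the step-up definition), and the Kruskal-Wallis layer against its
nominal type-I error on 500 null transcripts.

The simulator reproduces read architecture, dwell statistics, current
noise and the mPsi shift, but not real-pore phenomena: no basecalling, no
adaptive event detection, no current drift, no stalls/skips, no RNA004
chemistry, and the synthetic level table is not a vendor model. Passing
recovery therefore demonstrates internal correctness and calibration of
the algorithms under the stated noise model — not performance on real
flow-cell data, where emission parameters and the DTW threshold would
need recalibration against real squiggles. The mPsi shift magnitude is a
free parameter throughout.
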