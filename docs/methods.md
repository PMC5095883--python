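# Methods

## Overview

`cfmito` analyses paired-end plasma sequencing data for the mitochondrial
fraction of cell-free DNA (cf-mtDNA): it reconstructs DNA fragments from
aligned read pairs, profiles their length distribution, estimates the mtDNA
fractional concentration with optional in-silico size selection, and calls
mitochondrial heteroplasmy with a quality-aware likelihood-ratio statistic,
comparing plasma against white blood cells (WBC). A synthetic-data module
generates reads and alignments with the same statistical structure so that
every stage is testable without access to patient sequencing data.

## Fragment reconstruction (`readproc`)

A read pair is retained when it is inward-facing (FR) on a single contig,
both mates have mapping quality strictly greater than 20, and each mate's
mismatch count (edit-distance tag; indels counted) is strictly below 5% of
its trimmed read length. A pair with one passing and one failing mate fails
as a whole. The fragment is the interval from the leftmost mate start to the
rightmost mate end; coordinates are 0-based half-open internally, converted
from SAM's 1-based convention at the boundary. PCR duplicates share
(reference, start, end) — orientation is constant once only FR pairs
survive — and the first-seen record is kept, which is deterministic and
equivalent to quality-based selection for counting purposes.

NUMT screening: a fragment assigned to the mitochondrial contig is kept only
if neither mate has a nuclear alignment whose alignment score is at least
its mitochondrial score; otherwise it is flagged ambiguous and excluded from
mitochondrial counts. When alignment-score tags are absent the filter falls
back to requiring MAPQ > 20 on the mitochondrial alignment and logs the
degradation.

The mitochondrial genome is treated as linear (16,569 bp); fragments
spanning the origin of the circular genome are out of scope (the simulator
never emits them; real-data wraparound is a known limitation).

## Size profiling (`sizeprof`)

The mtDNA fractional concentration is
`100 * mito fragments / mapped fragments`, computed over deduplicated,
filter-passing fragments (fragment-level counting; ratios are invariant to
the factor-of-two mate count). The sliding-window profile uses width 10 bp
and step 1 bp by default; windows with an empty denominator are reported as
missing rather than zero, and the peak is the maximum-concentration window
with ties broken toward the smallest start. Size selection keeps fragments
with `lo <= length <= hi`, bounds inclusive on both ends; the default 30–60
bp insert window corresponds to a 150–190 bp adaptor-ligated library, a
conversion taken as given rather than modelled. Fold tables round per-sample
ratios to 2 decimals and per-method means to 4 decimals (percent scale),
matching the precision used in the bundled comparison table.

## Heteroplasmy model (`hetcall`)

Bases with Phred quality below 20 are excluded from pileups. Where mates of
one fragment overlap a position, the base is counted once: the
higher-quality copy wins, read 1 preferred on ties. Because read 1 starts
from either fragment end with equal probability, this keeps strand
composition informative even for fully-overlapping very short fragments.

With `l` major-allele bases and `k` minor-allele bases, each with error
probability `eps_j = 10^(-Q_j/10)`, the log-likelihood of major-allele
frequency `f` is

    log L(f) = sum_major log[ f (1 - eps_j) + (1 - f) eps_j / 3 ]
             + sum_minor log[ (1 - f)(1 - eps_j) + f eps_j / 3 ]

A misread base lands uniformly on the three alternative bases, hence the
`eps/3` allocation; the simulator uses the same error channel. `f_het` is
the maximiser over [0, 1], found by golden-section search to absolute
tolerance 1e-6 (the log-likelihood is a sum of logs of affine functions of
`f`, hence concave and unimodal); tests validate it against a brute-force
grid. `f_homo` is the better of the boundary values {0, 1}. The statistic
is `LLR = log10 L(f_het) - log10 L(f_homo)`, base 10 so that the `LLR > 5`
cutoff corresponds to a false-positive rate below 1e-5 under the
homoplasmic error model; the calibration test verifies this empirically on
one million simulated homoplasmic pileups (depth 500, qualities mixed
Q20–Q40). Ties in major-allele identity (exact 50/50) are broken by the
reference allele first, then alphabetically. Only single-nucleotide
substitutions are considered; indels are excluded.

Calling criteria, all exposed as parameters with these defaults:

| criterion | WBC | plasma |
|---|---|---|
| depth | > 400 | > 50 |
| minor allele | frequency >= 1% | count >= 4 |
| strand | per-strand frequency >= 0.6% and 2x2 chi-square p >= 0.05 | observed >= 1x on each strand |
| statistic | LLR > 5 | LLR > 5 |

The chi-square test is the 2x2 minor/major-by-strand contingency test
without continuity correction at significance 0.05. The plasma depth
threshold is deliberately a knob: a coverage floor of 40 is equally
defensible for low-coverage plasma data, and the classifier below does not
depend on the choice.

### Shared-site classification

A candidate site is classified "both" (present in plasma and WBC) when all
of the following hold, and otherwise assigned to the compartment carrying
the primary call (higher LLR if both, error if neither is called and the
site is not shared):

1. LLR > 5 in at least one compartment;
2. both alleles of the pair are observed in both compartments — the pair is
   taken from the compartment with the stronger signal, and major/minor
   roles may flip between compartments;
3. the locally minor allele has count >= 2 in each compartment;
4. the locally minor allele is observed at least once on each strand in
   each compartment.

These criteria are evaluated independently of the per-compartment primary
calls: a site can be "both" even when it narrowly fails a primary criterion
in each compartment separately (e.g. plasma depth just under the floor with
a sub-1% WBC frequency), which is exactly the situation the looser shared
criteria exist for.

### Consensus export

Two consensus sequences per compartment substitute the major or minor
allele at each heteroplasmic site into the reference (standing in for the
sample's homoplasmic alleles elsewhere); the FASTA output is suitable for
external haplogroup classification. Conflicting calls at one position are
an error.

## Synthetic data (`simdata`)

Fragment lengths are drawn from truncated (>= 20 bp), discretised
log-normal mixtures, parameterised by mode: a log-normal with log-scale
`sigma` and mode `m` has `mu = log m + sigma^2`. Defaults:

| component | weight | mode | sigma | emulates |
|---|---|---|---|---|
| mito | 1.00 | 42 bp | 0.15 | very short cf-mtDNA |
| nuclear 1 | 0.77 | 167 bp | 0.045 | sharp mononucleosomal peak |
| nuclear 2 | 0.23 | 77 bp | 0.40 | flat sub-nucleosomal shoulder |

The parametric family is a modelling choice (the underlying biology fixes
only the modes and qualitative shape); sigma values and weights were chosen
once to give sharp 42/167 bp discrete modes and a realistic sub-100 bp mass
(~15%). The default mitochondrial fraction is 0.0014 (0.14%), a typical
plasma fractional concentration under short-fragment-preserving library
preparation. Heteroplasmic sites are planted per fragment: each
mitochondrial fragment covering a configured site carries the minor allele
independently with the configured probability. Base qualities are i.i.d.
per base from a configurable discrete distribution (default: point mass at
Q30); each base is misread with probability `10^(-Q/10)` uniformly onto the
three alternatives. NUMT decoys are optional and off by default: a nuclear
locus carries a copy of an mtDNA region with 2% substitution divergence,
and decoy fragments are emitted with a mismapped primary mitochondrial
alignment plus secondary nuclear alignments (alignment scores penalise
mismatches at 6 per substitution), so the uniqueness filter can be
exercised without running an aligner. An optional `mito_region` restricts
mitochondrial fragment starts to a sub-interval, emulating targeted
coverage so per-site depth is controllable at small fragment counts.

What the simulator does **not** model: sequencer-specific error profiles,
indels, adapter read-through, quality decay along the read, GC bias,
fragments spanning the circular origin, and true biological NUMT diversity.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not performance on real instrument data.

References are synthetic: seeded random sequences of the correct lengths
(16,569 bp mitochondrial contig plus a 60 kb nuclear contig), since none of
the statistics exercised depend on real sequence content.

## Problem sizes and numerical choices

Simulation-based checks use: 1e6 fragment draws for fraction recovery, 1e5
for length-mode recovery, 1e6 pileups (depth 500) for LLR calibration, 200
replicates at depth 1000 for minor-fraction recovery (planted at 1, 5, 10
and 25%), and a few thousand fragments for read-level round trips — sizes
at which binomial standard errors make the assertions sharp. All randomness
flows through seeded NumPy generators; independent streams for fragment
sampling and read realisation are derived from the user seed so that
fragment tables and emitted reads are reproducible byte-for-byte.

Degenerate inputs: zero-depth pileups and empty fragment sets raise errors
rather than returning placeholder values; empty windows in the
concentration profile are missing, not zero; `mito_fraction` 0 and 1 are
valid degenerate mixtures.

## Known limitations

* The bundled printed tables carry their source's rounding: cross-method
  fold ratios recomputed from 5-decimal concentrations can differ from the
  printed folds in the final digit (up to ~1% relative), so regression
  tests compare at that precision.
* Reported depths times frequencies are not always integral; count
  reconstruction rounds to the nearest integer and splits strands evenly,
  which is the stated convention, not recovered truth.
* The package does not align reads or trim adapters; it consumes alignments
  produced upstream (or by its own simulator).
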