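# cfmito

Fragment-size profiling and heteroplasmy calling for cell-free
mitochondrial DNA (cf-mtDNA) in plasma.

Plasma cell-free DNA is mostly nuclear, released as nucleosome-protected
~167 bp fragments. The mitochondrial fraction lacks histone protection and
circulates as much shorter fragments (mode ~42 bp), at fractional
concentrations of order 0.01–1%. This package is for researchers working
with paired-end plasma sequencing who want to (a) quantify the mtDNA
fractional concentration and its enrichment under size selection, and
(b) detect mitochondrial heteroplasmy — the coexistence of two mtDNA
alleles at a site — in plasma and compare it against white blood cells
(WBC), e.g. to probe the tissue origins of cfDNA.

## The model

Fragments are reconstructed from proper read pairs (FR orientation,
MAPQ > 20, mismatches < 5% of read length), deduplicated, and screened
against nuclear mitochondrial segments (NUMTs) by requiring the
mitochondrial alignment to outscore any nuclear alignment. The fractional
concentration is `100 · n_mito / n_mapped` per fragment-size window; an
in-silico size selection (default 30–60 bp) enriches mtDNA severalfold.

At a candidate site with *l* major-allele bases, *k* minor-allele bases and
per-base error probabilities ε*j* = 10^(−Q*j*/10), the major-allele
frequency *f* has log-likelihood

```
log L(f) = Σ_major log[f(1−εj) + (1−f)εj/3] + Σ_minor log[(1−f)(1−εj) + f εj/3]
```

and the decision statistic is `LLR = log10 L(f_het) − log10 L(f_homo)`,
where `f_het` maximises L over [0, 1] and `f_homo` is the better of {0, 1}.
`LLR > 5` marks high-confidence heteroplasmy (empirical false-positive rate
below 10⁻⁵ under the homoplasmic error model). Compartment-specific depth,
frequency and strand criteria, and the plasma-vs-WBC shared-site
classification, are described in [docs/methods.md](docs/methods.md).

A synthetic-data module (`cfmito.simdata`) generates reads, alignments and
ground truth with this statistical structure, so the whole pipeline runs
and is tested without any external sequencing data.

## Worked example

Simulate a plasma-like sample (50,000 fragments, 2% mitochondrial, one
heteroplasmy planted at position 5000 with 15% minor-allele fraction),
reconstruct fragments, and profile sizes:

```
$ cfmito simulate --n-fragments 50000 --mito-fraction 0.02 --seed 7 \
      --het 5000:C:0.15 --out-dir sim
wrote 50000 fragments to sim
$ cfmito fragments sim/alignments.sam --out-bed frags.bed --out-summary summary.tsv
retained 49546 fragments
$ cfmito sizeprofile --bed frags.bed --out-dir size
mito_mode_bp    44
nuclear_mode_bp 166
concentration_pct       1.9275017155774432
short_fraction  0.15633956323416623
peak_window_start_bp    35
concentration_selected_pct      34.86375513251213
```

The length modes land at the configured 42/167 bp peaks (±2 bp sampling
noise at this depth), the overall mtDNA concentration recovers the planted
2%, the sliding-window concentration peaks in the 35–45 bp window, and
selecting 30–60 bp fragments raises the concentration from 1.93% to 34.9%
— an 18-fold in-silico enrichment.

Calling heteroplasmy on a targeted simulation of the same site
(`calls_plasma.tsv`):

```
position  compartment  depth  major_allele  major_freq_pct  minor_allele  minor_freq_pct  llr      heteroplasmic
5000      plasma       569    A             85.76           C             14.06           177.943  True
```

The planted 15% minor fraction is recovered (14.06% at depth 569, within
binomial error) with an overwhelming likelihood ratio.

The bundled seven-sample concentration table compares three library
preparations; `cfmito report --out-dir report` prints the per-sample fold
gains and the method means (standard 0.0098%, optimized 0.1428%, with a
mean 10.4-fold further gain from size selection). The bundled patient site
table classifies twelve plasma/WBC heteroplasmies with
`cfmito compare --table ... --out-dir cmp`, printing
`both=8  wbc_only=3  plasma_only=1`.

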