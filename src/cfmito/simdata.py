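"""Synthetic plasma / leukocyte sequencing data generator.

Emulates the statistical structure of paired-end plasma cfDNA sequencing:

* fragment lengths drawn from truncated, discretised log-normal mixtures —
  a single short mitochondrial component with its mode at 42 bp, and a
  two-component nuclear mixture with a sharp nucleosomal mode at 167 bp plus
  a flat sub-nucleosomal shoulder around 77 bp;
* a configurable mitochondrial fraction (default 0.14%, a typical plasma
  fractional concentration under short-fragment-preserving library
  preparation);
* heteroplasmic sites planted at configurable minor-allele fractions —
  each mitochondrial fragment covering a site carries the minor allele
  independently with the configured probability;
* Phred-quality-conditioned substitution errors: every emitted base is
  misread with probability 10**(-Q/10), landing uniformly on one of the
  three alternative bases;
* optional NUMT decoys: fragments of nuclear origin whose sequence is a
  diverged copy of an mtDNA region, emitted with a (mismapped) primary
  mitochondrial alignment plus a secondary nuclear alignment so the
  uniqueness filter downstream can be exercised.

Fragment tables are generated vectorised (millions of fragments in seconds);
sequences, qualities and errors are only materialised when reads or
alignments are written. Every fragment is recorded in a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .reference import MITO_LENGTH, MITO_NAME, ReferenceSet, make_reference_set

ORIGIN_MITO = "mito"
ORIGIN_NUCLEAR = "nuclear"
ORIGIN_NUMT = "numt"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthComponent:
    """One log-normal mixture component, parameterised by its mode (bp)."""

    weight: float
    mode_bp: float
    log_sigma: float

    @property
    def mu(self) -> float:
        # log-normal mode = exp(mu - sigma^2)  =>  mu = log(mode) + sigma^2
        return float(np.log(self.mode_bp) + self.log_sigma**2)


@dataclass(frozen=True)
class LengthMixture:
    components: tuple[LengthComponent, ...]
    min_bp: int = 20
    max_bp: int = 1000

    def __post_init__(self) -> None:
        weights = [c.weight for c in self.components]
        if not np.isclose(sum(weights), 1.0):
            raise ValueError(f"mixture weights must sum to 1, got {sum(weights)}")
        if self.min_bp < 1:
            raise ValueError("fragment lengths must be positive (min_bp >= 1)")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n integer lengths, resampling draws outside [min_bp, max_bp]."""
        weights = np.array([c.weight for c in self.components])
        comp = rng.choice(len(self.components), size=n, p=weights)
        mus = np.array([c.mu for c in self.components])[comp]
        sigmas = np.array([c.log_sigma for c in self.components])[comp]
        lengths = np.rint(np.exp(rng.normal(mus, sigmas))).astype(np.int64)
        bad = (lengths < self.min_bp) | (lengths > self.max_bp)
        while bad.any():
            redraw = np.rint(
                np.exp(rng.normal(mus[bad], sigmas[bad]))
            ).astype(np.int64)
            lengths[bad] = redraw
            bad = (lengths < self.min_bp) | (lengths > self.max_bp)
        return lengths


MITO_LENGTH_MODEL = LengthMixture((LengthComponent(1.0, 42.0, 0.15),))
NUCLEAR_LENGTH_MODEL = LengthMixture(
    (LengthComponent(0.77, 167.0, 0.045), LengthComponent(0.23, 77.0, 0.40))
)


@dataclass(frozen=True)
class HetSite:
    """A planted heteroplasmy: 1-based mtDNA position, minor allele, fraction."""

    position: int
    minor_allele: str
    minor_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.minor_fraction <= 0.5):
            raise ValueError("minor-allele fraction must be in (0, 0.5]")
        if not (1 <= self.position <= MITO_LENGTH):
            raise ValueError("het site outside the mitochondrial genome")


@dataclass(frozen=True)
class NumtDecoy:
    """A nuclear locus carrying a diverged copy of an mtDNA region."""

    nuclear_name: str
    nuclear_start: int
    mito_start: int
    length: int
    divergence: float = 0.02


@dataclass(frozen=True)
class QualityModel:
    """Discrete distribution over Phred scores, i.i.d. per emitted base."""

    scores: tuple[int, ...] = (30,)
    probs: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.probs) or not np.isclose(sum(self.probs), 1.0):
            raise ValueError("quality model probabilities must match scores and sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(np.array(self.scores), size=n, p=np.array(self.probs))


@dataclass
class SimConfig:
    n_fragments: int
    mito_fraction: float = 0.0014
    mito_length_model: LengthMixture = MITO_LENGTH_MODEL
    nuclear_length_model: LengthMixture = NUCLEAR_LENGTH_MODEL
    het_sites: tuple[HetSite, ...] = ()
    base_quality_model: QualityModel = QualityModel()
    numt_decoys: tuple[NumtDecoy, ...] = ()
    numt_fraction: float = 0.0
    read_length: int = 150
    seed: int = 0
    # restrict mito fragment starts to [a, b) — emulates targeted/amplicon
    # coverage so that per-site depth can be controlled at small n
    mito_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if self.mito_region is not None:
            a, b = self.mito_region
            if not (0 <= a < b <= MITO_LENGTH):
                raise ValueError("mito_region must be a sub-interval of the genome")
        if not (0.0 <= self.mito_fraction <= 1.0):
            raise ValueError("mito_fraction must lie in [0, 1]")
        if self.numt_fraction and not self.numt_decoys:
            raise ValueError("numt_fraction > 0 requires at least one decoy")
        if self.mito_fraction + self.numt_fraction > 1.0:
            raise ValueError("mito_fraction + numt_fraction must not exceed 1")


# ---------------------------------------------------------------------------
# fragment tables and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimFragments:
    """Vectorised fragment table: one entry per simulated fragment."""

    origin: np.ndarray          # str codes: mito | nuclear | numt
    chrom: np.ndarray           # contig the fragment physically comes from
    start: np.ndarray           # 0-based start on `chrom`
    length: np.ndarray
    minor_carrier: np.ndarray   # (n, n_het_sites) bool
    decoy_index: np.ndarray     # index into config.numt_decoys, -1 otherwise

    def __len__(self) -> int:
        return len(self.length)


@dataclass
class SimTruth:
    mito_fraction: float
    site_fractions: dict[int, float]
    fragments: SimFragments

    def to_frame(self) -> pd.DataFrame:
        frags = self.fragments
        return pd.DataFrame(
            {
                "fragment_id": [f"frag{i:07d}" for i in range(len(frags))],
                "origin": frags.origin,
                "chrom": frags.chrom,
                "start": frags.start,
                "end": frags.start + frags.length,
                "length": frags.length,
            }
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_fragments(
    config: SimConfig, reference: ReferenceSet | None = None
) -> tuple[SimFragments, SimTruth]:
    """Draw fragment origins, coordinates, lengths and planted alleles."""
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_fragments
    nuclear_lengths = (
        reference.lengths() if reference else {"nuc1": 60_000}
    )
    nuclear_names = [name for name in nuclear_lengths if name != MITO_NAME]

    u = rng.random(n)
    origin = np.full(n, ORIGIN_NUCLEAR, dtype=object)
    origin[u < config.mito_fraction] = ORIGIN_MITO
    origin[(u >= config.mito_fraction)
           & (u < config.mito_fraction + config.numt_fraction)] = ORIGIN_NUMT

    length = np.zeros(n, dtype=np.int64)
    chrom = np.full(n, "", dtype=object)
    start = np.zeros(n, dtype=np.int64)
    decoy_index = np.full(n, -1, dtype=np.int64)

    is_mito = origin == ORIGIN_MITO
    is_numt = origin == ORIGIN_NUMT
    is_nuc = origin == ORIGIN_NUCLEAR

    if is_mito.any():
        m = int(is_mito.sum())
        lengths = config.mito_length_model.sample(m, rng)
        lo, hi = config.mito_region or (0, MITO_LENGTH)
        lengths = np.minimum(lengths, hi - lo)
        starts = rng.integers(lo, hi - lengths + 1)
        length[is_mito] = lengths
        chrom[is_mito] = MITO_NAME
        start[is_mito] = starts

    if is_nuc.any():
        m = int(is_nuc.sum())
        lengths = config.nuclear_length_model.sample(m, rng)
        names = np.array(nuclear_names, dtype=object)
        sizes = np.array([nuclear_lengths[nm] for nm in nuclear_names])
        pick = rng.integers(0, len(names), size=m)
        lengths = np.minimum(lengths, sizes[pick])
        starts = rng.integers(0, sizes[pick] - lengths + 1)
        length[is_nuc] = lengths
        chrom[is_nuc] = names[pick]
        start[is_nuc] = starts

    if is_numt.any():
        m = int(is_numt.sum())
        lengths = config.mito_length_model.sample(m, rng)
        pick = rng.integers(0, len(config.numt_decoys), size=m)
        decoy_len = np.array([d.length for d in config.numt_decoys])[pick]
        decoy_start = np.array([d.nuclear_start for d in config.numt_decoys])[pick]
        lengths = np.minimum(lengths, decoy_len)
        offset = rng.integers(0, decoy_len - lengths + 1)
        length[is_numt] = lengths
        chrom[is_numt] = np.array(
            [d.nuclear_name for d in config.numt_decoys], dtype=object
        )[pick]
        start[is_numt] = decoy_start + offset
        decoy_index[is_numt] = pick

    # plant minor alleles on mitochondrial fragments covering each het site
    minor_carrier = np.zeros((n, len(config.het_sites)), dtype=bool)
    for j, site in enumerate(config.het_sites):
        covers = is_mito & (start <= site.position - 1) & (site.position - 1 < start + length)
        minor_carrier[covers, j] = rng.random(int(covers.sum())) < site.minor_fraction

    frags = SimFragments(origin, chrom, start, length, minor_carrier, decoy_index)
    truth = SimTruth(
        mito_fraction=config.mito_fraction,
        site_fractions={s.position: s.minor_fraction for s in config.het_sites},
        fragments=frags,
    )
    return frags, truth


# ---------------------------------------------------------------------------
# read realisation (sequences, qualities, errors)
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_ALT = {  # the three substitution targets per base, indexed 0..2
    b: [x for x in "ACGT" if x != b] for b in "ACGT"
}


def _decoy_sequence(decoy: NumtDecoy, reference: ReferenceSet, seed: int) -> str:
    """Diverged copy of the homologous mtDNA region (deterministic per seed)."""
    rng = np.random.default_rng([seed, 3, decoy.mito_start])
    seq = list(reference.mito[decoy.mito_start : decoy.mito_start + decoy.length])
    hits = np.flatnonzero(rng.random(decoy.length) < decoy.divergence)
    for i in hits:
        seq[i] = _ALT[seq[i]][rng.integers(0, 3)]
    return "".join(seq)


def reference_with_decoys(reference: ReferenceSet, config: SimConfig) -> ReferenceSet:
    """Patch each NUMT decoy's diverged mtDNA copy into its nuclear locus.

    This is the reference an aligner (and the alignment-score bookkeeping in
    ``write_sam``) should see: the nuclear genome genuinely contains the
    mtDNA-homologous segment.
    """
    if not config.numt_decoys:
        return reference
    nuclear = dict(reference.nuclear)
    for decoy in config.numt_decoys:
        seq = nuclear[decoy.nuclear_name]
        patch = _decoy_sequence(decoy, reference, config.seed)
        nuclear[decoy.nuclear_name] = (
            seq[: decoy.nuclear_start]
            + patch
            + seq[decoy.nuclear_start + decoy.length :]
        )
    return ReferenceSet(mito=reference.mito, nuclear=nuclear)


def _apply_errors(seq: str, quals: np.ndarray, rng: np.random.Generator) -> str:
    errs = np.flatnonzero(rng.random(len(seq)) < 10.0 ** (-quals / 10.0))
    if errs.size == 0:
        return seq
    out = list(seq)
    for i in errs:
        out[i] = _ALT[out[i]][rng.integers(0, 3)]
    return "".join(out)


@dataclass
class RealizedFragment:
    """Both mates of one fragment in forward reference orientation."""

    name: str
    origin: str
    chrom: str            # physical contig
    start: int
    length: int
    decoy_index: int
    seq1: str             # mate 1 (leftmost), forward orientation
    qual1: np.ndarray
    seq2: str             # mate 2 (rightmost), forward orientation
    qual2: np.ndarray
    start2: int           # 0-based start of mate 2 segment
    read1_left: bool = True  # whether read 1 is the left (forward) read


def realize_reads(
    frags: SimFragments,
    config: SimConfig,
    reference: ReferenceSet,
):
    """Yield per-fragment read pairs with qualities and sequencing errors."""
    rng = np.random.default_rng([config.seed, 2])
    decoy_seqs = [
        _decoy_sequence(d, reference, config.seed) for d in config.numt_decoys
    ]
    site_pos = np.array([s.position for s in config.het_sites], dtype=np.int64)
    site_minor = [s.minor_allele for s in config.het_sites]
    rl = config.read_length

    for i in range(len(frags)):
        origin = frags.origin[i]
        start, length = int(frags.start[i]), int(frags.length[i])
        if origin == ORIGIN_MITO:
            frag_seq = reference.mito[start : start + length]
            carriers = np.flatnonzero(frags.minor_carrier[i])
            if carriers.size:
                seq = list(frag_seq)
                for j in carriers:
                    seq[int(site_pos[j]) - 1 - start] = site_minor[j]
                frag_seq = "".join(seq)
        elif origin == ORIGIN_NUMT:
            decoy = config.numt_decoys[int(frags.decoy_index[i])]
            off = start - decoy.nuclear_start
            frag_seq = decoy_seqs[int(frags.decoy_index[i])][off : off + length]
        else:
            frag_seq = reference.nuclear[str(frags.chrom[i])][start : start + length]

        rl1 = min(rl, length)
        rl2 = min(rl, length)
        seg1 = frag_seq[:rl1]
        seg2 = frag_seq[length - rl2 :]
        q1 = config.base_quality_model.sample(rl1, rng).astype(float)
        q2 = config.base_quality_model.sample(rl2, rng).astype(float)
        seg1 = _apply_errors(seg1, q1, rng)
        seg2 = _apply_errors(seg2, q2, rng)
        # library ligation orientation is random: read 1 starts from either
        # fragment end with equal probability
        read1_left = bool(rng.random() < 0.5)
        yield RealizedFragment(
            name=f"frag{i:07d}",
            origin=str(origin),
            chrom=str(frags.chrom[i]),
            start=start,
            length=length,
            decoy_index=int(frags.decoy_index[i]),
            seq1=seg1,
            qual1=q1.astype(int),
            seq2=seg2,
            qual2=q2.astype(int),
            start2=start + length - rl2,
            read1_left=read1_left,
        )


def write_reads(
    frags: SimFragments,
    config: SimConfig,
    reference: ReferenceSet,
    fastq1: str,
    fastq2: str,
) -> None:
    """Write mate FASTQ files (Phred+33); mate 2 is reverse-complemented."""
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for rec in realize_reads(frags, config, reference):
            left = (rec.seq1, "".join(chr(q + 33) for q in rec.qual1))
            right = (revcomp(rec.seq2), "".join(chr(q + 33) for q in rec.qual2[::-1]))
            first, second = (left, right) if rec.read1_left else (right, left)
            f1.write(f"@{rec.name}/1\n{first[0]}\n+\n{first[1]}\n")
            f2.write(f"@{rec.name}/2\n{second[0]}\n+\n{second[1]}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def write_sam(
    frags: SimFragments,
    config: SimConfig,
    reference: ReferenceSet,
    path: str,
) -> None:
    """Emit aligned read pairs directly as SAM.

    Regular fragments get a proper FR primary pair on their true contig.
    NUMT decoy fragments are emitted the way an aligner would mismap them:
    primary pair on the mitochondrial contig at the homologous coordinate
    (alignment score penalised by the divergence mismatches) plus secondary
    records at the true nuclear locus.
    """
    reference = reference_with_decoys(reference, config)
    lengths = reference.lengths()
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": lengths[name]} for name in reference.names],
    }
    tid = {name: i for i, name in enumerate(reference.names)}

    def make_segment(
        af, rec, chrom, pos, seq, quals, reverse, first, secondary, tlen, mate_pos
    ):
        seg = pysam.AlignedSegment(af.header)
        seg.query_name = rec.name
        seg.query_sequence = seq
        seg.reference_id = tid[chrom]
        seg.reference_start = pos
        seg.next_reference_id = tid[chrom]
        seg.next_reference_start = mate_pos
        seg.mapping_quality = 0 if secondary else 60
        seg.cigarstring = f"{len(seq)}M"
        seg.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in quals)
        )
        flag = 0x1 | 0x2  # paired, proper pair
        flag |= 0x40 if first else 0x80
        if reverse:
            flag |= 0x10
        else:
            flag |= 0x20  # mate is reverse
        if secondary:
            flag = (flag | 0x100) & ~0x2
        seg.flag = flag
        seg.template_length = tlen
        ref_seq = reference.sequence(chrom)[pos : pos + len(seq)]
        nm = _hamming(seq, ref_seq)
        seg.set_tag("NM", nm)
        seg.set_tag("AS", -6 * nm)
        return seg

    with pysam.AlignmentFile(path, "wh", header=header) as af:
        for rec in realize_reads(frags, config, reference):
            if rec.origin == ORIGIN_NUMT:
                decoy = config.numt_decoys[rec.decoy_index]
                off = rec.start - decoy.nuclear_start
                mito_pos1 = decoy.mito_start + off
                mito_pos2 = mito_pos1 + rec.length - len(rec.seq2)
                first_left = rec.read1_left
                primaries = [
                    (MITO_NAME, mito_pos1, rec.seq1, rec.qual1, False, first_left, False, rec.length, mito_pos2),
                    (MITO_NAME, mito_pos2, rec.seq2, rec.qual2, True, not first_left, False, -rec.length, mito_pos1),
                ]
                secondaries = [
                    (rec.chrom, rec.start, rec.seq1, rec.qual1, False, first_left, True, rec.length, rec.start2),
                    (rec.chrom, rec.start2, rec.seq2, rec.qual2, True, not first_left, True, -rec.length, rec.start),
                ]
                for args in primaries + secondaries:
                    af.write(make_segment(af, rec, *args))
            else:
                af.write(
                    make_segment(
                        af, rec, rec.chrom, rec.start, rec.seq1, rec.qual1,
                        False, rec.read1_left, False, rec.length, rec.start2,
                    )
                )
                af.write(
                    make_segment(
                        af, rec, rec.chrom, rec.start2, rec.seq2, rec.qual2,
                        True, not rec.read1_left, False, -rec.length, rec.start,
                    )
                )


# ---------------------------------------------------------------------------
# direct pileup-level simulation (used for calibration and recovery studies)
# ---------------------------------------------------------------------------

def simulate_homoplasmic_quality_counts(
    n_sites: int,
    depth: int,
    qualities: np.ndarray,
    rng: np.random.Generator,
    quality_probs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate quality-binned pileup counts for homoplasmic sites.

    Every base is truly the major allele; each is misread with probability
    10**(-Q/10) and lands uniformly on the three alternatives. The reported
    minor allele is the alternative with the highest total count (ties by
    lower index), matching what a caller would pick. Returns
    ``(eps, major_counts, minor_counts)`` with counts of shape
    (n_sites, len(qualities)); bases misread onto the two remaining
    alternatives are excluded, as in the biallelic likelihood.
    """
    qualities = np.asarray(qualities, dtype=float)
    if quality_probs is None:
        quality_probs = np.full(len(qualities), 1.0 / len(qualities))
    eps = 10.0 ** (-qualities / 10.0)
    qual_counts = rng.multinomial(depth, quality_probs, size=n_sites)
    errors = rng.binomial(qual_counts, eps)
    alt1 = rng.binomial(errors, 1.0 / 3.0)
    alt2 = rng.binomial(errors - alt1, 0.5)
    alt3 = errors - alt1 - alt2
    alts = np.stack([alt1, alt2, alt3])            # (3, S, B)
    winner = alts.sum(axis=2).argmax(axis=0)       # (S,)
    minor_counts = alts[winner, np.arange(n_sites), :]
    major_counts = qual_counts - errors
    return eps, major_counts, minor_counts


def simulate_heteroplasmic_counts(
    n_sites: int,
    depth: int,
    minor_fraction: float,
    qual: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed (major, minor) counts for replicated two-allele pileups.

    True allele drawn per base at the planted minor fraction; sequencing
    errors at rate eps = 10**(-qual/10) move a base to a uniformly chosen
    different allele (so allele-swapping errors occur at rate eps/3).
    Bases misread onto the two off-pair alleles are dropped.
    """
    eps = 10.0 ** (-qual / 10.0)
    k_true = rng.binomial(depth, minor_fraction, size=n_sites)
    l_true = depth - k_true
    maj_err = rng.binomial(l_true, eps)
    min_err = rng.binomial(k_true, eps)
    maj_to_min = rng.binomial(maj_err, 1.0 / 3.0)
    min_to_maj = rng.binomial(min_err, 1.0 / 3.0)
    major = l_true - maj_err + min_to_maj
    minor = k_true - min_err + maj_to_min
    return major, minor


__all__ = [
    "HetSite",
    "LengthComponent",
    "LengthMixture",
    "MITO_LENGTH_MODEL",
    "NUCLEAR_LENGTH_MODEL",
    "NumtDecoy",
    "QualityModel",
    "RealizedFragment",
    "SimConfig",
    "SimFragments",
    "SimTruth",
    "make_reference_set",
    "realize_reads",
    "revcomp",
    "simulate_fragments",
    "simulate_heteroplasmic_counts",
    "simulate_homoplasmic_quality_counts",
    "write_reads",
    "write_sam",
]
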