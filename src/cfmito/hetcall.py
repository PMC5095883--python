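"""Quality-aware mitochondrial heteroplasmy calling.

A site is summarised as a pileup of quality-filtered bases. With ``l`` bases
supporting the major allele, ``k`` bases supporting the minor allele, and a
per-base sequencing-error probability ``eps_j = 10**(-Q_j/10)`` from the Phred
quality of each base, the log-likelihood of a major-allele frequency ``f`` is

    log L(f) = sum_major log[ f*(1-eps_j) + (1-f)*eps_j/3 ]
             + sum_minor log[ (1-f)*(1-eps_j) + f*eps_j/3 ]

where a misread base is assumed to land uniformly on the three alternative
bases (hence the eps/3 split). The heteroplasmic model estimates ``f_het`` as
the maximiser of L over [0, 1]; the homoplasmic model takes the better of the
boundary values f in {0, 1}. The decision statistic is the base-10
log-likelihood ratio

    LLR = log10 L(f_het) - log10 L(f_homo)

and LLR > 5 marks a high-confidence heteroplasmy (false-positive rate below
1e-5 under the homoplasmic error model; see the calibration tests).

Compartment-specific calling criteria:

* leukocytes (WBC): depth > 400, minor-allele frequency >= 1%, per-strand
  minor frequency >= 0.6% on each strand with no significant strand
  imbalance (2x2 chi-square, p >= 0.05), and LLR > 5;
* plasma (lower coverage, looser): depth > 50, minor-allele count >= 4,
  minor allele observed on both strands, and LLR > 5.

A site detected in either compartment is classified as shared ("both") when
the LLR exceeds 5 in at least one compartment, both alleles of the pair are
observed in both compartments (major/minor roles may flip between
compartments), and the locally-minor allele has count >= 2 with at least one
observation per strand in each compartment; otherwise the site is assigned to
the compartment that carries the call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.stats import chi2_contingency

from .reference import MITO_LENGTH, MITO_NAME

ALLELES = ("A", "C", "G", "T")
LN10 = math.log(10.0)

# published default thresholds, overridable per call
LLR_MIN = 5.0
WBC_MIN_DEPTH = 400          # strict >
WBC_MIN_MAF = 0.01
STRAND_MIN_MAF = 0.006
STRAND_ALPHA = 0.05
PLASMA_MIN_DEPTH = 50        # strict >  (a companion report uses >= 40)
PLASMA_MIN_MINOR = 4
BASEQ_MIN = 20


# ---------------------------------------------------------------------------
# vectorised likelihood core (shared by the scalar API and calibration runs)
# ---------------------------------------------------------------------------

def loglik_counts(
    f: np.ndarray,
    eps: np.ndarray,
    major_counts: np.ndarray,
    minor_counts: np.ndarray,
) -> np.ndarray:
    """Natural log-likelihood of major-allele frequency ``f`` per site.

    Parameters
    ----------
    f : (S,) major-allele frequencies, one per site.
    eps : (B,) distinct per-base error probabilities.
    major_counts, minor_counts : (S, B) base counts per site and error bin.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))[:, None]
    eps = np.asarray(eps, dtype=float)[None, :]
    p_major = f * (1.0 - eps) + (1.0 - f) * eps / 3.0
    p_minor = (1.0 - f) * (1.0 - eps) + f * eps / 3.0
    # counts of zero silence any log(0) at the boundaries
    with np.errstate(divide="ignore", invalid="ignore"):
        term_major = np.where(major_counts > 0, major_counts * np.log(p_major), 0.0)
        term_minor = np.where(minor_counts > 0, minor_counts * np.log(p_minor), 0.0)
    return term_major.sum(axis=1) + term_minor.sum(axis=1)


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(objective, lo: float, hi: float, tol: float, n_sites: int):
    """Vectorised golden-section maximisation of ``objective`` over [lo, hi]."""
    a = np.full(n_sites, lo)
    b = np.full(n_sites, hi)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc = objective(c)
    fd = objective(d)
    n_iter = int(math.ceil(math.log(tol / (hi - lo)) / math.log(_INVPHI)))
    for _ in range(n_iter):
        take_c = fc >= fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        new_c = b - _INVPHI * (b - a)
        new_d = a + _INVPHI * (b - a)
        # one new evaluation per iteration; the surviving interior point is reused
        fresh = objective(np.where(take_c, new_c, new_d))
        fc_new = np.where(take_c, fresh, fd)
        fd_new = np.where(take_c, fc, fresh)
        c, d, fc, fd = new_c, new_d, fc_new, fd_new
    x = np.where(fc >= fd, c, d)
    return x, objective(x)


def llr_counts(
    eps: np.ndarray,
    major_counts: np.ndarray,
    minor_counts: np.ndarray,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE major-allele frequency and base-10 LLR for many sites at once.

    Returns ``(f_het, f_homo, llr)`` arrays. The heteroplasmic MLE is found by
    golden-section search on [0, 1] (absolute tolerance ``tol``); the
    homoplasmic frequency is the better of the boundary values {0, 1}. The
    boundary candidates are always compared against the interior optimum, so
    LLR >= 0 exactly.
    """
    major_counts = np.atleast_2d(major_counts)
    minor_counts = np.atleast_2d(minor_counts)
    n_sites = major_counts.shape[0]

    def objective(f):
        return loglik_counts(f, eps, major_counts, minor_counts)

    f_in, ll_in = _golden_max(objective, 0.0, 1.0, tol, n_sites)
    ll0 = objective(np.zeros(n_sites))
    ll1 = objective(np.ones(n_sites))
    f_homo = np.where(ll1 >= ll0, 1.0, 0.0)
    ll_homo = np.maximum(ll0, ll1)
    # the interior search may stop a hair below a boundary optimum
    f_het = np.where(ll_in >= ll_homo, f_in, f_homo)
    ll_het = np.maximum(ll_in, ll_homo)
    llr = (ll_het - ll_homo) / LN10
    return f_het, f_homo, llr


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

@dataclass
class SitePileup:
    """Quality-filtered allele evidence at one mtDNA position (1-based)."""

    position: int
    counts: dict[str, list[int]] = field(default_factory=dict)  # base -> [fwd, rev]
    quals: dict[str, list[int]] = field(default_factory=dict)   # base -> Phred scores
    ref_base: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.position <= MITO_LENGTH):
            raise ValueError(f"position {self.position} outside 1..{MITO_LENGTH}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_bases(
        cls,
        position: int,
        bases: list[tuple[str, int, bool]],
        ref_base: str | None = None,
        baseq_min: int = BASEQ_MIN,
    ) -> "SitePileup":
        """Build from (base, quality, is_reverse) triples; Q < baseq_min dropped."""
        pile = cls(position=position, ref_base=ref_base)
        for base, qual, is_reverse in bases:
            if qual < baseq_min or base not in ALLELES:
                continue
            pile.add(base, qual, is_reverse)
        return pile

    @classmethod
    def from_counts(
        cls,
        position: int,
        allele_counts: dict[str, tuple[int, int]],
        qual: int = 30,
        ref_base: str | None = None,
    ) -> "SitePileup":
        """Build from per-allele (forward, reverse) counts at a uniform quality."""
        pile = cls(position=position, ref_base=ref_base)
        for base, (fwd, rev) in allele_counts.items():
            for _ in range(int(fwd)):
                pile.add(base, qual, False)
            for _ in range(int(rev)):
                pile.add(base, qual, True)
        return pile

    def add(self, base: str, qual: int, is_reverse: bool) -> None:
        fwd_rev = self.counts.setdefault(base, [0, 0])
        fwd_rev[1 if is_reverse else 0] += 1
        self.quals.setdefault(base, []).append(int(qual))

    # -- summaries ----------------------------------------------------------

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())

    def allele_count(self, base: str) -> int:
        fwd, rev = self.counts.get(base, (0, 0))
        return fwd + rev

    def strand_counts(self, base: str) -> tuple[int, int]:
        fwd, rev = self.counts.get(base, (0, 0))
        return fwd, rev

    def strand_depths(self) -> tuple[int, int]:
        fwd = sum(f for f, _ in self.counts.values())
        rev = sum(r for _, r in self.counts.values())
        return fwd, rev

    def _rank(self, base: str) -> tuple:
        # higher count first; ties broken by reference allele, then alphabet
        return (-self.allele_count(base), base != self.ref_base, base)

    @property
    def major_allele(self) -> str | None:
        present = [b for b in ALLELES if self.allele_count(b) > 0]
        if not present:
            return None
        return min(present, key=self._rank)

    @property
    def minor_allele(self) -> str | None:
        major = self.major_allele
        rest = [b for b in ALLELES if b != major and self.allele_count(b) > 0]
        if not rest:
            return None
        return min(rest, key=self._rank)

    def minor_count(self) -> int:
        minor = self.minor_allele
        return self.allele_count(minor) if minor else 0

    def minor_freq(self) -> float:
        d = self.depth
        return self.minor_count() / d if d else 0.0

    def epsilons(self, base: str) -> np.ndarray:
        return 10.0 ** (-np.asarray(self.quals.get(base, []), dtype=float) / 10.0)

    def quality_count_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Group major/minor bases by error probability for the likelihood core."""
        major, minor = self.major_allele, self.minor_allele
        q_major = np.asarray(self.quals.get(major, []), dtype=int) if major else np.array([], int)
        q_minor = np.asarray(self.quals.get(minor, []), dtype=int) if minor else np.array([], int)
        all_q = np.union1d(q_major, q_minor)
        if all_q.size == 0:
            raise ValueError(f"zero usable depth at position {self.position}")
        eps = 10.0 ** (-all_q.astype(float) / 10.0)
        maj = np.array([[np.sum(q_major == q) for q in all_q]])
        mino = np.array([[np.sum(q_minor == q) for q in all_q]])
        return eps, maj, mino


# ---------------------------------------------------------------------------
# likelihood API on pileups
# ---------------------------------------------------------------------------

def likelihood(pileup: SitePileup, f: float) -> float:
    """Natural log-likelihood of major-allele frequency ``f`` for one pileup."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f={f} outside [0, 1]")
    eps, maj, mino = pileup.quality_count_matrix()
    return float(loglik_counts(np.array([f]), eps, maj, mino)[0])


def llr(pileup: SitePileup, tol: float = 1e-6) -> tuple[float, float]:
    """Return ``(f_het, LLR)`` for one pileup; LLR is in log base 10."""
    if pileup.depth == 0:
        raise ValueError(f"zero depth at position {pileup.position}")
    eps, maj, mino = pileup.quality_count_matrix()
    f_het, _f_homo, value = llr_counts(eps, maj, mino, tol=tol)
    return float(f_het[0]), float(value[0])


def strand_test(
    pileup: SitePileup,
    min_strand_maf: float = STRAND_MIN_MAF,
    alpha: float = STRAND_ALPHA,
) -> tuple[bool, float]:
    """Per-strand minor-frequency floor plus 2x2 chi-square balance test.

    Passes when the minor-allele frequency is at least ``min_strand_maf`` on
    each strand and the chi-square test of minor vs major counts by strand
    (no continuity correction) is not significant at ``alpha``.
    Returns (pass, p-value); p is NaN when the frequency floor already fails.
    """
    major, minor = pileup.major_allele, pileup.minor_allele
    if major is None or minor is None:
        return False, float("nan")
    maj_f, maj_r = pileup.strand_counts(major)
    min_f, min_r = pileup.strand_counts(minor)
    depth_f, depth_r = maj_f + min_f, maj_r + min_r
    if depth_f == 0 or depth_r == 0:
        return False, float("nan")
    if min_f / depth_f < min_strand_maf or min_r / depth_r < min_strand_maf:
        return False, float("nan")
    table = np.array([[maj_f, min_f], [maj_r, min_r]])
    if table.sum(axis=0).min() == 0:
        return False, float("nan")
    _stat, p, _dof, _exp = chi2_contingency(table, correction=False)
    return bool(p >= alpha), float(p)


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------

@dataclass
class HeteroplasmyCall:
    position: int
    compartment: str                 # "plasma" | "wbc"
    major_allele: str | None
    minor_allele: str | None
    depth: int
    major_freq: float                # percent
    minor_freq: float                # percent
    f_het: float
    f_homo: float
    llr: float
    flags: dict[str, bool]
    is_heteroplasmic: bool


def _base_call(pileup: SitePileup, compartment: str, llr_min: float) -> tuple:
    major, minor = pileup.major_allele, pileup.minor_allele
    depth = pileup.depth
    if depth == 0:
        raise ValueError(f"zero depth at position {pileup.position}")
    f_het, value = llr(pileup)
    eps, maj, mino = pileup.quality_count_matrix()
    _, f_homo, _ = llr_counts(eps, maj, mino)
    maj_freq = 100.0 * pileup.allele_count(major) / depth if major else 0.0
    min_freq = 100.0 * pileup.minor_count() / depth
    return major, minor, depth, maj_freq, min_freq, f_het, float(f_homo[0]), value


def call_wbc(
    pileup: SitePileup,
    min_depth: int = WBC_MIN_DEPTH,
    min_maf: float = WBC_MIN_MAF,
    min_strand_maf: float = STRAND_MIN_MAF,
    alpha: float = STRAND_ALPHA,
    llr_min: float = LLR_MIN,
) -> HeteroplasmyCall:
    """Call heteroplasmy in the leukocyte compartment (high coverage)."""
    major, minor, depth, maj_f, min_f, f_het, f_homo, value = _base_call(
        pileup, "wbc", llr_min
    )
    strand_ok, _p = strand_test(pileup, min_strand_maf, alpha)
    flags = {
        "coverage": depth > min_depth,
        "maf": (min_f / 100.0) >= min_maf,
        "strand": strand_ok,
        "llr": value > llr_min,
    }
    return HeteroplasmyCall(
        pileup.position, "wbc", major, minor, depth, maj_f, min_f,
        f_het, f_homo, value, flags, all(flags.values()),
    )


def call_plasma(
    pileup: SitePileup,
    min_depth: int = PLASMA_MIN_DEPTH,
    min_minor: int = PLASMA_MIN_MINOR,
    llr_min: float = LLR_MIN,
) -> HeteroplasmyCall:
    """Call heteroplasmy in plasma with the looser low-coverage criteria."""
    major, minor, depth, maj_f, min_f, f_het, f_homo, value = _base_call(
        pileup, "plasma", llr_min
    )
    min_fwd, min_rev = pileup.strand_counts(minor) if minor else (0, 0)
    flags = {
        "coverage": depth > min_depth,
        "minor_count": pileup.minor_count() >= min_minor,
        "both_strands": min_fwd >= 1 and min_rev >= 1,
        "llr": value > llr_min,
    }
    return HeteroplasmyCall(
        pileup.position, "plasma", major, minor, depth, maj_f, min_f,
        f_het, f_homo, value, flags, all(flags.values()),
    )


@dataclass
class SharedSiteClass:
    position: int
    klass: str                        # "both" | "wbc_only" | "plasma_only"
    wbc: HeteroplasmyCall
    plasma: HeteroplasmyCall
    criteria: dict[str, bool]


def classify_shared(
    wbc_pileup: SitePileup,
    plasma_pileup: SitePileup,
    llr_min: float = LLR_MIN,
    **call_kwargs,
) -> SharedSiteClass:
    """Classify a candidate site as shared or compartment-specific.

    "both" requires: LLR > llr_min in at least one compartment; both alleles
    of the pair observed in both compartments; minor count >= 2 and >= 1 per
    strand in each compartment. Failing that, the site is assigned to the
    compartment whose primary criteria pass (higher LLR on a tie).
    """
    if wbc_pileup.position != plasma_pileup.position:
        raise ValueError("compartment pileups refer to different positions")
    wbc_call = call_wbc(wbc_pileup, llr_min=llr_min)
    plasma_call = call_plasma(plasma_pileup, llr_min=llr_min)

    # allele pair from the compartment with the stronger signal
    ranked = sorted(
        [(wbc_call, wbc_pileup), (plasma_call, plasma_pileup)],
        key=lambda cp: (cp[1].minor_allele is None, -cp[0].llr),
    )
    lead_call, lead_pile = ranked[0]
    pair = (lead_pile.major_allele, lead_pile.minor_allele)

    crit = {"llr": max(wbc_call.llr, plasma_call.llr) > llr_min}
    if pair[0] is None or pair[1] is None:
        crit.update(present_both=False, minor_count=False, minor_strands=False)
    else:
        present = all(
            pile.allele_count(a) >= 1
            for pile in (wbc_pileup, plasma_pileup)
            for a in pair
        )
        crit["present_both"] = present
        counts_ok, strands_ok = True, True
        for pile in (wbc_pileup, plasma_pileup):
            # the locally minor allele of the pair in this compartment
            local_minor = min(pair, key=pile.allele_count)
            counts_ok &= pile.allele_count(local_minor) >= 2
            fwd, rev = pile.strand_counts(local_minor)
            strands_ok &= fwd >= 1 and rev >= 1
        crit["minor_count"] = counts_ok
        crit["minor_strands"] = strands_ok

    if all(crit.values()):
        klass = "both"
    elif wbc_call.is_heteroplasmic and not plasma_call.is_heteroplasmic:
        klass = "wbc_only"
    elif plasma_call.is_heteroplasmic and not wbc_call.is_heteroplasmic:
        klass = "plasma_only"
    elif wbc_call.is_heteroplasmic and plasma_call.is_heteroplasmic:
        klass = "wbc_only" if wbc_call.llr >= plasma_call.llr else "plasma_only"
    else:
        raise ValueError(
            f"site {wbc_pileup.position}: not shared and called in neither compartment"
        )
    return SharedSiteClass(wbc_pileup.position, klass, wbc_call, plasma_call, crit)


# ---------------------------------------------------------------------------
# pileup construction from alignments
# ---------------------------------------------------------------------------

def pileups_from_alignments(
    path: str,
    keep_qnames: set[str] | None = None,
    baseq_min: int = BASEQ_MIN,
    reference: str | None = None,
) -> dict[int, SitePileup]:
    """Build per-position pileups over the mitochondrial contig from SAM/BAM.

    Only primary alignments on the mitochondrial contig contribute. Where the
    two mates of a fragment overlap a position, the base is counted once:
    the higher-quality copy wins, with read 1 preferred on ties (read 1's
    strand is random with respect to the fragment, so strand composition
    stays informative for fully-overlapping short fragments).
    """
    # (position -> qname -> (base, qual, is_reverse, is_read1))
    staged: dict[int, dict[str, tuple[str, int, bool, bool]]] = {}
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as af:
            for read in af:
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.reference_name != MITO_NAME
                ):
                    continue
                if keep_qnames is not None and read.query_name not in keep_qnames:
                    continue
                quals = read.query_qualities
                seq = read.query_sequence
                if seq is None or quals is None:
                    continue
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    base, q = seq[qpos], quals[qpos]
                    if q < baseq_min or base not in ALLELES:
                        continue
                    pos1 = rpos + 1
                    bucket = staged.setdefault(pos1, {})
                    prev = bucket.get(read.query_name)
                    if (
                        prev is None
                        or q > prev[1]
                        or (q == prev[1] and read.is_read1 and not prev[3])
                    ):
                        bucket[read.query_name] = (
                            base, q, read.is_reverse, read.is_read1
                        )
    finally:
        pysam.set_verbosity(save)
    pileups: dict[int, SitePileup] = {}
    for pos1, bucket in staged.items():
        ref_base = reference[pos1 - 1] if reference else None
        pile = SitePileup(position=pos1, ref_base=ref_base)
        for base, q, is_reverse, _is_read1 in bucket.values():
            pile.add(base, q, is_reverse)
        pileups[pos1] = pile
    return pileups


def reconstruct_pileup(
    position: int,
    depth: int,
    allele1: str,
    freq1_pct: float,
    allele2: str,
    freq2_pct: float,
    qual: int = 30,
) -> SitePileup:
    """Rebuild an integer-count pileup from a reported depth and frequencies.

    Counts are ``round(freq * depth)`` and are split as evenly as possible
    between strands (forward strand gets the extra base on odd counts).
    """
    pile = SitePileup(position=position)
    for base, freq_pct in ((allele1, freq1_pct), (allele2, freq2_pct)):
        count = int(round(freq_pct / 100.0 * depth))
        fwd = count - count // 2
        rev = count // 2
        for _ in range(fwd):
            pile.add(base, qual, False)
        for _ in range(rev):
            pile.add(base, qual, True)
    return pile


# ---------------------------------------------------------------------------
# consensus and output
# ---------------------------------------------------------------------------

def consensus_sequences(
    calls: list[HeteroplasmyCall],
    reference: str,
) -> tuple[str, str]:
    """Major- and minor-allele consensus sequences for haplogroup analysis.

    The major consensus carries each heteroplasmic site's major allele, the
    minor consensus the minor allele; every other position copies the
    reference (standing in for the sample's homoplasmic allele).
    """
    major_seq = list(reference)
    minor_seq = list(reference)
    seen: dict[int, tuple[str, str]] = {}
    for call in calls:
        if not call.is_heteroplasmic:
            continue
        alleles = (call.major_allele, call.minor_allele)
        if call.position in seen and seen[call.position] != alleles:
            raise ValueError(f"conflicting calls at position {call.position}")
        seen[call.position] = alleles
        major_seq[call.position - 1] = call.major_allele
        minor_seq[call.position - 1] = call.minor_allele
    return "".join(major_seq), "".join(minor_seq)


def calls_to_vcf(calls: list[HeteroplasmyCall], path: str, reference: str | None = None) -> None:
    """Write heteroplasmy calls as a minimal VCF 4.2 file."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID={MITO_NAME},length={MITO_LENGTH}>\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">\n')
        out.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        out.write('##INFO=<ID=LLR,Number=1,Type=Float,Description="log10 likelihood ratio het vs homo">\n')
        out.write('##INFO=<ID=CMP,Number=1,Type=String,Description="Compartment">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: c.position):
            if not call.is_heteroplasmic:
                continue
            ref_base = reference[call.position - 1] if reference else call.major_allele
            alt = call.minor_allele if call.minor_allele != ref_base else call.major_allele
            info = (
                f"DP={call.depth};AF={call.minor_freq / 100.0:.6f};"
                f"LLR={call.llr:.4f};CMP={call.compartment}"
            )
            out.write(
                f"{MITO_NAME}\t{call.position}\t.\t{ref_base}\t{alt}\t.\tPASS\t{info}\n"
            )
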