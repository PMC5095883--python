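"""Aligned read-pair filtering and fragment reconstruction.

Retention criteria for a read pair: proper inward-facing (FR) orientation on
one contig, mapping quality strictly greater than 20 on both mates, and each
mate's mismatch count strictly below 5% of its trimmed read length. The DNA
fragment is then the interval from the leftmost mate start to the rightmost
mate end (0-based half-open internally; SAM's 1-based coordinates are
converted at the boundary). PCR duplicates are collapsed on the
(reference, start, end, orientation) key, keeping the first record seen.

Mitochondrial assignments are additionally screened against nuclear
mitochondrial segments (NUMTs): a fragment initially placed on the
mitochondrial contig is kept only if neither mate has a nuclear alignment
scoring at least as well as its mitochondrial alignment; otherwise it is
flagged ambiguous and excluded from mitochondrial counts. When alignment
scores are unavailable the filter degrades to a mapping-quality proxy
(MAPQ > 20 on the mitochondrial alignment) and logs that it did so.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .reference import MITO_NAME

logger = logging.getLogger(__name__)

MAPQ_MIN = 20              # strict >
MAX_MISMATCH_FRAC = 0.05   # strict <


@dataclass
class MateAlignment:
    reference: str
    start: int                 # 0-based
    end: int                   # half-open
    mapq: int
    mismatches: int | None     # NM tag (indels included) when present
    trimmed_length: int
    is_reverse: bool
    score: int | None = None   # AS tag when present

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class AlignedPair:
    name: str
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def orientation(self) -> str:
        """FR (inward), RF (outward) or tandem."""
        m1, m2 = self.mate1, self.mate2
        if m1.is_reverse == m2.is_reverse:
            return "tandem"
        fwd, rev = (m1, m2) if not m1.is_reverse else (m2, m1)
        return "FR" if fwd.start <= rev.start else "RF"


@dataclass
class FragmentRecord:
    reference: str
    start: int                 # 0-based half-open interval
    end: int
    genome_class: str          # "mito" | "nuclear"
    name: str = ""
    duplicate: bool = False
    numt_ambiguous: bool = False
    pass_filters: bool = True
    fail_reason: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def retained(self) -> bool:
        return self.pass_filters and not self.duplicate and not self.numt_ambiguous


def filter_pair(
    pair: AlignedPair,
    mapq_min: int = MAPQ_MIN,
    max_mismatch_frac: float = MAX_MISMATCH_FRAC,
) -> tuple[bool, str | None]:
    """Apply the pair retention criteria; returns (pass, fail-reason)."""
    for mate in (pair.mate1, pair.mate2):
        if mate.reference is None:
            return False, "unmapped"
    if pair.mate1.reference != pair.mate2.reference:
        return False, "interchromosomal"
    if pair.orientation != "FR":
        return False, "orientation"
    if pair.mate1.mapq <= mapq_min or pair.mate2.mapq <= mapq_min:
        return False, "mapq"
    for mate in (pair.mate1, pair.mate2):
        if mate.mismatches is not None:
            if mate.mismatches >= max_mismatch_frac * mate.trimmed_length:
                return False, "mismatches"
    return True, None


def infer_fragment(pair: AlignedPair, mito_name: str = MITO_NAME) -> FragmentRecord:
    """Fragment interval from the outermost coordinates of the mate pair."""
    if pair.mate1.reference != pair.mate2.reference:
        raise ValueError(f"{pair.name}: mates on different references")
    start = min(pair.mate1.start, pair.mate2.start)
    end = max(pair.mate1.end, pair.mate2.end)
    ref = pair.mate1.reference
    return FragmentRecord(
        reference=ref,
        start=start,
        end=end,
        genome_class="mito" if ref == mito_name else "nuclear",
        name=pair.name,
    )


def dedupe(fragments: list[FragmentRecord]) -> list[FragmentRecord]:
    """Flag PCR duplicates in place; first fragment per key is retained.

    The key is (reference, start, end); orientation is part of the key in
    principle but all retained pairs are FR, so it is constant here.
    """
    seen: set[tuple] = set()
    for frag in fragments:
        key = (frag.reference, frag.start, frag.end)
        if key in seen:
            frag.duplicate = True
        else:
            frag.duplicate = False
            seen.add(key)
    return fragments


def numt_filter(
    fragment: FragmentRecord,
    mate_alignments: list[list[MateAlignment]],
    mapq_min: int = MAPQ_MIN,
) -> bool:
    """Decide whether a mitochondrial fragment is uniquely mitochondrial.

    ``mate_alignments`` lists, per mate, every reported alignment (primary
    and secondary). The fragment is retained iff no mate has a nuclear
    alignment whose score is >= its mitochondrial alignment score. Sets
    ``fragment.numt_ambiguous`` and returns the retention decision.
    """
    if fragment.genome_class != "mito":
        return True
    ambiguous = False
    for alignments in mate_alignments:
        mito = [a for a in alignments if a.reference == MITO_NAME]
        nuclear = [a for a in alignments if a.reference != MITO_NAME]
        if not nuclear:
            continue
        mito_scores = [a.score for a in mito]
        if any(s is None for s in mito_scores) or any(
            a.score is None for a in nuclear
        ):
            logger.warning(
                "alignment scores missing for %s; falling back to MAPQ proxy",
                fragment.name,
            )
            if not all(a.mapq > mapq_min for a in mito):
                ambiguous = True
            continue
        best_mito = max(mito_scores)
        if any(a.score >= best_mito for a in nuclear):
            ambiguous = True
    fragment.numt_ambiguous = ambiguous
    return not ambiguous


# ---------------------------------------------------------------------------
# SAM ingestion and the full fragment pipeline
# ---------------------------------------------------------------------------

def _mate_from_read(read: pysam.AlignedSegment) -> MateAlignment:
    return MateAlignment(
        reference=read.reference_name,
        start=read.reference_start,
        end=read.reference_end,
        mapq=read.mapping_quality,
        mismatches=read.get_tag("NM") if read.has_tag("NM") else None,
        trimmed_length=read.query_length or read.infer_query_length() or 0,
        is_reverse=read.is_reverse,
        score=read.get_tag("AS") if read.has_tag("AS") else None,
    )


def load_pairs(
    path: str,
) -> tuple[list[AlignedPair], dict[str, list[list[MateAlignment]]]]:
    """Read SAM/BAM and group primary records into pairs.

    Returns the primary pairs plus, per query name, the full per-mate
    alignment lists (primaries and secondaries) needed by the NUMT filter.
    """
    primaries: dict[str, dict[int, pysam.AlignedSegment]] = defaultdict(dict)
    all_alignments: dict[str, list[list[MateAlignment]]] = defaultdict(
        lambda: [[], []]
    )
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as af:
            for read in af:
                if read.is_unmapped or read.is_supplementary:
                    continue
                mate_idx = 1 if read.is_read2 else 0
                all_alignments[read.query_name][mate_idx].append(
                    _mate_from_read(read)
                )
                if not read.is_secondary:
                    primaries[read.query_name][mate_idx] = read
    finally:
        pysam.set_verbosity(save)
    pairs = []
    for name, mates in primaries.items():
        if len(mates) == 2:
            pairs.append(
                AlignedPair(name, _mate_from_read(mates[0]), _mate_from_read(mates[1]))
            )
    return pairs, dict(all_alignments)


@dataclass
class ProcessResult:
    fragments: list[FragmentRecord]
    summary: pd.DataFrame = field(repr=False, default=None)

    def retained(self) -> list[FragmentRecord]:
        return [f for f in self.fragments if f.retained]


def process_pairs(
    pairs: list[AlignedPair],
    alignments: dict[str, list[list[MateAlignment]]] | None = None,
    mapq_min: int = MAPQ_MIN,
    max_mismatch_frac: float = MAX_MISMATCH_FRAC,
    apply_numt_filter: bool = True,
) -> ProcessResult:
    """Filter pairs, infer fragments, dedupe, and apply the NUMT screen."""
    fragments: list[FragmentRecord] = []
    reasons: dict[str, int] = defaultdict(int)
    passing: list[FragmentRecord] = []
    for pair in pairs:
        ok, reason = filter_pair(pair, mapq_min, max_mismatch_frac)
        if not ok:
            reasons[reason] += 1
            frag = FragmentRecord(
                reference=pair.mate1.reference or "*",
                start=min(pair.mate1.start, pair.mate2.start),
                end=max(pair.mate1.end, pair.mate2.end),
                genome_class="mito"
                if pair.mate1.reference == MITO_NAME
                else "nuclear",
                name=pair.name,
                pass_filters=False,
                fail_reason=reason,
            )
            fragments.append(frag)
            continue
        frag = infer_fragment(pair)
        fragments.append(frag)
        passing.append(frag)
    dedupe(passing)
    reasons["duplicate"] = sum(f.duplicate for f in passing)
    if apply_numt_filter and alignments is not None:
        for frag in passing:
            if frag.genome_class == "mito" and not frag.duplicate:
                numt_filter(frag, alignments.get(frag.name, []))
    reasons["numt_ambiguous"] = sum(f.numt_ambiguous for f in passing)
    reasons["retained"] = sum(f.retained for f in fragments)
    reasons["input_pairs"] = len(pairs)
    summary = pd.DataFrame(
        sorted(reasons.items()), columns=["category", "count"]
    )
    return ProcessResult(fragments=fragments, summary=summary)


def process_sam(path: str, **kwargs) -> ProcessResult:
    """Run the complete pair-to-fragment pipeline on a SAM/BAM file."""
    pairs, alignments = load_pairs(path)
    return process_pairs(pairs, alignments, **kwargs)


def write_bed(fragments: list[FragmentRecord], path: str) -> None:
    """Write retained fragments as BED (0-based half-open)."""
    with open(path, "w") as out:
        for frag in fragments:
            if frag.retained:
                out.write(
                    f"{frag.reference}\t{frag.start}\t{frag.end}\t{frag.name}\t"
                    f"{frag.genome_class}\n"
                )


def fragments_to_frame(fragments: list[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reference": [f.reference for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "length": [f.length for f in fragments],
            "genome_class": [f.genome_class for f in fragments],
            "retained": [f.retained for f in fragments],
        }
    )
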