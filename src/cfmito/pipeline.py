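"""End-to-end orchestration: simulate -> process -> profile -> call -> compare.

`RunConfig` carries every tunable threshold with its default; the run
functions are deterministic given their inputs and write plain-text outputs
(TSV/VCF/FASTA) so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields

import pandas as pd

from . import hetcall, readproc, sizeprof
from .reference import MITO_LENGTH, ReferenceSet

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    # pair / fragment filters
    mapq_min: int = 20
    max_mismatch_frac: float = 0.05
    baseq_min: int = 20
    # heteroplasmy criteria
    wbc_min_depth: int = 400
    wbc_min_maf: float = 0.01
    strand_min_maf: float = 0.006
    strand_alpha: float = 0.05
    plasma_min_depth: int = 50
    plasma_min_minor: int = 4
    llr_min: float = 5.0
    # size analysis
    size_select_lo: int = 30
    size_select_hi: int = 60
    window_width: int = 10
    window_step: int = 1
    short_cutoff: int = 100

    def to_file(self, path: str) -> None:
        with open(path, "w") as out:
            for key, value in asdict(self).items():
                out.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                if key not in types:
                    raise ValueError(f"unknown config key: {key}")
                caster = float if "float" in str(types[key]) else int
                kwargs[key] = caster(raw)
        return cls(**kwargs)

    def log_thresholds(self) -> None:
        for key, value in asdict(self).items():
            logger.info("config %s=%s", key, value)


# ---------------------------------------------------------------------------
# size analysis
# ---------------------------------------------------------------------------

def run_size_analysis(
    fragments: pd.DataFrame,
    out_dir: str,
    config: RunConfig | None = None,
) -> dict:
    """Histogram, sliding-window profile and size-selection summary.

    ``fragments`` needs columns ``length`` and ``genome_class`` (``mito`` /
    ``nuclear``); a ``retained`` column restricts to retained fragments if
    present. Writes TSVs under ``out_dir`` and returns the key numbers.
    """
    import os

    config = config or RunConfig()
    config.log_thresholds()
    if "retained" in fragments.columns:
        fragments = fragments[fragments["retained"]]
    if len(fragments) == 0:
        raise ValueError("no retained fragments to analyse")
    os.makedirs(out_dir, exist_ok=True)

    lengths = fragments["length"].to_numpy()
    is_mito = (fragments["genome_class"] == "mito").to_numpy()
    results: dict = {}
    for klass, mask in (("mito", is_mito), ("nuclear", ~is_mito)):
        if mask.any():
            hist = sizeprof.LengthHistogram.from_lengths(lengths[mask], klass)
            hist.to_frame().to_csv(
                os.path.join(out_dir, f"lengths_{klass}.tsv"), sep="\t", index=False
            )
            results[f"{klass}_mode_bp"] = hist.mode()

    overall = sizeprof.LengthHistogram.from_lengths(lengths, "all")
    results["concentration_pct"] = sizeprof.fractional_concentration(
        int(is_mito.sum()), len(lengths)
    )
    results["short_fraction"] = sizeprof.short_fraction(overall, config.short_cutoff)

    profile = sizeprof.window_concentration(
        lengths, is_mito, config.window_width, config.window_step
    )
    profile.to_frame().to_csv(
        os.path.join(out_dir, "window_concentration.tsv"), sep="\t", index=False
    )
    if any(w[2] for w in profile.windows):
        results["peak_window_start_bp"] = profile.peak()[0]

    selected = sizeprof.size_select(
        lengths, config.size_select_lo, config.size_select_hi
    )
    if selected.any():
        results["concentration_selected_pct"] = sizeprof.fractional_concentration(
            int((selected & is_mito).sum()), int(selected.sum())
        )
    pd.DataFrame([results]).to_csv(
        os.path.join(out_dir, "size_summary.tsv"), sep="\t", index=False
    )
    return results


def run_fold_report(concentrations: pd.DataFrame, out_dir: str) -> dict:
    """Method-comparison fold table from a sample x method concentration table."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    report = sizeprof.fold_table(concentrations)
    report["folds"].to_csv(os.path.join(out_dir, "folds.tsv"), sep="\t", index=False)
    report["means"].rename("mean_concentration_pct").to_csv(
        os.path.join(out_dir, "method_means.tsv"), sep="\t"
    )
    report["mean_folds"].rename("mean_fold").to_csv(
        os.path.join(out_dir, "mean_folds.tsv"), sep="\t"
    )
    return report


# ---------------------------------------------------------------------------
# heteroplasmy
# ---------------------------------------------------------------------------

def _compartment_pileups(
    sam_path: str, compartment: str, config: RunConfig, reference: str | None
) -> dict[int, hetcall.SitePileup]:
    result = readproc.process_sam(
        sam_path,
        mapq_min=config.mapq_min,
        max_mismatch_frac=config.max_mismatch_frac,
    )
    keep = {f.name for f in result.retained()}
    return hetcall.pileups_from_alignments(
        sam_path, keep_qnames=keep, baseq_min=config.baseq_min, reference=reference
    )


def _call_site(pileup: hetcall.SitePileup, compartment: str, config: RunConfig):
    if compartment == "wbc":
        return hetcall.call_wbc(
            pileup,
            min_depth=config.wbc_min_depth,
            min_maf=config.wbc_min_maf,
            min_strand_maf=config.strand_min_maf,
            alpha=config.strand_alpha,
            llr_min=config.llr_min,
        )
    return hetcall.call_plasma(
        pileup,
        min_depth=config.plasma_min_depth,
        min_minor=config.plasma_min_minor,
        llr_min=config.llr_min,
    )


def calls_to_frame(calls: list[hetcall.HeteroplasmyCall]) -> pd.DataFrame:
    """Site table in the published layout (frequencies as printed percents)."""
    rows = []
    for call in sorted(calls, key=lambda c: c.position):
        rows.append(
            {
                "position": call.position,
                "compartment": call.compartment,
                "depth": call.depth,
                "major_allele": call.major_allele,
                "major_freq_pct": round(call.major_freq, 2),
                "minor_allele": call.minor_allele,
                "minor_freq_pct": round(call.minor_freq, 2),
                "llr": round(call.llr, 3),
                "heteroplasmic": call.is_heteroplasmic,
            }
        )
    return pd.DataFrame(rows)


def run_heteroplasmy(
    plasma_sam: str,
    out_dir: str,
    wbc_sam: str | None = None,
    reference_fasta: str | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Call heteroplasmy per compartment, compare, and export consensus.

    Writes per-compartment call TSVs and VCFs, a shared-site classification
    TSV when both compartments are given, and major/minor consensus FASTA
    (when a reference is available) suitable for haplogroup classification.
    """
    import os

    config = config or RunConfig()
    config.log_thresholds()
    os.makedirs(out_dir, exist_ok=True)

    reference = None
    if reference_fasta:
        refset = ReferenceSet.read_fasta(reference_fasta)
        if len(refset.mito) != MITO_LENGTH:
            raise ValueError(
                f"mitochondrial reference length {len(refset.mito)} != {MITO_LENGTH}"
            )
        reference = refset.mito

    pileups = {"plasma": _compartment_pileups(plasma_sam, "plasma", config, reference)}
    if wbc_sam:
        pileups["wbc"] = _compartment_pileups(wbc_sam, "wbc", config, reference)

    results: dict = {}
    all_calls: dict[str, dict[int, hetcall.HeteroplasmyCall]] = {}
    for compartment, piles in pileups.items():
        calls = {
            pos: _call_site(pile, compartment, config)
            for pos, pile in sorted(piles.items())
            if pile.depth > 0
        }
        all_calls[compartment] = calls
        het = [c for c in calls.values() if c.is_heteroplasmic]
        frame = calls_to_frame(het)
        frame.to_csv(
            os.path.join(out_dir, f"calls_{compartment}.tsv"), sep="\t", index=False
        )
        hetcall.calls_to_vcf(
            het, os.path.join(out_dir, f"calls_{compartment}.vcf"), reference
        )
        results[f"{compartment}_het_sites"] = sorted(c.position for c in het)
        if reference is not None:
            major_seq, minor_seq = hetcall.consensus_sequences(het, reference)
            fasta = os.path.join(out_dir, f"consensus_{compartment}.fasta")
            with open(fasta, "w") as out:
                out.write(f">{compartment}_major_consensus\n{major_seq}\n")
                out.write(f">{compartment}_minor_consensus\n{minor_seq}\n")

    if wbc_sam:
        shared_rows = []
        candidates = sorted(
            set(results["plasma_het_sites"]) | set(results["wbc_het_sites"])
        )
        for pos in candidates:
            wbc_pile = pileups["wbc"].get(pos)
            plasma_pile = pileups["plasma"].get(pos)
            if wbc_pile is None or wbc_pile.depth == 0:
                klass = "plasma_only"
            elif plasma_pile is None or plasma_pile.depth == 0:
                klass = "wbc_only"
            else:
                klass = hetcall.classify_shared(
                    wbc_pile, plasma_pile, llr_min=config.llr_min
                ).klass
            shared_rows.append({"position": pos, "class": klass})
        shared = pd.DataFrame(shared_rows, columns=["position", "class"])
        shared.to_csv(os.path.join(out_dir, "shared_sites.tsv"), sep="\t", index=False)
        results["shared_classes"] = dict(
            zip(shared["position"], shared["class"])
        )
    return results
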