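"""Fragment-size distributions and mtDNA fractional concentration.

The mtDNA fractional concentration of a fragment set is

    concentration (%) = 100 * (mitochondrial fragments) / (mapped fragments)

computed over deduplicated, filter-passing fragments. Because plasma
cf-mtDNA is far shorter than nucleosome-protected nuclear cfDNA, the
concentration varies strongly with fragment size; a sliding-window profile
makes that visible, and an in-silico size selection (default 30-60 bp, the
insert range corresponding to a 150-190 bp adaptor-ligated library) enriches
the mitochondrial fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class LengthHistogram:
    """Counts of fragments per integer length (bp) for one genome class."""

    genome_class: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(length < 1 for length in self.counts):
            raise ValueError("fragment lengths must be >= 1 bp")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_lengths(cls, lengths, genome_class: str = "all") -> "LengthHistogram":
        lengths = np.asarray(lengths, dtype=int)
        values, counts = np.unique(lengths, return_counts=True)
        return cls(genome_class, dict(zip(values.tolist(), counts.tolist())))

    def mode(self) -> int:
        """Most frequent length; ties broken by the smaller length."""
        if not self.counts:
            raise ValueError("empty histogram has no mode")
        return min(self.counts, key=lambda ln: (-self.counts[ln], ln))

    def truncate(self, lo: int, hi: int) -> "LengthHistogram":
        return LengthHistogram(
            self.genome_class,
            {ln: c for ln, c in self.counts.items() if lo <= ln <= hi},
        )

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.counts)
        return pd.DataFrame(
            {"length": lengths, "count": [self.counts[ln] for ln in lengths]}
        )


@dataclass
class ConcentrationProfile:
    """mtDNA fractional concentration (%) per fragment-size window."""

    windows: list[tuple[int, int, float | None]]   # (start, end, concentration %)
    width: int
    step: int

    def __post_init__(self) -> None:
        for _a, _b, conc in self.windows:
            if conc is not None and not (0.0 <= conc <= 100.0):
                raise ValueError("window concentrations must lie in [0, 100]")

    def peak(self) -> tuple[int, int, float]:
        """Window with the maximum concentration; ties to the smallest start."""
        defined = [w for w in self.windows if w[2] is not None]
        if not defined:
            raise ValueError("profile has no populated windows")
        return max(defined, key=lambda w: (w[2], -w[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.windows, columns=["window_start", "window_end", "concentration_pct"]
        )


def fractional_concentration(mito_count: int, total_mapped: int) -> float:
    """Percent of mapped fragments assigned to the mitochondrial genome."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if mito_count > total_mapped:
        raise ValueError("mito_count cannot exceed total_mapped")
    return 100.0 * mito_count / total_mapped


def short_fraction(hist: LengthHistogram, cutoff: int) -> float:
    """Proportion of fragments strictly shorter than ``cutoff`` bp."""
    total = hist.total
    if total == 0:
        raise ValueError("empty histogram")
    short = sum(c for ln, c in hist.counts.items() if ln < cutoff)
    return short / total


def window_concentration(
    lengths, is_mito, width: int = 10, step: int = 1
) -> ConcentrationProfile:
    """Sliding-window mtDNA concentration over fragment length.

    Windows are [a, a+width) advancing by ``step`` from the shortest to the
    longest observed length; windows without any fragment are reported as
    missing (None), not as zero.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    lengths = np.asarray(lengths, dtype=int)
    is_mito = np.asarray(is_mito, dtype=bool)
    if lengths.size == 0:
        return ConcentrationProfile([], width, step)
    windows = []
    for a in range(int(lengths.min()), int(lengths.max()) + 1, step):
        in_win = (lengths >= a) & (lengths < a + width)
        denom = int(in_win.sum())
        conc = 100.0 * int((in_win & is_mito).sum()) / denom if denom else None
        windows.append((a, a + width, conc))
    return ConcentrationProfile(windows, width, step)


def size_select(lengths, lo: int, hi: int) -> np.ndarray:
    """Boolean mask of fragments with lo <= length <= hi (inclusive bounds)."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    lengths = np.asarray(lengths, dtype=int)
    return (lengths >= lo) & (lengths <= hi)


def fold_table(concentrations: pd.DataFrame, sample_col: str = "sample") -> dict:
    """Per-sample fold changes between methods plus per-method means.

    ``concentrations`` holds one row per sample and one column per method
    (percent scale). Returns a dict with:

    * ``folds``: DataFrame of per-sample pairwise ratios later/earlier method
      (column order defines "later"), rounded to 2 decimals;
    * ``means``: per-method across-sample means rounded to 4 decimals;
    * ``mean_folds``: across-sample mean of each rounded fold column, rounded
      to 1 decimal.
    Ratios with a zero denominator are left undefined (NaN).
    """
    methods = [c for c in concentrations.columns if c != sample_col]
    if len(methods) < 2 or len(concentrations) < 1:
        raise ValueError("need at least one sample and two methods")
    folds = pd.DataFrame({sample_col: concentrations[sample_col]})
    for earlier, later in combinations(methods, 2):
        denom = concentrations[earlier].to_numpy(dtype=float)
        numer = concentrations[later].to_numpy(dtype=float)
        ratio = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
        folds[f"{later}/{earlier}"] = np.round(ratio, 2)
    means = concentrations[methods].mean().round(4)
    fold_cols = [c for c in folds.columns if c != sample_col]
    mean_folds = folds[fold_cols].mean().round(1)
    return {"folds": folds, "means": means, "mean_folds": mean_folds}
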