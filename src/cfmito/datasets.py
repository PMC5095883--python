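"""Bundled example datasets.

Small published measurement tables from a plasma cfDNA sequencing study of
sepsis patients, shipped as TSV: mtDNA fractional concentrations for seven
samples under three library preparations, and per-site heteroplasmy depths
and allele frequencies for three patients (plasma vs leukocytes). They drive
worked examples and regression tests without any sequence data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import hetcall


def _read(name: str) -> pd.DataFrame:
    with resources.files("cfmito.data").joinpath(name).open("r") as handle:
        return pd.read_csv(handle, sep="\t")


def load_concentration_table() -> pd.DataFrame:
    """mtDNA fractional concentration (%) per sample and library method.

    Columns: sample, standard, optimized, optimized_ss (optimized library
    preparation followed by 30-60 bp in-silico-equivalent size selection).
    """
    return _read("concentration_by_method.tsv")


def load_shared_site_table() -> pd.DataFrame:
    """Per-site plasma/leukocyte depths and allele frequencies, patient 42.

    Twelve candidate heteroplasmic sites, two rows each (plasma and wbc).
    """
    return _read("heteroplasmy_patient42.tsv")


def load_single_site_table() -> pd.DataFrame:
    """Single-site plasma/leukocyte comparisons for patients 1 and 93."""
    return _read("heteroplasmy_patients_1_93.tsv")


def shared_site_pileups(
    table: pd.DataFrame | None = None, qual: int = 30
) -> dict[int, dict[str, hetcall.SitePileup]]:
    """Reconstruct per-compartment pileups from a printed site table.

    Integer allele counts are rebuilt as round(frequency x depth) and split
    evenly between strands; every base is assigned the given Phred quality.
    Returns {position: {"plasma": pileup, "wbc": pileup}}.
    """
    if table is None:
        table = load_shared_site_table()
    out: dict[int, dict[str, hetcall.SitePileup]] = {}
    for row in table.itertuples(index=False):
        pile = hetcall.reconstruct_pileup(
            position=int(row.position),
            depth=int(row.depth),
            allele1=str(row.allele1),
            freq1_pct=float(row.freq1_pct),
            allele2=str(row.allele2),
            freq2_pct=float(row.freq2_pct),
            qual=qual,
        )
        out.setdefault(int(row.position), {})[str(row.compartment)] = pile
    return out


def classify_shared_sites(
    table: pd.DataFrame | None = None, qual: int = 30
) -> pd.DataFrame:
    """Run the shared-site classifier over a reconstructed site table.

    Returns one row per position with the assigned class and per-compartment
    LLR values.
    """
    records = []
    for position, piles in shared_site_pileups(table, qual=qual).items():
        result = hetcall.classify_shared(piles["wbc"], piles["plasma"])
        records.append(
            {
                "position": position,
                "class": result.klass,
                "wbc_llr": result.wbc.llr,
                "plasma_llr": result.plasma.llr,
                "wbc_minor_freq": result.wbc.minor_freq,
                "plasma_minor_freq": result.plasma.minor_freq,
            }
        )
    return pd.DataFrame.from_records(records).sort_values("position", ignore_index=True)
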