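"""Synthetic reference genomes for simulation and testing.

The human mitochondrial reference (rCRS) is 16,569 bp; real sequence content
is irrelevant for the statistics exercised here, so a seeded random sequence
of the correct length stands in for it, alongside a small nuclear contig.
Both are labelled synthetic and are regenerated deterministically from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MITO_NAME = "chrM"
MITO_LENGTH = 16569  # rCRS length in bp
BASES = np.array(list("ACGT"))


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


@dataclass
class ReferenceSet:
    """A mitochondrial sequence plus one or more nuclear contigs."""

    mito: str
    nuclear: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [MITO_NAME, *self.nuclear.keys()]

    def sequence(self, name: str) -> str:
        if name == MITO_NAME:
            return self.mito
        return self.nuclear[name]

    def lengths(self) -> dict[str, int]:
        return {name: len(self.sequence(name)) for name in self.names}

    def write_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(self.sequence(name)), id=name, description="synthetic")
            for name in self.names
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")

    @classmethod
    def read_fasta(cls, path: str) -> "ReferenceSet":
        mito = None
        nuclear: dict[str, str] = {}
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id == MITO_NAME:
                mito = str(rec.seq).upper()
            else:
                nuclear[rec.id] = str(rec.seq).upper()
        if mito is None:
            raise ValueError(f"no {MITO_NAME} sequence in {path}")
        return cls(mito=mito, nuclear=nuclear)


def make_reference_set(seed: int = 2016, nuclear_length: int = 60_000) -> ReferenceSet:
    """Build a synthetic mito (16,569 bp) + single nuclear contig reference."""
    rng = np.random.default_rng(seed)
    mito = _random_sequence(MITO_LENGTH, rng)
    nuclear = {"nuc1": _random_sequence(nuclear_length, rng)}
    return ReferenceSet(mito=mito, nuclear=nuclear)
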