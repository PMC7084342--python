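"""Genetic-code tables and synonymous-family structure.

Wraps Biopython's NCBI codon tables in a small immutable object that also
exposes the synonymous families (amino acid -> codon list) needed for RSCU
and for Nei–Gojobori site counting.  The default throughout the package is
NCBI translation table 2, the vertebrate mitochondrial code (AGA/AGG are
stops, ATA encodes Met, TGA encodes Trp), which fish mitogenomes use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable

BASES = ("T", "C", "A", "G")

#: All 64 codons in TCAG order (the conventional codon-table layout).
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))

STOP_SYMBOL = "*"

VERTEBRATE_MITO_TABLE_ID = 2


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI genetic code with its synonymous-family partition.

    Attributes
    ----------
    table_id : int
        NCBI translation table number.
    name : str
        Table name as given by NCBI.
    forward : mapping of codon -> one-letter amino acid
        Covers all 64 codons; stop codons map to ``"*"``.
    stop_codons : frozenset of str
    families : mapping of amino acid -> tuple of codons
        Partition of the 60 (for table 2) non-stop codons.
    """

    table_id: int
    name: str
    forward: Mapping[str, str]
    stop_codons: frozenset[str]
    families: Mapping[str, tuple[str, ...]] = field(repr=False)

    @classmethod
    @lru_cache(maxsize=None)
    def from_ncbi_id(cls, table_id: int = VERTEBRATE_MITO_TABLE_ID) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = {c: table.forward_table.get(c, STOP_SYMBOL) for c in ALL_CODONS}
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = forward[codon]
            if aa != STOP_SYMBOL:
                fams.setdefault(aa, []).append(codon)
        return cls(
            table_id=table_id,
            name="; ".join(table.names[:1]),
            forward=MappingProxyType(forward),
            stop_codons=frozenset(table.stop_codons),
            families=MappingProxyType({aa: tuple(v) for aa, v in fams.items()}),
        )

    def translate(self, codon: str) -> str:
        """One-letter amino acid for ``codon``; ``"*"`` for a stop."""
        return self.forward[codon.upper().replace("U", "T")]

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.stop_codons

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        """True when the two non-stop codons encode the same amino acid."""
        aa, ab = self.translate(codon_a), self.translate(codon_b)
        if STOP_SYMBOL in (aa, ab):
            raise ValueError("synonymy is undefined for stop codons")
        return aa == ab

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.translate(codon)]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)


def vertebrate_mitochondrial() -> GeneticCode:
    """The vertebrate mitochondrial code (NCBI table 2)."""
    return GeneticCode.from_ncbi_id(VERTEBRATE_MITO_TABLE_ID)
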