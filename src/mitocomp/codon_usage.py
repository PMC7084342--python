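"""Codon counting, terminal-codon classification, and RSCU.

Mitochondrial protein genes frequently end in the incomplete stop codons
``TA`` or ``T``, completed to TAA by polyadenylation of the transcript;
:func:`classify_terminal_codons` recognises these from the coding-strand
sequence alone.  RSCU (relative synonymous codon usage) for codon *c* in a
synonymous family of size *k* with family total *X* is ``k · x_c / X``:
1 means no bias, >1 means the codon is over-used relative to its synonyms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genetic_code import ALL_CODONS, GeneticCode, vertebrate_mitochondrial

STOP_CLASSES = ("TAA", "TAG", "AGA", "AGG", "TA", "T")


@dataclass(frozen=True)
class CodonCounts:
    """Pooled complete-codon counts with discard bookkeeping."""

    counts: Mapping[str, int]
    scope: str = "pooled"
    n_incomplete: int = 0        # trailing incomplete codons discarded
    incomplete_bases: int = 0    # bases in those incomplete codons
    n_terminal_stops: int = 0    # terminal stop codons dropped (when flagged)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class RscuTable:
    """Per-codon RSCU and per-amino-acid usage frequency."""

    rscu: Mapping[str, float | None]   # None for codons in unused families
    aa_usage: Mapping[str, float]

    def as_frame(self, counts: CodonCounts, code: GeneticCode) -> pd.DataFrame:
        total = counts.total or 1
        rows = [
            {
                "codon": c,
                "amino_acid": code.translate(c),
                "count": counts.counts.get(c, 0),
                "frequency": counts.counts.get(c, 0) / total,
                "rscu": self.rscu.get(c),
            }
            for c in ALL_CODONS
            if not code.is_stop(c)
        ]
        return pd.DataFrame(rows)


def classify_terminal_codons(
    cds: str, code: GeneticCode | None = None
) -> tuple[str, str]:
    """(start codon, stop classification) for a coding-strand sequence.

    Stop classification: a complete terminal stop codon when the length is a
    multiple of 3; ``"TA"``/``"T"`` for the incomplete endings left by
    polyadenylation-completed stops; ``"none"`` otherwise.
    """
    code = code or vertebrate_mitochondrial()
    s = cds.upper().replace("U", "T")
    if len(s) < 4:
        raise ValueError("coding sequence shorter than 4 bases")
    start = s[:3]
    rem = len(s) % 3
    if rem == 0 and code.is_stop(s[-3:]):
        stop = s[-3:]
    elif rem == 2 and s[-2:] == "TA":
        stop = "TA"
    elif rem == 1 and s[-1] == "T":
        stop = "T"
    else:
        stop = "none"
    return start, stop


def count_codons(
    cds_list: Iterable[str],
    code: GeneticCode | None = None,
    drop_terminal_stop: bool = True,
    scope: str = "pooled",
) -> CodonCounts:
    """Count complete codons over a pool of in-frame coding sequences.

    Trailing incomplete codons are discarded (and tallied); with
    ``drop_terminal_stop`` a gene's final complete codon is excluded when it
    is a stop, so pooled usage reflects sense codons only.  An internal stop
    codon raises a warning naming the gene and codon index, not an error
    (mitochondrial annotations legitimately disagree about boundaries).
    """
    code = code or vertebrate_mitochondrial()
    counts: dict[str, int] = {}
    n_incomplete = incomplete_bases = n_terminal_stops = 0
    for gene_idx, cds in enumerate(cds_list):
        s = cds.upper().replace("U", "T")
        n_complete = len(s) // 3
        rem = len(s) % 3
        if rem:
            n_incomplete += 1
            incomplete_bases += rem
        codons = [s[3 * i : 3 * i + 3] for i in range(n_complete)]
        if drop_terminal_stop and codons and code.is_stop(codons[-1]):
            codons.pop()
            n_terminal_stops += 1
        for i, codon in enumerate(codons):
            if code.is_stop(codon) and i < len(codons) - 1:
                warnings.warn(
                    f"internal stop codon {codon} at codon {i + 1} of "
                    f"sequence {gene_idx + 1}"
                )
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(
        counts=counts, scope=scope, n_incomplete=n_incomplete,
        incomplete_bases=incomplete_bases, n_terminal_stops=n_terminal_stops,
    )


def amino_acid_usage(
    counts: CodonCounts, code: GeneticCode | None = None
) -> dict[str, float]:
    """Share of each amino acid among all counted sense codons (sums to 1)."""
    code = code or vertebrate_mitochondrial()
    per_aa: dict[str, float] = {aa: 0 for aa in code.families}
    total = 0
    for codon, n in counts.counts.items():
        if code.is_stop(codon):
            continue
        per_aa[code.translate(codon)] += n
        total += n
    if total == 0:
        raise ValueError("no sense codons counted")
    return {aa: n / total for aa, n in per_aa.items()}


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> RscuTable:
    """Relative synonymous codon usage over every synonymous family.

    Families with zero total usage get ``None`` for each member; otherwise
    the family's RSCU values sum to the family size (mean 1).
    """
    code = code or vertebrate_mitochondrial()
    values: dict[str, float | None] = {}
    for aa, family in code.families.items():
        family_total = sum(counts.counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            values[c] = (
                k * counts.counts.get(c, 0) / family_total if family_total else None
            )
    return RscuTable(rscu=values, aa_usage=amino_acid_usage(counts, code))
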