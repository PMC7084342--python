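"""Base composition and AT/GC strand-asymmetry skews.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed on exact
base counts.  Gene-level skews are taken on the coding-strand (sense)
sequence, so the single L-strand protein gene (ND6) shows the sign flip
that makes it the classic outlier in mitogenome skew profiles.  Whole-genome
values are conventionally computed on the H-strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .feature_table import MitogenomeAnnotation, extract_gene_sequence

_CANONICAL = frozenset("ACGT")


@dataclass(frozen=True)
class CompositionVector:
    """Exact A/T/G/C counts; ambiguity codes are tallied separately."""

    a: int = 0
    t: int = 0
    g: int = 0
    c: int = 0
    ambiguous: int = 0

    @property
    def n(self) -> int:
        return self.a + self.t + self.g + self.c

    def fraction(self, base: str) -> float | None:
        if self.n == 0:
            return None
        return getattr(self, base.lower()) / self.n

    @property
    def at_content(self) -> float | None:
        return (self.a + self.t) / self.n if self.n else None

    @property
    def gc_content(self) -> float | None:
        return (self.g + self.c) / self.n if self.n else None

    def __add__(self, other: "CompositionVector") -> "CompositionVector":
        return CompositionVector(
            self.a + other.a, self.t + other.t, self.g + other.g,
            self.c + other.c, self.ambiguous + other.ambiguous,
        )


def base_composition(sequence: str) -> CompositionVector:
    """Count bases case-insensitively; U counts as T; others as ambiguous."""
    s = sequence.upper().replace("U", "T")
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    return CompositionVector(a, t, g, c, ambiguous=len(s) - a - t - g - c)


def _as_comp(x: str | CompositionVector) -> CompositionVector:
    return x if isinstance(x, CompositionVector) else base_composition(x)


def at_skew(comp: str | CompositionVector) -> float | None:
    """(A − T)/(A + T); None when A + T = 0."""
    v = _as_comp(comp)
    return (v.a - v.t) / (v.a + v.t) if (v.a + v.t) else None


def gc_skew(comp: str | CompositionVector) -> float | None:
    """(G − C)/(G + C); None when G + C = 0."""
    v = _as_comp(comp)
    return (v.g - v.c) / (v.g + v.c) if (v.g + v.c) else None


def pcg_skew_profile(annotation: MitogenomeAnnotation) -> pd.DataFrame:
    """Per-PCG AT/GC skews on the coding strand, ordered by genome position.

    Columns: gene, strand, at_skew, gc_skew.
    """
    if annotation.sequence is None:
        raise ValueError(f"{annotation.label}: skew profile needs a sequence")
    rows = []
    for f in annotation.pcgs():
        seq = extract_gene_sequence(annotation, f.name)
        rows.append(
            {"gene": f.name, "strand": f.strand,
             "at_skew": at_skew(seq), "gc_skew": gc_skew(seq)}
        )
    return pd.DataFrame(rows)


def codon_position_composition(
    cds_list: Iterable[str],
) -> tuple[CompositionVector, CompositionVector, CompositionVector]:
    """Pooled composition at codon positions 1, 2, 3.

    Each sequence is read in frame from its first base; a trailing
    incomplete codon contributes only the positions it has (so genes ending
    in incomplete stop codons T/TA leave the three totals unequal).
    """
    comps = [CompositionVector(), CompositionVector(), CompositionVector()]
    for cds in cds_list:
        for pos in range(3):
            comps[pos] = comps[pos] + base_composition(cds[pos::3])
    return tuple(comps)  # type: ignore[return-value]


def composition_table(annotation: MitogenomeAnnotation) -> pd.DataFrame:
    """Genome-wide composition summary (percentages to 2 decimals).

    Rows: complete genome (H-strand); PCG codon positions 1/2/3 and total
    (coding strand, pooled over the 13 genes); tRNA; rRNA; D-loop.
    """
    if annotation.sequence is None:
        raise ValueError(f"{annotation.label}: composition table needs a sequence")

    def row(region: str, comp: CompositionVector) -> dict:
        n = comp.n
        pct = lambda x: round(100.0 * x / n, 2) if n else None  # noqa: E731
        return {
            "region": region,
            "A": pct(comp.a), "T": pct(comp.t), "G": pct(comp.g), "C": pct(comp.c),
            "A+T": pct(comp.a + comp.t), "n": n,
        }

    rows = [row("complete genome", base_composition(annotation.sequence))]
    pcg_seqs = [extract_gene_sequence(annotation, f.name) for f in annotation.pcgs()]
    p1, p2, p3 = codon_position_composition(pcg_seqs)
    rows += [row("PCG first", p1), row("PCG second", p2), row("PCG third", p3),
             row("PCG total", p1 + p2 + p3)]
    for category, region in (("tRNA", "tRNA"), ("rRNA", "rRNA"),
                             ("control", "D-loop")):
        comp = CompositionVector()
        for i, f in enumerate(annotation.features):
            if f.category == category:
                occ = sum(1 for g in annotation.features[:i] if g.name == f.name)
                comp = comp + base_composition(
                    extract_gene_sequence(annotation, f.name, occurrence=occ)
                )
        rows.append(row(region, comp))
    return pd.DataFrame(rows)
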