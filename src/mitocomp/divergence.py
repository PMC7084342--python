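"""Pairwise coding-sequence divergence: partitioned p-distance and NG86 Ka/Ks.

The Nei–Gojobori (1986) counting method is implemented with equal-weight
pathway averaging and Jukes–Cantor correction:

* synonymous/nonsynonymous *sites* per codon: each of the 9 single-base
  mutants is classified; mutants that create stop codons are excluded with
  per-position renormalization, so every sense codon contributes exactly
  3 sites (s + n = 3);
* *differences* between two codons differing at d positions: the d! orderings
  of the single-base steps are enumerated, pathways passing through a stop
  codon are dropped (weights renormalized), and synonymous/nonsynonymous step
  counts are averaged over the legal pathways;
* proportions pS = Sd/S and pN = Nd/N are corrected with
  d = −(3/4)·ln(1 − 4p/3); ω = Ka/Ks = dN/dS.

p-distances are reported over all codon positions, positions 1+2 pooled,
and position 3, after complete-deletion of codon columns containing gaps or
ambiguity codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Sequence

import pandas as pd

from .feature_table import MitogenomeAnnotation, extract_gene_sequence
from .genetic_code import GeneticCode, STOP_SYMBOL, vertebrate_mitochondrial

_BASES = "ACGT"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedCodingPair:
    """Two aligned in-frame coding sequences (gap character ``-`` allowed).

    Trailing bases that do not complete a codon are trimmed at construction,
    mirroring the convention of dropping incomplete terminal codons.
    """

    seq_a: str
    seq_b: str
    gene: str = ""

    def __post_init__(self) -> None:
        a = self.seq_a.upper().replace("U", "T")
        b = self.seq_b.upper().replace("U", "T")
        if len(a) != len(b):
            raise AlignmentError(
                f"{self.gene or 'pair'}: aligned lengths differ "
                f"({len(a)} vs {len(b)})"
            )
        trim = len(a) - len(a) % 3
        object.__setattr__(self, "seq_a", a[:trim])
        object.__setattr__(self, "seq_b", b[:trim])

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_columns(self) -> list[tuple[str, str]]:
        """Codon-column pairs after complete deletion of gap/ambiguity columns."""
        out = []
        for i in range(self.n_codons):
            ca = self.seq_a[3 * i : 3 * i + 3]
            cb = self.seq_b[3 * i : 3 * i + 3]
            if all(ch in _BASES for ch in ca + cb):
                out.append((ca, cb))
        return out


@dataclass(frozen=True)
class DistanceResult:
    """Codon-position-partitioned p-distances with site bookkeeping."""

    p_all: float | None
    p_12: float | None
    p_3: float | None
    sites_all: int
    sites_12: int
    sites_3: int
    excluded_columns: int = 0


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts and Jukes–Cantor-corrected rates."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    ks: float | None
    ka: float | None
    omega: float | None
    n_codons: int
    excluded_columns: int = 0
    saturated_s: bool = False
    saturated_n: bool = False
    zero_ks: bool = False


def p_distance(pair: AlignedCodingPair) -> DistanceResult:
    """Proportion of differing sites, overall and by codon-position partition."""
    cols = pair.codon_columns()
    sites = [0, 0, 0]
    diffs = [0, 0, 0]
    for ca, cb in cols:
        for pos in range(3):
            sites[pos] += 1
            if ca[pos] != cb[pos]:
                diffs[pos] += 1
    s12, d12 = sites[0] + sites[1], diffs[0] + diffs[1]
    s_all, d_all = sum(sites), sum(diffs)
    frac = lambda d, s: d / s if s else None  # noqa: E731
    return DistanceResult(
        p_all=frac(d_all, s_all), p_12=frac(d12, s12), p_3=frac(diffs[2], sites[2]),
        sites_all=s_all, sites_12=s12, sites_3=sites[2],
        excluded_columns=pair.n_codons - len(cols),
    )


# ---------------------------------------------------------------------------
# NG86 counting


def _sites_uncached(codon: str, table_id: int) -> tuple[float, float]:
    code = GeneticCode.from_ncbi_id(table_id)
    if code.is_stop(codon):
        raise ValueError(f"{codon} is a stop codon; sites undefined")
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            valid += 1
            if code.translate(mutant) == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


_sites_cached = lru_cache(maxsize=None)(_sites_uncached)


def ng86_sites(
    codon: str, code: GeneticCode | None = None
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon; sums to 3."""
    code = code or vertebrate_mitochondrial()
    return _sites_cached(codon.upper().replace("U", "T"), code.table_id)


def _differences_uncached(
    codon_a: str, codon_b: str, table_id: int
) -> tuple[float, float, bool]:
    code = GeneticCode.from_ncbi_id(table_id)
    if code.is_stop(codon_a) or code.is_stop(codon_b):
        raise ValueError("differences undefined for stop codons")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0, False

    legal: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            mutant = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(mutant):
                ok = False
                break
            if code.translate(current) == code.translate(mutant):
                sd += 1
            else:
                nd += 1
            current = mutant
        if ok:
            legal.append((sd, nd))
    if legal:
        sd = sum(x[0] for x in legal) / len(legal)
        nd = sum(x[1] for x in legal) / len(legal)
        return sd, nd, False
    # Every pathway traverses a stop: fall back to direct per-position
    # classification of the end-point codons.
    sd = nd = 0
    for pos in diff_pos:
        mutant = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
        if not code.is_stop(mutant) and code.translate(codon_a) == code.translate(mutant):
            sd += 1
        else:
            nd += 1
    return float(sd), float(nd), True


_differences_cached = lru_cache(maxsize=None)(_differences_uncached)


def ng86_differences(
    codon_a: str, codon_b: str, code: GeneticCode | None = None
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    Averages over the d! substitution orderings for codons differing at d
    positions; orderings passing through stop codons are excluded and the
    average renormalized over the legal ones.  sd + nd = d whenever at least
    one legal pathway exists.
    """
    code = code or vertebrate_mitochondrial()
    sd, nd, _ = _differences_cached(
        codon_a.upper().replace("U", "T"),
        codon_b.upper().replace("U", "T"),
        code.table_id,
    )
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); requires p < 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError("saturated: p >= 3/4 has no Jukes–Cantor distance")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks(pair: AlignedCodingPair, code: GeneticCode | None = None) -> KaKsResult:
    """NG86 Ka/Ks for an aligned coding pair.

    Codon columns with gaps/ambiguity, and columns where either codon is a
    stop (terminal stops included), are excluded by complete deletion.  Site
    totals S and N are the average of the two sequences; differences are
    summed over columns.  ω is undefined (None) when Ks = 0 or either class
    is saturated.
    """
    code = code or vertebrate_mitochondrial()
    cols = pair.codon_columns()
    used = [
        (ca, cb) for ca, cb in cols if not (code.is_stop(ca) or code.is_stop(cb))
    ]
    S = N = Sd = Nd = 0.0
    for ca, cb in used:
        sa, na = ng86_sites(ca, code)
        sb, nb = ng86_sites(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = ng86_differences(ca, cb, code)
        Sd += sd
        Nd += nd

    pS = Sd / S if S else None
    pN = Nd / N if N else None
    saturated_s = pS is not None and pS >= 0.75
    saturated_n = pN is not None and pN >= 0.75
    ks = jukes_cantor(pS) if pS is not None and not saturated_s else None
    ka = jukes_cantor(pN) if pN is not None and not saturated_n else None
    zero_ks = ks == 0.0
    omega = ka / ks if (ka is not None and ks not in (None, 0.0)) else None
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, ks=ks, ka=ka, omega=omega,
        n_codons=len(used), excluded_columns=pair.n_codons - len(used),
        saturated_s=saturated_s, saturated_n=saturated_n, zero_ks=zero_ks,
    )


# ---------------------------------------------------------------------------
# multi-genome drivers


def pairwise_gene_matrix(
    genomes: Sequence[MitogenomeAnnotation],
    gene: str,
    code: GeneticCode | None = None,
    aligned: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Divergence statistics for one gene over all unordered genome pairs.

    Sequences are taken from ``aligned`` (label -> aligned coding sequence)
    when given, else extracted from each genome; ungapped pairing requires
    equal lengths and otherwise raises, instructing pre-alignment.

    Returns a long-format DataFrame with one row per pair: pair labels,
    p-distances, and the full NG86 quantity set.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    code = code or vertebrate_mitochondrial()
    seqs: dict[str, str] = {}
    for g in genomes:
        if aligned and g.label in aligned:
            seqs[g.label] = aligned[g.label]
        else:
            seqs[g.label] = extract_gene_sequence(g, gene)
    rows = []
    for ga, gb in combinations(genomes, 2):
        a, b = seqs[ga.label], seqs[gb.label]
        if len(a) != len(b):
            raise AlignmentError(
                f"{gene}: sequences for {ga.label} and {gb.label} differ in "
                f"length ({len(a)} vs {len(b)}); supply a pre-aligned FASTA"
            )
        pair = AlignedCodingPair(a, b, gene=gene)
        dist = p_distance(pair)
        kk = kaks(pair, code)
        rows.append(
            {
                "gene": gene, "pair": f"{ga.label}|{gb.label}",
                "p_all": dist.p_all, "p_12": dist.p_12, "p_3": dist.p_3,
                "S": kk.S, "N": kk.N, "Sd": kk.Sd, "Nd": kk.Nd,
                "ka": kk.ka, "ks": kk.ks, "omega": kk.omega,
                "saturated": kk.saturated_s or kk.saturated_n,
                "zero_ks": kk.zero_ks,
            }
        )
    return pd.DataFrame(rows)


def write_phylip_matrix(
    labels: Sequence[str], matrix: Sequence[Sequence[float]], path
) -> None:
    """Write a square distance matrix in relaxed PHYLIP format."""
    n = len(labels)
    width = max(10, max(len(l) for l in labels) + 2)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for label, row in zip(labels, matrix):
            cells = "  ".join(f"{x:.6f}" for x in row)
            fh.write(f"{label:<{width}}{cells}\n")
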