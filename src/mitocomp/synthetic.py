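"""Synthetic mitogenomes and divergent coding pairs with known ground truth.

The generator tiles a circular molecule with an ordered, stranded feature
template (by default the canonical 38-feature vertebrate mitogenome layout,
with sizes, spacings and terminal codons taken from the packaged
*G. filamentosus* table), plants protein-coding sequences drawn under a
configurable synonymous-codon bias in the vertebrate mitochondrial code,
and can evolve a coding sequence by an exact, ledgered plan of synonymous
and nonsynonymous single-base substitutions.  Every downstream statistic
therefore has an exact expectation: spacer/overlap censuses equal the
configured spacing list, and NG86 difference counts equal the planted
substitution classes in the low-divergence (one hit per codon) regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .feature_table import (
    AnnotationError,
    GeneFeature,
    MitogenomeAnnotation,
    adjacency_profile,
    extract_gene_sequence,
    genome_length,
    reverse_complement,
)
from .genetic_code import GeneticCode, vertebrate_mitochondrial

_ENDING_BASES = {"TAA": 3, "TAG": 3, "AGA": 3, "AGG": 3, "TA": 2, "T": 1, "none": 0}


@dataclass(frozen=True)
class FeatureSpec:
    """One template slot: a feature's identity, size, and gap to the next."""

    name: str
    category: str
    strand: str
    size: int
    spacing_after: int  # signed bp to the next feature (last slot: origin gap)
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None


@dataclass(frozen=True)
class SubstitutionRecord:
    """One planted single-base change (positions are 0-based in the cds)."""

    codon_index: int
    position: int
    from_base: str
    to_base: str
    substitution_class: str  # "S" or "N"


@dataclass(frozen=True)
class SubstitutionPlan:
    n_synonymous: int
    n_nonsynonymous: int


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic genome.

    ``base_probs`` (A,C,G,T order) governs non-coding fill, tRNA and rRNA
    sequence; ``codon_bias`` is a distribution over sense codons for
    protein genes (None = uniform).  ``length`` may declare the expected
    molecule length; a mismatch with the tiling identity is an error.
    """

    seed: int = 0
    label: str = "synthetic"
    template: Sequence[FeatureSpec] | None = None
    base_probs: tuple[float, float, float, float] = (0.30, 0.25, 0.18, 0.27)
    codon_bias: Mapping[str, float] | None = None
    length: int | None = None
    with_sequence: bool = True
    code_id: int = 2


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for exact downstream checks."""

    config: GeneratorConfig
    annotation: MitogenomeAnnotation
    intended_cds: dict[str, str] = field(default_factory=dict)
    gene_sequences: dict[str, str] = field(default_factory=dict)
    ledgers: dict[str, list[SubstitutionRecord]] = field(default_factory=dict)


def default_template() -> list[FeatureSpec]:
    """The 38-feature vertebrate layout with the packaged GF sizes/spacings."""
    from .fixtures import load_fixture

    return template_from_annotation(load_fixture("GF"))


def template_from_annotation(ann: MitogenomeAnnotation) -> list[FeatureSpec]:
    """Turn any annotation into a generator template (sizes + spacings)."""
    spacings = [r.spacing for r in adjacency_profile(ann)]
    if len(spacings) == len(ann.features) - 1:  # linear: no wrap record
        spacings.append(0)
    return [
        FeatureSpec(
            name=f.name, category=f.category, strand=f.strand, size=f.size,
            spacing_after=spacings[i], anticodon=f.anticodon,
            start_codon=f.start_codon, stop_codon=f.stop_codon,
        )
        for i, f in enumerate(ann.features)
    ]


def _codon_sampler(
    bias: Mapping[str, float] | None, code: GeneticCode
) -> tuple[list[str], np.ndarray]:
    sense = list(code.sense_codons)
    if bias is None:
        probs = np.full(len(sense), 1.0 / len(sense))
        return sense, probs
    for codon in bias:
        if code.is_stop(codon):
            raise ValueError(f"codon bias assigns mass to stop codon {codon}")
    codons = list(bias)
    probs = np.asarray([bias[c] for c in codons], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("codon bias must be a non-negative distribution")
    return codons, probs / probs.sum()


def generate_cds(
    n_codons: int,
    codon_bias: Mapping[str, float] | None = None,
    code: GeneticCode | None = None,
    seed: int | np.random.Generator = 0,
    start_codon: str = "ATG",
    ending: str = "TAA",
) -> str:
    """An in-frame coding sequence of ``n_codons`` sense codons plus ending.

    The first codon is ``start_codon``; the remaining ``n_codons − 1`` are
    i.i.d. draws from ``codon_bias`` (uniform over sense codons by default);
    ``ending`` may be a complete stop, the incomplete ``"TA"``/``"T"``, or
    ``"none"``.
    """
    if n_codons < 1:
        raise ValueError("need at least the start codon")
    if ending not in _ENDING_BASES:
        raise ValueError(f"ending must be one of {sorted(_ENDING_BASES)}")
    code = code or vertebrate_mitochondrial()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons, probs = _codon_sampler(codon_bias, code)
    draws = rng.choice(len(codons), size=n_codons - 1, p=probs)
    body = "".join(codons[i] for i in draws)
    return start_codon + body + ("" if ending == "none" else ending)


def _mutation_options(
    codon: str, code: GeneticCode
) -> dict[str, list[tuple[int, str]]]:
    """Single-base non-stop mutants of a codon, keyed by class S/N."""
    out: dict[str, list[tuple[int, str]]] = {"S": [], "N": []}
    aa = code.translate(codon)
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            cls = "S" if code.translate(mutant) == aa else "N"
            out[cls].append((pos, base))
    return out


def evolve_cds(
    cds: str,
    plan: SubstitutionPlan,
    code: GeneticCode | None = None,
    seed: int | np.random.Generator = 0,
    low_divergence: bool = True,
    protect_start: bool = True,
) -> tuple[str, list[SubstitutionRecord]]:
    """Apply exactly the planned substitution counts to a coding sequence.

    Eligible targets are complete sense codons (the start codon is protected
    by default; stop codons and any trailing incomplete codon are never
    touched).  In low-divergence mode each codon receives at most one change,
    so NG86 counting recovers the plan exactly.  Substitutions never create
    stop codons.  Returns the descendant and a replayable ledger.
    """
    code = code or vertebrate_mitochondrial()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = cds.upper().replace("U", "T")
    codons = [s[3 * i : 3 * i + 3] for i in range(len(s) // 3)]
    first = 1 if protect_start else 0
    eligible = [
        i for i in range(first, len(codons)) if not code.is_stop(codons[i])
    ]
    if not low_divergence:
        return _evolve_multihit(s, codons, eligible, plan, code, rng)

    options = {i: _mutation_options(codons[i], code) for i in eligible}
    order = list(rng.permutation(eligible))
    chosen: list[tuple[int, str]] = []
    need = {"S": plan.n_synonymous, "N": plan.n_nonsynonymous}
    for i in order:
        if need["S"] and options[i]["S"]:
            chosen.append((i, "S"))
            need["S"] -= 1
        elif need["N"] and options[i]["N"]:
            chosen.append((i, "N"))
            need["N"] -= 1
        if not need["S"] and not need["N"]:
            break
    if need["S"] or need["N"]:
        raise ValueError(
            f"infeasible plan: {need['S']} synonymous and {need['N']} "
            f"nonsynonymous changes could not be placed on {len(eligible)} "
            "eligible codons"
        )
    ledger: list[SubstitutionRecord] = []
    out = list(codons)
    for i, cls in sorted(chosen):
        pos, base = options[i][cls][rng.integers(len(options[i][cls]))]
        ledger.append(
            SubstitutionRecord(
                codon_index=i, position=3 * i + pos,
                from_base=out[i][pos], to_base=base, substitution_class=cls,
            )
        )
        out[i] = out[i][:pos] + base + out[i][pos + 1 :]
    tail = s[3 * len(codons) :]
    return "".join(out) + tail, ledger


def _evolve_multihit(s, codons, eligible, plan, code, rng):
    out = list(codons)
    ledger: list[SubstitutionRecord] = []
    for cls, count in (("S", plan.n_synonymous), ("N", plan.n_nonsynonymous)):
        for _ in range(count):
            candidates = [i for i in eligible if _mutation_options(out[i], code)[cls]]
            if not candidates:
                raise ValueError(f"infeasible plan: no codon admits a {cls} change")
            i = candidates[rng.integers(len(candidates))]
            opts = _mutation_options(out[i], code)[cls]
            pos, base = opts[rng.integers(len(opts))]
            ledger.append(
                SubstitutionRecord(i, 3 * i + pos, out[i][pos], base, cls)
            )
            out[i] = out[i][:pos] + base + out[i][pos + 1 :]
    return "".join(out) + s[3 * len(codons) :], ledger


def generate_annotation(
    config: GeneratorConfig,
) -> tuple[MitogenomeAnnotation, SyntheticTruth]:
    """Tile a circular genome from the template and plant its sequences.

    Feature coordinates follow the spacing list exactly, so the spacer and
    overlap censuses of the output equal the configured totals.  When two
    features overlap, the later (downstream) feature's planted sequence wins
    in the shared bases; ``truth.gene_sequences`` always holds the sequence
    actually present in the final molecule, while ``truth.intended_cds``
    holds each protein gene's pre-assembly draw.
    """
    template = list(config.template) if config.template else default_template()
    if not template:
        raise AnnotationError("empty template")
    code = GeneticCode.from_ncbi_id(config.code_id)
    rng = np.random.default_rng(config.seed)

    features: list[GeneFeature] = []
    start = 1
    for spec in template:
        end = start + spec.size - 1
        if start < 1:
            raise AnnotationError(
                f"unrealizable tiling: {spec.name} would start at {start} < 1 "
                "(overlap exceeds the upstream feature)"
            )
        features.append(
            GeneFeature(
                name=spec.name, category=spec.category, strand=spec.strand,
                start=start, end=end, anticodon=spec.anticodon,
                start_codon=spec.start_codon, stop_codon=spec.stop_codon,
            )
        )
        start = end + 1 + spec.spacing_after
    length = features[-1].end + template[-1].spacing_after
    if config.length is not None and config.length != length:
        sizes = sum(sp.size for sp in template)
        gaps = sum(sp.spacing_after for sp in template if sp.spacing_after > 0)
        overlaps = -sum(sp.spacing_after for sp in template if sp.spacing_after < 0)
        raise AnnotationError(
            f"unrealizable tiling: sizes {sizes} + gaps {gaps} - overlaps "
            f"{overlaps} = {length} != declared length {config.length}"
        )

    sequence = None
    truth = SyntheticTruth(config=config, annotation=None)  # type: ignore[arg-type]
    if config.with_sequence:
        bases = np.array(list("ACGT"))
        probs = np.asarray(config.base_probs, dtype=float)
        probs = probs / probs.sum()
        genome = rng.choice(bases, size=length, p=probs)
        for feat, spec in zip(features, template):
            if spec.category == "PCG":
                ending = spec.stop_codon or "TAA"
                n_cod = (spec.size - _ENDING_BASES[ending]) // 3
                if 3 * n_cod + _ENDING_BASES[ending] != spec.size:
                    raise AnnotationError(
                        f"{spec.name}: size {spec.size} incompatible with "
                        f"stop class {ending}"
                    )
                cds = generate_cds(
                    n_cod, config.codon_bias, code, rng,
                    start_codon=spec.start_codon or "ATG", ending=ending,
                )
                truth.intended_cds[spec.name] = cds
                h_strand = reverse_complement(cds) if spec.strand == "L" else cds
                genome[feat.start - 1 : feat.end] = list(h_strand)
        sequence = "".join(genome)

    annotation = MitogenomeAnnotation(
        label=config.label, length=length, features=features,
        circular=True, sequence=sequence,
    )
    truth.annotation = annotation
    if sequence is not None:
        for i, f in enumerate(annotation.features):
            occ = sum(1 for g in annotation.features[:i] if g.name == f.name)
            key = f.name if occ == 0 else f"{f.name}#{occ + 1}"
            truth.gene_sequences[key] = extract_gene_sequence(
                annotation, f.name, occurrence=occ
            )
    return annotation, truth


def evolve_genome(
    truth: SyntheticTruth,
    plans: Mapping[str, SubstitutionPlan],
    seed: int = 0,
    label: str | None = None,
) -> tuple[MitogenomeAnnotation, SyntheticTruth]:
    """Derive a descendant genome by per-gene substitution plans.

    Each named protein gene's current sequence (as present in the molecule)
    is evolved by its plan and written back at the same coordinates, so the
    descendant stays colinear and ungapped-alignable with the ancestor.
    For genes that share bases with a downstream overlapping feature the
    written-back overlap bases are then overwritten again by the neighbour's
    unchanged copy; exact ledger-recovery checks should use non-overlapping
    genes (or an overlap-free template).
    """
    ann = truth.annotation
    if ann.sequence is None:
        raise AnnotationError(f"{ann.label}: cannot evolve a sequence-less genome")
    code = GeneticCode.from_ncbi_id(truth.config.code_id)
    rng = np.random.default_rng(seed)
    genome = list(ann.sequence)
    ledgers: dict[str, list[SubstitutionRecord]] = {}
    for gene, plan in plans.items():
        feat = ann.feature(gene)
        current = extract_gene_sequence(ann, gene)
        descendant, ledger = evolve_cds(current, plan, code, rng)
        ledgers[gene] = ledger
        h_strand = reverse_complement(descendant) if feat.strand == "L" else descendant
        genome[feat.start - 1 : feat.end] = list(h_strand)
    new_label = label or f"{ann.label}_desc"
    new_ann = MitogenomeAnnotation(
        label=new_label, length=ann.length,
        features=list(ann.features), circular=ann.circular,
        sequence="".join(genome),
    )
    new_truth = SyntheticTruth(
        config=replace(truth.config, label=new_label),
        annotation=new_ann,
        intended_cds=dict(truth.intended_cds),
        ledgers=ledgers,
    )
    for i, f in enumerate(new_ann.features):
        occ = sum(1 for g in new_ann.features[:i] if g.name == f.name)
        key = f.name if occ == 0 else f"{f.name}#{occ + 1}"
        new_truth.gene_sequences[key] = extract_gene_sequence(
            new_ann, f.name, occurrence=occ
        )
    return new_ann, new_truth


# ---------------------------------------------------------------------------
# writers (round-trip partners of the feature_table loaders)

_CATEGORY_GENBANK_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                          "control": "D-loop"}


def write_genbank(annotation: MitogenomeAnnotation, path: str | Path) -> None:
    """Write an annotated GenBank flat file readable by ``load_genbank``.

    L-strand features become complement locations.  Observed terminal-codon
    columns are not serialized (GenBank has no standard qualifier for them).
    """
    if not annotation.sequence:
        raise AnnotationError(f"{annotation.label}: refusing to write GenBank "
                              "without a sequence")
    if len(annotation.sequence) != genome_length(annotation):
        raise AnnotationError(f"{annotation.label}: sequence/length mismatch")
    record = SeqRecord(
        Seq(annotation.sequence),
        id=annotation.label,
        name=annotation.label[:16],
        description=f"{annotation.label} mitochondrial genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if annotation.circular else "linear"
    for f in annotation.features:
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon_seq"] = [f.anticodon]
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "L" else 1),
                type=_CATEGORY_GENBANK_TYPE[f.category],
                qualifiers=quals,
            )
        )
    SeqIO.write(record, str(path), "genbank")


def write_fasta(annotation: MitogenomeAnnotation, path: str | Path) -> None:
    """Write the H-strand genome sequence as single-record FASTA."""
    if not annotation.sequence:
        raise AnnotationError(f"{annotation.label}: refusing to write FASTA "
                              "without a sequence")
    record = SeqRecord(
        Seq(annotation.sequence), id=annotation.label, description=""
    )
    SeqIO.write(record, str(path), "fasta")
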