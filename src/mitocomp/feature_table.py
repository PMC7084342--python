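"""Ordered, stranded feature maps of circular mitochondrial genomes.

The central container is :class:`MitogenomeAnnotation`: a 1-based, inclusive
(GenBank-convention) list of :class:`GeneFeature` records over a circular
molecule, optionally carrying the H-strand sequence.  All coordinate-derived
statistics live here: gene sizes, intergenic spacers (IGS), gene overlaps,
the light-strand replication origin (O_L) spacer between tRNA-Asn and
tRNA-Cys, strand census, and protein-coding-gene length totals.

Spacing convention: for consecutive features ``u`` then ``d``,
``spacing = d.start − u.end − 1``; positive values are intergenic gaps,
negative values are overlaps, zero means abutting.  On a circular molecule
the wrap-around pair (last feature, first feature) contributes
``(length − last.end) + (first.start − 1)``.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

CATEGORIES = ("PCG", "tRNA", "rRNA", "control")

#: Gene labels whose duplication within one genome is biologically expected
#: (the two Leu and two Ser tRNA isoacceptors).
DUPLICATE_OK = {"tRNA-Leu", "tRNA-Ser"}

#: Dialect map for gene names as found in GenBank records from various
#: annotation pipelines; values are the canonical labels used in fixtures.
NAME_ALIASES = {
    "COX1": "COXI", "CO1": "COXI", "COI": "COXI",
    "COX2": "COXII", "CO2": "COXII", "COII": "COXII",
    "COX3": "COXIII", "CO3": "COXIII", "COIII": "COXIII",
    "CYTB": "CYTB", "COB": "CYTB", "CYB": "CYTB", "MT-CYB": "CYTB",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8", "ATP 6": "ATP6", "ATP 8": "ATP8",
    "12S RIBOSOMAL RNA": "12S-rRNA", "12S RRNA": "12S-rRNA", "RRNS": "12S-rRNA",
    "S-RRNA": "12S-rRNA", "SMALL SUBUNIT RIBOSOMAL RNA": "12S-rRNA",
    "16S RIBOSOMAL RNA": "16S-rRNA", "16S RRNA": "16S-rRNA", "RRNL": "16S-rRNA",
    "L-RRNA": "16S-rRNA", "LARGE SUBUNIT RIBOSOMAL RNA": "16S-rRNA",
    "D-LOOP": "D-loop", "CONTROL REGION": "D-loop",
}

PCG_NAMES = {
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COXI", "COXII", "COXIII", "ATP6", "ATP8", "CYTB",
}

STOP_CLASSES = ("TAA", "TAG", "AGA", "AGG", "TA", "T")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent feature maps."""


def normalize_gene_name(raw: str) -> str:
    """Map a gene label from any common dialect to the canonical form."""
    name = raw.strip()
    key = name.upper()
    if key in NAME_ALIASES:
        return NAME_ALIASES[key]
    if key.startswith("TRNA-") or key.startswith("TRN-"):
        rest = name.split("-", 1)[1]
        return "tRNA-" + rest[:1].upper() + rest[1:].lower()
    return name


def infer_category(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name.startswith("tRNA-"):
        return "tRNA"
    if name.endswith("rRNA"):
        return "rRNA"
    if name == "D-loop":
        return "control"
    raise AnnotationError(f"cannot infer category for feature {name!r}")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated element of a mitogenome (1-based, inclusive ends)."""

    name: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(f"{self.name}: unknown category {self.category!r}")
        if self.strand not in ("H", "L"):
            raise AnnotationError(f"{self.name}: strand must be 'H' or 'L'")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.name}: coordinates must be >= 1")
        if self.anticodon is not None and self.category != "tRNA":
            raise AnnotationError(f"{self.name}: anticodon on non-tRNA feature")
        if self.stop_codon is not None and self.stop_codon not in STOP_CLASSES:
            raise AnnotationError(
                f"{self.name}: stop codon {self.stop_codon!r} not one of {STOP_CLASSES}"
            )
        if self.category == "tRNA" and not self.wraps_origin \
                and not 60 <= self.size <= 95:
            warnings.warn(
                f"{self.name}: tRNA size {self.size} bp outside the usual 60–95 bp",
                stacklevel=2,
            )

    @property
    def wraps_origin(self) -> bool:
        """End before start marks a feature spanning the circular origin."""
        return self.end < self.start

    @property
    def size(self) -> int:
        if self.wraps_origin:
            raise AnnotationError(
                f"{self.name}: size of an origin-spanning feature needs the "
                "genome length"
            )
        return self.end - self.start + 1


@dataclass(frozen=True)
class AdjacencyRecord:
    """Signed spacing between two consecutive features (gap>0, overlap<0)."""

    upstream: str
    downstream: str
    spacing: int


@dataclass(frozen=True)
class OriginLight:
    """O_L spacer length between tRNA-Asn and tRNA-Cys."""

    spacing: int
    is_spacer: bool  # False when the adjacency is abutting or overlapping


@dataclass(frozen=True)
class StrandCensus:
    counts: dict[tuple[str, str], int]  # (strand, category) -> n

    def per_strand(self, strand: str) -> int:
        return sum(n for (s, _), n in self.counts.items() if s == strand)

    def per_category(self, category: str) -> int:
        return sum(n for (_, c), n in self.counts.items() if c == category)


@dataclass
class MitogenomeAnnotation:
    """A circular mitogenome's ordered feature map, with optional sequence."""

    label: str
    length: int | None
    features: list[GeneFeature]
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.length is not None and self.features:
            worst = max(self.features, key=lambda f: f.end)
            if worst.end > self.length:
                raise AnnotationError(
                    f"{self.label}: feature {worst.name} ends at {worst.end} "
                    f"beyond declared length {self.length}"
                )
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.length is not None and len(self.sequence) != self.length:
                raise AnnotationError(
                    f"{self.label}: sequence length {len(self.sequence)} != "
                    f"declared length {self.length}"
                )

    def feature(self, name: str, occurrence: int = 0) -> GeneFeature:
        """Fetch a feature by canonical name.

        ``occurrence`` disambiguates the duplicated Leu/Ser tRNAs (0 = first
        in genome order).
        """
        hits = [f for f in self.features if f.name == name]
        if not hits:
            raise KeyError(f"{self.label}: no feature named {name!r}")
        return hits[occurrence]

    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.category == "PCG"]


# ---------------------------------------------------------------------------
# loaders / writers


def load_feature_tsv(path: str | Path) -> MitogenomeAnnotation:
    """Read a feature-table TSV.

    First line is ``#label=<id> length=<bp> circular=<0|1>``; then a header
    row and one row per feature with columns name, category, strand, start,
    end, anticodon, start_codon, stop_codon (trailing optionals may be
    empty or absent).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise AnnotationError(f"{path}: missing '#label=... length=...' header")
    meta = dict(
        item.split("=", 1) for item in lines[0].lstrip("#").split() if "=" in item
    )
    label = meta.get("label", path.stem)
    length = int(meta["length"]) if "length" in meta else None
    circular = meta.get("circular", "1") == "1"

    rows = [ln for ln in lines[1:] if ln.strip() and not ln.startswith("#")]
    if rows and rows[0].lower().startswith("name\t"):
        rows = rows[1:]
    if not rows:
        raise AnnotationError(f"{path}: no features")

    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for row in rows:
        cells = row.rstrip("\n").split("\t")
        cells += [""] * (8 - len(cells))
        name, category, strand, start, end, anticodon, start_c, stop_c = cells[:8]
        name = normalize_gene_name(name)
        if int(start) > int(end):
            raise AnnotationError(f"{path}: {name} start {start} > end {end}")
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1 and name not in DUPLICATE_OK:
            raise AnnotationError(f"{path}: duplicate feature name {name!r}")
        features.append(
            GeneFeature(
                name=name,
                category=category or infer_category(name),
                strand=strand,
                start=int(start),
                end=int(end),
                anticodon=anticodon or None,
                start_codon=start_c or None,
                stop_codon=stop_c or None,
            )
        )
    return MitogenomeAnnotation(
        label=label, length=length, features=features, circular=circular
    )


def write_feature_tsv(annotation: MitogenomeAnnotation, path: str | Path) -> None:
    """Inverse of :func:`load_feature_tsv` (round-trip identical)."""
    buf = io.StringIO()
    length = genome_length(annotation)
    buf.write(
        f"#label={annotation.label} length={length} "
        f"circular={1 if annotation.circular else 0}\n"
    )
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(
        ["name", "category", "strand", "start", "end",
         "anticodon", "start_codon", "stop_codon"]
    )
    for f in annotation.features:
        writer.writerow(
            [f.name, f.category, f.strand, f.start, f.end,
             f.anticodon or "", f.start_codon or "", f.stop_codon or ""]
        )
    Path(path).write_text(buf.getvalue())


_GENBANK_TYPE_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                          "D-loop": "control", "D_loop": "control"}


def load_genbank(path: str | Path) -> MitogenomeAnnotation:
    """Parse an annotated GenBank flat file into a feature map.

    CDS/tRNA/rRNA/D-loop features are kept ('gene' features are redundant
    with their CDS and skipped); complement locations become L-strand
    features; names are normalized through the dialect table.  A record
    without an ORIGIN block yields an annotation without sequence plus a
    warning.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # malformed record
        raise AnnotationError(f"{path}: cannot parse GenBank record: {exc}") from exc

    sequence: str | None
    try:
        sequence = str(record.seq).upper()
        if not sequence:
            sequence = None
    except UndefinedSequenceError:
        sequence = None
    if sequence is None:
        warnings.warn(f"{path}: no ORIGIN sequence; annotation is coordinates-only")

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _GENBANK_TYPE_CATEGORY:
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        if not raw and feat.type in ("D-loop", "D_loop"):
            raw = "D-loop"
        if not raw:
            raise AnnotationError(f"{path}: {feat.type} feature without a name "
                                  f"at {feat.location}")
        name = normalize_gene_name(raw)
        try:
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
            strand = "L" if feat.location.strand == -1 else "H"
        except (TypeError, AttributeError) as exc:
            raise AnnotationError(f"{path}: feature {name!r} has a malformed "
                                  f"location {feat.location}") from exc
        anticodon = None
        if feat.type == "tRNA" and "anticodon_seq" in quals:
            anticodon = quals["anticodon_seq"][0].upper()
        features.append(
            GeneFeature(
                name=name,
                category=_GENBANK_TYPE_CATEGORY[feat.type],
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
            )
        )
    length = len(sequence) if sequence else (len(record) or None)
    circular = record.annotations.get("topology", "circular") == "circular"
    return MitogenomeAnnotation(
        label=record.id or record.name or path.stem,
        length=length,
        features=features,
        circular=circular,
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# coordinate statistics


def genome_length(annotation: MitogenomeAnnotation) -> int:
    """Declared molecule length, falling back to the maximum feature end."""
    if annotation.length is not None:
        return annotation.length
    if not annotation.features:
        raise AnnotationError(f"{annotation.label}: empty annotation has no length")
    return max(f.end for f in annotation.features)


def adjacency_profile(annotation: MitogenomeAnnotation) -> list[AdjacencyRecord]:
    """Signed spacings between consecutive features, in genome order.

    A feature fully nested inside its predecessor is excluded (with a
    warning): consecutive-pair spacing is meaningless for containment.
    Includes the origin-spanning (last, first) pair when circular.
    """
    feats = annotation.features
    if len(feats) < 2:
        return []
    chain = [feats[0]]
    for f in feats[1:]:
        prev = chain[-1]
        if f.start >= prev.start and f.end <= prev.end:
            warnings.warn(
                f"{annotation.label}: {f.name} ({f.start}..{f.end}) is nested "
                f"inside {prev.name}; excluded from spacer/overlap tallies"
            )
            continue
        chain.append(f)
    records = [
        AdjacencyRecord(u.name, d.name, d.start - u.end - 1)
        for u, d in zip(chain, chain[1:])
    ]
    if annotation.circular and len(chain) > 1:
        last, first = chain[-1], chain[0]
        wrap = (genome_length(annotation) - last.end) + (first.start - 1)
        records.append(AdjacencyRecord(last.name, first.name, wrap))
    return records


def igs_summary(annotation: MitogenomeAnnotation) -> tuple[int, int]:
    """(number of intergenic spacers, total spacer bp): positive spacings only."""
    pos = [r.spacing for r in adjacency_profile(annotation) if r.spacing > 0]
    return len(pos), sum(pos)


def overlap_summary(annotation: MitogenomeAnnotation) -> tuple[int, int]:
    """(number of overlap sites, total overlapped bp as a positive count)."""
    neg = [-r.spacing for r in adjacency_profile(annotation) if r.spacing < 0]
    return len(neg), sum(neg)


def locate_OL(annotation: MitogenomeAnnotation) -> OriginLight:
    """Spacer between tRNA-Asn and tRNA-Cys, the canonical O_L location."""
    names = {f.name for f in annotation.features}
    for needed in ("tRNA-Asn", "tRNA-Cys"):
        if needed not in names:
            raise AnnotationError(f"{annotation.label}: {needed} absent; cannot "
                                  "locate the light-strand replication origin")
    for rec in adjacency_profile(annotation):
        if {rec.upstream, rec.downstream} == {"tRNA-Asn", "tRNA-Cys"}:
            return OriginLight(spacing=rec.spacing, is_spacer=rec.spacing > 0)
    raise AnnotationError(
        f"{annotation.label}: tRNA-Asn and tRNA-Cys are not adjacent"
    )


def strand_census(annotation: MitogenomeAnnotation) -> StrandCensus:
    counts: dict[tuple[str, str], int] = {}
    for f in annotation.features:
        key = (f.strand, f.category)
        counts[key] = counts.get(key, 0) + 1
    return StrandCensus(counts)


def pcg_length_stats(annotation: MitogenomeAnnotation) -> tuple[int, float]:
    """(summed PCG bp, percent of genome length rounded to 2 decimals)."""
    pcgs = annotation.pcgs()
    if not pcgs:
        raise AnnotationError(f"{annotation.label}: no protein-coding genes")
    total = sum(f.size for f in pcgs)
    percent = round(100.0 * total / genome_length(annotation), 2)
    return total, percent


_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gene_sequence(
    annotation: MitogenomeAnnotation,
    gene: str,
    occurrence: int = 0,
) -> str:
    """Coding-strand (sense) sequence of one gene.

    L-strand genes are reverse-complemented; a feature whose end precedes
    its start wraps across the origin of the circular molecule.
    """
    if annotation.sequence is None:
        raise AnnotationError(f"{annotation.label}: no sequence attached")
    f = annotation.feature(gene, occurrence)
    seq = annotation.sequence
    if f.end >= f.start:
        sub = seq[f.start - 1 : f.end]
    else:
        if not annotation.circular:
            raise AnnotationError(f"{annotation.label}: {gene} wraps the origin "
                                  "of a linear molecule")
        sub = seq[f.start - 1 :] + seq[: f.end]
    return reverse_complement(sub) if f.strand == "L" else sub


def feature_summary_table(annotation: MitogenomeAnnotation):
    """Gene-table style summary as a pandas DataFrame.

    Columns: name, category, strand, start, end, size, gc_percent (when a
    sequence is attached), start_codon, stop_codon, spacing (signed bp to the
    next feature), anticodon.
    """
    import pandas as pd

    spacing = {
        (r.upstream, r.downstream): r.spacing for r in adjacency_profile(annotation)
    }
    ordered = annotation.features
    rows = []
    for i, f in enumerate(ordered):
        nxt = ordered[(i + 1) % len(ordered)]
        gc = None
        if annotation.sequence is not None:
            sub = extract_gene_sequence(annotation, f.name,
                                        occurrence=_occurrence_index(ordered, i))
            gc_n = sum(sub.count(b) for b in "GC")
            gc = round(100.0 * gc_n / len(sub), 2) if sub else None
        rows.append(
            {
                "name": f.name, "category": f.category, "strand": f.strand,
                "start": f.start, "end": f.end, "size": f.size,
                "gc_percent": gc,
                "start_codon": f.start_codon, "stop_codon": f.stop_codon,
                "spacing": spacing.get((f.name, nxt.name)),
                "anticodon": f.anticodon,
            }
        )
    return pd.DataFrame(rows)


def _occurrence_index(features: Sequence[GeneFeature], i: int) -> int:
    name = features[i].name
    return sum(1 for f in features[:i] if f.name == name)
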