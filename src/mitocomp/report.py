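"""One-call report bundles over one or more annotated mitogenomes.

``run_summary`` degrades gracefully with input capability: coordinate-only
feature tables yield the structural tables; genomes with sequence add
composition, skew and codon-usage tables; two or more sequenced genomes add
pairwise divergence tables and PHYLIP distance matrices.  All data files are
deterministic for fixed inputs (fixed rounding, no timestamps), and a JSON
manifest records every artifact together with input checksums.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import composition as comp_mod
from . import divergence as div_mod
from .codon_usage import count_codons, rscu
from .feature_table import (
    MitogenomeAnnotation,
    adjacency_profile,
    extract_gene_sequence,
    feature_summary_table,
    genome_length,
    igs_summary,
    load_feature_tsv,
    load_genbank,
    locate_OL,
    overlap_summary,
    pcg_length_stats,
    strand_census,
)
from .genetic_code import GeneticCode


@dataclass
class RunConfig:
    inputs: Sequence[str | Path]
    out_dir: str | Path = "mitocomp_out"
    code_id: int = 2
    precision: int = 2
    drop_terminal_stop: bool = True
    aligned_dir: str | Path | None = None  # per-gene pre-aligned FASTAs


def load_any(path: str | Path) -> MitogenomeAnnotation:
    """Dispatch on extension: .tsv feature tables, .gb/.gbk/.genbank records."""
    p = Path(path)
    if p.suffix.lower() in (".tsv", ".txt"):
        return load_feature_tsv(p)
    if p.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return load_genbank(p)
    raise ValueError(f"{p}: unrecognized input format (.tsv or GenBank expected)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _structure_summary(ann: MitogenomeAnnotation) -> dict:
    igs_n, igs_bp = igs_summary(ann)
    ov_n, ov_bp = overlap_summary(ann)
    census = strand_census(ann)
    out = {
        "label": ann.label,
        "genome_length_bp": genome_length(ann),
        "igs": {"count": igs_n, "total_bp": igs_bp},
        "overlap": {"count": ov_n, "total_bp": ov_bp},
        "strand_census": {f"{s}:{c}": n for (s, c), n in sorted(census.counts.items())},
        "adjacencies": [
            {"upstream": r.upstream, "downstream": r.downstream, "spacing": r.spacing}
            for r in adjacency_profile(ann)
        ],
    }
    try:
        ol = locate_OL(ann)
        out["origin_light"] = {"spacing": ol.spacing, "is_spacer": ol.is_spacer}
    except Exception:
        out["origin_light"] = None
    try:
        total, percent = pcg_length_stats(ann)
        out["pcg"] = {"total_bp": total, "percent_of_genome": percent}
    except Exception:
        out["pcg"] = None
    return out


def run_summary(config: RunConfig) -> dict:
    """Run every applicable stage and write the artifact bundle.

    Returns the manifest (also written as ``manifest.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    code = GeneticCode.from_ncbi_id(config.code_id)

    manifest: dict = {
        "settings": {
            "code_id": config.code_id,
            "precision": config.precision,
            "drop_terminal_stop": config.drop_terminal_stop,
            "skew_convention": "coding-strand per gene; H-strand genome-wide",
            "kaks_method": "NG86 equal-weight pathway counting, Jukes-Cantor",
        },
        "inputs": [],
        "artifacts": [],
        "notices": [],
    }

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        manifest["artifacts"].append(name)

    genomes: list[MitogenomeAnnotation] = []
    for raw in config.inputs:
        path = Path(raw)
        ann = load_any(path)
        genomes.append(ann)
        manifest["inputs"].append({"path": str(path), "sha256": _sha256(path),
                                   "label": ann.label})

    for ann in genomes:
        label = ann.label
        emit(f"{label}.features.tsv",
             lambda p, a=ann: feature_summary_table(a).to_csv(p, sep="\t", index=False))
        emit(f"{label}.structure.json",
             lambda p, a=ann: p.write_text(
                 json.dumps(_structure_summary(a), indent=2) + "\n"))
        if ann.sequence is None:
            manifest["notices"].append(
                f"{label}: no sequence attached; composition, skew, codon-usage "
                "and divergence tables skipped"
            )
            continue
        emit(f"{label}.composition.tsv",
             lambda p, a=ann: comp_mod.composition_table(a)
             .to_csv(p, sep="\t", index=False))
        emit(f"{label}.skew.tsv",
             lambda p, a=ann: comp_mod.pcg_skew_profile(a)
             .round(6).to_csv(p, sep="\t", index=False))
        counts = count_codons(
            [extract_gene_sequence(ann, f.name) for f in ann.pcgs()],
            code, drop_terminal_stop=config.drop_terminal_stop, scope=label,
        )
        table = rscu(counts, code).as_frame(counts, code).round(6)
        emit(f"{label}.codon_usage.tsv",
             lambda p, t=table: t.to_csv(p, sep="\t", index=False))

    sequenced = [g for g in genomes if g.sequence is not None]
    if len(sequenced) >= 2:
        _divergence_stage(sequenced, code, out_dir, manifest, emit, config)
    return_manifest = dict(manifest)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return_manifest["artifacts"] = manifest["artifacts"] + ["manifest.json"]
    return return_manifest


def _load_aligned(aligned_dir: Path, gene: str) -> dict[str, str] | None:
    """Per-gene aligned FASTA ``<gene>.fasta`` with one record per genome label."""
    from Bio import SeqIO

    for ext in (".fasta", ".fa", ".aln"):
        path = aligned_dir / f"{gene}{ext}"
        if path.exists():
            return {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(path), "fasta")}
    return None


def _divergence_stage(genomes, code, out_dir, manifest, emit, config) -> None:
    shared = None
    for g in genomes:
        names = [f.name for f in g.pcgs()]
        shared = names if shared is None else [n for n in shared if n in names]
    frames = []
    aligned_dir = Path(config.aligned_dir) if config.aligned_dir else None
    for gene in shared or []:
        aligned = _load_aligned(aligned_dir, gene) if aligned_dir else None
        try:
            frames.append(
                div_mod.pairwise_gene_matrix(genomes, gene, code, aligned=aligned)
            )
        except div_mod.AlignmentError as exc:
            manifest["notices"].append(str(exc))
    if not frames:
        manifest["notices"].append("divergence stage: no comparable genes")
        return
    import warnings as _warnings

    with _warnings.catch_warnings():
        # saturated pairs leave all-NA ka/ks columns in some per-gene frames
        _warnings.simplefilter("ignore", FutureWarning)
        long = pd.concat(frames, ignore_index=True).round(6)
    emit("divergence.tsv", lambda p: long.to_csv(p, sep="\t", index=False))

    labels = [g.label for g in genomes]
    for column, fname in (("p_all", "pdistance.phy"), ("ka", "ka.phy"),
                          ("ks", "ks.phy")):
        matrix = [[0.0] * len(labels) for _ in labels]
        means = long.groupby("pair")[column].mean()
        ok = True
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    continue
                key = f"{a}|{b}" if f"{a}|{b}" in means.index else f"{b}|{a}"
                val = means.get(key)
                if val is None or pd.isna(val):
                    ok = False
                else:
                    matrix[i][j] = float(val)
        if ok:
            emit(fname, lambda p, m=matrix: div_mod.write_phylip_matrix(labels, m, p))
        else:
            manifest["notices"].append(
                f"{fname}: some pairs undefined (saturation); matrix skipped"
            )
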