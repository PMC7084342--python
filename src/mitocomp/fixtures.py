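"""Packaged feature-table fixtures for the three *Gerres* mitogenomes.

Coordinates, strands, sizes, anticodons and start/stop codons are the
published gene tables for *G. filamentosus* (GF, MG587039, 16,673 bp),
*G. erythrourus* (GE, MN075144, 16,728 bp) and *G. decacanthus*
(GD, MT023107, 16,871 bp).  These carry no nucleotide sequence: every
coordinate-derived statistic (sizes, spacers, overlaps, O_L, strand census,
PCG totals) is computable from them alone.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .feature_table import MitogenomeAnnotation, load_feature_tsv

FIXTURE_FILES = {
    "GF": "gerres_filamentosus.tsv",
    "GE": "gerres_erythrourus.tsv",
    "GD": "gerres_decacanthus.tsv",
}


def fixture_path(key: str) -> Path:
    try:
        fname = FIXTURE_FILES[key.upper()]
    except KeyError:
        raise KeyError(f"unknown fixture {key!r}; choose from {sorted(FIXTURE_FILES)}")
    return Path(str(files("mitocomp.data").joinpath(fname)))


def load_fixture(key: str) -> MitogenomeAnnotation:
    """Load one of the packaged genomes by its two-letter key (GF/GE/GD)."""
    return load_feature_tsv(fixture_path(key))
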