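"""Loaders for the bundled study fixtures.

Two transcribed MR studies of genetically predicted telomere length are
bundled: the 2017 meta-analysis covering 9 cancers (per SD longer gTL) and 5
non-neoplastic diseases (per SD shorter gTL), and the 2020 UK-Biobank study of
7 proliferative conditions (per SD longer gTL, point ORs only).  Alongside them
ship the matching registry burden rates (age-standardized incidence and DALYs
per 100,000, Europe, 2017), the one published sub-condition fraction
(idiopathic pulmonary fibrosis = 26.8% of interstitial lung disease), a curated
106-SNP telomere-length panel on 18 chromosomes, and its per-chromosome R²
matrices.  ``data/provenance.csv`` records every transcription fix applied.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .definition_mapping import CaseFraction, read_fraction_table
from .tables_io import (
    BurdenEstimate,
    DiseaseAssociation,
    LDMatrix,
    SNPRecord,
    read_burden_table,
    read_ld_matrix,
    read_or_table,
    read_snp_table,
)

__all__ = [
    "data_path",
    "load_associations",
    "load_burdens",
    "load_printed_excess",
    "load_fractions",
    "load_snp_panel",
    "load_ld_matrices",
    "ipf_fraction",
]

# Sub-condition share used in the bundled sensitivity analysis: IPF as a
# fraction of interstitial-lung-disease cases (Danish national registry).
IPF_OF_ILD = 0.268


def data_path(name: str) -> Path:
    return Path(resources.files("telburden").joinpath("data", name))


def load_associations(study: str = "haycock") -> list[DiseaseAssociation]:
    """Odds ratios per SD of gTL for ``study`` in {"haycock", "li"}."""
    if study not in ("haycock", "li"):
        raise ValueError(f"unknown study {study!r}")
    return read_or_table(data_path(f"{study}_or.csv"))


def load_burdens(study: str = "haycock") -> list[BurdenEstimate]:
    """Matching age-standardized burden rates per 100,000 (Europe, 2017)."""
    if study not in ("haycock", "li"):
        raise ValueError(f"unknown study {study!r}")
    return read_burden_table(data_path(f"{study}_burden.csv"), dialect="simple")


def load_printed_excess(study: str = "haycock") -> pd.DataFrame:
    """The source's printed excess columns, for reproduction diffs only."""
    if study not in ("haycock", "li"):
        raise ValueError(f"unknown study {study!r}")
    return pd.read_csv(data_path(f"{study}_printed.csv"))


def load_fractions() -> list[CaseFraction]:
    return read_fraction_table(data_path("fractions.csv"))


def ipf_fraction() -> CaseFraction:
    """IPF share of interstitial-lung-disease cases (0.268)."""
    for frac in load_fractions():
        if frac.narrow_name == "Idiopathic pulmonary fibrosis":
            return frac
    raise LookupError("IPF fraction missing from bundled fixtures")


def load_snp_panel() -> list[SNPRecord]:
    """The curated 106-SNP telomere-length panel (18 chromosomes)."""
    return read_snp_table(data_path("snp_panel.csv"))


def load_ld_matrices() -> list[LDMatrix]:
    """Per-chromosome R² matrices, in chromosome order."""
    ld_dir = data_path("ld")
    paths = sorted(ld_dir.glob("chr*.tsv"), key=lambda p: int(p.stem[3:]))
    return [read_ld_matrix(p) for p in paths]
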