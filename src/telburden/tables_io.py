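"""Typed records and delimited-table I/O for the burden-attribution pipeline.

Every table the pipeline touches — odds-ratio tables, registry burden tables
(incidence and DALY rates per 100,000, age-standardized), SEER-style case-count
tables, SNP annotation tables and per-chromosome LD matrices — is read into
validated dataclass records here, so downstream modules never see raw strings.

Missing data is an explicit ``None`` sentinel, never silently zero.  Values are
kept at full parsed precision; rounding to two decimals happens only in display
columns written by :func:`write_excess_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PER_SD_LONGER",
    "PER_SD_SHORTER",
    "INCIDENCE",
    "DALY",
    "TableFormatError",
    "ValidationError",
    "DiseaseAssociation",
    "BurdenEstimate",
    "SNPRecord",
    "LDMatrix",
    "read_or_table",
    "write_or_table",
    "read_burden_table",
    "write_burden_table",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_snp_table",
    "write_snp_table",
    "write_excess_table",
    "round_display",
]

# Effect directions: odds ratios are per one standard deviation of genetically
# predicted telomere length, and the direction of that SD change must travel
# with the number.
PER_SD_LONGER = "per_sd_longer"
PER_SD_SHORTER = "per_sd_shorter"
_DIRECTIONS = (PER_SD_LONGER, PER_SD_SHORTER)

INCIDENCE = "incidence"
DALY = "daly"
_MEASURES = (INCIDENCE, DALY)

_MISSING_TOKENS = {"", "na", "n/a", "nan", "none", "missing", "."}


class TableFormatError(ValueError):
    """A file could not be parsed as the expected table layout."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


def _is_missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    return str(cell).strip().lower() in _MISSING_TOKENS


def _parse_number(cell, *, context: str) -> float | None:
    """Parse a rate/OR cell; '.' decimal mark, ',' thousands separator only."""
    if _is_missing(cell):
        return None
    text = str(cell).strip().replace(",", "")
    try:
        return float(text)
    except ValueError:
        raise TableFormatError(f"unparseable number {cell!r} in {context}") from None


def _parse_bool(cell, *, context: str) -> bool:
    text = str(cell).strip().lower()
    if text in {"true", "t", "yes", "y", "1"}:
        return True
    if text in {"false", "f", "no", "n", "0"}:
        return False
    raise TableFormatError(f"unparseable boolean {cell!r} in {context}")


# En-dash and hyphen both accepted as CI range separators.
_OR_CI_RE = re.compile(
    r"^\s*(?P<or>[\d.,]+)\s*\(\s*(?P<lo>[\d.,]+)\s*[–—-]\s*(?P<hi>[\d.,]+)\s*\)\s*$"
)


@dataclass(frozen=True)
class DiseaseAssociation:
    """One disease's odds ratio per SD of gTL, with its 95% CI and direction.

    ``ci_lower``/``ci_upper`` may be ``None`` when the source study prints only
    a point estimate.  ``significant`` flags statistical significance as
    reported by the source; non-significant rows are retained at parse time and
    filtered downstream as a visible pipeline step.
    """

    disease_name: str
    or_per_sd: float
    ci_lower: float | None
    ci_upper: float | None
    direction: str
    source: str = ""
    significant: bool = True

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValidationError(
                f"{self.disease_name}: unknown direction {self.direction!r}"
            )
        if not self.or_per_sd > 0:
            raise ValidationError(f"{self.disease_name}: OR must be positive")
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise ValidationError(
                f"{self.disease_name}: CI bounds must both be present or both missing"
            )
        if self.ci_lower is not None:
            if not (self.ci_lower > 0 and self.ci_upper > 0):
                raise ValidationError(f"{self.disease_name}: CI bounds must be positive")
            if self.ci_lower > self.ci_upper:
                raise ValidationError(
                    f"{self.disease_name}: inverted CI ({self.ci_lower} > {self.ci_upper})"
                )
            if not (self.ci_lower <= self.or_per_sd <= self.ci_upper):
                raise ValidationError(
                    f"{self.disease_name}: OR {self.or_per_sd} outside its CI "
                    f"({self.ci_lower}, {self.ci_upper})"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None


@dataclass(frozen=True)
class BurdenEstimate:
    """Age-standardized rate per 100,000 persons for one cause and measure.

    ``measure`` is ``incidence`` or ``daly``; a MISSING registry value is
    ``None`` (and then both bounds are ``None`` too).
    """

    cause_name: str
    measure: str
    value: float | None
    ci_lower: float | None = None
    ci_upper: float | None = None
    population: str = ""
    year: int | None = None

    def __post_init__(self):
        if self.measure not in _MEASURES:
            raise ValidationError(f"{self.cause_name}: unknown measure {self.measure!r}")
        if self.value is None:
            if self.ci_lower is not None or self.ci_upper is not None:
                raise ValidationError(
                    f"{self.cause_name}: MISSING value but CI bounds present"
                )
            return
        if self.value < 0:
            raise ValidationError(f"{self.cause_name}: negative rate {self.value}")
        if self.ci_lower is not None and self.ci_upper is not None:
            if self.ci_lower < 0 or self.ci_upper < 0:
                raise ValidationError(f"{self.cause_name}: negative CI bound")
            if not (self.ci_lower <= self.value <= self.ci_upper):
                raise ValidationError(
                    f"{self.cause_name}: rate {self.value} outside CI "
                    f"({self.ci_lower}, {self.ci_upper})"
                )


@dataclass(frozen=True)
class SNPRecord:
    """One telomere-length-associated SNP from the curated panel."""

    rsid: str
    chromosome: str
    position: int
    short_allele: str | None = None
    long_allele: str | None = None
    short_allele_freq: float | None = None
    gene_is_telomere_maintenance: str = "unknown"  # yes / no / unknown
    n_participants: int | None = None
    gwas: bool = False
    population: str = ""

    def __post_init__(self):
        if self.position <= 0:
            raise ValidationError(f"{self.rsid}: position must be > 0")
        if self.short_allele_freq is not None and not (
            0.0 <= self.short_allele_freq <= 1.0
        ):
            raise ValidationError(
                f"{self.rsid}: allele frequency {self.short_allele_freq} outside [0, 1]"
            )
        if self.gene_is_telomere_maintenance not in ("yes", "no", "unknown"):
            raise ValidationError(
                f"{self.rsid}: bad telomere-maintenance flag "
                f"{self.gene_is_telomere_maintenance!r}"
            )


_SYMMETRY_TOL = 1e-12


@dataclass
class LDMatrix:
    """Square symmetric R-squared matrix over SNP identifiers.

    ``r2`` is a float array with ``nan`` for MISSING cells; the diagonal is 1
    for every row that is not entirely MISSING.
    """

    chromosome: str
    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValidationError(
                f"chromosome {self.chromosome}: matrix shape {self.r2.shape} "
                f"does not match {n} rsids"
            )
        if len(set(self.rsids)) != n:
            raise ValidationError(f"chromosome {self.chromosome}: duplicate rsids")
        finite = ~np.isnan(self.r2)
        if np.any((self.r2[finite] < 0) | (self.r2[finite] > 1)):
            raise ValidationError(
                f"chromosome {self.chromosome}: R^2 outside [0, 1]"
            )
        both = finite & finite.T
        if np.any(np.abs((self.r2 - self.r2.T)[both]) > _SYMMETRY_TOL):
            raise ValidationError(f"chromosome {self.chromosome}: asymmetric matrix")
        for i in range(n):
            row_missing = np.all(np.isnan(self.r2[i]))
            if not row_missing and not np.isclose(self.r2[i, i], 1.0, atol=_SYMMETRY_TOL):
                raise ValidationError(
                    f"chromosome {self.chromosome}: diagonal != 1 for {self.rsids[i]}"
                )

    @property
    def n(self) -> int:
        return len(self.rsids)


# ---------------------------------------------------------------------------
# odds-ratio tables


def _parse_or_cell(cell: str, *, context: str) -> tuple[float, float, float]:
    m = _OR_CI_RE.match(str(cell))
    if m is None:
        raise TableFormatError(f"malformed OR cell {cell!r} in {context}")
    return (
        _parse_number(m["or"], context=context),
        _parse_number(m["lo"], context=context),
        _parse_number(m["hi"], context=context),
    )


def read_or_table(path) -> list[DiseaseAssociation]:
    """Read a disease-association CSV into :class:`DiseaseAssociation` records.

    Two layouts are accepted: a combined ``or_ci`` column formatted
    ``"X.XX (L–U)"`` (hyphen or en-dash), or separate ``or_per_sd``,
    ``ci_lower``, ``ci_upper`` columns (bounds may be empty/NA).
    Required columns: ``disease_name``, ``direction``; optional: ``source``,
    ``significant`` (defaults to true).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = set(df.columns)
    if "disease_name" not in cols or "direction" not in cols:
        raise TableFormatError(f"{path}: need disease_name and direction columns")
    combined = "or_ci" in cols
    if not combined and "or_per_sd" not in cols:
        raise TableFormatError(f"{path}: need an or_ci or or_per_sd column")
    out: list[DiseaseAssociation] = []
    for idx, row in df.iterrows():
        context = f"{path} row {idx + 2} ({row['disease_name']})"
        if combined:
            or_, lo, hi = _parse_or_cell(row["or_ci"], context=context)
        else:
            or_ = _parse_number(row["or_per_sd"], context=context)
            lo = _parse_number(row.get("ci_lower", ""), context=context)
            hi = _parse_number(row.get("ci_upper", ""), context=context)
        try:
            out.append(
                DiseaseAssociation(
                    disease_name=row["disease_name"].strip(),
                    or_per_sd=or_,
                    ci_lower=lo,
                    ci_upper=hi,
                    direction=row["direction"].strip(),
                    source=row.get("source", "").strip(),
                    significant=(
                        _parse_bool(row["significant"], context=context)
                        if "significant" in cols and not _is_missing(row["significant"])
                        else True
                    ),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{context}: {err}") from None
    return out


def write_or_table(assocs: Iterable[DiseaseAssociation], path) -> None:
    rows = [
        {
            "disease_name": a.disease_name,
            "or_per_sd": repr(a.or_per_sd),
            "ci_lower": "" if a.ci_lower is None else repr(a.ci_lower),
            "ci_upper": "" if a.ci_upper is None else repr(a.ci_upper),
            "direction": a.direction,
            "source": a.source,
            "significant": a.significant,
        }
        for a in assocs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "disease_name",
            "or_per_sd",
            "ci_lower",
            "ci_upper",
            "direction",
            "source",
            "significant",
        ],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# burden tables

# Column layout of a GBD-Results-Tool export.
_GBD_COLUMNS = {"measure", "location", "sex", "age", "cause", "metric", "year",
                "val", "upper", "lower"}

_GBD_MEASURE_MAP = {
    "incidence": INCIDENCE,
    "dalys (disability-adjusted life years)": DALY,
    "dalys": DALY,
    "daly": DALY,
}


def _coerce_measure(text: str, *, context: str) -> str:
    key = str(text).strip().lower()
    if key in _GBD_MEASURE_MAP:
        return _GBD_MEASURE_MAP[key]
    raise TableFormatError(f"unknown measure {text!r} in {context}")


def read_burden_table(path, dialect: str = "simple") -> list[BurdenEstimate]:
    """Read burden rates (per 100,000, age-standardized) from a CSV.

    ``dialect="simple"`` expects columns ``cause_name, measure, value,
    ci_lower, ci_upper[, population, year]``.  ``dialect="gbd_results"``
    expects the GBD Results Tool export layout (``measure, location, sex, age,
    cause, metric, year, val, upper, lower``).  Thousands separators are
    accepted ("2,106.22"); NA cells become MISSING values.
    """
    if dialect not in ("simple", "gbd_results"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: list[BurdenEstimate] = []
    if dialect == "gbd_results":
        missing = _GBD_COLUMNS - set(df.columns)
        if missing:
            raise TableFormatError(f"{path}: missing GBD columns {sorted(missing)}")
        for idx, row in df.iterrows():
            context = f"{path} row {idx + 2} ({row['cause']})"
            value = _parse_number(row["val"], context=context)
            out.append(
                BurdenEstimate(
                    cause_name=row["cause"].strip(),
                    measure=_coerce_measure(row["measure"], context=context),
                    value=value,
                    ci_lower=None if value is None else _parse_number(row["lower"], context=context),
                    ci_upper=None if value is None else _parse_number(row["upper"], context=context),
                    population=row["location"].strip(),
                    year=int(row["year"]) if not _is_missing(row["year"]) else None,
                )
            )
        return out
    required = {"cause_name", "measure", "value"}
    if not required <= set(df.columns):
        raise TableFormatError(f"{path}: need columns {sorted(required)}")
    for idx, row in df.iterrows():
        context = f"{path} row {idx + 2} ({row['cause_name']})"
        value = _parse_number(row["value"], context=context)
        out.append(
            BurdenEstimate(
                cause_name=row["cause_name"].strip(),
                measure=_coerce_measure(row["measure"], context=context),
                value=value,
                ci_lower=None if value is None else _parse_number(row.get("ci_lower", ""), context=context),
                ci_upper=None if value is None else _parse_number(row.get("ci_upper", ""), context=context),
                population=row.get("population", "").strip(),
                year=int(row["year"]) if "year" in df.columns and not _is_missing(row["year"]) else None,
            )
        )
    return out


def write_burden_table(burdens: Iterable[BurdenEstimate], path) -> None:
    rows = [
        {
            "cause_name": b.cause_name,
            "measure": b.measure,
            "value": "" if b.value is None else repr(b.value),
            "ci_lower": "" if b.ci_lower is None else repr(b.ci_lower),
            "ci_upper": "" if b.ci_upper is None else repr(b.ci_upper),
            "population": b.population,
            "year": "" if b.year is None else b.year,
        }
        for b in burdens
    ]
    pd.DataFrame(
        rows,
        columns=["cause_name", "measure", "value", "ci_lower", "ci_upper",
                 "population", "year"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# LD matrices


def read_ld_matrix(path, chromosome: str | None = None) -> LDMatrix:
    """Read a square R-squared table (whitespace- or comma-delimited).

    The first row and first column hold rsids.  Lower- or upper-triangular
    input is mirrored to a full symmetric matrix; "NA" cells become MISSING.
    A row whose cells are all NA (an unmeasurable SNP) stays fully MISSING.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise TableFormatError(f"{path}: empty LD file")
    delim = "," if "," in text.splitlines()[0] else None
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split(delim) if delim else lines[0].split()
    header = [h.strip() for h in header]
    names = header[1:] if header else []
    rows = []
    row_names = []
    for ln in lines[1:]:
        parts = [p.strip() for p in (ln.split(delim) if delim else ln.split())]
        row_names.append(parts[0])
        rows.append(parts[1:])
    if names and row_names and names != row_names:
        # header may be an abbreviated list; trust row labels when longer
        if len(row_names) > len(names) and row_names[: len(names)] == names:
            names = row_names
        elif len(row_names) < len(names) and names[: len(row_names)] == row_names:
            pass  # fewer rows than header columns: caught as non-square below
        else:
            raise TableFormatError(f"{path}: header rsids do not match row rsids")
    if not names:
        names = row_names
    n = len(names)
    if len(rows) != n:
        raise TableFormatError(f"{path}: {len(rows)} rows for {n} rsids (non-square)")
    r2 = np.full((n, n), np.nan)
    for i, cells in enumerate(rows):
        if len(cells) > n:
            raise TableFormatError(f"{path}: row {names[i]} has {len(cells)} cells")
        for j, cell in enumerate(cells):
            r2[i, j] = np.nan if _is_missing(cell) else _parse_number(
                cell, context=f"{path} row {names[i]}"
            )
    # mirror: where exactly one triangle holds a value, copy it across
    upper_only = np.isnan(r2) & ~np.isnan(r2.T)
    r2[upper_only] = r2.T[upper_only]
    if chromosome is None:
        chromosome = path.stem.replace("chr", "")
    return LDMatrix(chromosome=chromosome, rsids=names, r2=r2)


def write_ld_matrix(matrix: LDMatrix, path) -> None:
    """Write a full square matrix, tab-delimited, NA for MISSING."""
    with open(path, "w") as fh:
        fh.write("RS_number\t" + "\t".join(matrix.rsids) + "\n")
        for i, name in enumerate(matrix.rsids):
            cells = [
                "NA" if np.isnan(v) else repr(float(v)) for v in matrix.r2[i]
            ]
            fh.write(name + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# SNP tables


def read_snp_table(path) -> list[SNPRecord]:
    """Read the SNP annotation panel; rsids must be unique within the table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"rsid", "chromosome", "position"}
    if not required <= set(df.columns):
        raise TableFormatError(f"{path}: need columns {sorted(required)}")
    dupes = df["rsid"][df["rsid"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate rsids {sorted(set(dupes))}")
    out = []
    for idx, row in df.iterrows():
        context = f"{path} row {idx + 2} ({row['rsid']})"
        freq = _parse_number(row.get("short_allele_freq", ""), context=context)
        n_part = row.get("n_participants", "")
        try:
            out.append(
                SNPRecord(
                    rsid=row["rsid"].strip(),
                    chromosome=row["chromosome"].strip(),
                    position=int(row["position"]),
                    short_allele=None if _is_missing(row.get("short_allele", "")) else row["short_allele"].strip(),
                    long_allele=None if _is_missing(row.get("long_allele", "")) else row["long_allele"].strip(),
                    short_allele_freq=freq,
                    gene_is_telomere_maintenance=(
                        row["gene_is_telomere_maintenance"].strip().lower()
                        if "gene_is_telomere_maintenance" in df.columns
                        and not _is_missing(row["gene_is_telomere_maintenance"])
                        else "unknown"
                    ),
                    n_participants=None if _is_missing(n_part) else int(str(n_part).replace(",", "")),
                    gwas=_parse_bool(row["gwas"], context=context) if "gwas" in df.columns and not _is_missing(row["gwas"]) else False,
                    population=row.get("population", "").strip(),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{context}: {err}") from None
    return out


def write_snp_table(snps: Iterable[SNPRecord], path) -> None:
    rows = [
        {
            "rsid": s.rsid,
            "chromosome": s.chromosome,
            "position": s.position,
            "short_allele": s.short_allele or "NA",
            "long_allele": s.long_allele or "NA",
            "short_allele_freq": "NA" if s.short_allele_freq is None else repr(s.short_allele_freq),
            "gene_is_telomere_maintenance": s.gene_is_telomere_maintenance,
            "n_participants": "NA" if s.n_participants is None else s.n_participants,
            "gwas": s.gwas,
            "population": s.population,
        }
        for s in snps
    ]
    pd.DataFrame(
        rows,
        columns=["rsid", "chromosome", "position", "short_allele", "long_allele",
                 "short_allele_freq", "gene_is_telomere_maintenance",
                 "n_participants", "gwas", "population"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# excess-burden output


def round_display(x: float | None, decimals: int = 2) -> str:
    """Half-even rounding for display columns (report time only)."""
    if x is None:
        return "NA"
    from decimal import Decimal, ROUND_HALF_EVEN

    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def write_excess_table(records: Sequence, path, decimals: int = 2) -> None:
    """Write ExcessBurden rows: fixed column order, raw values plus a
    fixed-decimal display column."""
    rows = [
        {
            "cause_name": r.cause_name,
            "measure": r.measure,
            "direction": r.direction,
            "value": repr(float(r.value)),
            "ci_lower": "" if r.ci_lower is None else repr(float(r.ci_lower)),
            "ci_upper": "" if r.ci_upper is None else repr(float(r.ci_upper)),
            "display": (
                f"{round_display(r.value, decimals)} "
                f"({round_display(r.ci_lower, decimals)}"
                f"–{round_display(r.ci_upper, decimals)})"
                if r.ci_lower is not None
                else round_display(r.value, decimals)
            ),
            "components": ";".join(r.components),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["cause_name", "measure", "direction", "value", "ci_lower",
                 "ci_upper", "display", "components"],
    ).to_csv(path, index=False)
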