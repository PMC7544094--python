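"""The core statistic: excess incidence and excess DALYs per SD of gTL.

For a disease with harmonized odds ratio OR per SD of genetically predicted
telomere length and an age-standardized burden rate V (incidence or DALYs per
100,000 persons), the attributed excess is

    excess = (OR − 1) × V

with 95% bounds (OR_L − 1) × V and (OR_U − 1) × V from the OR's CI; the burden
rate's own CI is not propagated.  Group totals sum values and like bounds
across diseases — a deliberately conservative convention that assumes perfect
dependence between diseases (an optional root-sum-square alternative is
provided).  Diseases whose registry burden is unavailable for a measure are
excluded from that measure's total with a machine-readable reason.

Note the statistic treats OR − 1 as an excess relative risk even for common
diseases where OR and RR diverge; that approximation is inherited from the
analysis convention and documented, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .tables_io import (
    DALY,
    INCIDENCE,
    BurdenEstimate,
    DiseaseAssociation,
    ValidationError,
)

__all__ = ["ExcessBurden", "AttributionReport", "excess", "total_excess",
           "attribute"]


@dataclass(frozen=True)
class ExcessBurden:
    """Attributed excess cases or DALYs per 100,000 persons per SD of gTL."""

    cause_name: str
    measure: str
    direction: str
    value: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    components: tuple[str, ...] = ()

    def __post_init__(self):
        if self.ci_lower is not None and self.ci_upper is not None:
            if self.ci_lower > self.ci_upper + 1e-12:
                raise ValidationError(
                    f"{self.cause_name}: inverted excess CI "
                    f"({self.ci_lower} > {self.ci_upper})"
                )


@dataclass
class Exclusion:
    disease_name: str
    measure: str | None
    reason: str


@dataclass
class AttributionReport:
    """Per-disease excess rows, exclusions with reasons, and group totals.

    ``totals`` is keyed by (measure, direction).  Every input association
    appears, for each measure, either in a row or in an exclusion.
    """

    rows: list[ExcessBurden] = field(default_factory=list)
    excluded: list[Exclusion] = field(default_factory=list)
    totals: dict[tuple[str, str], ExcessBurden] = field(default_factory=dict)

    def rows_for(self, measure: str, direction: str) -> list[ExcessBurden]:
        return [r for r in self.rows
                if r.measure == measure and r.direction == direction]


def excess(
    assoc: DiseaseAssociation,
    burden: BurdenEstimate,
    ci_source: str = "or",
) -> ExcessBurden:
    """Per-disease excess statistic (OR − 1) × rate with its CI.

    ``ci_source="or"`` (default) takes bounds from the OR's CI times the
    burden point value.  ``ci_source="burden"`` takes the OR point value times
    the burden CI bounds — the convention needed when the source study prints
    no OR CI.  ``ci_source="auto"`` uses the OR CI when present, else the
    burden CI.
    """
    if burden.value is None:
        raise ValidationError(
            f"{burden.cause_name}: MISSING burden value — route to exclusions"
        )
    if ci_source not in ("or", "burden", "auto"):
        raise ValidationError(f"unknown ci_source {ci_source!r}")
    or_ = assoc.or_per_sd
    value = (or_ - 1.0) * burden.value
    use = ci_source
    if use == "auto":
        use = "or" if assoc.has_ci else "burden"
    if use == "or" and assoc.has_ci:
        lo = (assoc.ci_lower - 1.0) * burden.value
        hi = (assoc.ci_upper - 1.0) * burden.value
    elif use == "burden" and burden.ci_lower is not None:
        lo = (or_ - 1.0) * burden.ci_lower
        hi = (or_ - 1.0) * burden.ci_upper
        if or_ < 1.0:
            lo, hi = hi, lo
    else:
        lo = hi = None
    return ExcessBurden(
        cause_name=assoc.disease_name,
        measure=burden.measure,
        direction=assoc.direction,
        value=value,
        ci_lower=lo,
        ci_upper=hi,
        components=(assoc.disease_name,),
    )


def total_excess(
    rows: Sequence[ExcessBurden],
    name: str = "total",
    bounds: str = "sum",
) -> ExcessBurden:
    """Aggregate per-disease excess rows sharing measure and direction.

    ``bounds="sum"`` (default) sums values and like CI bounds, the
    perfect-dependence convention; ``bounds="rss"`` combines bound half-widths
    by root-sum-square instead (independence).  Bounds are only produced when
    every row carries them.
    """
    if not rows:
        raise ValidationError("total_excess: empty row list")
    measures = {r.measure for r in rows}
    directions = {r.direction for r in rows}
    if len(measures) != 1 or len(directions) != 1:
        raise ValidationError("total_excess: mixed measure or direction")
    if bounds not in ("sum", "rss"):
        raise ValidationError(f"total_excess: unknown bounds rule {bounds!r}")
    value = math.fsum(r.value for r in rows)
    have_ci = all(r.ci_lower is not None and r.ci_upper is not None for r in rows)
    lo = hi = None
    if have_ci:
        if bounds == "sum":
            lo = math.fsum(r.ci_lower for r in rows)
            hi = math.fsum(r.ci_upper for r in rows)
        else:
            lo = value - math.sqrt(math.fsum((r.value - r.ci_lower) ** 2 for r in rows))
            hi = value + math.sqrt(math.fsum((r.ci_upper - r.value) ** 2 for r in rows))
    components = tuple(c for r in rows for c in (r.components or (r.cause_name,)))
    return ExcessBurden(
        cause_name=name,
        measure=next(iter(measures)),
        direction=next(iter(directions)),
        value=value,
        ci_lower=lo,
        ci_upper=hi,
        components=components,
    )


def attribute(
    assocs: Sequence[DiseaseAssociation],
    burdens: Sequence[BurdenEstimate],
    aliases: Mapping[str, str] | None = None,
    ci_source: str = "or",
    bounds: str = "sum",
) -> AttributionReport:
    """Match associations to burden records and build the full report.

    Matching is exact on cause name after applying the ``aliases`` map
    (association name -> burden cause name).  A disease with burden available
    for only one measure contributes only to that measure's total; the other
    measure records an exclusion with a machine-readable reason.  Duplicate
    cause names in either input are an error.
    """
    aliases = dict(aliases or {})
    names = [a.disease_name for a in assocs]
    if len(set(names)) != len(names):
        raise ValidationError("attribute: duplicate disease in associations")
    keys = [(b.cause_name, b.measure) for b in burdens]
    if len(set(keys)) != len(keys):
        raise ValidationError("attribute: duplicate cause x measure in burdens")
    burden_map = {k: b for k, b in zip(keys, burdens)}

    report = AttributionReport()
    grouped: dict[tuple[str, str], list[ExcessBurden]] = {}
    for assoc in assocs:
        cause = aliases.get(assoc.disease_name, assoc.disease_name)
        for measure in (INCIDENCE, DALY):
            burden = burden_map.get((cause, measure))
            if burden is None:
                report.excluded.append(
                    Exclusion(assoc.disease_name, measure, "no burden record")
                )
                continue
            if burden.value is None:
                report.excluded.append(
                    Exclusion(assoc.disease_name, measure, "burden value missing")
                )
                continue
            row = excess(assoc, burden, ci_source=ci_source)
            report.rows.append(row)
            grouped.setdefault((measure, assoc.direction), []).append(row)
    for (measure, direction), rows in grouped.items():
        report.totals[(measure, direction)] = total_excess(
            rows, name=f"total {measure} {direction}", bounds=bounds
        )
    return report
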