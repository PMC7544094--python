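"""Disease-definition reconciliation between MR case definitions and registry
burden categories.

MR studies often estimate ORs for narrower case definitions (e.g. lung
adenocarcinoma) than the registry burden category (trachea/bronchus/lung
cancer).  Registry burden is allocated to the narrow definition in proportion
to case counts pulled from a SEER-style registry; sensitivity analyses subtract
a sub-condition's approximate share from an excess-burden total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .tables_io import BurdenEstimate, TableFormatError, ValidationError

__all__ = ["CaseFraction", "case_fraction", "allocate", "subtract_subcondition",
           "read_fraction_table"]


@dataclass(frozen=True)
class CaseFraction:
    """Narrow/broad case counts and the resulting allocation fraction."""

    narrow_name: str
    broad_name: str
    fraction: float
    narrow_count: int | None = None
    broad_count: int | None = None
    source: str = ""

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValidationError(
                f"{self.narrow_name}: fraction {self.fraction} outside [0, 1]"
            )
        if (self.narrow_count is None) != (self.broad_count is None):
            raise ValidationError(
                f"{self.narrow_name}: counts must both be present or both absent"
            )
        if self.narrow_count is not None:
            if self.broad_count <= 0:
                raise ValidationError(f"{self.narrow_name}: zero broad count")
            if self.narrow_count < 0 or self.narrow_count > self.broad_count:
                raise ValidationError(
                    f"{self.narrow_name}: narrow count {self.narrow_count} "
                    f"exceeds broad count {self.broad_count}"
                )
            if self.fraction != self.narrow_count / self.broad_count:
                raise ValidationError(
                    f"{self.narrow_name}: fraction inconsistent with counts"
                )


def case_fraction(
    narrow_count: int,
    broad_count: int,
    narrow_name: str = "",
    broad_name: str = "",
    source: str = "",
) -> CaseFraction:
    """Fraction of the broad category's cases belonging to the narrow
    definition, at full precision."""
    if broad_count <= 0:
        raise ValidationError("case_fraction: broad count must be positive")
    if narrow_count < 0 or narrow_count > broad_count:
        raise ValidationError("case_fraction: narrow count exceeds broad count")
    return CaseFraction(
        narrow_name=narrow_name,
        broad_name=broad_name,
        narrow_count=narrow_count,
        broad_count=broad_count,
        fraction=narrow_count / broad_count,
        source=source,
    )


def allocate(broad: BurdenEstimate, frac: CaseFraction) -> BurdenEstimate:
    """Scale a broad burden estimate down to a narrow case definition.

    The rate and both CI bounds are each multiplied by the fraction and the
    cause is renamed; allocation is linear in the fraction, so a partition of
    fractions summing to one conserves the broad value exactly.
    """
    if broad.value is None:
        raise ValidationError(f"{broad.cause_name}: cannot allocate MISSING value")
    if frac.broad_name and frac.broad_name != broad.cause_name:
        raise ValidationError(
            f"allocate: fraction is for {frac.broad_name!r}, "
            f"burden is {broad.cause_name!r}"
        )
    f = frac.fraction
    return replace(
        broad,
        cause_name=frac.narrow_name,
        value=broad.value * f,
        ci_lower=None if broad.ci_lower is None else broad.ci_lower * f,
        ci_upper=None if broad.ci_upper is None else broad.ci_upper * f,
    )


def subtract_subcondition(total, component, fraction: float):
    """Sensitivity adjustment: remove a sub-condition's approximate share from
    an excess-burden total.

    ``adjusted = total − fraction × component`` applied to the value and to
    each CI bound; e.g. removing the idiopathic-pulmonary-fibrosis share
    (26.8%) of the interstitial-lung-disease excess from the short-gTL totals.
    Both arguments are ExcessBurden records sharing measure and direction.
    """
    from .burden_attribution import ExcessBurden  # local import avoids a cycle

    if not (0.0 <= fraction <= 1.0):
        raise ValidationError(f"fraction {fraction} outside [0, 1]")
    if total.measure != component.measure:
        raise ValidationError(
            f"measure mismatch: {total.measure} vs {component.measure}"
        )
    if total.direction != component.direction:
        raise ValidationError(
            f"direction mismatch: {total.direction} vs {component.direction}"
        )
    value = total.value - fraction * component.value

    def _bound(t, c):
        if t is None or c is None:
            return None
        return t - fraction * c

    if value < 0:
        raise ValidationError(
            "subtract_subcondition: adjusted value negative — inconsistent inputs"
        )
    return ExcessBurden(
        cause_name=f"{total.cause_name} minus {fraction:.3g} x {component.cause_name}",
        measure=total.measure,
        direction=total.direction,
        value=value,
        ci_lower=_bound(total.ci_lower, component.ci_lower),
        ci_upper=_bound(total.ci_upper, component.ci_upper),
        components=tuple(total.components),
    )


def read_fraction_table(path) -> list[CaseFraction]:
    """Read a fraction CSV: columns ``narrow_name, broad_name`` and either
    ``narrow_count, broad_count`` or a precomputed ``fraction``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"narrow_name", "broad_name"} <= set(df.columns):
        raise TableFormatError(f"{path}: need narrow_name and broad_name columns")
    out = []
    for idx, row in df.iterrows():
        has_counts = (
            "narrow_count" in df.columns
            and row.get("narrow_count", "").strip() != ""
            and row.get("broad_count", "").strip() != ""
        )
        if has_counts:
            out.append(
                case_fraction(
                    int(row["narrow_count"]),
                    int(row["broad_count"]),
                    narrow_name=row["narrow_name"].strip(),
                    broad_name=row["broad_name"].strip(),
                    source=row.get("source", "").strip(),
                )
            )
        elif "fraction" in df.columns and row["fraction"].strip() != "":
            out.append(
                CaseFraction(
                    narrow_name=row["narrow_name"].strip(),
                    broad_name=row["broad_name"].strip(),
                    fraction=float(row["fraction"]),
                    source=row.get("source", "").strip(),
                )
            )
        else:
            raise TableFormatError(
                f"{path} row {idx + 2}: need counts or a fraction"
            )
    return out
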