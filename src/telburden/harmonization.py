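"""Effect-direction harmonization and collapse of narrow-definition odds ratios.

MR studies report odds ratios per SD of genetically predicted telomere length
in either direction (per SD longer or per SD shorter).  Before attribution,
every OR is put on the declared target direction by reciprocal inversion —
OR' = 1/OR with CI bounds swapped and inverted — and multiple narrow-definition
ORs that share one registry burden category are collapsed into a single OR by a
weighted mean on the OR scale (weights are relative incidence or prevalence of
the narrow definitions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .tables_io import (
    PER_SD_LONGER,
    PER_SD_SHORTER,
    DiseaseAssociation,
    ValidationError,
)

__all__ = [
    "HarmonizedAssociation",
    "invert_or",
    "normalize_direction",
    "collapse_ors",
    "filter_significant",
]

logger = logging.getLogger(__name__)

_OPPOSITE = {PER_SD_LONGER: PER_SD_SHORTER, PER_SD_SHORTER: PER_SD_LONGER}


@dataclass(frozen=True)
class HarmonizedAssociation(DiseaseAssociation):
    """A DiseaseAssociation on a declared target direction, with provenance.

    ``protective_in_target_direction`` flags ORs < 1 after harmonization:
    harmonizing each disease group to its risk-increasing direction should
    leave all ORs >= 1, so a violation is a warning, never a silent drop.
    """

    harmonized_to: str = PER_SD_LONGER
    provenance: tuple[str, ...] = ()
    protective_in_target_direction: bool = False


def invert_or(assoc: DiseaseAssociation) -> DiseaseAssociation:
    """Invert an OR to the opposite SD direction: OR' = 1/OR, CI' = (1/U, 1/L).

    The reciprocal-and-swap convention preserves CI ordering and the CI's
    coverage of the point estimate, and is an exact involution.
    """
    if not assoc.or_per_sd > 0:
        raise ValidationError(f"{assoc.disease_name}: cannot invert nonpositive OR")
    new = replace(
        assoc,
        or_per_sd=1.0 / assoc.or_per_sd,
        ci_lower=None if assoc.ci_upper is None else 1.0 / assoc.ci_upper,
        ci_upper=None if assoc.ci_lower is None else 1.0 / assoc.ci_lower,
        direction=_OPPOSITE[assoc.direction],
    )
    if isinstance(assoc, HarmonizedAssociation):
        new = replace(new, provenance=assoc.provenance + ("inverted",))
    return new


def normalize_direction(
    assocs: Iterable[DiseaseAssociation], target: str
) -> list[HarmonizedAssociation]:
    """Return every association expressed on ``target`` direction.

    Associations already on the target pass through unchanged; the rest are
    inverted.  ORs that end up < 1 (protective in the target direction) are
    flagged, not dropped.  Idempotent: applying twice equals applying once.
    """
    if target not in _OPPOSITE:
        raise ValidationError(f"unknown target direction {target!r}")
    out: list[HarmonizedAssociation] = []
    for assoc in assocs:
        if assoc.direction is None:
            raise ValidationError(f"{assoc.disease_name}: missing direction")
        prov = (
            assoc.provenance if isinstance(assoc, HarmonizedAssociation) else ()
        )
        if assoc.direction == target:
            adjusted, prov_out = assoc, prov
        else:
            adjusted = invert_or(assoc)
            prov_out = prov + ("inverted",)
        out.append(
            HarmonizedAssociation(
                disease_name=adjusted.disease_name,
                or_per_sd=adjusted.or_per_sd,
                ci_lower=adjusted.ci_lower,
                ci_upper=adjusted.ci_upper,
                direction=target,
                source=adjusted.source,
                significant=adjusted.significant,
                harmonized_to=target,
                provenance=prov_out,
                protective_in_target_direction=adjusted.or_per_sd < 1.0,
            )
        )
        if adjusted.or_per_sd < 1.0:
            logger.warning(
                "%s: OR %.4g is protective on target direction %s",
                adjusted.disease_name,
                adjusted.or_per_sd,
                target,
            )
    return out


def collapse_ors(
    assocs: Sequence[DiseaseAssociation],
    weights: Sequence[float],
    name: str | None = None,
    scale: str = "arithmetic",
) -> HarmonizedAssociation:
    """Collapse several narrow-definition ORs into one, weighted by relative
    incidence or prevalence.

    Default is the weighted arithmetic mean on the OR scale, applied
    identically to each CI bound; ``scale="geometric"`` weights on the log-OR
    scale instead.  The result is invariant to rescaling all weights by a
    constant and lies within [min OR, max OR].
    """
    if not assocs:
        raise ValidationError("collapse_ors: empty association list")
    if len(weights) != len(assocs):
        raise ValidationError("collapse_ors: weights length mismatch")
    total = float(sum(weights))
    if not total > 0:
        raise ValidationError("collapse_ors: zero total weight")
    if any(w < 0 for w in weights):
        raise ValidationError("collapse_ors: negative weight")
    directions = {a.direction for a in assocs}
    if len(directions) != 1:
        raise ValidationError("collapse_ors: mixed effect directions")
    if scale not in ("arithmetic", "geometric"):
        raise ValidationError(f"collapse_ors: unknown scale {scale!r}")
    norm = [float(w) / total for w in weights]

    def _mean(values: list[float | None]) -> float | None:
        if any(v is None for v in values):
            return None
        if scale == "arithmetic":
            return sum(w * v for w, v in zip(norm, values))
        import math

        return math.exp(sum(w * math.log(v) for w, v in zip(norm, values)))

    or_c = _mean([a.or_per_sd for a in assocs])
    lo = _mean([a.ci_lower for a in assocs])
    hi = _mean([a.ci_upper for a in assocs])
    members = ", ".join(
        f"{a.disease_name}:{w:.6g}" for a, w in zip(assocs, norm)
    )
    direction = assocs[0].direction
    return HarmonizedAssociation(
        disease_name=name or " + ".join(a.disease_name for a in assocs),
        or_per_sd=or_c,
        ci_lower=lo,
        ci_upper=hi,
        direction=direction,
        source=";".join(sorted({a.source for a in assocs if a.source})),
        significant=all(a.significant for a in assocs),
        harmonized_to=direction,
        provenance=(f"collapsed[{scale}]({members})",),
    )


def filter_significant(
    assocs: Iterable[DiseaseAssociation],
) -> tuple[list[DiseaseAssociation], list[DiseaseAssociation]]:
    """Split associations into (kept, dropped) on the significance flag.

    Only statistically significant ORs enter the attribution; the drop is a
    visible pipeline step with a logged count.
    """
    kept, dropped = [], []
    for a in assocs:
        (kept if a.significant else dropped).append(a)
    if dropped:
        logger.info(
            "significance filter dropped %d of %d associations: %s",
            len(dropped),
            len(dropped) + len(kept),
            ", ".join(a.disease_name for a in dropped),
        )
    return kept, dropped
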