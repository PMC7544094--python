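"""telburden: population burden attribution for genetically predicted
telomere length (gTL).

Converts MR odds ratios of disease per SD of gTL and registry burden rates
(age-standardized incidence and DALYs per 100,000) into the excess burden
statistic (OR − 1) × rate, with direction harmonization, disease-definition
allocation, sensitivity subtraction, and LD-threshold counting of independent
telomere-length-associated variants.
"""

from .tables_io import (
    DALY,
    INCIDENCE,
    PER_SD_LONGER,
    PER_SD_SHORTER,
    BurdenEstimate,
    DiseaseAssociation,
    LDMatrix,
    SNPRecord,
    TableFormatError,
    ValidationError,
)
from .harmonization import (
    HarmonizedAssociation,
    collapse_ors,
    filter_significant,
    invert_or,
    normalize_direction,
)
from .definition_mapping import (
    CaseFraction,
    allocate,
    case_fraction,
    subtract_subcondition,
)
from .burden_attribution import (
    AttributionReport,
    ExcessBurden,
    attribute,
    excess,
    total_excess,
)
from .ld_analysis import (
    LDThresholdConfig,
    VariantCluster,
    build_ld_graph,
    cluster_variants,
    summarize_snp_panel,
)
from .synthetic_data import (
    SyntheticLDConfig,
    SyntheticStudyConfig,
    simulate_ld,
    simulate_study,
)
from . import datasets

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def reproduce_study(study: str = "haycock") -> AttributionReport:
    """Run the full attribution on a bundled study fixture.

    Applies the significance filter, harmonizes each disease group to its
    risk-increasing direction, and attributes excess incidence and DALYs.
    CI bounds come from the OR CIs where the study prints them, otherwise
    from the burden-rate CIs.
    """
    assocs = datasets.load_associations(study)
    kept, _dropped = filter_significant(assocs)
    harmonized: list[HarmonizedAssociation] = []
    for direction in (PER_SD_LONGER, PER_SD_SHORTER):
        group = [a for a in kept if a.direction == direction]
        harmonized.extend(normalize_direction(group, direction))
    return attribute(harmonized, datasets.load_burdens(study), ci_source="auto")
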