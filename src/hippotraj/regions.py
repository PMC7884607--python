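"""Fixed region registry shared by every stage of the pipeline.

Volumes are bilateral, in mm^3.  The 13 hippocampal subfields follow the
FreeSurfer 6.0 ex-vivo probabilistic atlas nomenclature (head/body splits
for the subicular complex and CA fields, plus GC-ML-DG, molecular layer
and HATA).  Control regions are neighbouring medial temporal structures
used to check that genotype effects are hippocampus-specific.
"""

from __future__ import annotations

WHOLE_HIPPOCAMPUS = "whole_hippocampus"
TOTAL_GREY_MATTER = "total_grey_matter"

SUBFIELDS: tuple[str, ...] = (
    "parasubiculum",
    "presubiculum_head",
    "presubiculum_body",
    "subiculum_head",
    "subiculum_body",
    "CA1_head",
    "CA1_body",
    "CA3_head",
    "CA3_body",
    "CA4",
    "GC_ML_DG",
    "molecular_layer",
    "HATA",
)

CONTROL_REGIONS: tuple[str, ...] = (
    "superior_temporal",
    "middle_temporal",
    "inferior_temporal",
    "fusiform",
    "parahippocampal",
    "temporal_pole",
)

#: hippocampal regions = whole structure + subfields (carry the genotype effect)
HIPPOCAMPAL_REGIONS: tuple[str, ...] = (WHOLE_HIPPOCAMPUS,) + SUBFIELDS

#: every volume column a participant table must carry
ALL_REGIONS: tuple[str, ...] = (
    HIPPOCAMPAL_REGIONS + (TOTAL_GREY_MATTER,) + CONTROL_REGIONS
)

CONFOUND_COLUMNS: tuple[str, ...] = ("scan_date", "table_position", "head_size")

#: non-volume columns of a participant table, in canonical order
META_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "age",
    "sex",
    "apoe",
    "excluded_flag",
) + CONFOUND_COLUMNS

SEX_LEVELS: tuple[str, ...] = ("female", "male")
APOE_LEVELS: tuple[str, ...] = ("e3/e3", "e3/e4", "e4/e4", "neither")


def validate_region(region: str) -> str:
    """Return *region* unchanged, raising ``KeyError`` if unregistered."""
    if region not in ALL_REGIONS:
        raise KeyError(
            f"unknown region {region!r}; registered regions: {', '.join(ALL_REGIONS)}"
        )
    return region
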