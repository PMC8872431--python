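"""Cohort schema: column names, vocabularies, and the fixed resource ordering.

A cohort is a :class:`pandas.DataFrame` with one row per in-patient visit.
The outcome resource is a CT scan of the pelvis/abdomen without contrast;
the seven competing resources are the alternative imaging modalities used
during the same visit.  The resource ordering is fixed (alphabetical) so
that seven-digit usage bitstrings are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Fixed alphabetical ordering of the seven competing imaging resources.
RESOURCES: tuple[str, ...] = (
    "ct_other",
    "miscellaneous",
    "mri_mra",
    "nuclear_medicine",
    "special_imaging",
    "ultrasound",
    "xray",
)

N_RESOURCES = len(RESOURCES)
N_POSSIBLE_PATTERNS = 2 ** N_RESOURCES  # 128 joint usage combinations

OUTCOME = "outcome_used"

ID_COLUMNS = ("visit_id", "patient_id", "facility_id", "discharge_date")

#: patient-level binary flags present in the reduced default schema
DEFAULT_FLAGS: tuple[str, ...] = (
    "icd_principal",
    "malignancy_history",
    "cm_congestive_heart_failure",
    "cm_fluid_electrolyte",
    "cm_hypertension_uncomplicated",
    "cm_metastatic_cancer",
    "cm_renal_failure",
)

#: categorical patient variables in the reduced default schema
DEFAULT_CATEGORICALS: tuple[str, ...] = ("age_group", "race", "payor", "discharge_status")

#: continuous covariates
DEFAULT_CONTINUOUS: tuple[str, ...] = ("los_days",)


@dataclass
class CohortSchema:
    """Declares the columns of a visit-level table and their roles.

    ``categoricals`` maps each categorical variable to its declared
    vocabulary (order defines display order; unknown values read from a
    CSV are preserved as their own level).  ``model_categoricals`` lists
    the categoricals entering the patient-level covariate set; collapsing
    may remove discharge_status levels etc. before modelling.
    """

    resources: tuple[str, ...] = RESOURCES
    outcome: str = OUTCOME
    flags: tuple[str, ...] = DEFAULT_FLAGS
    categoricals: dict[str, list[str]] = field(default_factory=dict)
    model_categoricals: tuple[str, ...] = ("age_group", "race", "payor")
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.categoricals:
            self.categoricals = default_vocabularies()
        if not self.reference_levels:
            self.reference_levels = default_reference_levels(self.categoricals)

    @property
    def bit_columns(self) -> tuple[str, ...]:
        return (self.outcome,) + tuple(self.resources) + tuple(self.flags)

    @property
    def columns(self) -> list[str]:
        return (
            list(ID_COLUMNS)
            + [self.outcome]
            + list(self.resources)
            + list(self.categoricals)
            + list(self.flags)
            + list(self.continuous)
        )


def default_vocabularies() -> dict[str, list[str]]:
    return {
        "age_group": [
            "<=45", "46-50", "51-55", "56-60", "61-65",
            "66-70", "71-75", "76-80", "81-85", ">85",
        ],
        "race": [
            "american_indian", "asian", "black", "pacific_islander",
            "unknown", "white", "other",
        ],
        "payor": [
            "charity", "indigent", "commercial_indemnity", "direct_employer",
            "managed_care_capitated", "managed_care_noncapitated",
            "medicaid_mc_capitated", "medicaid_mc_noncapitated",
            "medicaid_traditional", "medicare_mc_capitated",
            "medicare_mc_noncapitated", "medicare_traditional",
            "other_government", "self_pay", "workers_comp", "other",
        ],
        "discharge_status": [
            "home", "home_health", "snf", "expired", "hospice_home",
            "rehab_facility", "hospice_facility", "other_facility",
            "ltch", "ama", "icf", "swing_bed", "court_law", "other",
        ],
    }


def default_reference_levels(categoricals: dict[str, list[str]]) -> dict[str, str]:
    """White and Medicare Traditional are the conventional reference groups
    for race/payor comparisons; other variables default to their first level
    (overridden to the modal level at design-matrix time when data are
    available)."""
    refs = {}
    for var, levels in categoricals.items():
        refs[var] = levels[0]
    if "race" in categoricals:
        refs["race"] = "white"
    if "payor" in categoricals:
        refs["payor"] = "medicare_traditional"
    return refs


def pattern_string(bits) -> str:
    """Seven-character bitstring over the fixed resource ordering."""
    return "".join("1" if int(b) else "0" for b in bits)
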