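"""Reading visit-level tables, category collapsing, design matrices and
descriptive statistics.

Collapsing mirrors common administrative-data practice: rare payor types
merged, low-count adjacent age groups pooled, discharge-status levels below
a share threshold sent to 'other', and comorbidity flags / MS-DRGs below a
visit-count floor removed from the covariate set (MS-DRGs pooled into a
catch-all level instead of dropped as rows).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .schema import CohortSchema, ID_COLUMNS


class SchemaError(ValueError):
    """A mandatory column is missing or mistyped."""


class DesignError(ValueError):
    """The design matrix is rank deficient after collapsing."""


def percent(count: int, n: int) -> float:
    """Share of the cohort as a percentage, rounded to 2 decimals."""
    return round(100.0 * count / n, 2)


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------

def read_cohort(path, schema: CohortSchema | None = None) -> pd.DataFrame:
    """Read a visit-level CSV into a typed cohort table.

    Unknown categorical values are preserved as their own level; binary
    columns must be strictly 0/1 and errors name the offending row.
    """
    schema = schema or CohortSchema()
    cohort = pd.read_csv(path, dtype={c: str for c in ID_COLUMNS})
    mandatory = ["visit_id", "patient_id", "facility_id", schema.outcome, *schema.resources]
    missing = [c for c in mandatory if c not in cohort.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    for col in schema.bit_columns:
        if col not in cohort.columns:
            continue
        vals = pd.to_numeric(cohort[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"column {col!r} must be binary 0/1; bad value {cohort[col].iloc[row]!r} "
                f"at row {row}"
            )
        cohort[col] = vals.astype(int)
    for col in schema.continuous:
        if col in cohort.columns:
            cohort[col] = pd.to_numeric(cohort[col])
            if (cohort[col] < 0).any():
                row = int(np.flatnonzero((cohort[col] < 0).to_numpy())[0])
                raise ValueError(f"column {col!r} must be non-negative; bad row {row}")
    return cohort


def deduplicate_first_visit(cohort: pd.DataFrame) -> pd.DataFrame:
    """Keep each patient's earliest visit (ties broken by smallest visit_id)."""
    if "discharge_date" not in cohort.columns:
        raise SchemaError("discharge_date required for deduplication")
    order = cohort.sort_values(
        ["patient_id", "discharge_date", "visit_id"], kind="stable"
    )
    return order.drop_duplicates("patient_id", keep="first").sort_index()


# ----------------------------------------------------------------------
# collapsing
# ----------------------------------------------------------------------

@dataclass
class CollapseRules:
    """Category-collapsing thresholds.

    * ``payor_merge``: payor levels merged into one named level.
    * ``age_merge_max``: age-group levels whose whole range lies at or
      below this bound are pooled into one ``<=bound`` level.
    * ``discharge_min_share``: discharge-status levels with strictly less
      than this share of visits move to 'other'.
    * ``flag_min_count``: comorbidity flags (and MS-DRG levels) need at
      least this many visits to stay in the covariate set.
    """

    payor_merge: frozenset = frozenset({"charity", "indigent"})
    payor_merge_label: str = "charity_or_indigent"
    age_merge_max: int = 45
    discharge_min_share: float = 0.001
    flag_min_count: int = 500
    drg_other_label: str = "other"

    def __post_init__(self) -> None:
        if not 0 < self.discharge_min_share < 1:
            raise ValueError("discharge_min_share must be in (0,1)")
        if self.flag_min_count < 1:
            raise ValueError("flag_min_count must be >= 1")


def _age_upper_bound(level: str) -> float:
    """Upper age of a level like '<=45', '46-50', '>85'."""
    level = level.strip()
    if level.startswith("<="):
        return float(level[2:])
    if level.startswith(">"):
        return float("inf")
    m = re.match(r"^(\d+)\s*-\s*(\d+)$", level)
    if m:
        return float(m.group(2))
    return float("inf")


def collapse_categories(
    cohort: pd.DataFrame,
    rules: CollapseRules | None = None,
    schema: CohortSchema | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the collapsing rules; returns the collapsed cohort and a report
    listing every merge and drop.  Idempotent."""
    rules = rules or CollapseRules()
    schema = schema or CohortSchema()
    out = cohort.copy()
    report: dict = {"payor_merged": [], "age_merged": [], "discharge_merged": [],
                    "flags_dropped": [], "drg_pooled": []}

    if "payor" in out.columns:
        present = sorted(set(out["payor"]) & set(rules.payor_merge))
        if present:
            out.loc[out["payor"].isin(rules.payor_merge), "payor"] = rules.payor_merge_label
            report["payor_merged"] = present

    if "age_group" in out.columns:
        merged_label = f"<={rules.age_merge_max}"
        to_merge = [
            lvl for lvl in out["age_group"].unique()
            if _age_upper_bound(lvl) <= rules.age_merge_max and lvl != merged_label
        ]
        if to_merge:
            out.loc[out["age_group"].isin(to_merge), "age_group"] = merged_label
            report["age_merged"] = sorted(to_merge)

    if "discharge_status" in out.columns:
        shares = out["discharge_status"].value_counts(normalize=True)
        low = sorted(lvl for lvl, s in shares.items()
                     if s < rules.discharge_min_share and lvl != "other")
        if low:
            out.loc[out["discharge_status"].isin(low), "discharge_status"] = "other"
            report["discharge_merged"] = low

    for flag in schema.flags:
        if flag in out.columns and flag.startswith("cm_"):
            if int(out[flag].sum()) < rules.flag_min_count:
                out = out.drop(columns=flag)
                report["flags_dropped"].append(flag)

    if "ms_drg" in out.columns:
        counts = out["ms_drg"].value_counts()
        low = sorted(lvl for lvl, c in counts.items()
                     if c < rules.flag_min_count and lvl != rules.drg_other_label)
        if low:
            out.loc[out["ms_drg"].isin(low), "ms_drg"] = rules.drg_other_label
            report["drg_pooled"] = low

    return out, report


# ----------------------------------------------------------------------
# design matrices
# ----------------------------------------------------------------------

COVARIATE_SETS = ("a", "b", "c")  # a: patient+resources, b: patient, c: resources


@dataclass
class DesignMatrix:
    """Dummy-coded design with an explicit intercept column.

    ``data`` holds one float column per term ('intercept', 'var=level'
    dummies, flag and resource bits, continuous terms).
    """

    data: pd.DataFrame
    covariate_set: str
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    dependent = piv[len(diag[diag > tol]):]
    return [names[j] for j in sorted(dependent)]


def build_design(
    cohort: pd.DataFrame,
    covariate_set: str = "a",
    schema: CohortSchema | None = None,
    include_los: bool = True,
) -> DesignMatrix:
    """Build the dummy-coded design for covariate set a, b or c.

    Reference levels: race=white, payor=medicare_traditional (when those
    levels are present), otherwise the modal level of each variable.  Set
    (c) is the seven competing-resource bits plus the intercept.
    """
    schema = schema or CohortSchema()
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(f"covariate_set must be one of {COVARIATE_SETS}")
    n = len(cohort)
    parts = [pd.Series(1.0, index=cohort.index, name="intercept")]
    references: dict[str, str] = {}

    if covariate_set in ("b", "a"):
        for var in schema.model_categoricals:
            if var not in cohort.columns:
                continue
            counts = cohort[var].value_counts()
            ref = schema.reference_levels.get(var)
            if ref not in counts.index:
                ref = counts.index[0]  # modal level
            references[var] = ref
            for level in sorted(counts.index):
                if level == ref:
                    continue
                parts.append(
                    (cohort[var] == level).astype(float).rename(f"{var}={level}")
                )
        for flag in schema.flags:
            if flag in cohort.columns:
                parts.append(cohort[flag].astype(float).rename(flag))
        if include_los:
            for col in schema.continuous:
                if col in cohort.columns:
                    parts.append(cohort[col].astype(float).rename(col))

    if covariate_set in ("a", "c"):
        for r in schema.resources:
            parts.append(cohort[r].astype(float).rename(r))

    data = pd.concat(parts, axis=1)
    X = data.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, list(data.columns))
        raise DesignError(f"design matrix rank deficient; aliased columns: {aliased}")
    assert len(data) == n
    return DesignMatrix(data=data, covariate_set=covariate_set, reference_levels=references)


# ----------------------------------------------------------------------
# descriptive statistics
# ----------------------------------------------------------------------

def descriptive_stats(cohort: pd.DataFrame, schema: CohortSchema | None = None) -> pd.DataFrame:
    """Counts and percentages per level for categorical/binary variables and
    mean (sd) for continuous ones, in display order."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    schema = schema or CohortSchema()
    n = len(cohort)
    rows = []
    for col in schema.continuous:
        if col in cohort.columns:
            rows.append({
                "variable": col, "level": "", "count": np.nan, "percent": np.nan,
                "mean": round(float(cohort[col].mean()), 2),
                "sd": round(float(cohort[col].std()), 2),
            })
    for var in schema.categoricals:
        if var not in cohort.columns:
            continue
        counts = cohort[var].value_counts()
        declared = [l for l in schema.categoricals[var] if l in counts.index]
        extra = sorted(set(counts.index) - set(declared))
        for level in declared + extra:
            c = int(counts[level])
            rows.append({"variable": var, "level": level, "count": c,
                         "percent": percent(c, n), "mean": np.nan, "sd": np.nan})
    for col in (*schema.flags, *schema.resources, schema.outcome):
        if col in cohort.columns:
            c = int(cohort[col].sum())
            rows.append({"variable": col, "level": "1", "count": c,
                         "percent": percent(c, n), "mean": np.nan, "sd": np.nan})
    return pd.DataFrame(rows)
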