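"""Disparities in misutilization across patient characteristics.

For each non-reference level of a characteristic, the odds ratio of being
labelled under- (or over-) utilized relative to the reference level, from
a logistic regression of the label indicator on the characteristic's
dummies (unadjusted by default; all visits form the denominator for both
label kinds so the two ORs are directly comparable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

Z975 = float(norm.ppf(0.975))


@dataclass
class OddsRatioRow:
    characteristic: str
    level: str
    reference: str
    outcome_kind: str  # {"under", "over"}
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    defined: bool = True


def _fit_or_rows(
    response: np.ndarray,
    values: pd.Series,
    characteristic: str,
    reference: str,
    kind: str,
    extra: pd.DataFrame | None = None,
) -> list[OddsRatioRow]:
    levels = sorted(values.unique())
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")
    events_by_level = pd.Series(response).groupby(values.to_numpy()).sum()
    sizes = values.value_counts()
    degenerate = {
        lvl for lvl in levels
        if events_by_level.get(lvl, 0) in (0, sizes[lvl])
    }
    fit_levels = [l for l in levels if l != reference and l not in degenerate]

    X = pd.DataFrame({"intercept": np.ones(len(values))}, index=values.index)
    for lvl in fit_levels:
        X[f"{characteristic}={lvl}"] = (values == lvl).astype(float)
    if extra is not None:
        X = pd.concat([X, extra], axis=1)
    keep = ~values.isin(degenerate - {reference})
    res = sm.GLM(
        response[keep.to_numpy()], X.loc[keep].to_numpy(), family=sm.families.Binomial()
    ).fit(maxiter=200, tol=1e-10)
    cols = list(X.columns)

    rows = []
    for lvl in levels:
        if lvl == reference:
            continue
        if lvl in degenerate:
            rows.append(OddsRatioRow(
                characteristic, lvl, reference, kind,
                odds_ratio=float("nan"), ci95=(float("nan"), float("nan")),
                p=float("nan"), defined=False,
            ))
            continue
        j = cols.index(f"{characteristic}={lvl}")
        beta = float(res.params[j])
        se = float(res.bse[j])
        z = beta / se if se > 0 else float("inf")
        rows.append(OddsRatioRow(
            characteristic, lvl, reference, kind,
            odds_ratio=float(np.exp(beta)),
            ci95=(float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se))),
            p=float(2 * norm.sf(abs(z))),
        ))
    return rows


def misuse_odds_ratios(
    labels,
    cohort: pd.DataFrame,
    characteristic: str,
    reference_level: str,
    kinds: tuple[str, ...] = ("under", "over"),
    adjust_columns: list[str] | None = None,
) -> list[OddsRatioRow]:
    """Odds ratios of under-/over-utilization by level of a characteristic.

    Levels with zero (or all) events produce flagged rows with undefined
    CIs rather than raising.  ``adjust_columns`` optionally adds further
    dummy/flag columns of the cohort to the model (adjusted variant).
    """
    if characteristic not in cohort.columns:
        raise ValueError(f"characteristic {characteristic!r} not in cohort")
    labels = np.asarray(labels)
    values = cohort[characteristic].astype(str)
    extra = None
    if adjust_columns:
        extra = pd.get_dummies(
            cohort[adjust_columns], drop_first=True, dtype=float
        )
    rows: list[OddsRatioRow] = []
    for kind in kinds:
        response = (labels == kind).astype(float)
        rows.extend(_fit_or_rows(response, values, characteristic,
                                 reference_level, kind, extra))
    return rows


def odds_ratio_table(rows: list[OddsRatioRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "characteristic": r.characteristic, "level": r.level,
        "reference": r.reference, "outcome_kind": r.outcome_kind,
        "odds_ratio": r.odds_ratio, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
        "p": r.p, "defined": r.defined,
    } for r in rows])


def forest_data(rows: list[OddsRatioRow]) -> pd.DataFrame:
    """Log-odds-ratio coordinates for a forest plot; the reference level sits
    at 0 with no interval."""
    if not rows:
        raise ValueError("need at least one odds-ratio row")
    out = []
    seen_ref = set()
    for r in rows:
        key = (r.characteristic, r.outcome_kind)
        if key not in seen_ref:
            out.append({
                "characteristic": r.characteristic, "outcome_kind": r.outcome_kind,
                "level": r.reference, "log_or": 0.0,
                "lo": float("nan"), "hi": float("nan"), "reference": True,
            })
            seen_ref.add(key)
        out.append({
            "characteristic": r.characteristic, "outcome_kind": r.outcome_kind,
            "level": r.level, "log_or": float(np.log(r.odds_ratio)),
            "lo": float(np.log(r.ci95[0])), "hi": float(np.log(r.ci95[1])),
            "reference": False,
        })
    return pd.DataFrame(out)
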