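"""Facility profiling: volume-adjusted outlier detection and rankings.

Under the null that every facility misutilizes at a common per-visit rate,
each facility's misutilization count is Poisson with mean (pooled rate x
volume).  Facilities whose exact one-sided upper-tail p-value falls below
alpha depart substantially from industry-standard practice.  The exact
Poisson tail stays valid at small volumes, where a per-facility Wald
approximation would not be.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

KINDS = ("mis", "over", "under")


def facility_rates(labels, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-facility volumes, misutilization counts and rates.

    Returns one row per facility with columns volume, {kind}_count and
    {kind}_rate for kind in mis/over/under.
    """
    labels = np.asarray(labels)
    df = pd.DataFrame({
        "facility_id": cohort["facility_id"].to_numpy(),
        "over": (labels == "over").astype(int),
        "under": (labels == "under").astype(int),
    })
    g = df.groupby("facility_id", sort=True)
    profiles = pd.DataFrame({
        "volume": g.size(),
        "over_count": g["over"].sum(),
        "under_count": g["under"].sum(),
    })
    profiles["mis_count"] = profiles["over_count"] + profiles["under_count"]
    for kind in KINDS:
        profiles[f"{kind}_rate"] = profiles[f"{kind}_count"] / profiles["volume"]
    return profiles.reset_index()


def profiles_from_counts(
    facility_id, volume, mis_count=None, over_count=None, under_count=None
) -> pd.DataFrame:
    """Build a profile table directly from per-facility counts (e.g. for
    simulation studies of the flagging procedure)."""
    profiles = pd.DataFrame({
        "facility_id": facility_id,
        "volume": np.asarray(volume, dtype=int),
    })
    over = np.zeros(len(profiles), dtype=int) if over_count is None else np.asarray(over_count)
    under = np.zeros(len(profiles), dtype=int) if under_count is None else np.asarray(under_count)
    mis = over + under if mis_count is None else np.asarray(mis_count)
    profiles["over_count"] = over
    profiles["under_count"] = under
    profiles["mis_count"] = mis
    for kind in KINDS:
        profiles[f"{kind}_rate"] = profiles[f"{kind}_count"] / profiles["volume"]
    return profiles


def pooled_rate(profiles: pd.DataFrame, kind: str) -> float:
    """Common events-per-visit rate: sum of counts over sum of volumes — the
    Poisson MLE of an intercept-only rate model with volume exposure."""
    total_volume = profiles["volume"].sum()
    if total_volume <= 0:
        raise ValueError("total volume is zero")
    return float(profiles[f"{kind}_count"].sum() / total_volume)


def poisson_upper_p(c, mean):
    """Exact one-sided P(X >= c) for X ~ Poisson(mean), via the upper
    regularized incomplete gamma function (stable for large means)."""
    c = np.asarray(c)
    if (c < 0).any():
        raise ValueError("c must be non-negative")
    if not np.issubdtype(c.dtype, np.integer) and not np.allclose(c, np.round(c)):
        raise ValueError("c must be integer-valued")
    out = stats.poisson.sf(np.asarray(np.round(c), dtype=int) - 1, mean)
    return float(out) if out.ndim == 0 else out


def add_expected_and_p(
    profiles: pd.DataFrame, leave_one_out: bool = False
) -> pd.DataFrame:
    """Attach expected counts (pooled rate x volume) and one-sided upper-tail
    p-values per kind.  ``leave_one_out`` excludes each facility from its
    own pooled rate."""
    out = profiles.copy()
    for kind in KINDS:
        counts = out[f"{kind}_count"].to_numpy()
        volumes = out["volume"].to_numpy()
        if leave_one_out:
            tot_c, tot_v = counts.sum(), volumes.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                lam = (tot_c - counts) / (tot_v - volumes)
        else:
            lam = pooled_rate(out, kind)
        expected = lam * volumes
        out[f"{kind}_expected"] = expected
        out[f"{kind}_p"] = poisson_upper_p(counts, np.maximum(expected, 1e-300))
    return out


def flag_facilities(
    profiles: pd.DataFrame, alpha: float = 0.01, method: str = "raw"
) -> dict[str, pd.DataFrame]:
    """Flag and rank outlying facilities per kind at the given level.

    ``method="raw"`` flags strict p < alpha (no multiplicity correction);
    ``method="bh"`` applies Benjamini-Hochberg across facilities instead.
    Ranking is deterministic: p ascending, rate descending, facility_id.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if not {f"{k}_p" for k in KINDS} <= set(profiles.columns):
        profiles = add_expected_and_p(profiles)
    flagged = {}
    for kind in KINDS:
        p = profiles[f"{kind}_p"].to_numpy()
        if method == "raw":
            keep = p < alpha
        elif method == "bh":
            m = len(p)
            order = np.argsort(p, kind="stable")
            thresh = alpha * (np.arange(1, m + 1)) / m
            passed = p[order] <= thresh
            keep = np.zeros(m, dtype=bool)
            if passed.any():
                cutoff = np.max(np.flatnonzero(passed))
                keep[order[: cutoff + 1]] = True
        else:
            raise ValueError("method must be 'raw' or 'bh'")
        sub = profiles.loc[keep].copy()
        sub["rank_p"] = sub[f"{kind}_p"]
        sub = sub.sort_values(
            ["rank_p", f"{kind}_rate", "facility_id"],
            ascending=[True, False, True], kind="stable",
        ).drop(columns="rank_p")
        flagged[kind] = sub.reset_index(drop=True)
    return flagged


def bubble_data(profiles: pd.DataFrame, kind: str, alpha: float = 0.01) -> pd.DataFrame:
    """Actual vs expected counts and log volume for flagged facilities."""
    flagged = flag_facilities(profiles, alpha)[kind]
    return pd.DataFrame({
        "facility_id": flagged["facility_id"],
        "actual": flagged[f"{kind}_count"],
        "expected": flagged[f"{kind}_expected"],
        "log_volume": np.log(flagged["volume"].to_numpy(dtype=float)),
    })


@dataclass
class VolumeRegression:
    outcome_kind: str
    slope: float      # change in rate (percentage points) per unit ln(volume)
    intercept: float
    p: float
    n_facilities: int


def volume_regression(profiles: pd.DataFrame, kind: str) -> VolumeRegression:
    """OLS of the facility rate (in percent) on ln(volume), unweighted."""
    sub = profiles[profiles["volume"] >= 1]
    if len(sub) < 3:
        raise ValueError("need at least 3 facilities")
    x = np.log(sub["volume"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("volumes are constant; slope undefined")
    y = sub[f"{kind}_rate"].to_numpy(dtype=float) * 100.0
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return VolumeRegression(
        outcome_kind=kind,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p=float(res.pvalues[1]),
        n_facilities=len(sub),
    )


def extreme_tables(
    profiles: pd.DataFrame, min_volume: int = 30, k: int = 10
) -> dict[str, dict[str, pd.DataFrame]]:
    """Top-k and bottom-k facilities by rate per kind, among facilities with
    at least ``min_volume`` visits.  Ties break by volume descending, then
    facility_id; the bottom table admits 0% rates."""
    eligible = profiles[profiles["volume"] >= min_volume]
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for kind in KINDS:
        ranked_top = eligible.sort_values(
            [f"{kind}_rate", "volume", "facility_id"],
            ascending=[False, False, True], kind="stable",
        )
        ranked_bot = eligible.sort_values(
            [f"{kind}_rate", "volume", "facility_id"],
            ascending=[True, False, True], kind="stable",
        )
        out[kind] = {
            "top": ranked_top.head(k).reset_index(drop=True),
            "bottom": ranked_bot.head(k).reset_index(drop=True),
        }
    return out
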