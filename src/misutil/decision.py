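"""Decision-curve analysis, threshold calibration, and per-visit
misutilization labels.

Net benefit at probability threshold t weighs true positives against false
positives at the exchange rate t/(1-t): flagging a visit as
"expected use" is worth it only if the harm of a false flag is t/(1-t)
times the value of a true one.  The operating threshold is calibrated so
that the share of visits flagged as expected use matches the observed
industry-wide utilization intensity; a visit then counts as over-utilized
when the resource was used despite a fitted probability below the
threshold, and under-utilized when it was not used despite a probability
at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABELS = ("concordant_used", "concordant_unused", "over", "under")


class CalibrationError(RuntimeError):
    pass


def default_grid() -> np.ndarray:
    """Probability thresholds in 0.001 steps over (0, 0.99]."""
    return np.round(np.arange(1, 991) * 0.001, 3)


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float
    positive_range: tuple[float, float] | None
    value_add_range: tuple[float, float] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "nb_model": self.nb_model,
            "nb_all": self.nb_all,
            "nb_none": self.nb_none,
        })


def _counts_at(p_hat_sorted: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Number of values >= each threshold given an ascending-sorted array."""
    idx = np.searchsorted(p_hat_sorted, thresholds, side="left")
    return len(p_hat_sorted) - idx


def net_benefit_curve(p_hat, outcome, grid: np.ndarray | None = None) -> DecisionCurve:
    """Net benefit of flagging visits with fitted probability >= t, against
    treat-all and treat-none comparators, over a threshold grid.

    nb_model(t) = TP(t)/n - FP(t)/n * t/(1-t); nb_all is the same with every
    visit flagged; nb_none is identically 0.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("threshold grid must lie inside (0, 1)")
    n = len(y)
    prev = y.mean()
    odds = grid / (1.0 - grid)
    pos = np.sort(p_hat[y == 1])
    neg = np.sort(p_hat[y == 0])
    tp = _counts_at(pos, grid)
    fp = _counts_at(neg, grid)
    nb_model = tp / n - fp / n * odds
    nb_all = prev - (1.0 - prev) * odds
    nb_none = np.zeros_like(grid)

    def _range(mask: np.ndarray):
        if not mask.any():
            return None
        ts = grid[mask]
        return (float(ts.min()), float(ts.max()))

    return DecisionCurve(
        thresholds=grid,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=nb_none,
        prevalence=float(prev),
        positive_range=_range(nb_model > 0),
        value_add_range=_range((nb_model > nb_all) & (nb_model > 0)),
    )


def threshold_odds(t: float) -> float:
    """Cost:benefit odds implied by a probability threshold: t/(1-t).
    A threshold of 0.20 corresponds to 1:4 (cost of a missed flag is a
    quarter of the benefit of a correct one)."""
    if not 0 < t < 1:
        raise ValueError("threshold must be strictly inside (0, 1)")
    return t / (1.0 - t)


def flagged_rate(p_hat, t: float) -> float:
    """Share of visits flagged as expected use (p_hat >= t)."""
    return float(np.mean(np.asarray(p_hat, dtype=float) >= t))


def calibrate_threshold(p_hat, outcome, curve: DecisionCurve) -> tuple[float, dict]:
    """Choose the grid threshold, within the value-adding range of the
    decision curve, whose flagged rate best matches the observed
    utilization intensity (cohort prevalence); ties go to the smaller t.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(outcome, dtype=int)
    mask = (curve.nb_model > curve.nb_all) & (curve.nb_model > 0)
    if not mask.any():
        raise CalibrationError(
            "the model adds no net benefit over treat-all/treat-none on the grid; "
            "set a threshold manually"
        )
    candidates = curve.thresholds[mask]
    target = y.mean()
    sorted_p = np.sort(p_hat)
    rates = _counts_at(sorted_p, candidates) / len(p_hat)
    i = int(np.argmin(np.abs(rates - target)))  # first minimum = smallest t
    t = float(candidates[i])
    report = {
        "threshold": t,
        "flagged_rate": float(rates[i]),
        "target_rate": float(target),
        "cost_benefit_odds": threshold_odds(t),
        "value_add_range": curve.value_add_range,
    }
    return t, report


@dataclass
class MisutilizationSummary:
    n: int
    mis_rate: float
    over_rate: float
    under_rate: float
    over_share: float
    under_share: float
    flagged_rate: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def classify_visits(p_hat, outcome, t: float) -> tuple[np.ndarray, MisutilizationSummary]:
    """Label every visit and summarize misutilization.

    over: used but p_hat < t; under: unused but p_hat >= t; otherwise
    concordant.  A visit exactly at the threshold counts as expected use.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(outcome, dtype=int)
    expected = p_hat >= t
    labels = np.where(
        y == 1,
        np.where(expected, "concordant_used", "over"),
        np.where(expected, "under", "concordant_unused"),
    )
    n = len(y)
    over = int(np.sum(labels == "over"))
    under = int(np.sum(labels == "under"))
    mis = over + under
    summary = MisutilizationSummary(
        n=n,
        mis_rate=mis / n,
        over_rate=over / n,
        under_rate=under / n,
        over_share=over / mis if mis else float("nan"),
        under_share=under / mis if mis else float("nan"),
        flagged_rate=float(expected.mean()),
    )
    return labels, summary
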