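"""Utilization models: logistic regression, DeLong AUC machinery, joint
resource-usage patterns and tetrachoric correlations.

The binary outcome (use of the target imaging resource during a visit) is
risk-adjusted by maximum-likelihood logistic regression on one of three
covariate sets: (a) patient characteristics plus the seven competing
resources, (b) patient characteristics only, (c) competing resources only.
Discrimination is summarized by the AUC with DeLong structural-component
variance, and models are compared by the paired DeLong test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2_contingency, multivariate_normal, norm

from .ingest import DesignMatrix
from .schema import RESOURCES, CohortSchema, pattern_string

logger = logging.getLogger(__name__)

Z975 = float(norm.ppf(0.975))


class SeparationWarning(UserWarning):
    """A logistic coefficient is diverging (quasi-complete separation)."""


class ConvergenceError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# logistic fitting
# ----------------------------------------------------------------------

@dataclass
class FittedUtilizationModel:
    covariate_set: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    fitted_probabilities: np.ndarray
    log_likelihood: float
    converged: bool
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "covariate_set": self.covariate_set,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "reference_levels": self.reference_levels,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def predict(self, design: DesignMatrix) -> np.ndarray:
        beta = np.array([self.coefficients[c] for c in design.columns])
        eta = design.to_numpy() @ beta
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(design: DesignMatrix, outcome) -> FittedUtilizationModel:
    """Maximum-likelihood logistic fit (IRLS) with Wald standard errors.

    Near-separated fits (a coefficient past ±15) trigger a
    :class:`SeparationWarning` and a tiny-ridge refit for stability;
    non-convergence raises :class:`ConvergenceError`.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = design.to_numpy()
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own convergence chatter
        res = model.fit(maxiter=200, tol=1e-10)
    params = np.asarray(res.params)
    converged = bool(res.converged)
    if np.max(np.abs(params)) > 15:
        warnings.warn(
            "possible separation: a coefficient exceeds |15|; refitting with a "
            "ridge penalty of 1e-8",
            SeparationWarning,
            stacklevel=2,
        )
        reg = model.fit_regularized(alpha=1e-8, L1_wt=0.0)
        params = np.asarray(reg.params)
        mu = model.predict(params)
        W = mu * (1 - mu)
        cov = np.linalg.pinv((X * W[:, None]).T @ X)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        mu_fit = mu
        llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        converged = True
    elif not converged:
        raise ConvergenceError("IRLS failed to converge after 200 iterations")
    else:
        bse = np.asarray(res.bse)
        mu_fit = np.asarray(res.fittedvalues)
        llf = float(res.llf)
    cols = design.columns
    return FittedUtilizationModel(
        covariate_set=design.covariate_set,
        coefficients=dict(zip(cols, map(float, params))),
        standard_errors=dict(zip(cols, map(float, bse))),
        fitted_probabilities=mu_fit,
        log_likelihood=llf,
        converged=converged,
        reference_levels=dict(design.reference_levels),
    )


# ----------------------------------------------------------------------
# DeLong AUC
# ----------------------------------------------------------------------

@dataclass
class AucEstimate:
    auc: float
    variance: float
    ci95: tuple[float, float]


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (ties averaged), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """AUCs and structural components for k score vectors over one outcome.

    Returns (aucs (k,), V10 (k,m) event components, V01 (k,n) non-event
    components) following the midrank formulation of the DeLong estimator.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r in range(k):
        combined = np.concatenate([pos[r], neg[r]])
        tz = _midrank(combined)
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    return aucs, v10, v01


def _delong_cov(v10: np.ndarray, v01: np.ndarray) -> np.ndarray:
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if m > 1 else np.zeros((v10.shape[0],) * 2)
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if n > 1 else np.zeros((v01.shape[0],) * 2)
    return s10 / m + s01 / n


def auc_delong(p_hat, outcome) -> AucEstimate:
    """AUC (Mann-Whitney with ties counted 1/2) and DeLong variance with a
    normal 95% CI truncated to [0, 1]."""
    aucs, v10, v01 = _delong_components(np.asarray(p_hat, dtype=float), outcome)
    var = float(_delong_cov(v10, v01)[0, 0])
    auc = float(aucs[0])
    half = Z975 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return AucEstimate(auc=auc, variance=var, ci95=ci)


def compare_auc_delong(p_hat_a, p_hat_b, outcome):
    """Paired DeLong test for the AUC difference of two models evaluated on
    the same visits.  Returns (auc_diff, ci95, p_value)."""
    a = np.asarray(p_hat_a, dtype=float)
    b = np.asarray(p_hat_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("probability vectors must cover the same visits")
    aucs, v10, v01 = _delong_components(np.vstack([a, b]), outcome)
    S = _delong_cov(v10, v01)
    diff = float(aucs[0] - aucs[1])
    var = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    var = max(var, 0.0)
    if var == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        half = 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
        half = Z975 * np.sqrt(var)
    return diff, (diff - half, diff + half), p


# ----------------------------------------------------------------------
# joint usage patterns
# ----------------------------------------------------------------------

@dataclass
class PatternSummary:
    pattern: str
    count: int
    outcome_rate: float


def pattern_analysis(
    cohort: pd.DataFrame, schema: CohortSchema | None = None
) -> tuple[list[PatternSummary], float, int, float]:
    """Summarize the observed joint competing-resource usage patterns and
    test outcome-rate homogeneity across them.

    Returns (summaries, chi-square statistic, dof, p).  The dof counts
    observed patterns only (unobserved combinations are excluded); no
    continuity correction; expected counts below 5 are logged, not fatal.
    """
    schema = schema or CohortSchema()
    bits = cohort[list(schema.resources)].to_numpy(dtype=int)
    y = cohort[schema.outcome].to_numpy(dtype=int)
    codes = bits @ (1 << np.arange(len(schema.resources) - 1, -1, -1))
    df = pd.DataFrame({"code": codes, "y": y})
    grouped = df.groupby("code")["y"].agg(["size", "sum"])
    if len(grouped) < 2:
        raise ValueError("need at least 2 observed patterns")
    summaries = []
    width = len(schema.resources)
    for code, row in grouped.iterrows():
        summaries.append(PatternSummary(
            pattern=format(int(code), f"0{width}b"),
            count=int(row["size"]),
            outcome_rate=float(row["sum"] / row["size"]),
        ))
    observed = np.column_stack([grouped["sum"], grouped["size"] - grouped["sum"]])
    # patterns where the outcome never (or always) occurs still enter the table
    stat, p, dof, expected = chi2_contingency(observed, correction=False)
    if (expected < 5).any():
        logger.info(
            "chi-square: %d of %d cells have expected count < 5",
            int((expected < 5).sum()), expected.size,
        )
    return summaries, float(stat), int(dof), float(p)


# ----------------------------------------------------------------------
# tetrachoric correlations
# ----------------------------------------------------------------------

@dataclass
class TetrachoricEstimate:
    pair: tuple[str, str]
    rho: float
    table: np.ndarray  # table[i, j] = count(x=i, y=j)
    defined: bool = True


def tetrachoric_rho(table: np.ndarray) -> float:
    """ML tetrachoric correlation of a 2x2 table under the bivariate-normal
    liability model.  ``table[i, j]`` counts (x=i, y=j).  Thresholds come
    from the margins; rho maximizes the multinomial likelihood over
    [-0.999, 0.999].  NaN when a margin is empty."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 count matrix")
    n = t.sum()
    px0 = t[0].sum() / n  # P(x = 0)
    py0 = t[:, 0].sum() / n
    if px0 in (0.0, 1.0) or py0 in (0.0, 1.0):
        return float("nan")
    tau_x = norm.ppf(px0)
    tau_y = norm.ppf(py0)

    def neg_loglik(rho: float) -> float:
        p00 = multivariate_normal.cdf(
            [tau_x, tau_y], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        p01 = norm.cdf(tau_x) - p00
        p10 = norm.cdf(tau_y) - p00
        p11 = 1.0 - p00 - p01 - p10
        probs = np.clip([p00, p01, p10, p11], 1e-12, None)
        counts = np.array([t[0, 0], t[0, 1], t[1, 0], t[1, 1]])
        return -float(counts @ np.log(probs))

    res = minimize_scalar(neg_loglik, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def tetrachoric(
    cohort: pd.DataFrame, schema: CohortSchema | None = None
) -> list[TetrachoricEstimate]:
    """Tetrachoric correlations for all 21 competing-resource pairs plus the
    7 resource-outcome pairs.  Pairs with an empty margin are flagged
    undefined rather than raising."""
    schema = schema or CohortSchema()
    cols = list(schema.resources)
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    pairs += [(r, schema.outcome) for r in cols]
    out = []
    for a, b in pairs:
        x = cohort[a].to_numpy(dtype=int)
        y = cohort[b].to_numpy(dtype=int)
        table = np.zeros((2, 2))
        for i in (0, 1):
            for j in (0, 1):
                table[i, j] = np.sum((x == i) & (y == j))
        rho = tetrachoric_rho(table)
        out.append(TetrachoricEstimate(
            pair=(a, b), rho=rho, table=table, defined=bool(np.isfinite(rho))
        ))
    return out


def pattern_table(summaries: list[PatternSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pattern": s.pattern, "count": s.count, "outcome_rate": s.outcome_rate}
         for s in summaries]
    ).sort_values("pattern", ignore_index=True)


N_POSSIBLE_PATTERNS = 2 ** len(RESOURCES)
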