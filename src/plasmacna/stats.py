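"""Cohort-level statistics: association tests, rank statistics with a
censoring policy, and survival analysis.

Association between rrSCNA status and categorical outcomes uses the Pearson
chi-square test without continuity correction (Fisher's exact test is
available alongside).  Tumor fractions printed as "<3.0%" enter rank
statistics at a common value of 2.9 (ties, average ranks) and are excluded
from range reporting.  Survival uses Kaplan-Meier / log-rank and Cox
proportional hazards with Efron tie handling; multivariate models are pruned
by stepwise backward elimination at a removal threshold of 0.10.  All
p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

DEFAULT_CENSOR_VALUE = 2.9
DEFAULT_P_REMOVE = 0.10


class StatsInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatsInputError("need a non-negative 2x2 table")
    if t.sum() <= 0:
        raise StatsInputError("empty table")
    return t


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = 1.

    Identity: the statistic equals N (ad - bc)^2 / (r1 r2 c1 c2).
    """
    t = _as_2x2(table)
    if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        raise StatsInputError("zero margin in 2x2 table")
    stat, p, _, expected = sps.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise StatsInputError("expected cell count of zero")
    return float(stat), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p (hypergeometric tables as or more extreme)."""
    t = _as_2x2(table)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# rank statistics with the tumor-fraction censoring policy
# ---------------------------------------------------------------------------

def apply_censor_policy(values, censor_value: float = DEFAULT_CENSOR_VALUE) -> np.ndarray:
    """Map censored entries to a common numeric value below the threshold.

    Accepts floats, strings ("<3.0%", "4.5%") and
    :class:`~plasmacna.patients.TumorFractionValue` objects.
    """
    from .patients import TumorFractionValue

    out = []
    for v in values:
        if isinstance(v, TumorFractionValue):
            out.append(v.numeric(censor_value))
        elif isinstance(v, str):
            out.append(TumorFractionValue.parse(v).numeric(censor_value))
        else:
            out.append(float(v))
    return np.asarray(out)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U: exact when both groups are small and tie-free,
    otherwise the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsInputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y, censor_value: float = DEFAULT_CENSOR_VALUE) -> tuple[float, float]:
    """Spearman rank correlation with average ranks and the censoring policy.

    Censored entries in either vector share the value ``censor_value`` and
    hence a common (average) rank; p is from the t approximation.
    """
    xv = apply_censor_policy(x, censor_value)
    yv = apply_censor_policy(y, censor_value)
    if len(xv) != len(yv):
        raise StatsInputError("length mismatch")
    if len(xv) < 4:
        raise StatsInputError("need at least 4 pairs")
    res = sps.spearmanr(xv, yv)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event observation with covariates."""

    time: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise StatsInputError("survival time must be positive")


def _survival_frame(records, covariates=None) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [dict(time=r.time, event=int(r.event), **r.covariates) for r in records]
        )
    if covariates is not None:
        df = df[["time", "event", *covariates]]
    return df


@dataclass
class KMResult:
    median: float           # inf when the curve never reaches 0.5
    curve: pd.DataFrame     # columns: time, survival

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


def km_median(times, events) -> KMResult:
    """Product-limit survival curve and its median.

    The median is the earliest time at which S(t) <= 0.5; with no events, or
    a curve that never falls to 0.5, the median is undefined (inf).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    return KMResult(median, curve)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test (chi-square, df = 1)."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise StatsInputError("both groups must be non-empty")
    if not (np.any(events_a) or np.any(events_b)):
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs, and the retained covariate set."""

    table: pd.DataFrame       # index: covariate; columns: hr, ci_low, ci_high, p
    retained: tuple[str, ...]
    converged: bool
    log_likelihood: float
    model: CoxPHFitter | None = None

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])


def cox_fit(records, covariates: list[str]) -> CoxResult:
    """Cox proportional hazards fit (Efron ties, Wald inference).

    ``records`` is a DataFrame with ``time``/``event`` columns or a list of
    :class:`SurvivalRecord`.  Constant covariates are rejected; a
    non-converging fit is returned flagged, never silently.
    """
    df = _survival_frame(records, covariates)
    if df["event"].sum() == 0:
        raise StatsInputError("no events: Cox model is not identifiable")
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise StatsInputError(f"covariate {cov!r} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # tight precision: the partial-likelihood score at the optimum
            # should vanish to ~1e-6, not just to plotting accuracy
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-14})
    except ConvergenceError:
        empty = pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"])
        return CoxResult(empty, tuple(covariates), False, float("nan"))
    s = cph.summary
    table = pd.DataFrame({
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxResult(table, tuple(covariates), True, float(cph.log_likelihood_), cph)


def stepwise_backward(
    records, covariates: list[str], p_remove: float = DEFAULT_P_REMOVE
) -> CoxResult:
    """Backward elimination: drop the worst Wald p > ``p_remove`` until none.

    With every covariate removable the retained set may be empty; that is
    reported as an empty result, not an error.
    """
    current = list(covariates)
    result = cox_fit(records, current)
    while current:
        result = cox_fit(records, current)
        if not result.converged:
            return result
        worst = result.table["p"].idxmax()
        if result.table.loc[worst, "p"] <= p_remove:
            break
        current.remove(worst)
    if not current:
        empty = pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"])
        return CoxResult(empty, (), True, float("nan"))
    return result


def cox_partial_likelihood_score(records, covariates: list[str], coefs) -> np.ndarray:
    """Score (gradient) of the Efron partial log-likelihood at ``coefs``.

    Provided so fits can be verified independently: at the optimum the score
    should vanish.
    """
    df = _survival_frame(records, covariates).sort_values("time", ignore_index=True)
    X = df[covariates].to_numpy(dtype=float)
    t = df["time"].to_numpy()
    d = df["event"].to_numpy(dtype=bool)
    beta = np.asarray(coefs, dtype=float)
    eta = X @ beta
    w = np.exp(eta)
    score = np.zeros(len(beta))
    for tt in np.unique(t[d]):
        D = d & (t == tt)
        R = t >= tt
        m = int(D.sum())
        sum_w_R = w[R].sum()
        sum_wx_R = (w[R, None] * X[R]).sum(axis=0)
        sum_w_D = w[D].sum()
        sum_wx_D = (w[D, None] * X[D]).sum(axis=0)
        score += X[D].sum(axis=0)
        for ell in range(m):
            denom = sum_w_R - (ell / m) * sum_w_D
            numer = sum_wx_R - (ell / m) * sum_wx_D
            score -= numer / denom
    return score
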