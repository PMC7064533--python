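"""Kaplan-Meier estimation, (stratified) log-rank testing and Cox regression.

Every downstream stage (risk stratification, composite grouping, gene-set
survival scoring, methylation clustering) funnels through these three
primitives.  Model fitting delegates to lifelines (Efron tie handling); the
score test at beta = 0 is implemented directly because gene-level screening
evaluates it tens of thousands of times and only needs the null-point
statistic, not a full fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

NOT_REACHED = "not reached"


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalData:
    """Right-censored time-to-event data with optional groups and strata.

    ``time`` is in months and must be positive; ``event`` is 1 for an
    observed event (recurrence or death depending on the endpoint) and 0 for
    censoring.
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None
    strata: np.ndarray | None = None
    endpoint: str = "RFS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise SurvivalError("time and event must have identical length")
        if self.time.size == 0:
            raise SurvivalError("empty survival data")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise SurvivalError("times must be finite and positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise SurvivalError("event flags must be 0/1")
        for name in ("group", "strata"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.time.shape:
                    raise SurvivalError(f"{name} must match time in length")
                setattr(self, name, arr)

    @classmethod
    def from_clinical(cls, clinical: pd.DataFrame, group=None, strata=None) -> "SurvivalData":
        """Build from the clinical TSV schema (time_months, event columns)."""
        endpoint = "RFS"
        if "endpoint" in clinical.columns and len(clinical):
            endpoint = str(clinical["endpoint"].iloc[0])
        return cls(
            time=clinical["time_months"].to_numpy(),
            event=clinical["event"].to_numpy(),
            group=None if group is None else np.asarray(group),
            strata=None if strata is None else np.asarray(strata),
            endpoint=endpoint,
        )

    @property
    def n(self) -> int:
        return self.time.size


@dataclass
class KMCurve:
    """Product-limit estimate: step function plus median survival."""

    times: np.ndarray
    survival: np.ndarray
    median: float | str  # months, or the explicit "not reached" token

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CoxResult:
    """Per-covariate Cox partial-likelihood summary."""

    covariate: str
    coefficient: float
    hr: float
    ci95: tuple[float, float]
    p: float

    @property
    def sign(self) -> int:
        return 1 if self.coefficient >= 0 else -1


def km_curve(data: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Median survival is the earliest observed time with S(t) <= 0.5; when the
    curve never drops that low the median is reported as the explicit
    token ``"not reached"`` (never infinity).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, data.event)
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    values = surv.to_numpy(dtype=float)
    if times.size and times[0] == 0.0:  # drop the S(0)=1 anchor; times are > 0
        times, values = times[1:], values[1:]
    median = kmf.median_survival_time_
    if not math.isfinite(median):
        median = NOT_REACHED
    else:
        median = float(median)
    return KMCurve(times=times, survival=values, median=median)


def _logrank_moments(time, event, group_idx, n_groups):
    """Observed, expected and covariance contributions of one stratum."""
    observed = np.zeros(n_groups)
    expected = np.zeros(n_groups)
    cov = np.zeros((n_groups, n_groups))
    order = np.argsort(time, kind="stable")
    time, event, group_idx = time[order], event[order], group_idx[order]
    n = len(time)
    at_risk = np.bincount(group_idx, minlength=n_groups).astype(float)
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        deaths = np.bincount(group_idx[i:j][event[i:j] == 1], minlength=n_groups).astype(float)
        d = deaths.sum()
        n_tot = at_risk.sum()
        if d > 0 and n_tot > 0:
            frac = at_risk / n_tot
            observed += deaths
            expected += d * frac
            if n_tot > 1:
                scale = d * (n_tot - d) / (n_tot - 1)
                cov += scale * (np.diag(frac) - np.outer(frac, frac))
        at_risk -= np.bincount(group_idx[i:j], minlength=n_groups)
        i = j
    return observed, expected, cov


def logrank(data: SurvivalData) -> LogRankResult:
    """(Stratified) log-rank test across the groups in ``data``.

    Observed-minus-expected death counts and their covariance are accumulated
    per stratum and summed before forming the chi-square quadratic form — the
    standard stratified construction, which reduces to the plain log-rank
    test when no strata are given.
    """
    from scipy import stats

    if data.group is None:
        raise SurvivalError("log-rank test needs group labels")
    labels, counts = np.unique(data.group, return_counts=True)
    if len(labels) < 2:
        raise SurvivalError("log-rank test needs >= 2 groups")
    if np.any(counts == 0):
        raise SurvivalError("every group must contain at least one subject")
    n_groups = len(labels)
    group_idx = np.searchsorted(labels, data.group)
    strata = np.zeros(data.n, dtype=int) if data.strata is None else (
        np.searchsorted(np.unique(data.strata), data.strata)
    )
    diff = np.zeros(n_groups)
    cov = np.zeros((n_groups, n_groups))
    for s in np.unique(strata):
        mask = strata == s
        obs, exp, c = _logrank_moments(
            data.time[mask], data.event[mask], group_idx[mask], n_groups
        )
        diff += obs - exp
        cov += c
    # the contributions sum to zero across groups: drop the last component
    v = cov[:-1, :-1]
    d = diff[:-1]
    df = n_groups - 1
    if not np.any(v):
        return LogRankResult(statistic=0.0, df=df, p=1.0)
    statistic = float(d @ np.linalg.pinv(v) @ d)
    return LogRankResult(statistic=statistic, df=df, p=float(stats.chi2.sf(statistic, df)))


def cox_fit(
    data: SurvivalData,
    covariates: pd.DataFrame,
    univariate: bool = False,
) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron tie correction).

    ``covariates`` is samples x covariates, row-aligned with ``data``.  In
    multivariate mode all columns enter one model; in univariate mode each
    column is fitted on its own and one result per column is returned.
    """
    covariates = pd.DataFrame(covariates)
    if len(covariates) != data.n:
        raise SurvivalError("covariates must be row-aligned with survival data")
    if data.event.sum() < 1:
        raise SurvivalError("Cox fit needs at least one event")
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise SurvivalError(f"covariate {col!r} is constant")
    if univariate and covariates.shape[1] > 1:
        out: list[CoxResult] = []
        for col in covariates.columns:
            out.extend(cox_fit(data, covariates[[col]]))
        return out

    frame = covariates.reset_index(drop=True).copy()
    frame["_time"] = data.time
    frame["_event"] = data.event
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises on separation/collinearity
        raise SurvivalError(f"Cox fit failed: {exc}") from exc
    results = []
    for col in covariates.columns:
        coef = float(cph.params_[col])
        se = float(cph.standard_errors_[col])
        lo, hi = math.exp(coef - 1.959964 * se), math.exp(coef + 1.959964 * se)
        results.append(
            CoxResult(
                covariate=str(col),
                coefficient=coef,
                hr=math.exp(coef),
                ci95=(lo, hi),
                p=float(cph.summary.loc[col, "p"]),
            )
        )
    return results


def cox_score_test(time, event, x) -> tuple[float, float, int]:
    """Score (Rao) test of a single covariate at beta = 0, Efron ties.

    Returns (chi-square statistic, two-sided p, sign of the score), where the
    sign is the direction the coefficient estimate would take.  For a binary
    covariate without ties this is exactly the two-group log-rank test.
    Constant covariates return (0, 1, +1), the degenerate no-information case.
    """
    from scipy import stats

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0, 1.0, 1
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    n = len(time)
    u = 0.0
    info = 0.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        deaths = np.nonzero(event[i:j])[0] + i
        d = len(deaths)
        if d:
            risk = slice(i, n)  # sorted ascending: risk set = {k : time_k >= t}
            s1_r = x[risk].sum()
            s2_r = (x[risk] ** 2).sum()
            n_r = n - i
            s1_d = x[deaths].sum()
            s2_d = (x[deaths] ** 2).sum()
            u += s1_d
            for ell in range(d):
                frac = ell / d
                denom = n_r - frac * d
                m1 = (s1_r - frac * s1_d) / denom
                m2 = (s2_r - frac * s2_d) / denom
                u -= m1
                info += m2 - m1 * m1
        i = j
    if info <= 0:
        return 0.0, 1.0, 1
    chi2 = u * u / info
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, (1 if u >= 0 else -1)
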