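"""Time-to-onset (TTO) analysis with Weibull failure-mode classification.

TTO is the interval from therapy start (earliest START_DT of the
primary-suspect drug) to event onset (EVENT_DT), in days, with +0.5 added so
that a same-day onset contributes half a day.  Records with partial or
invalid dates, or a non-positive interval, are excluded with a reason.

The onset distribution is summarized by a two-parameter Weibull fit
(scale alpha in days, shape beta): beta < 1 means a decreasing hazard
("early failure"), beta near 1 a constant hazard ("random failure"),
beta > 1 an increasing hazard ("wear-out failure").  The call is made
against the shape's 95% confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize

from .ingest import PartialDate, parse_date

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-report onset records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: str
    drug: str
    tto_days: float | None
    included: bool
    exclusion_reason: str  # missing_date | partial_date | negative_or_zero | none


def compute_tto(
    start: PartialDate, event: PartialDate, primaryid: str = "", drug: str = ""
) -> OnsetRecord:
    """Onset interval (event - start) in whole days plus 0.5.

    Both dates must have day precision; otherwise the record is excluded as
    missing/partial.  Event on or before... strictly, a non-positive
    interval (event before start) is excluded as an input error; a same-day
    pair yields 0.5 days and is included.
    """
    for date in (start, event):
        if date.precision == "invalid":
            return OnsetRecord(primaryid, drug, None, False, "missing_date")
    if start.precision != "day" or event.precision != "day":
        return OnsetRecord(primaryid, drug, None, False, "partial_date")
    delta = (event.to_timestamp() - start.to_timestamp()).days
    tto = delta + 0.5
    if tto <= 0:
        return OnsetRecord(primaryid, drug, None, False, "negative_or_zero")
    return OnsetRecord(primaryid, drug, tto, True, "none")


def onset_records(dataset) -> list[OnsetRecord]:
    """One onset record per event-positive (case, PS-drug) pair.

    Therapy start is the earliest START_DT among the case's therapy rows;
    the event date comes from the report's EVENT_DT.
    """
    ther = dataset.ther
    start_by_pid: dict[str, PartialDate] = {}
    if ther is not None and not ther.empty and "START_DT" in ther.columns:
        for pid, raw in zip(ther["PRIMARYID"], ther["START_DT"]):
            pd_date = parse_date(raw)
            if pd_date.precision == "invalid":
                continue
            pid = str(pid)
            prev = start_by_pid.get(pid)
            if prev is None or pd_date.sort_key < prev.sort_key:
                start_by_pid[pid] = pd_date
    event_dt_by_pid = {c.primaryid: c.event_dt for c in dataset.cases}
    invalid = PartialDate()
    records = []
    m = dataset.mentions
    positive = m[m["PRIMARYID"].isin(dataset.event_positive)]
    for pid, drug in zip(positive["PRIMARYID"], positive["INGREDIENT"]):
        records.append(
            compute_tto(
                start_by_pid.get(pid, invalid),
                event_dt_by_pid.get(pid, invalid),
                primaryid=pid,
                drug=drug,
            )
        )
    n_inc = sum(r.included for r in records)
    logger.info("onset_records: %d included / %d total", n_inc, len(records))
    return records


# ---------------------------------------------------------------------------
# Weibull fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeibullFit:
    alpha: float          # scale, days (63.2% quantile of the distribution)
    beta: float           # shape, dimensionless
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n: int
    loglik: float


def _profile_score(beta: float, t: np.ndarray, log_t: np.ndarray, mean_log: float) -> float:
    # d(profile loglik)/d(beta), up to positive factor: the classic MLE
    # estimating equation sum(t^b log t)/sum(t^b) - 1/b - mean(log t)
    tb = t ** beta
    return float(np.dot(tb, log_t) / np.sum(tb) - 1.0 / beta - mean_log)


def fit_weibull(ttos, min_n: int = 10) -> WeibullFit:
    """Maximum-likelihood two-parameter Weibull fit of onset times.

    The shape is found by solving the one-dimensional profile estimating
    equation with a deterministic bracketed root search; the scale then has
    the closed form (mean of t^beta)^(1/beta).  95% CIs come from the
    observed information on the log-parameter scale, back-transformed.
    """
    t = np.asarray(ttos, dtype=float)
    if len(t) < min_n:
        raise ValueError(f"need at least {min_n} onset times, got {len(t)}")
    if np.any(t <= 0):
        raise ValueError("onset times must be positive")
    if np.allclose(t, t[0]):
        raise ValueError("degenerate sample: all onset times identical")
    log_t = np.log(t)
    mean_log = float(np.mean(log_t))
    # scale to geometric mean 1 for numerical stability; alpha rescales back
    z = t / math.exp(mean_log)
    log_z = log_t - mean_log

    def score(beta):
        return _profile_score(beta, z, log_z, 0.0)

    lo, hi = 1e-3, 1.0
    while score(hi) < 0 and hi < 1e4:
        hi *= 2.0
    beta = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14)
    n = len(t)
    alpha = math.exp(mean_log) * float(np.mean(z ** beta)) ** (1.0 / beta)
    x = t / alpha
    loglik = float(
        n * math.log(beta) - n * beta * math.log(alpha) + (beta - 1) * np.sum(log_t) - np.sum(x ** beta)
    )
    # observed information in (log alpha, log beta)
    # negative Hessian of the loglik in (log alpha, log beta); with
    # u_i = beta*log(t_i/alpha): i_aa = b^2*S0, i_ab = -b(S0 - n + S1),
    # i_bb = S2 + S1 - sum(u), where Sk = sum(x^b * u^k)
    xb = x ** beta
    u = beta * np.log(x)
    s_xb = float(np.sum(xb))
    s_xbu = float(np.dot(xb, u))
    s_xbu2 = float(np.dot(xb, u * u))
    i_aa = beta * beta * s_xb
    i_ab = -beta * (s_xb - n + s_xbu)
    i_bb = s_xbu2 + s_xbu - float(np.sum(u))
    info = np.array([[i_aa, i_ab], [i_ab, i_bb]])
    cov = np.linalg.inv(info)
    se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    z95 = 1.959963984540054
    return WeibullFit(
        alpha=alpha,
        beta=beta,
        alpha_ci=(alpha * math.exp(-z95 * se_la), alpha * math.exp(z95 * se_la)),
        beta_ci=(beta * math.exp(-z95 * se_lb), beta * math.exp(z95 * se_lb)),
        n=n,
        loglik=loglik,
    )


def classify_failure(fit: WeibullFit) -> str:
    """Failure mode from the shape CI: early (<1), wear_out (>1), random."""
    lo, hi = fit.beta_ci
    if fit.beta < 1 and hi < 1:
        return "early"
    if fit.beta > 1 and lo > 1:
        return "wear_out"
    return "random"


# ---------------------------------------------------------------------------
# Summaries and group comparison
# ---------------------------------------------------------------------------


def median_iqr(ttos) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation (type-7), in days."""
    t = np.asarray(ttos, dtype=float)
    if len(t) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(t, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def cumulative_incidence(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Empirical cumulative incidence 1 - S(t) per group (Kaplan-Meier).

    Onset times are fully observed (no censoring), so this equals the ECDF;
    returned tidy with columns group, time, cuminc.
    """
    frames = []
    for name, ttos in groups.items():
        t = np.asarray(ttos, dtype=float)
        if len(t) == 0:
            raise ValueError(f"group {name!r} is empty")
        km = KaplanMeierFitter()
        km.fit(t, event_observed=np.ones_like(t))
        sf = km.survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": name,
                    "time": sf.index.to_numpy(dtype=float),
                    "cuminc": 1.0 - sf.iloc[:, 0].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def logrank_test(groups: dict[str, np.ndarray]) -> tuple[float, int, float]:
    """K-sample Mantel-Cox log-rank test on uncensored onset times.

    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, labels = [], []
    for name, ttos in groups.items():
        t = np.asarray(ttos, dtype=float)
        if len(t) == 0:
            raise ValueError(f"group {name!r} is empty")
        times.append(t)
        labels.extend([name] * len(t))
    durations = np.concatenate(times)
    res = multivariate_logrank_test(
        durations, np.array(labels), np.ones_like(durations)
    )
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def tto_summary_table(
    records: list[OnsetRecord],
    by: dict[str, str] | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-group onset summary: n, median/IQR, Weibull fit, failure mode.

    ``by`` optionally maps drug -> group label (e.g. ATC level 1); default
    groups by drug.  Groups with n <= min_n get quantiles but no fit.
    """
    rows = []
    included = [r for r in records if r.included]
    key = (lambda r: by.get(r.drug, "unknown")) if by is not None else (lambda r: r.drug)
    df = pd.DataFrame({"group": [key(r) for r in included],
                       "tto": [r.tto_days for r in included]})
    for group, sub in df.groupby("group"):
        t = sub["tto"].to_numpy()
        med, q1, q3 = median_iqr(t)
        row = {
            "group": group, "n": len(t), "median": med, "q1": q1, "q3": q3,
            "alpha": np.nan, "alpha_lo": np.nan, "alpha_hi": np.nan,
            "beta": np.nan, "beta_lo": np.nan, "beta_hi": np.nan,
            "failure_mode": None,
        }
        if len(t) > min_n and not np.allclose(t, t[0]):
            fit = fit_weibull(t, min_n=min_n)
            row.update(
                alpha=fit.alpha, alpha_lo=fit.alpha_ci[0], alpha_hi=fit.alpha_ci[1],
                beta=fit.beta, beta_lo=fit.beta_ci[0], beta_hi=fit.beta_ci[1],
                failure_mode=classify_failure(fit),
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("median").reset_index(drop=True)
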