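"""Disproportionality statistics for drug-event pairs in spontaneous reports.

For each drug the deduplicated reports are cross-classified into the 2x2
table

    =============  =======  =========
    .              event    no event
    =============  =======  =========
    target drug    a        b
    other drugs    c        d
    =============  =======  =========

with N = a+b+c+d, and four estimators are computed:

* ROR  — reporting odds ratio ad/(bc) with Wald CI on the log scale;
* PRR  — proportional reporting ratio with a (Yates-corrected) chi-square;
* IC   — the BCPNN information component, a shrunk log2 observed/expected
  ratio, with its lower credibility bound IC025;
* EBGM — the MGPS empirical-Bayes geometric mean of the posterior relative
  reporting rate, with its 5th percentile EBGM05.

A pair is a positive signal only when all four criteria hold simultaneously
(configurable thresholds), and positive drugs are stratified into risk
levels A-D by ROR percentile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair; all cells are case counts."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self) -> "ContingencyTable":
        """Haldane continuity correction: +0.5 to every cell."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    @property
    def expected_a(self) -> float:
        """Expected a under independence, (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def contingency(dataset, drug: str) -> ContingencyTable:
    """Build the 2x2 table for one ingredient from an analysis dataset.

    The counting unit is the deduplicated case; a case is drug-exposed when
    it has >=1 primary-suspect mention of the ingredient.
    """
    mentions = dataset.mentions
    exposed = set(mentions.loc[mentions["INGREDIENT"] == drug, "PRIMARYID"])
    if not exposed:
        raise ValueError(f"drug {drug!r} absent from dataset")
    positives = dataset.event_positive
    n_total = dataset.n_total_reports
    a = len(exposed & positives)
    b = len(exposed) - a
    c = len(positives) - a
    d = n_total - a - b - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# Priors / thresholds configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters for the Bayesian estimators and CI quantiles.

    BCPNN defaults are the standard vague prior (alpha=beta=2,
    alpha1=beta1=1, gamma11=1, gamma tuned so IC=0 at independence).
    MGPS initial values are DuMouchel's canonical starting point for the
    two-component gamma mixture.
    """

    bcpnn_alpha: float = 2.0
    bcpnn_beta: float = 2.0
    bcpnn_alpha1: float = 1.0
    bcpnn_beta1: float = 1.0
    bcpnn_gamma11: float = 1.0
    mgps_init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3)
    z_two_sided: float = 1.96
    z_one_sided: float = 1.645

    def __post_init__(self):
        if min(self.bcpnn_alpha, self.bcpnn_beta, self.bcpnn_alpha1,
               self.bcpnn_beta1, self.bcpnn_gamma11) <= 0:
            raise ValueError("BCPNN hyperparameters must be positive")
        p = self.mgps_init[4]
        if not 0 < p < 1:
            raise ValueError("MGPS mixture weight must be in (0,1)")


@dataclass(frozen=True)
class SignalThresholds:
    """The combined-positive rule, one criterion per algorithm."""

    min_a: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


# ---------------------------------------------------------------------------
# Frequentist estimators
# ---------------------------------------------------------------------------


def ror(table: ContingencyTable, z: float = 1.96) -> tuple[float, float, float, bool]:
    """Reporting odds ratio ad/(bc) with Wald CI.

    A zero cell triggers the Haldane +0.5 correction of all four cells; the
    returned flag records whether the correction was applied.
    """
    corrected = table.has_zero_cell
    t = table.corrected() if corrected else table
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_point = math.log(point)
    return (
        point,
        math.exp(log_point - z * se),
        math.exp(log_point + z * se),
        corrected,
    )


def prr_chi2(table: ContingencyTable, yates: bool = True) -> tuple[float, float]:
    """PRR = [a/(a+b)] / [c/(c+d)] and the 2x2 chi-square from marginals.

    The chi-square uses the Yates continuity correction by default, with the
    conventional floor: terms are (max(|O-E|-0.5, 0))^2 / E.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0:
        raise ValueError("zero margin: a+b (no drug-exposed reports)")
    if c + d == 0:
        raise ValueError("zero margin: c+d (no comparator reports)")
    denom = c / (c + d)
    prr = math.inf if denom == 0 else (a / (a + b)) / denom
    n = table.n
    row = (a + b, c + d)
    col = (a + c, b + d)
    chi2 = 0.0
    for obs, (i, j) in zip((a, b, c, d), ((0, 0), (0, 1), (1, 0), (1, 1))):
        e = row[i] * col[j] / n
        if e == 0:
            continue
        dev = abs(obs - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / e
    return prr, chi2


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------


def bcpnn_ic(
    table: ContingencyTable,
    prior: PriorConfig = PriorConfig(),
    variant: str = "simplified",
) -> tuple[float, float]:
    """Information component IC (log2) and its lower bound IC025.

    ``simplified``
        IC = log2(a N / ((a+b)(a+c))) evaluated on continuity-corrected
        cells when a cell is zero; IC025 = IC - 2*sqrt(V) with V the
        three-term posterior variance of the beta-binomial model.
    ``bate``
        Posterior expectation E(IC) of the original BCPNN, with gamma
        chosen so that E(IC)=0 at exact independence; IC025 likewise
        E(IC) - 2*sqrt(V(IC)).
    """
    n = table.n
    if table.a + table.b == 0 or table.a + table.c == 0:
        raise ValueError("zero drug or event margin")
    if n <= 0:
        raise ValueError("empty table")
    al, be = prior.bcpnn_alpha, prior.bcpnn_beta
    al1, be1, g11 = prior.bcpnn_alpha1, prior.bcpnn_beta1, prior.bcpnn_gamma11
    a, ab, ac = table.a, table.a + table.b, table.a + table.c
    # gamma calibrated so the posterior expectation vanishes at independence
    gamma = g11 * (n + al) * (n + be) / ((ab + al1) * (ac + be1))
    var = (1 / math.log(2)) ** 2 * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - ab + al - al1) / ((ab + al1) * (1 + n + al))
        + (n - ac + be - be1) / ((ac + be1) * (1 + n + be))
    )
    if variant == "bate":
        ic = math.log2(
            (a + g11) * (n + al) * (n + be) / ((n + gamma) * (ab + al1) * (ac + be1))
        )
    elif variant == "simplified":
        t = table.corrected() if table.has_zero_cell else table
        ic = math.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c)))
    else:
        raise ValueError(f"unknown BCPNN variant {variant!r}")
    return ic, ic - 2.0 * math.sqrt(var)


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------


@dataclass
class GammaPoissonMixture:
    """Two-component gamma prior on the relative reporting rate lambda.

    lambda ~ P * Gamma(alpha1, rate beta1) + (1-P) * Gamma(alpha2, rate beta2);
    observed counts a ~ Poisson(lambda * E) with E the expected count under
    independence, so each component's marginal is negative binomial.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.p])

    def marginal_loglik(self, a: np.ndarray, e: np.ndarray) -> float:
        return float(np.sum(_mixture_logpmf(self.as_array(), a, e)))


def _nb_logpmf(a, alpha, beta, e):
    # marginal of Poisson(lambda*e), lambda ~ Gamma(alpha, rate beta)
    p = beta / (beta + e)
    return stats.nbinom.logpmf(a, alpha, p)


def _mixture_logpmf(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> np.ndarray:
    a1, b1, a2, b2, p = theta
    l1 = _nb_logpmf(a, a1, b1, e) + math.log(p)
    l2 = _nb_logpmf(a, a2, b2, e) + math.log1p(-p)
    return np.logaddexp(l1, l2)


def fit_gamma_poisson_mixture(
    a: np.ndarray,
    e: np.ndarray,
    init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
    max_iter: int = 500,
) -> GammaPoissonMixture:
    """Fit the mixture prior by direct marginal-likelihood maximization.

    Parameters are optimized on an unconstrained scale (log shapes/rates,
    logit weight) with L-BFGS-B.  Raises on optimizer failure, carrying the
    last parameter values in the message.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)

    def unpack(x):
        return np.array([*np.exp(x[:4]), special.expit(x[4])])

    def nll(x):
        theta = unpack(x)
        return -float(np.sum(_mixture_logpmf(theta, a, e)))

    x0 = np.array([*np.log(init[:4]), special.logit(init[4])])
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter},
    )
    theta = unpack(res.x)
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise RuntimeError(
            f"gamma-Poisson mixture fit failed ({res.message}); "
            f"last parameters {theta.round(4).tolist()}"
        )
    # order components so component 1 has the smaller prior mean
    if theta[0] / theta[1] > theta[2] / theta[3]:
        theta = np.array([theta[2], theta[3], theta[0], theta[1], 1 - theta[4]])
    return GammaPoissonMixture(*theta)


def _posterior_ebgm_ebgm05(
    mix: GammaPoissonMixture, a: float, e: float
) -> tuple[float, float]:
    """EBGM = exp E[log lambda | a]; EBGM05 = posterior 5th percentile."""
    lw1 = _nb_logpmf(a, mix.alpha1, mix.beta1, e) + math.log(mix.p)
    lw2 = _nb_logpmf(a, mix.alpha2, mix.beta2, e) + math.log1p(-mix.p)
    norm = np.logaddexp(lw1, lw2)
    q1, q2 = math.exp(lw1 - norm), math.exp(lw2 - norm)
    s1, r1 = mix.alpha1 + a, mix.beta1 + e
    s2, r2 = mix.alpha2 + a, mix.beta2 + e
    elog = q1 * (special.digamma(s1) - math.log(r1)) + q2 * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm = math.exp(elog)

    def cdf(x):
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + q2 * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    hi = max(stats.gamma.ppf(0.999, s1, scale=1 / r1),
             stats.gamma.ppf(0.999, s2, scale=1 / r2))
    lo = min(stats.gamma.ppf(1e-9, s1, scale=1 / r1),
             stats.gamma.ppf(1e-9, s2, scale=1 / r2))
    lo = max(lo, 1e-12)
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-10)
    return ebgm, ebgm05


def mgps_ebgm(
    tables: list[ContingencyTable],
    prior: PriorConfig = PriorConfig(),
    variant: str = "closed_form",
) -> list[tuple[float, float]]:
    """EBGM and EBGM05 for every drug-event table.

    ``closed_form`` scores each table independently: EBGM is the raw
    observed/expected ratio a N/((a+b)(a+c)) and EBGM05 applies a one-sided
    lognormal bound (z=1.645) with continuity correction on zero cells.
    ``em`` fits the two-component gamma-Poisson mixture across all tables
    and reports the posterior geometric mean and 5th percentile.
    """
    if variant == "closed_form":
        out = []
        for table in tables:
            t = table.corrected() if table.has_zero_cell else table
            ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
            se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
            ebgm05 = math.exp(math.log(ebgm) - prior.z_one_sided * se)
            out.append((ebgm, ebgm05))
        return out
    if variant != "em":
        raise ValueError(f"unknown MGPS variant {variant!r}")
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected_a for t in tables], dtype=float)
    mix = fit_gamma_poisson_mixture(a, e, init=prior.mgps_init)
    return [_posterior_ebgm_ebgm05(mix, ai, ei) for ai, ei in zip(a, e)]


# ---------------------------------------------------------------------------
# Combined rule, results, stratification
# ---------------------------------------------------------------------------


@dataclass
class SignalMetrics:
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    n_reports: int
    corrected: bool = False


@dataclass
class SignalResult:
    drug: str
    metrics: SignalMetrics
    criteria_flags: dict[str, bool]
    combined_positive: bool
    risk_level: str | None = None
    atc1: str | None = None
    atc3: str | None = None


def combined_signal(
    drug: str,
    metrics: SignalMetrics,
    thresholds: SignalThresholds = SignalThresholds(),
) -> SignalResult:
    """Apply the four per-algorithm criteria; positive only if all hold."""
    a = metrics.n_reports
    flags = {
        "ror": a >= thresholds.min_a and metrics.ror_ci_low > thresholds.ror_ci_low,
        "prr": (
            a >= thresholds.min_a
            and metrics.prr >= thresholds.prr_min
            and metrics.chi2 >= thresholds.chi2_min
        ),
        "bcpnn": metrics.ic025 > thresholds.ic025_min,
        "mgps": metrics.ebgm05 > thresholds.ebgm05_min,
    }
    return SignalResult(
        drug=drug,
        metrics=metrics,
        criteria_flags=flags,
        combined_positive=all(flags.values()),
    )


def evaluate_pair(
    table: ContingencyTable,
    drug: str = "",
    prior: PriorConfig = PriorConfig(),
    thresholds: SignalThresholds = SignalThresholds(),
    bcpnn_variant: str = "simplified",
    yates: bool = True,
    ebgm: tuple[float, float] | None = None,
) -> SignalResult:
    """All four estimators plus the combined rule for a single table.

    ``ebgm`` may carry a precomputed (EBGM, EBGM05) pair from a joint MGPS
    fit; otherwise the closed-form variant is used.
    """
    r, lo, hi, corrected = ror(table, z=prior.z_two_sided)
    prr, chi2 = prr_chi2(table, yates=yates)
    ic, ic025 = bcpnn_ic(table, prior, variant=bcpnn_variant)
    if ebgm is None:
        (eb, eb05), = mgps_ebgm([table], prior, variant="closed_form")
    else:
        eb, eb05 = ebgm
    metrics = SignalMetrics(
        ror=r, ror_ci_low=lo, ror_ci_high=hi, prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=eb, ebgm05=eb05,
        n_reports=int(table.a), corrected=corrected,
    )
    return combined_signal(drug, metrics, thresholds)


def stratify_risk(positives: list[SignalResult]) -> list[SignalResult]:
    """Assign risk levels A-D by ROR percentile among positive signals.

    Drugs are ranked by ROR descending (ties: more reports first, then drug
    name); with n drugs the cumulative boundaries are floor(0.05 n),
    floor(0.20 n) and floor(0.50 n): level A covers ranks 1..floor(0.05 n),
    B to floor(0.20 n), C to floor(0.50 n), D the rest.
    """
    if any(not r.combined_positive for r in positives):
        raise ValueError("risk stratification applies to positive signals only")
    n = len(positives)
    if n == 0:
        return []
    ranked = sorted(
        positives,
        key=lambda r: (-r.metrics.ror, -r.metrics.n_reports, r.drug),
    )
    k1 = math.floor(0.05 * n)
    k2 = math.floor(0.20 * n)
    k3 = math.floor(0.50 * n)
    out = []
    for rank, res in enumerate(ranked, start=1):
        level = "A" if rank <= k1 else "B" if rank <= k2 else "C" if rank <= k3 else "D"
        out.append(replace(res, risk_level=level))
    return out


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------


def compute_signals(
    dataset,
    prior: PriorConfig = PriorConfig(),
    thresholds: SignalThresholds = SignalThresholds(),
    bcpnn_variant: str = "simplified",
    mgps_variant: str = "closed_form",
    yates: bool = True,
    min_reports: int = 1,
    include_unmapped: bool = False,
) -> pd.DataFrame:
    """Per-drug signal table over every ingredient in the dataset.

    Returns one row per drug with the 2x2 cells, all four estimators, the
    per-algorithm flags, the combined call and (for positives) the risk
    level — the data behind a forest plot of the screen.
    """
    drugs = dataset.drug_universe(mapped_only=not include_unmapped)
    atc_info = (
        dataset.mentions.drop_duplicates("INGREDIENT").set_index("INGREDIENT")
        if not dataset.mentions.empty
        else pd.DataFrame()
    )
    tables, kept = [], []
    for drug in drugs:
        t = contingency(dataset, drug)
        if t.a + t.b < min_reports:
            continue
        tables.append(t)
        kept.append(drug)
    if mgps_variant == "em":
        ebgms = mgps_ebgm(tables, prior, variant="em")
    else:
        ebgms = [None] * len(tables)
    results = []
    for drug, t, eb in zip(kept, tables, ebgms):
        res = evaluate_pair(
            t, drug=drug, prior=prior, thresholds=thresholds,
            bcpnn_variant=bcpnn_variant, yates=yates, ebgm=eb,
        )
        if not atc_info.empty and drug in atc_info.index:
            res.atc1 = atc_info.loc[drug, "ATC1"]
            res.atc3 = atc_info.loc[drug, "ATC3"]
        results.append((t, res))
    positives = [r for _, r in results if r.combined_positive]
    stratified = {r.drug: r.risk_level for r in stratify_risk(positives)}
    rows = []
    for t, r in results:
        m = r.metrics
        rows.append(
            {
                "drug": r.drug, "a": int(t.a), "b": int(t.b), "c": int(t.c),
                "d": int(t.d), "N": int(t.n),
                "ROR": m.ror, "ROR_L": m.ror_ci_low, "ROR_U": m.ror_ci_high,
                "PRR": m.prr, "CHI2": m.chi2, "IC": m.ic, "IC025": m.ic025,
                "EBGM": m.ebgm, "EBGM05": m.ebgm05,
                "flag_ror": r.criteria_flags["ror"],
                "flag_prr": r.criteria_flags["prr"],
                "flag_bcpnn": r.criteria_flags["bcpnn"],
                "flag_mgps": r.criteria_flags["mgps"],
                "corrected": m.corrected,
                "combined": r.combined_positive,
                "level": stratified.get(r.drug),
                "ATC1": r.atc1, "ATC3": r.atc3,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("ROR", ascending=False).reset_index(drop=True)
    logger.info(
        "compute_signals: %d drugs evaluated, %d combined-positive",
        len(df), int(df["combined"].sum()) if not df.empty else 0,
    )
    return df


def atc_level_shares(signal_table: pd.DataFrame, level: str = "ATC1") -> pd.DataFrame:
    """Counts and percentage shares of positive-signal drugs per ATC group."""
    pos = signal_table[signal_table["combined"]]
    counts = pos[level].value_counts(dropna=False)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "n": counts,
            "percent": (100 * counts / total).round(1),
        }
    )
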