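"""Survival statistics: Cox regression, cutpoint selection, KM and log-rank.

Cox partial-likelihood fits (Efron tie handling) go through lifelines; the
maximally selected rank statistic is implemented here.  For a candidate
cutpoint mu of a feature x, the two-sample log-rank statistic is written in
rank-score form: with Nelson-Aalen cumulative hazard L(t), each subject
carries the log-rank score a_i = delta_i - L(t_i); the group statistic
S(mu) = sum_{x_i <= mu} a_i is standardized by its permutation mean and
variance.  The cutpoint maximizes |S| over splits whose group proportions
stay within [minprop, 1 - minprop], and the familywise-adjusted p-value
uses the Brownian-bridge crossing approximation

    p(b) ~= phi(b) (b - 1/b) log[ e2 (1 - e1) / (e1 (1 - e2)) ] + 4 phi(b) / b

with e1 = minprop, e2 = 1 - minprop, never reported below the pointwise
two-sided normal p of the best split.  A seeded permutation mode is
available for validating the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm

from .errors import SurvivalModelError

__all__ = [
    "CoxFit",
    "CutpointResult",
    "KMCurve",
    "fit_cox",
    "stepwise_cox",
    "maxstat_cutpoint",
    "km_curve",
    "logrank_test",
]


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate: coef, hazard_ratio, ci_lo,
    ci_hi (Wald 95%), p.
    """

    summary: pd.DataFrame
    log_partial_likelihood: float
    aic: float
    n: int
    n_events: int
    covariates: tuple[str, ...]


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    max_statistic: float
    adjusted_p: float
    minprop: float
    candidate_cutpoints: np.ndarray = field(repr=False, default=None)
    candidate_statistics: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def _validate_table(table: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in table.columns:
            raise SurvivalModelError(f"survival table missing column {col!r}")
    if (table["time"] <= 0).any():
        raise SurvivalModelError("all survival times must be positive")
    if not set(np.unique(table["event"])) <= {0, 1}:
        raise SurvivalModelError("event indicator must be binary 0/1")
    if "patient_id" in table.columns and table["patient_id"].duplicated().any():
        raise SurvivalModelError("duplicate patient_id in survival table")


def fit_cox(table: pd.DataFrame, covariate_names: list[str]) -> CoxFit:
    """Cox partial-likelihood fit with Efron tie correction.

    Deterministic Newton optimization via lifelines; Wald 95% confidence
    intervals.  Raises :class:`SurvivalModelError` for fewer than two
    events, a constant covariate (no information) or non-convergence.
    """
    _validate_table(table)
    if int(table["event"].sum()) < 2:
        raise SurvivalModelError("need at least 2 events to fit a Cox model")
    for name in covariate_names:
        if name not in table.columns:
            raise SurvivalModelError(f"covariate {name!r} not in table")
        if table[name].nunique() < 2:
            raise SurvivalModelError(
                f"covariate {name!r} is constant: no information to fit"
            )
    df = table[["time", "event", *covariate_names]].astype(float)
    cph = CoxPHFitter()
    try:
        # tight Newton tolerance so small-sample fits agree with a
        # brute-force partial-likelihood maximizer to ~1e-6
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise SurvivalModelError(
            f"Cox fit did not converge (check covariate scaling/separation): {exc}"
        ) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": np.exp(s["coef"]),
            "ci_lo": np.exp(s["coef lower 95%"]),
            "ci_hi": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    k = len(covariate_names)
    ll = float(cph.log_likelihood_)
    return CoxFit(
        summary=summary,
        log_partial_likelihood=ll,
        aic=-2.0 * ll + 2.0 * k,
        n=len(df),
        n_events=int(df["event"].sum()),
        covariates=tuple(covariate_names),
    )


def stepwise_cox(
    table: pd.DataFrame,
    candidates: list[str],
    forced: list[str] = (),
) -> tuple[CoxFit, pd.DataFrame]:
    """Bidirectional stepwise selection minimizing AIC, from the full model.

    ``forced`` covariates are always retained.  Returns the final fit and a
    trace of every accepted move (action, covariate, AIC).
    """
    forced = list(forced)
    candidates = list(candidates)
    if not candidates:
        raise SurvivalModelError("empty candidate set for stepwise selection")
    overlap = set(candidates) & set(forced)
    if overlap:
        raise SurvivalModelError(
            f"candidate and forced sets overlap: {sorted(overlap)}"
        )

    def try_fit(names: list[str]) -> CoxFit | None:
        try:
            return fit_cox(table, names)
        except SurvivalModelError:
            return None

    current = [c for c in candidates if try_fit(forced + [c]) is not None]
    fit = try_fit(forced + current)
    if fit is None:
        raise SurvivalModelError("full candidate model could not be fitted")
    trace = [{"step": 0, "action": "start", "covariate": "+".join(forced + current),
              "aic": fit.aic}]
    step = 0
    while True:
        step += 1
        moves: list[tuple[float, str, str, CoxFit]] = []
        for c in current:
            trial = [x for x in current if x != c]
            if forced + trial:
                f = try_fit(forced + trial)
                if f is not None:
                    moves.append((f.aic, "drop", c, f))
        for c in candidates:
            if c not in current:
                f = try_fit(forced + current + [c])
                if f is not None:
                    moves.append((f.aic, "add", c, f))
        if not moves:
            break
        best_aic, action, cov, best_fit = min(moves, key=lambda m: m[0])
        if best_aic >= fit.aic - 1e-10:
            break
        if action == "drop":
            current.remove(cov)
        else:
            current.append(cov)
        fit = best_fit
        trace.append({"step": step, "action": action, "covariate": cov,
                      "aic": fit.aic})
    return fit, pd.DataFrame(trace)


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank (Savage) scores a_i = event_i - NelsonAalen(time_i)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    n = len(time)
    t_sorted = time[order]
    e_sorted = event[order]
    cumhaz_sorted = np.empty(n)
    at_risk = n
    ch = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        d = int(e_sorted[i:j].sum())
        ch += d / at_risk
        cumhaz_sorted[i:j] = ch
        at_risk -= j - i
        i = j
    cumhaz = np.empty(n)
    cumhaz[order] = cumhaz_sorted
    return event - cumhaz


def lausen_adjusted_p(b: float, minprop: float) -> float:
    """Brownian-bridge crossing approximation for the maximal statistic.

    Two-sided familywise p for sup |B(t)| / sqrt(t(1-t)) over
    t in [minprop, 1 - minprop]; floored at the pointwise two-sided normal
    p of the observed maximum and capped at 1.
    """
    e1, e2 = minprop, 1.0 - minprop
    pointwise = 2.0 * norm.sf(b)
    if b <= 0:
        return 1.0
    approx = norm.pdf(b) * (b - 1.0 / b) * np.log(e2 * (1 - e1) / (e1 * (1 - e2)))
    approx += 4.0 * norm.pdf(b) / b
    return float(min(1.0, max(approx, pointwise)))


def maxstat_cutpoint(
    table: pd.DataFrame,
    feature_name: str,
    minprop: float = 0.1,
    pmethod: str = "lausen",
    n_permutations: int = 1000,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for one feature.

    Candidate cutpoints are the observed feature values whose induced
    low/high groups both hold at least ``minprop`` of the patients; ties in
    the maximum go to the smaller cutpoint.  ``pmethod`` is "lausen"
    (analytic approximation) or "permutation" (seeded).
    """
    _validate_table(table)
    if not 0 < minprop < 0.5:
        raise SurvivalModelError("minprop must be in (0, 0.5)")
    x = table[feature_name].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise SurvivalModelError(f"feature {feature_name!r} has < 2 distinct values")
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    n = len(x)
    a = logrank_scores(time, event)
    a_bar = a.mean()
    ss = np.sum((a - a_bar) ** 2)

    order = np.argsort(x, kind="stable")
    x_sorted = x[order]
    csum = np.cumsum(a[order])
    # m = number of subjects with x <= candidate value; candidates are the
    # unique values at the upper edge of each tied run.
    uniq_mask = np.r_[x_sorted[1:] != x_sorted[:-1], True]
    m_all = np.flatnonzero(uniq_mask) + 1
    lo = int(np.ceil(minprop * n))
    hi = int(np.floor((1 - minprop) * n))
    keep = (m_all >= lo) & (m_all <= hi)
    if not keep.any():
        raise SurvivalModelError(
            f"no candidate split keeps both groups above minprop={minprop}"
        )
    m = m_all[keep]
    cuts = x_sorted[m - 1]
    s = csum[m - 1]
    var = m * (n - m) / (n * (n - 1.0)) * ss
    if np.any(var <= 0):
        raise SurvivalModelError("degenerate log-rank scores (no events?)")
    z = np.abs((s - m * a_bar) / np.sqrt(var))
    best = int(np.argmax(z))  # first max -> smaller cutpoint on ties
    b = float(z[best])

    if pmethod == "lausen":
        p = lausen_adjusted_p(b, minprop)
    elif pmethod == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            ap = rng.permutation(a)
            csum_p = np.cumsum(ap)
            sp = csum_p[m - 1]
            zp = np.max(np.abs((sp - m * a_bar) / np.sqrt(var)))
            count += zp >= b
        p = (count + 1) / (n_permutations + 1)
    else:
        raise SurvivalModelError(f"unknown pmethod {pmethod!r}")
    return CutpointResult(
        cutpoint=float(cuts[best]),
        max_statistic=b,
        adjusted_p=float(p),
        minprop=minprop,
        candidate_cutpoints=cuts,
        candidate_statistics=z,
    )


def km_curve(table: pd.DataFrame, group_col: str) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit curves per group."""
    _validate_table(table)
    if int(table["event"].sum()) < 1:
        raise SurvivalModelError("need at least one event for a KM curve")
    out = {}
    for g, sub in table.groupby(group_col):
        if len(sub) == 0:
            raise SurvivalModelError(f"group {g!r} has zero patients")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(
            kmf.survival_function_.index
        ).to_numpy(dtype=float)
        out[g] = KMCurve(times=times, survival=surv, at_risk=at_risk)
    if not out:
        raise SurvivalModelError("no groups to fit")
    return out


def logrank_test(table: pd.DataFrame, group_col: str) -> tuple[float, float]:
    """Log-rank chi-square test across groups (1 df for two groups)."""
    _validate_table(table)
    groups = table[group_col]
    if groups.nunique() < 2:
        raise SurvivalModelError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(table["time"], groups, table["event"])
    return float(res.test_statistic), float(res.p_value)
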