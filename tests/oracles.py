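"""Independent brute-force oracles used by the test suite.

Everything here is written from the defining formulas with plain Python
loops (or scipy optimizers over an explicitly written likelihood), sharing
no code with the package, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def oracle_region_stats(values, n_bins: int, lo: float, hi: float) -> dict:
    """The 12 region statistics by direct formula evaluation."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    mean = sum(xs) / n

    def perc(q):  # linear-interpolation percentile
        pos = (n - 1) * q / 100.0
        i = int(math.floor(pos))
        frac = pos - i
        if i + 1 >= n:
            return xs[-1]
        return xs[i] * (1 - frac) + xs[i + 1] * frac

    median = perc(50)
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    m4 = sum((x - mean) ** 4 for x in xs) / n
    abs_dev = sorted(abs(x - median) for x in xs)
    mad = abs_dev[n // 2] if n % 2 == 1 else 0.5 * (abs_dev[n // 2 - 1] + abs_dev[n // 2])

    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for x in xs:
        xc = min(max(x, lo), hi)
        idx = min(int((xc - lo) / width), n_bins - 1)
        counts[idx] += 1
    p = [c / n for c in counts]
    return {
        "min": xs[0],
        "max": xs[-1],
        "mean": mean,
        "median": median,
        "mean_median_diff": mean - median,
        "std": math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1)),
        "iqr": perc(75) - perc(25),
        "mad": mad,
        "skewness": m3 / m2**1.5,
        "kurtosis": m4 / m2**2 - 3.0,
        "hist_energy": sum(pi**2 for pi in p),
        "hist_entropy": -sum(pi * math.log(pi) for pi in p if pi > 0),
    }


def efron_negative_log_partial_likelihood(beta, time, event, x):
    """Single-covariate Cox partial likelihood with Efron tie correction."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        d_idx = np.flatnonzero((time == t) & (event == 1))
        r_idx = np.flatnonzero(time >= t)
        d = len(d_idx)
        sum_r = theta[r_idx].sum()
        sum_d = theta[d_idx].sum()
        ll += beta * x[d_idx].sum()
        for ell in range(d):
            ll -= math.log(sum_r - (ell / d) * sum_d)
    return -ll


def brute_force_cox_beta(time, event, x, bound: float = 8.0) -> float:
    """Maximize the written-out Efron partial likelihood numerically."""
    res = minimize_scalar(
        efron_negative_log_partial_likelihood,
        bounds=(-bound, bound),
        args=(time, event, x),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def hand_logrank(time, event, group) -> tuple[float, float]:
    """Two-sample log-rank chi-square from observed-minus-expected 2x2 tables."""
    from scipy.stats import chi2 as chi2_dist

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    g1 = sorted(set(group))[1]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == g1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == g1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return float(chi2), float(chi2_dist.sf(chi2, 1))


def oracle_logrank_scores(time, event):
    """Log-rank scores event_i - NelsonAalen(t_i), by explicit loop."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(time)
    scores = np.empty(n)
    for i in range(n):
        ch = 0.0
        for t in sorted(set(time[time <= time[i]])):
            d = ((time == t) & (event == 1)).sum()
            r = (time >= t).sum()
            ch += d / r
        scores[i] = event[i] - ch
    return scores


def exhaustive_maxstat(time, event, x, minprop: float):
    """Enumerate every admissible split and its standardized statistic."""
    x = np.asarray(x, float)
    n = len(x)
    a = oracle_logrank_scores(time, event)
    a_bar = a.mean()
    ss = float(((a - a_bar) ** 2).sum())
    results = []
    for mu in sorted(set(x)):
        low = x <= mu
        m = int(low.sum())
        if m < math.ceil(minprop * n) or m > math.floor((1 - minprop) * n):
            continue
        s = float(a[low].sum())
        v = m * (n - m) / (n * (n - 1.0)) * ss
        results.append((mu, abs(s - m * a_bar) / math.sqrt(v)))
    best_mu, best_z = max(results, key=lambda r: (r[1], -r[0]))
    # ties in the max resolve to the smaller cutpoint
    for mu, z in results:
        if z == best_z and mu < best_mu:
            best_mu = mu
    return best_mu, best_z, results
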