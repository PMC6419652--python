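"""Statistical layer: paired comparison, Cox regression, Kaplan-Meier/log-rank.

Per-feature pairs of ungated/gated values are compared with the Wilcoxon
signed-rank test.  Prognostic value is assessed feature-by-feature with a
univariate Cox proportional-hazards model on standard-scaled features
(hazard ratio per 1 SD) and with maximally selected log-rank cutoffs that
dichotomize a feature into two Kaplan-Meier groups.  The Cox model is fit
in-package (single covariate, Efron tie handling, Newton-Raphson); the
Kaplan-Meier curves and two-group log-rank test come from lifelines.

No multiple-testing correction is applied across the feature panel; the
naive cutoff p-values are maximally selected statistics and anti-conservative.
A synthetic survival generator ties exponential hazards to chosen
standardized features for end-to-end simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import optimize, stats

__all__ = [
    "WilcoxonResult",
    "CoxResult",
    "CutoffResult",
    "wilcoxon_paired",
    "standard_scale",
    "cox_univariate",
    "cox_score_test",
    "km_logrank",
    "optimal_cutoff",
    "simulate_survival",
    "table2_analysis",
]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p: float
    n_used: int
    degenerate: bool = False


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: hazard ratio per 1 SD of the (scaled) feature."""

    hr: float
    ci95: tuple[float, float]
    p: float
    n: int
    n_events: int
    beta: float
    se: float
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")
        if not (self.ci95[0] <= self.hr <= self.ci95[1]):
            raise ValueError("ci95 must contain the hazard ratio")


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    group_sizes: tuple[int, int]  # (low = value <= cutoff, high = value > cutoff)
    logrank_chi2: float
    logrank_p: float


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 untied differences, the normal approximation with continuity
    correction otherwise.  All-zero differences give a flagged p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 6:
        raise ValueError("x and y must be equal-length 1-D with n >= 6")
    d = y - x
    nz = d[d != 0]
    if nz.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, degenerate=True)
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return WilcoxonResult(float(res.statistic), float(res.pvalue), int(nz.size))


def standard_scale(values: Sequence[float]) -> np.ndarray:
    """(v - mean) / population SD.  Constant input returns flagged zeros."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=0)
    if sd == 0:
        warnings.warn("standard_scale: constant input, returning zeros", stacklevel=2)
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _efron_quantities(beta, x, times, events):
    """(loglik, score U, information I) of the Efron partial likelihood."""
    order = np.argsort(-times, kind="stable")  # descending time
    x_s = x[order]
    t_s = times[order]
    e_s = events[order]
    w = np.exp(beta * x_s)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x_s)
    s2 = np.cumsum(w * x_s**2)
    ll = 0.0
    U = 0.0
    info = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # risk set = everyone with time >= t_s[i] -> prefix up to j-1 in sorted order
        ev = np.nonzero(e_s[i:j] == 1)[0] + i
        d = len(ev)
        if d > 0:
            S0r, S1r, S2r = s0[j - 1], s1[j - 1], s2[j - 1]
            wD = w[ev]
            S0d, S1d, S2d = wD.sum(), (wD * x_s[ev]).sum(), (wD * x_s[ev] ** 2).sum()
            xD = x_s[ev].sum()
            ll += beta * xD
            for l in range(d):
                frac = l / d
                den = S0r - frac * S0d
                n1 = S1r - frac * S1d
                n2 = S2r - frac * S2d
                ll -= math.log(den)
                U += -n1 / den
                info += n2 / den - (n1 / den) ** 2
            U += xD
        i = j
    return ll, U, info


def cox_univariate(
    x: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Newton-Raphson fit of the univariate Cox model with Efron ties.

    Converged when |score| < tol; monotone likelihood (perfect separation)
    and non-convergence are flagged.  Fewer than 10 events triggers a
    warning (estimates are unstable).
    """
    x = np.asarray(x, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if not (len(x) == len(times) == len(events)):
        raise ValueError("x, times, events must have equal length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    n = len(x)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events")
    if n_events < 10:
        warnings.warn(f"only {n_events} events; Cox estimate unstable", stacklevel=2)

    beta = 0.0
    flag = None
    for it in range(max_iter):
        ll, U, info = _efron_quantities(beta, x, times, events)
        if abs(U) < tol:
            break
        if info <= 1e-12:
            flag = "degenerate"
            break
        step = U / info
        step = float(np.clip(step, -2.0, 2.0))  # guard huge first steps
        new_beta = beta + step
        ll_new, _, _ = _efron_quantities(new_beta, x, times, events)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            ll_new, _, _ = _efron_quantities(new_beta, x, times, events)
            halvings += 1
        beta = new_beta
        if abs(beta) > 10.0:
            flag = "separation"
            break
    else:
        flag = "non-convergence"
    _, _, info = _efron_quantities(beta, x, times, events)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    hr = math.exp(beta)
    ci = (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)) if math.isfinite(se) else (0.0, math.inf)
    return CoxResult(hr, ci, float(p), n, n_events, float(beta), float(se), flag)


def cox_score_test(
    x: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> tuple[float, float]:
    """Cox score test at beta = 0: (chi2, p).

    For a binary covariate with distinct event times this equals the
    two-group log-rank chi-square.
    """
    x = np.asarray(x, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    _, U, info = _efron_quantities(0.0, x, times, events)
    if info <= 0:
        return 0.0, 1.0
    chi2 = U**2 / info
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_logrank(
    times: Sequence[float], events: Sequence[int], group_labels: Sequence
) -> Dict[str, object]:
    """Two-group Kaplan-Meier estimates and log-rank test.

    Returns ``{"chi2", "p", "km_curves"}`` where km_curves maps each group
    label to a DataFrame with columns time/survival.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(uniq)}")
    curves = {}
    for g in uniq:
        sel = labels == g
        if sel.sum() == 0:
            raise ValueError(f"group {g} is empty")
        if events[sel].sum() == 0:
            raise ValueError(f"group {g} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a = labels == uniq[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return {"chi2": float(res.test_statistic), "p": float(res.p_value), "km_curves": curves}


def _logrank_chi2(times, events, high) -> float:
    """Fast two-group log-rank chi-square (hypergeometric moments)."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    h = high[order].astype(np.float64)
    n = len(t)
    obs_minus_exp = 0.0
    var = 0.0
    i = 0
    at_risk = n
    at_risk_h = float(h.sum())
    while i < n:
        j = i
        d = 0.0
        d_h = 0.0
        while j < n and t[j] == t[i]:
            d += e[j]
            d_h += e[j] * h[j]
            j += 1
        if d > 0 and 0 < at_risk_h < at_risk:
            frac = at_risk_h / at_risk
            obs_minus_exp += d_h - d * frac
            if at_risk > 1:
                var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        at_risk -= j - i
        at_risk_h -= float(h[i:j].sum())
        i = j
    if var <= 0:
        return 0.0
    return obs_minus_exp**2 / var


def optimal_cutoff(
    feature_values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    min_group_size: Optional[int] = None,
) -> CutoffResult:
    """Maximally selected log-rank cutoff for one feature.

    Candidates are the unique feature values between the 10th and 90th
    percentiles; each dichotomizes into low (<= cutoff) and high (> cutoff)
    groups, both required to have at least max(5, 10% of n) subjects.  The
    cutoff maximizing the log-rank chi-square wins, ties going to the
    smaller cutoff.  The reported p-value is the naive log-rank p and is
    anti-conservative (no correction for the maximal selection).
    """
    v = np.asarray(feature_values, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    n = len(v)
    if n < 20:
        raise ValueError("optimal_cutoff needs at least 20 subjects")
    mgs = min_group_size if min_group_size is not None else max(5, math.ceil(0.1 * n))
    q10, q90 = np.percentile(v, [10, 90])
    candidates = np.unique(v[(v >= q10) & (v <= q90)])
    best: Optional[tuple[float, float]] = None
    for c in candidates:
        high = v > c
        nh = int(high.sum())
        if nh < mgs or n - nh < mgs:
            continue
        chi2 = _logrank_chi2(times, events, high)
        if best is None or chi2 > best[1]:
            best = (float(c), chi2)
    if best is None:
        raise ValueError("no cutoff satisfies the group-size constraint")
    cutoff, chi2 = best
    high = v > cutoff
    p = float(stats.chi2.sf(chi2, df=1))
    return CutoffResult(cutoff, (int((~high).sum()), int(high.sum())), float(chi2), p)


def simulate_survival(
    lin_pred: Sequence[float],
    lambda0: float = math.log(2) / 40.0,
    censor_frac: float = 0.2,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-hazard survival with independent uniform censoring.

    Event times T_i ~ Exp(lambda0 * exp(lin_pred_i)); censoring C_i ~
    U(0, m) with m solved so the expected censoring fraction matches
    ``censor_frac``.  Returns (observed times, event indicators).  The
    default baseline puts the median survival at 40 weeks under a null
    linear predictor.
    """
    lp = np.asarray(lin_pred, dtype=np.float64)
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    if not (0.0 <= censor_frac < 1.0):
        raise ValueError("censor_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rates = lambda0 * np.exp(lp)
    T = rng.exponential(1.0 / rates)
    if censor_frac == 0.0:
        return T, np.ones(len(T), dtype=np.int64)

    def expected_censored(m: float) -> float:
        rm = rates * m
        return float(np.mean((1.0 - np.exp(-rm)) / rm))

    lo, hi = 1e-6 / lambda0, 1e6 / lambda0
    m = optimize.brentq(lambda mm: expected_censored(mm) - censor_frac, lo, hi)
    C = rng.uniform(0.0, m, size=len(T))
    obs = np.minimum(T, C)
    ev = (T <= C).astype(np.int64)
    return obs, ev


def table2_analysis(
    feature_table: pd.DataFrame,
    survival_table: pd.DataFrame,
    feature_names: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature, per-reconstruction Cox HRs and optimal cutoffs.

    ``feature_table`` is tidy: columns subject_id, reconstruction (values
    "nonORG"/"ORG") and one column per feature.  ``survival_table`` has
    columns subject_id, time_weeks, event.  Returns (cox table, cutoff
    table); Cox rows carry HR, 95% CI and Wald p per 1 SD.
    """
    required = {"subject_id", "reconstruction"}
    if not required <= set(feature_table.columns):
        raise ValueError("feature_table needs subject_id and reconstruction columns")
    recons = sorted(feature_table["reconstruction"].unique())
    subj_sets = [
        frozenset(feature_table.loc[feature_table["reconstruction"] == r, "subject_id"])
        for r in recons
    ]
    if len(set(subj_sets)) != 1:
        raise ValueError("subjects differ across reconstructions")
    if len(subj_sets[0]) < 2:
        raise ValueError("need at least 2 subjects")
    if feature_names is None:
        feature_names = [
            c for c in feature_table.columns if c not in ("subject_id", "reconstruction")
        ]
    surv = survival_table.set_index("subject_id")
    cox_rows = []
    cut_rows = []
    for recon in recons:
        sub = feature_table[feature_table["reconstruction"] == recon].set_index("subject_id")
        sub = sub.loc[surv.index]
        times = surv["time_weeks"].to_numpy(dtype=float)
        events = surv["event"].to_numpy(dtype=int)
        for name in feature_names:
            vals = sub[name].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaled = standard_scale(vals)
                res = cox_univariate(scaled, times, events)
            cox_rows.append(
                {
                    "feature": name,
                    "reconstruction": recon,
                    "HR": res.hr,
                    "CI95_low": res.ci95[0],
                    "CI95_high": res.ci95[1],
                    "p_value": res.p,
                    "flag": res.flag or "",
                }
            )
            try:
                cut = optimal_cutoff(vals, times, events)
                cut_rows.append(
                    {
                        "feature": name,
                        "reconstruction": recon,
                        "cutoff": cut.cutoff,
                        "n_low": cut.group_sizes[0],
                        "n_high": cut.group_sizes[1],
                        "logrank_chi2": cut.logrank_chi2,
                        "logrank_p": cut.logrank_p,
                    }
                )
            except ValueError:
                cut_rows.append(
                    {
                        "feature": name,
                        "reconstruction": recon,
                        "cutoff": float("nan"),
                        "n_low": 0,
                        "n_high": 0,
                        "logrank_chi2": float("nan"),
                        "logrank_p": float("nan"),
                    }
                )
    return pd.DataFrame(cox_rows), pd.DataFrame(cut_rows)
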