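"""Outcome statistics: survival estimation and the cohort's hypothesis tests.

The survival machinery — Kaplan–Meier product-limit estimation, the two-group
log-rank test, maximally selected rank-statistic cutpoints, univariate Cox
proportional hazards with Efron tie handling, and Holm / Benjamini–Hochberg
multiplicity adjustment — is implemented here directly. Classical
well-characterized kernels (Shapiro–Wilk, t and rank-sum tests, Spearman,
one-way ANOVA, Tukey HSD) are delegated to scipy/statsmodels.

Conventions:

* Biomarker cutpoints are chosen by scanning observed covariate values whose
  quantile rank lies in a (0.1, 0.9) window and maximizing the absolute
  standardized log-rank statistic of the induced dichotomy. The log-rank p
  at the selected cutpoint ignores the selection and is reported as
  ``p_uncorrected``; an optional permutation p accounts for selection.
* Two-group comparisons are routed by per-group Shapiro–Wilk normality at
  α = 0.05: Student's t when both groups pass, Wilcoxon rank-sum otherwise
  (signed-rank for explicitly paired designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KaplanMeier",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "CutpointResult",
    "maxstat_cutpoint",
    "CoxResult",
    "cox_univariate",
    "TwoGroupResult",
    "two_group_test",
    "adjust_pvalues",
    "differential_marker_test",
    "spearman_matrix",
    "anova_tukey",
]


# ----------------------------------------------------------------- Kaplan–Meier


@dataclass
class KaplanMeier:
    """Product-limit survival estimate with per-event-time risk-set counts."""

    event_times: np.ndarray  # distinct times with >= 1 death
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """Step-function evaluation; S(t) = 1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:  # no deaths observed: S = 1 throughout
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right")
        return np.where(idx == 0, 1.0, self.survival[np.maximum(idx - 1, 0)])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KaplanMeier:
    """Kaplan–Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored subjects (event flag 0) leave the risk set after their time
    (standard convention: at a tied time, deaths precede censorings).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times[events == 1])
    n = times.size
    n_risk = np.empty(distinct.size)
    n_events = np.empty(distinct.size)
    surv = np.empty(distinct.size)
    s = 1.0
    for i, t in enumerate(distinct):
        at_risk = np.sum(times >= t)
        deaths = np.sum((times == t) & (events == 1))
        s *= 1.0 - deaths / at_risk
        n_risk[i], n_events[i], surv[i] = at_risk, deaths, s
    return KaplanMeier(distinct, n_risk.astype(int), n_events.astype(int), surv)


# --------------------------------------------------------------------- log-rank


@dataclass
class LogrankResult:
    statistic: float  # chi-square
    df: int
    p_value: float
    observed: float  # deaths observed in group 1
    expected: float  # deaths expected in group 1 under H0
    variance: float


def _logrank_oe(times: np.ndarray, events: np.ndarray, in_group1: np.ndarray):
    """Observed, expected and hypergeometric variance for group 1 deaths."""
    event_times = np.unique(times[events == 1])
    o = e = v = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_group1).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o, e, v


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> LogrankResult:
    """Two-group log-rank test: chi-square (O − E)²/V with 1 df.

    Invariant under swapping the group labels; statistic 0 when the groups'
    event experience is identical.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {labels.size}")
    in_g1 = groups == labels[0]
    o, e, v = _logrank_oe(times, events, in_g1)
    if v <= 0:
        return LogrankResult(0.0, 1, 1.0, o, e, v)
    chi2 = (o - e) ** 2 / v
    p = float(sps.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), 1, p, float(o), float(e), float(v))


# ----------------------------------------------------------- maxstat cutpoints


@dataclass
class CutpointResult:
    covariate: str
    cutpoint: float
    statistic: float  # |standardized log-rank| at the selected cutpoint
    p_uncorrected: float  # naive log-rank p, ignores cutpoint selection
    scan: pd.DataFrame  # candidate, statistic, n_low, n_high
    n_low: int
    n_high: int
    p_permutation: float | None = None


def maxstat_cutpoint(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    bounds: tuple[float, float] = (0.1, 0.9),
    covariate: str = "covariate",
    permutations: int = 0,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected rank-statistic cutpoint for a survival biomarker.

    Candidates are the distinct observed values whose empirical quantile rank
    lies strictly inside ``bounds``; each dichotomizes the cohort into
    low (≤ cutpoint) vs high (> cutpoint) and is scored by the absolute
    standardized log-rank statistic |O − E|/√V. The argmax wins (ties → the
    smaller cutpoint). Because the scan maximizes over candidates, the naive
    log-rank p at the winner is anti-conservative; it is labeled
    ``p_uncorrected`` and an optional permutation p (covariate permuted,
    selection re-run) is offered.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = values.size
    if n < 10:
        raise ValueError(f"maxstat needs >= 10 subjects, got {n}")

    def _scan(vals: np.ndarray) -> tuple[float, float, pd.DataFrame] | None:
        ranks = sps.rankdata(vals, method="average") / n
        candidates = np.unique(vals[(ranks > bounds[0]) & (ranks < bounds[1])])
        rows = []
        best = None
        for c in candidates:
            high = vals > c
            n_high = int(high.sum())
            n_low = n - n_high
            if n_high == 0 or n_low == 0:
                continue
            o, e, v = _logrank_oe(times, events, high)
            stat = abs(o - e) / np.sqrt(v) if v > 0 else 0.0
            rows.append((c, stat, n_low, n_high))
            if best is None or stat > best[1]:
                best = (c, stat, n_low, n_high)
        if best is None:
            return None
        scan = pd.DataFrame(rows, columns=["candidate", "statistic", "n_low", "n_high"])
        return best[0], best[1], scan

    result = _scan(values)
    if result is None:
        raise ValueError(
            f"no candidate cutpoints inside quantile bounds {bounds} "
            f"(covariate needs >= 2 distinct values there)"
        )
    cut, stat, scan = result
    row = scan.loc[scan["candidate"] == cut].iloc[0]
    p_naive = float(sps.chi2.sf(stat**2, df=1))

    p_perm = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm = _scan(rng.permutation(values))
            if perm is not None and perm[1] >= stat:
                hits += 1
        p_perm = (hits + 1) / (permutations + 1)
    return CutpointResult(
        covariate=covariate,
        cutpoint=float(cut),
        statistic=float(stat),
        p_uncorrected=p_naive,
        scan=scan,
        n_low=int(row["n_low"]),
        n_high=int(row["n_high"]),
        p_permutation=p_perm,
    )


# ------------------------------------------------------------------------- Cox


@dataclass
class CoxResult:
    coef: float
    hazard_ratio: float
    se: float
    ci_low: float  # 95% CI on the hazard ratio
    ci_high: float
    p_value: float  # Wald
    converged: bool
    n_iter: int
    estimable: bool = True
    note: str = ""


def _cox_derivatives(beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray):
    """Log partial likelihood and its first two derivatives, Efron ties."""
    order = np.argsort(times, kind="stable")
    times, events, x = times[order], events[order], x[order]
    theta = np.exp(beta * x)
    ll = u = i_info = 0.0
    event_times = np.unique(times[events == 1])
    for t in event_times:
        at_risk = times >= t
        tied = (times == t) & (events == 1)
        d = int(tied.sum())
        s0 = theta[at_risk].sum()
        s1 = (theta[at_risk] * x[at_risk]).sum()
        s2 = (theta[at_risk] * x[at_risk] ** 2).sum()
        t0 = theta[tied].sum()
        t1 = (theta[tied] * x[tied]).sum()
        t2 = (theta[tied] * x[tied] ** 2).sum()
        ll += beta * x[tied].sum()
        for k in range(d):
            f = k / d
            z0 = s0 - f * t0
            z1 = s1 - f * t1
            z2 = s2 - f * t2
            ll -= np.log(z0)
            u += x[tied].sum() / d - z1 / z0  # accumulate per-tie mean score
            i_info += z2 / z0 - (z1 / z0) ** 2
    # the x-sum term above distributes the tied deaths' covariate sum evenly
    return ll, u, i_info


def cox_univariate(
    times: Sequence[float],
    events: Sequence[int],
    x: Sequence[float],
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton–Raphson (Efron ties).

    Returns the hazard ratio exp(β̂), a Wald 95% CI from the observed
    information, and a convergence report. Monotone likelihoods (complete
    separation, e.g. all events in one covariate extreme) are detected by
    coefficient blow-up and flagged non-estimable instead of reporting a
    huge finite HR.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    if events.sum() < 2:
        raise ValueError("Cox fit needs >= 2 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    # center & scale for numerical stability; back-transform at the end
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, u, info = _cox_derivatives(beta, times, events, xs)
        if info <= 0:
            break
        step = u / info
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 50:
            break

    # |standardized log-HR| beyond ~15 only arises when the likelihood is
    # monotone and Newton walks off to infinity
    if abs(beta) > 15 or not np.isfinite(beta):
        return CoxResult(
            coef=float("nan"),
            hazard_ratio=float("nan"),
            se=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            converged=False,
            n_iter=it,
            estimable=False,
            note="monotone partial likelihood (complete separation)",
        )
    _, _, info = _cox_derivatives(beta, times, events, xs)
    se_s = 1.0 / np.sqrt(info)
    coef = beta / sd
    se = se_s / sd
    z = coef / se
    p = float(2 * sps.norm.sf(abs(z)))
    with np.errstate(over="ignore"):  # wide CIs may overflow to inf; keep them
        hr = float(np.exp(coef))
        ci_low = float(np.exp(coef - 1.959963984540054 * se))
        ci_high = float(np.exp(coef + 1.959963984540054 * se))
    return CoxResult(
        coef=float(coef),
        hazard_ratio=hr,
        se=float(se),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        converged=converged,
        n_iter=it,
    )


def cox_partial_loglik(
    beta: float, times: Sequence[float], events: Sequence[int], x: Sequence[float]
) -> float:
    """Efron log partial likelihood at a given coefficient (QC / oracle use)."""
    ll, _, _ = _cox_derivatives(
        float(beta),
        np.asarray(times, dtype=float),
        np.asarray(events, dtype=int),
        np.asarray(x, dtype=float),
    )
    return float(ll)


# -------------------------------------------------------- routed two-group test


@dataclass
class TwoGroupResult:
    test: str  # "t-test" | "rank-sum" | "signed-rank" | "not-computable"
    statistic: float
    p_value: float
    shapiro_p: tuple[float, float]
    note: str = ""


def two_group_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> TwoGroupResult:
    """Normality-routed two-group comparison.

    Shapiro–Wilk is run per group; when both p-values exceed
    ``normality_alpha`` the two-tailed Student's t-test is used, otherwise
    the Wilcoxon rank-sum (unpaired) or signed-rank (paired) test. The test
    actually applied is recorded in the result.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TwoGroupResult("not-computable", float("nan"), float("nan"),
                                  (float("nan"), float("nan")),
                                  "zero variance in both groups")
        # constant but different: every permutation separates them; report
        # the rank test which handles the degenerate spread
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TwoGroupResult("rank-sum", float(stat), float(p),
                              (float("nan"), float("nan")), "both groups constant")
    sw_a = sps.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sw_b = sps.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
    normal = sw_a > normality_alpha and sw_b > normality_alpha
    if normal:
        stat, p = sps.ttest_ind(a, b) if not paired else sps.ttest_rel(a, b)
        return TwoGroupResult("t-test", float(stat), float(p), (float(sw_a), float(sw_b)))
    if paired:
        stat, p = sps.wilcoxon(a, b)
        name = "signed-rank"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "rank-sum"
    return TwoGroupResult(name, float(stat), float(p), (float(sw_a), float(sw_b)))


# ------------------------------------------------------- multiplicity adjustment


def adjust_pvalues(p_values: Sequence[float], method: str = "holm") -> np.ndarray:
    """Holm (step-down) or Benjamini–Hochberg (step-up) adjusted p-values.

    Input order is preserved; monotonicity is enforced; output is capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adjusted[idx] = min(running, 1.0)
    elif method == "bh":
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, m * p[idx] / (rank + 1))
            adjusted[idx] = min(running, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}; use 'holm' or 'bh'")
    return adjusted


# --------------------------------------------------- differential marker model


def differential_marker_test(
    medians: pd.DataFrame,
    groups: Sequence,
    log_transform: bool = True,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Per-marker group-indicator linear model on per-sample medians.

    ``medians`` is samples × markers; ``groups`` gives each sample's label
    (exactly two levels). Each marker is regressed on the indicator of the
    second (alphabetically later) level; with ``log_transform`` the response
    is log2(median), so the coefficient is the log2 fold change. p-values are
    BH-adjusted across markers — a volcano-ready table.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    counts = [(groups == g).sum() for g in levels]
    if min(counts) < 3:
        raise ValueError("need >= 3 samples per group")
    indicator = (groups == levels[1]).astype(float)
    rows = []
    for marker in medians.columns:
        y = medians[marker].to_numpy(dtype=float)
        if log_transform:
            if np.any(y <= 0):
                y = np.log2(y + pseudocount - min(0.0, y.min()))
            else:
                y = np.log2(y)
        if np.ptp(y) == 0:
            rows.append((marker, 0.0, float("nan"), "constant"))
            continue
        res = sps.linregress(indicator, y)
        rows.append((marker, float(res.slope), float(res.pvalue), ""))
    out = pd.DataFrame(rows, columns=["marker", "logFC", "p_value", "flag"])
    ok = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = adjust_pvalues(out.loc[ok, "p_value"].to_numpy(), "bh")
    out["p_adj_bh"] = adj
    out["contrast"] = f"{levels[1]} vs {levels[0]}"
    return out


# ------------------------------------------------------------------ correlation


def spearman_matrix(x: pd.DataFrame, y: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlation between the columns of two tables.

    Rows are paired samples (aligned on index); ties receive average ranks.
    Returns ``(R, p)`` DataFrames indexed x-column × y-column; pairs with a
    constant vector are NaN (not computable).
    """
    if len(x) != len(y):
        raise ValueError("x and y must have the same number of (paired) rows")
    if len(x) < 4:
        raise ValueError("need >= 4 paired samples")
    r = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    p = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    for cx in x.columns:
        for cy in y.columns:
            a = x[cx].to_numpy(dtype=float)
            b = y[cy].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            res = sps.spearmanr(a, b)
            r.loc[cx, cy] = float(res.statistic)
            p.loc[cx, cy] = float(res.pvalue)
    return r, p


# ------------------------------------------------------------------ ANOVA+Tukey


def anova_tukey(values: Sequence[float], groups: Sequence) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey HSD post-hoc for >= 3 groups.

    Returns ``(F, p, pairwise)`` where pairwise has one row per group pair
    with the mean difference, Tukey-adjusted p and 95% family-wise CI.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 3:
        raise ValueError("ANOVA+Tukey path is for >= 3 groups; use two_group_test")
    samples = [values[groups == g] for g in labels]
    f_stat, p = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, groups)
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return float(f_stat), float(p), pairwise
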