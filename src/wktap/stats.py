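"""Group-level inference on per-participant timing metrics.

Between-group differences are estimated by linear regression of a metric
on a group indicator, optionally adjusting for age and gender;
heteroskedasticity-consistent (HC3) standard errors are reported because
metric variances differ markedly between groups, but interval inference
rests on the non-parametric bias-corrected and accelerated (BCa)
bootstrap, resampling participants (the independent unit) stratified by
group and refitting the regression in every replicate.  Default 2000
replications.

Also provided: the drift-direction x group interaction model for absolute
drift, cognition-tapping association models (per-group slopes and their
interaction), and an exact Fisher test for the per-group proportions of
sessions violating the two-process model's rho(1) <= 0 prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr, ndtri

logger = logging.getLogger("wktap")

__all__ = [
    "GroupComparison", "AssociationResult", "DriftInteraction",
    "ViolationTest", "StatsError", "bca_ci", "compare_groups",
    "drift_direction_interaction", "association", "violation_test",
    "fisher_exact_rx2",
]


class StatsError(ValueError):
    """Ill-posed group-level analysis (empty stratum, constant score, ...)."""


# ---------------------------------------------------------------------------
# BCa bootstrap


@dataclass(frozen=True)
class BcaInterval:
    low: float
    high: float
    flags: tuple[str, ...] = ()


def bca_ci(statistic: Callable[[np.ndarray], float], data: np.ndarray,
           n_boot: int = 2000, seed: int = 0,
           strata: np.ndarray | None = None,
           alpha: float = 0.05) -> BcaInterval:
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``statistic`` maps a (resampled) row-array to a scalar.  Rows are
    resampled with replacement, within strata when ``strata`` labels are
    given.  The bias correction ``z0`` comes from the fraction of
    bootstrap statistics below the point estimate and the acceleration
    ``a`` from jackknife skewness.  Deterministic for a fixed seed.

    Degenerate situations are flagged rather than hidden: identical
    bootstrap statistics yield a zero-width interval (``degenerate``);
    an undefined ``z0`` (fraction 0 or 1) falls back to the percentile
    interval (``percentile_fallback``).
    """
    data = np.asarray(data)
    n = len(data)
    if n_boot < 199:
        raise StatsError("n_boot must be >= 199")
    if n < 3:
        raise StatsError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(data))

    if strata is not None:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
    else:
        groups = [np.arange(n)]

    thetas = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in groups])
        thetas[b] = statistic(data[idx])

    flags: list[str] = []
    if np.ptp(thetas) == 0 and thetas[0] == theta_hat:
        return BcaInterval(theta_hat, theta_hat, ("degenerate",))

    frac_below = float(np.mean(thetas < theta_hat))
    if frac_below in (0.0, 1.0):
        flags.append("percentile_fallback")
        lo, hi = np.quantile(thetas, [alpha / 2, 1 - alpha / 2])
        return BcaInterval(float(lo), float(hi), tuple(flags))
    z0 = float(ndtri(frac_below))

    # jackknife acceleration
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(data[mask])
        mask[i] = True
    diffs = jack.mean() - jack
    denom = float(np.sum(diffs ** 2)) ** 1.5
    a = float(np.sum(diffs ** 3)) / (6.0 * denom) if denom > 0 else 0.0

    z_lo, z_hi = ndtri(alpha / 2), ndtri(1 - alpha / 2)
    def adj(z):
        return float(ndtr(z0 + (z0 + z) / (1 - a * (z0 + z))))
    lo, hi = np.quantile(thetas, [adj(z_lo), adj(z_hi)])
    if not (lo <= theta_hat <= hi):
        flags.append("estimate_outside_ci")
    return BcaInterval(float(lo), float(hi), tuple(flags))


# ---------------------------------------------------------------------------
# regression helpers


def _gender_indicator(g: pd.Series) -> np.ndarray:
    return (g.to_numpy() == "M").astype(float)


def _merge_results(results: pd.DataFrame, cohort: pd.DataFrame,
                   condition: str | None) -> pd.DataFrame:
    df = results
    if condition is not None:
        df = df[df["condition"] == condition]
    if df["participant_id"].duplicated().any():
        raise StatsError("results table has duplicate participants; "
                         "filter to a single condition first")
    merged = df.merge(cohort, on="participant_id", how="inner",
                      suffixes=("", "_cohort"))
    if "group_cohort" in merged.columns:
        clash = merged["group"] != merged["group_cohort"]
        if clash.any():
            pid = merged.loc[clash, "participant_id"].iloc[0]
            raise StatsError(f"group label mismatch for participant {pid!r}")
        merged = merged.drop(columns="group_cohort")
    return merged


def _lstsq_coef(data: np.ndarray, col: int) -> float:
    """Coefficient ``col`` of OLS of data[:,0] on data[:,1:] (const added)."""
    y = data[:, 0]
    X = np.column_stack([np.ones(len(data)), data[:, 1:]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[col])


def _robust_fit(y: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit(cov_type="HC3")


def _covariates(sub: pd.DataFrame, flags: list[str]) -> list[np.ndarray]:
    cols = []
    age = sub["age"].to_numpy(dtype=float)
    if np.ptp(age) > 0:
        cols.append(age)
    else:
        flags.append("constant_age_dropped")
    gender = _gender_indicator(sub["gender"])
    if np.ptp(gender) > 0:
        cols.append(gender)
    else:
        flags.append("constant_gender_dropped")
    return cols


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    reference_group: str
    comparison_group: str
    unadjusted_diff: float
    adjusted_diff: float
    adjusted: bool
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    robust_se: float
    p_value: float
    n_reference: int
    n_comparison: int
    flags: tuple[str, ...] = ()

    @property
    def estimate(self) -> float:
        return self.adjusted_diff if self.adjusted else self.unadjusted_diff


def compare_groups(results: pd.DataFrame, cohort: pd.DataFrame, metric: str,
                   reference: str, comparison: str, adjust: bool = True,
                   n_boot: int = 2000, seed: int = 0,
                   condition: str | None = None) -> GroupComparison:
    """Between-group difference in one metric with a BCa bootstrap CI.

    The point estimate is the group-indicator coefficient of a linear
    regression of the metric on group membership (plus age and a gender
    indicator when ``adjust``); positive values mean the comparison group
    exceeds the reference group.  The CI resamples participants within
    groups and refits the regression per replicate.
    """
    merged = _merge_results(results, cohort, condition)
    if metric not in merged.columns:
        raise StatsError(f"metric {metric!r} not in results table")
    sub = merged[merged["group"].isin([reference, comparison])].copy()
    sub = sub[np.isfinite(sub[metric].to_numpy(dtype=float))]
    counts = sub["group"].value_counts()
    for g in (reference, comparison):
        if counts.get(g, 0) < 2:
            raise StatsError(f"group {g!r} has fewer than 2 usable participants")

    flags: list[str] = []
    y = sub[metric].to_numpy(dtype=float)
    ind = (sub["group"] == comparison).to_numpy(dtype=float)
    covs = _covariates(sub, flags)
    if float(np.ptp(y)) == 0.0:
        flags.append("zero_variance_metric")

    res_unadj = _robust_fit(y, ind[:, None])
    unadjusted = float(res_unadj.params[1])
    X_adj = np.column_stack([ind] + covs) if covs else ind[:, None]
    res_adj = _robust_fit(y, X_adj)
    adjusted_diff = float(res_adj.params[1])
    headline = res_adj if adjust else res_unadj

    if adjust:
        data = np.column_stack([y, ind] + covs)
    else:
        data = np.column_stack([y, ind])
    ci = bca_ci(lambda d: _lstsq_coef(d, 1), data, n_boot=n_boot, seed=seed,
                strata=sub["group"].to_numpy())
    flags.extend(ci.flags)
    return GroupComparison(
        metric=metric, reference_group=reference, comparison_group=comparison,
        unadjusted_diff=unadjusted, adjusted_diff=adjusted_diff,
        adjusted=adjust, ci_low=ci.low, ci_high=ci.high,
        n_boot=n_boot, seed=seed,
        robust_se=float(headline.bse[1]), p_value=float(headline.pvalues[1]),
        n_reference=int(counts[reference]), n_comparison=int(counts[comparison]),
        flags=tuple(flags))


# ---------------------------------------------------------------------------
# drift-direction interaction


@dataclass(frozen=True)
class DriftInteraction:
    reference_group: str
    comparison_group: str
    diff_positive: float
    ci_positive: tuple[float, float]
    diff_negative: float
    ci_negative: tuple[float, float]
    interaction: float
    ci_interaction: tuple[float, float]
    n_cells: dict
    flags: tuple[str, ...] = ()


def drift_direction_interaction(results: pd.DataFrame, cohort: pd.DataFrame,
                                groups: tuple[str, str], n_boot: int = 2000,
                                seed: int = 0,
                                condition: str | None = None) -> DriftInteraction:
    """Does the group difference in absolute drift depend on drift sign?

    Regresses absolute drift on group x drift-direction (negative =
    getting faster) with age/gender covariates, and reports the group
    difference within each direction stratum plus their difference (the
    interaction), each with a BCa CI.  Resampling is stratified by
    group x direction cell so every replicate retains all four cells.
    """
    reference, comparison = groups
    merged = _merge_results(results, cohort, condition)
    sub = merged[merged["group"].isin(groups)].copy()
    sub = sub[np.isfinite(sub["drift_ms"].to_numpy(dtype=float))
              & np.isfinite(sub["abs_drift_ms"].to_numpy(dtype=float))]
    sub["negative"] = sub["drift_ms"] < 0
    n_cells = {}
    for g in groups:
        for sign, label in ((True, "negative"), (False, "positive")):
            k = int(((sub["group"] == g) & (sub["negative"] == sign)).sum())
            n_cells[f"{g}/{label}"] = k
            if k == 0:
                raise StatsError(f"group {g!r} has no participants with "
                                 f"{label} drift")

    flags: list[str] = []
    y = sub["abs_drift_ms"].to_numpy(dtype=float)
    grp = (sub["group"] == comparison).to_numpy(dtype=float)
    neg = sub["negative"].to_numpy(dtype=float)
    covs = _covariates(sub, flags)
    data = np.column_stack([y, grp, neg, grp * neg] + covs)
    cells = (sub["group"].astype(str) + "/" + sub["negative"].astype(str)).to_numpy()

    def coef(which):
        if which == "positive":
            return lambda d: _lstsq_coef(d, 1)
        if which == "interaction":
            return lambda d: _lstsq_coef(d, 3)
        return lambda d: _lstsq_coef(d, 1) + _lstsq_coef(d, 3)

    estimates = {w: float(coef(w)(data)) for w in ("positive", "negative",
                                                   "interaction")}
    cis = {}
    for w in ("positive", "negative", "interaction"):
        ci = bca_ci(coef(w), data, n_boot=n_boot, seed=seed, strata=cells)
        cis[w] = (ci.low, ci.high)
        flags.extend(f"{w}:{f}" for f in ci.flags)
    return DriftInteraction(
        reference_group=reference, comparison_group=comparison,
        diff_positive=estimates["positive"], ci_positive=cis["positive"],
        diff_negative=estimates["negative"], ci_negative=cis["negative"],
        interaction=estimates["interaction"], ci_interaction=cis["interaction"],
        n_cells=n_cells, flags=tuple(flags))


# ---------------------------------------------------------------------------
# cognition-tapping associations


@dataclass(frozen=True)
class AssociationResult:
    metric: str
    score: str
    slope_control: float | None
    slope_patient: float | None
    interaction: float | None
    ci_control: tuple[float, float] | None
    ci_patient: tuple[float, float] | None
    ci_interaction: tuple[float, float] | None
    pooled_slope: float | None
    ci_pooled: tuple[float, float] | None
    n_used: int
    n_dropped: int
    flags: tuple[str, ...] = ()


def association(results: pd.DataFrame, cohort: pd.DataFrame, metric: str,
                score: str, groups: tuple[str, str],
                with_interaction: bool = True, n_boot: int = 2000,
                seed: int = 0, condition: str | None = None) -> AssociationResult:
    """Relationship between a tapping metric and a cognitive score.

    With ``with_interaction``: per-group slopes (metric units per score
    unit) and their difference; otherwise a pooled slope across both
    groups.  Age/gender enter as covariates; participants missing the
    score are dropped listwise (counted in ``n_dropped``).
    """
    reference, comparison = groups
    merged = _merge_results(results, cohort, condition)
    if score not in merged.columns:
        raise StatsError(f"score column {score!r} not in cohort")
    sub = merged[merged["group"].isin(groups)].copy()
    have = np.isfinite(sub[score].to_numpy(dtype=float)) \
        & np.isfinite(sub[metric].to_numpy(dtype=float))
    n_dropped = int((~have).sum())
    if n_dropped:
        logger.info("association %s~%s: dropped %d participant(s) with "
                    "missing values", metric, score, n_dropped)
    sub = sub[have]
    for g in groups:
        if int((sub["group"] == g).sum()) < 5:
            raise StatsError(f"group {g!r} has fewer than 5 participants "
                             f"with non-missing {score}")
    s = sub[score].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise StatsError(f"score {score!r} is constant")

    flags: list[str] = []
    y = sub[metric].to_numpy(dtype=float)
    grp = (sub["group"] == comparison).to_numpy(dtype=float)
    covs = _covariates(sub, flags)
    strata = sub["group"].to_numpy()

    if with_interaction:
        data = np.column_stack([y, grp, s, grp * s] + covs)
        sl_c = _lstsq_coef(data, 2)
        sl_i = _lstsq_coef(data, 3)
        ci_c = bca_ci(lambda d: _lstsq_coef(d, 2), data, n_boot, seed, strata)
        ci_p = bca_ci(lambda d: _lstsq_coef(d, 2) + _lstsq_coef(d, 3),
                      data, n_boot, seed, strata)
        ci_i = bca_ci(lambda d: _lstsq_coef(d, 3), data, n_boot, seed, strata)
        for name, ci in (("control", ci_c), ("patient", ci_p),
                         ("interaction", ci_i)):
            flags.extend(f"{name}:{f}" for f in ci.flags)
        return AssociationResult(
            metric=metric, score=score,
            slope_control=sl_c, slope_patient=sl_c + sl_i, interaction=sl_i,
            ci_control=(ci_c.low, ci_c.high), ci_patient=(ci_p.low, ci_p.high),
            ci_interaction=(ci_i.low, ci_i.high),
            pooled_slope=None, ci_pooled=None,
            n_used=len(sub), n_dropped=n_dropped, flags=tuple(flags))

    data = np.column_stack([y, grp, s] + covs)
    pooled = _lstsq_coef(data, 2)
    ci = bca_ci(lambda d: _lstsq_coef(d, 2), data, n_boot, seed, strata)
    flags.extend(ci.flags)
    return AssociationResult(
        metric=metric, score=score,
        slope_control=None, slope_patient=None, interaction=None,
        ci_control=None, ci_patient=None, ci_interaction=None,
        pooled_slope=pooled, ci_pooled=(ci.low, ci.high),
        n_used=len(sub), n_dropped=n_dropped, flags=tuple(flags))


# ---------------------------------------------------------------------------
# rho(1) violation contingency test


@dataclass(frozen=True)
class ViolationTest:
    table: pd.DataFrame
    p_value: float
    method: str
    n_dropped: int = 0


def fisher_exact_rx2(counts: np.ndarray, seed: int = 0,
                     enumeration_limit: int = 60, n_mc: int = 100_000) -> tuple[float, str]:
    """Exact (or Monte Carlo) Fisher test for an r x 2 contingency table.

    Enumerates all tables with the observed margins when the grand total
    is at most ``enumeration_limit``, summing the hypergeometric
    probabilities of tables no more probable than the observed one;
    otherwise estimates the same tail by Monte Carlo sampling from the
    margin-conditional null with a fixed seed.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != 2 or (counts < 0).any():
        raise StatsError("expected an r x 2 table of non-negative counts")
    sizes = counts.sum(axis=1)
    if (sizes == 0).any():
        raise StatsError("empty group in contingency table")
    A = int(counts[:, 0].sum())
    N = int(sizes.sum())
    if A == 0 or A == N:
        return 1.0, "degenerate"

    def logp(a: np.ndarray) -> float:
        # multivariate hypergeometric mass with fixed margins
        num = sum(gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
                  for n, x in zip(sizes, a))
        den = gammaln(N + 1) - gammaln(A + 1) - gammaln(N - A + 1)
        return float(num - den)

    lp_obs = logp(counts[:, 0])
    tol = 1e-9
    if N <= enumeration_limit:
        total = 0.0
        def rec(i: int, remaining: int, acc: list[int]):
            nonlocal total
            if i == len(sizes) - 1:
                if 0 <= remaining <= sizes[i]:
                    lp = logp(np.array(acc + [remaining]))
                    if lp <= lp_obs + tol:
                        total += np.exp(lp)
                return
            lo = max(0, remaining - int(sizes[i + 1:].sum()))
            hi = min(sizes[i], remaining)
            for a in range(lo, hi + 1):
                rec(i + 1, remaining - a, acc + [a])
        rec(0, A, [])
        return min(float(total), 1.0), "enumeration"

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(sizes, A, size=n_mc)
    lps = np.array([logp(a) for a in draws])
    return float(np.mean(lps <= lp_obs + tol)), "monte_carlo"


def violation_test(results: pd.DataFrame,
                   group_labels: Sequence[str] | None = None,
                   condition: str | None = None, seed: int = 0) -> ViolationTest:
    """Do the proportions of model violations (rho(1) > 0) differ by group?

    Counts participants with positive lag-1 autocorrelation per group and
    applies the exact Fisher test to the resulting r x 2 table.  Sessions
    without a defined rho(1) are dropped and counted.
    """
    df = results
    if condition is not None:
        df = df[df["condition"] == condition]
    if group_labels is None:
        group_labels = list(pd.unique(df["group"]))
    if len(group_labels) < 2:
        raise StatsError("need at least 2 groups")
    rows = []
    n_dropped = 0
    for g in group_labels:
        rho = df.loc[df["group"] == g, "rho1"].to_numpy(dtype=float)
        if rho.size == 0:
            raise StatsError(f"empty group {g!r}")
        ok = np.isfinite(rho)
        n_dropped += int((~ok).sum())
        rho = rho[ok]
        rows.append((int((rho > 0).sum()), int((rho <= 0).sum())))
    table = pd.DataFrame(rows, index=list(group_labels),
                         columns=["violation", "no_violation"])
    p, method = fisher_exact_rx2(table.to_numpy(), seed=seed)
    return ViolationTest(table=table, p_value=p, method=method,
                         n_dropped=n_dropped)
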