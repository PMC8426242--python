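"""Survival layer: log2(x+1) covariates, Cox proportional hazards with
forward-LR stepwise selection, Gönen–Heller concordance, Kaplan–Meier /
log-rank, optimized cutoffs, quartile grouping, and paired MTV agreement.

The Cox partial likelihood is maximised in-package by damped Newton
iterations with Efron handling of tied event times; Wald standard
errors come from the inverse observed information.  A fully vectorised
fast path handles untied data, which keeps bootstrap procedures that
refit the model thousands of times inside interactive runtimes.
Kaplan–Meier estimation and the log-rank test are delegated to
lifelines.

The Gönen–Heller concordance probability estimate (CPE) is a function
of the fitted linear predictors only — for each subject pair it adds
the model-implied probability that the higher-risk subject fails first,
``1 / (1 + exp(-|eta_i - eta_j|))`` — and is therefore robust to
censoring.  Two nested or non-nested Cox models are compared by a
paired patient-level bootstrap of the CPE difference with a standard
normal reference for ``mean(delta) / SD(delta)`` (a bootstrap Gauss
test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import expit


class ConvergenceError(RuntimeError):
    """The partial likelihood has no finite maximiser (monotone likelihood)."""


class CollinearityError(RuntimeError):
    """The observed information is singular."""


def log2p1(x):
    """log2(x + 1); the skewness-correcting transform for MTV covariates.

    Raises
    ------
    ValueError
        On negative input (volumes cannot be negative).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log2p1 requires non-negative input")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(x) else out


# --------------------------------------------------------------------------
# Cox partial likelihood (Efron ties)
# --------------------------------------------------------------------------

def _sorted_quantities(t: np.ndarray, d: np.ndarray, x: np.ndarray,
                       beta: np.ndarray, no_ties: bool,
                       ev: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood, gradient and observed information,
    for data already sorted by descending time.

    Risk-set sums are prefix sums in this ordering.  When no time is
    tied the per-group Efron corrections vanish and a fully vectorised
    path is used (``ev`` holds the event positions).
    """
    n, p = x.shape
    eta = x @ beta
    shift = eta.max() if n else 0.0
    e = np.exp(eta - shift)
    xe = x * e[:, None]

    if no_ties:
        s0 = np.cumsum(e)[ev]
        s1 = np.add.accumulate(xe)[ev]
        xev = x[ev]
        m = s1 / s0[:, None]
        ll = float(np.sum(eta[ev]) - ev.size * shift - np.log(s0).sum())
        grad = xev.sum(axis=0) - m.sum(axis=0)
        # E[xx'] over risk sets minus outer(mean): accumulate xx'e as (n, p*p)
        xxe = (x[:, :, None] * xe[:, None, :]).reshape(n, p * p)
        s2 = np.add.accumulate(xxe)[ev].reshape(ev.size, p, p)
        info = (s2 / s0[:, None, None]).sum(axis=0) - m.T @ m
        return ll, grad, info

    # tied path, vectorised over all (tie group, within-group rank) pairs:
    # for a group with k events the Efron denominator at rank l is
    # S0_risk - (l/k) * S0_events, l = 0..k-1
    xxe = (x[:, :, None] * xe[:, None, :]).reshape(n, p * p)
    S0 = np.cumsum(e)
    S1 = np.cumsum(xe, axis=0)
    S2 = np.cumsum(xxe, axis=0)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], n]
    k = np.add.reduceat(d, starts)
    S0D = np.add.reduceat(e * d, starts)
    S1D = np.add.reduceat(xe * d[:, None], starts, axis=0)
    S2D = np.add.reduceat(xxe * d[:, None], starts, axis=0)
    g = np.flatnonzero(k > 0)
    kk = k[g]
    reps = np.repeat(g, kk)
    kk_rep = np.repeat(kk, kk)
    offs = np.arange(kk.sum()) - np.repeat(np.cumsum(kk) - kk, kk)
    f = offs / kk_rep
    last = ends - 1
    den = S0[last][reps] - f * S0D[reps]
    num = S1[last][reps] - f[:, None] * S1D[reps]
    m = num / den[:, None]
    ll = float(((eta - shift) * d).sum() - np.log(den).sum())
    grad = (x * d[:, None]).sum(axis=0) - m.sum(axis=0)
    info = ((S2[last][reps] - f[:, None] * S2D[reps]) / den[:, None]
            ).sum(axis=0).reshape(p, p) - m.T @ m
    return ll, grad, info


def _presort(time: np.ndarray, event: np.ndarray, X: np.ndarray):
    """Sort by descending time; precompute tie flag and event positions."""
    order = np.argsort(-time, kind="stable")
    t, d, x = time[order], event[order], X[order]
    no_ties = np.unique(t).size == t.size
    ev = np.flatnonzero(d == 1)
    return t, d, x, no_ties, ev


def _loglik_grad_hess(time: np.ndarray, event: np.ndarray, X: np.ndarray,
                      beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood, gradient and observed information."""
    t, d, x, no_ties, ev = _presort(time, event, X)
    return _sorted_quantities(t, d, x, beta, no_ties, ev)


def _newton_fit(time: np.ndarray, event: np.ndarray, X: np.ndarray,
                beta0: np.ndarray | None = None, tol: float = 1e-8,
                max_iter: int = 60,
                names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Damped Newton maximisation; returns (beta, covariance, loglik)."""
    n, p = X.shape
    if event.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    t, d, x, no_ties, ev = _presort(time, event, X)
    ll, grad, info = _sorted_quantities(t, d, x, beta, no_ties, ev)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) <= tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise CollinearityError("singular information matrix "
                                    "(collinear covariates)") from None
        # step halving until the likelihood improves
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _sorted_quantities(t, d, x, cand,
                                                            no_ties, ev)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 50:
            worst = int(np.argmax(np.abs(beta)))
            name = names[worst] if names else f"covariate {worst}"
            raise ConvergenceError(
                f"monotone partial likelihood: {name} separates the risk sets")
    else:
        raise ConvergenceError("Newton iterations did not converge")
    if np.max(np.abs(beta)) > 20:
        # a |log HR| this large only arises when a covariate orders the
        # risk sets monotonically and the likelihood has no finite maximum
        worst = int(np.argmax(np.abs(beta)))
        name = names[worst] if names else f"covariate {worst}"
        raise ConvergenceError(
            f"monotone partial likelihood: {name} separates the risk sets")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise CollinearityError("singular information matrix at the optimum") from None
    return beta, cov, ll


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model."""

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    log_likelihood: float
    n: int
    n_events: int

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.beta - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.beta + 1.959963984540054 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "coef": self.beta,
            "se": self.se,
            "hr": self.hazard_ratios,
            "hr_ci_lower": self.ci_lower,
            "hr_ci_upper": self.ci_upper,
            "p": self.p_values,
        })

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        X = records[self.covariates].to_numpy(dtype=float)
        return X @ self.beta


def cox_fit(records: pd.DataFrame, covariates: list[str],
            duration_col: str = "time_months", event_col: str = "event",
            tol: float = 1e-8) -> CoxFit:
    """Fit a Cox model by damped Newton on the Efron partial likelihood.

    Raises
    ------
    ConvergenceError
        Monotone likelihood (a covariate perfectly separates risk sets).
    CollinearityError
        Singular observed information.
    """
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=int)
    X = records[list(covariates)].to_numpy(dtype=float)
    for j, name in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    beta, cov, ll = _newton_fit(time, event, X, tol=tol, names=list(covariates))
    return CoxFit(covariates=list(covariates), beta=beta,
                  se=np.sqrt(np.diag(cov)), log_likelihood=ll,
                  n=len(records), n_events=int(event.sum()))


# --------------------------------------------------------------------------
# forward-LR stepwise selection
# --------------------------------------------------------------------------

def _score_test(time, event, X_current, beta_current, x_new) -> float:
    """Rao score chi-square (1 df) for adding one covariate.

    Evaluated at the current fit extended with a zero coefficient; the
    current-model score vanishes there, so the statistic reduces to the
    efficient score of the entrant.
    """
    X = np.column_stack([X_current, x_new]) if X_current.size else x_new[:, None]
    beta0 = np.r_[beta_current, 0.0]
    _, grad, info = _loglik_grad_hess(time, event, X, beta0)
    try:
        inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return 0.0
    return float(grad @ inv @ grad)


@dataclass
class StepwiseResult:
    fit: CoxFit | None                 # None when no covariate entered
    selected: list[str]
    trace: list[dict] = field(default_factory=list)


def stepwise_cox(records: pd.DataFrame, candidates: list[str],
                 duration_col: str = "time_months", event_col: str = "event",
                 alpha_entry: float = 0.05, alpha_removal: float = 0.10,
                 max_steps: int = 50) -> StepwiseResult:
    """Forward-LR stepwise Cox selection.

    Covariates enter by the score test at ``alpha_entry`` (best
    candidate first) and are removed by the likelihood-ratio test at
    ``alpha_removal``; iteration stops when no entry or removal
    changes the model.  The trace records every tested entry/removal.
    """
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=int)
    cols = {c: records[c].to_numpy(dtype=float) for c in candidates}
    selected: list[str] = []
    trace: list[dict] = []

    def _fit(names: list[str]) -> tuple[np.ndarray, float]:
        if not names:
            ll, _, _ = _loglik_grad_hess(time, event, np.empty((len(time), 0)),
                                         np.empty(0))
            return np.empty(0), ll
        X = np.column_stack([cols[c] for c in names])
        beta, _, ll = _newton_fit(time, event, X, names=names)
        return beta, ll

    beta_cur, ll_cur = _fit(selected)
    for _ in range(max_steps):
        changed = False
        # entry: best score statistic among remaining candidates
        remaining = [c for c in candidates if c not in selected]
        best_stat, best_name = -np.inf, None
        X_cur = (np.column_stack([cols[c] for c in selected])
                 if selected else np.empty((len(time), 0)))
        for name in remaining:
            stat = _score_test(time, event, X_cur, beta_cur, cols[name])
            p = float(stats.chi2.sf(stat, 1))
            trace.append({"step": "entry-test", "covariate": name,
                          "statistic": stat, "p": p})
            if stat > best_stat:
                best_stat, best_name = stat, name
        if best_name is not None and stats.chi2.sf(best_stat, 1) < alpha_entry:
            selected.append(best_name)
            beta_cur, ll_cur = _fit(selected)
            trace.append({"step": "enter", "covariate": best_name,
                          "statistic": best_stat,
                          "p": float(stats.chi2.sf(best_stat, 1))})
            changed = True
        # removal: worst LR among selected
        while len(selected) > 0:
            worst_p, worst_name, worst_lr = -np.inf, None, None
            for name in selected:
                reduced = [c for c in selected if c != name]
                _, ll_red = _fit(reduced)
                lr = 2.0 * (ll_cur - ll_red)
                p = float(stats.chi2.sf(max(lr, 0.0), 1))
                trace.append({"step": "removal-test", "covariate": name,
                              "statistic": lr, "p": p})
                if p > worst_p:
                    worst_p, worst_name, worst_lr = p, name, lr
            if worst_name is not None and worst_p > alpha_removal:
                selected.remove(worst_name)
                beta_cur, ll_cur = _fit(selected)
                trace.append({"step": "remove", "covariate": worst_name,
                              "statistic": worst_lr, "p": worst_p})
                changed = True
            else:
                break
        if not changed:
            break

    fit = cox_fit(records, selected, duration_col, event_col) if selected else None
    return StepwiseResult(fit=fit, selected=selected, trace=trace)


# --------------------------------------------------------------------------
# Gönen–Heller concordance probability
# --------------------------------------------------------------------------

@dataclass
class CPEResult:
    value: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def gonen_heller_cpe(linear_predictor: np.ndarray,
                     bandwidth: float | None = None) -> CPEResult:
    """Concordance probability estimate from fitted risk scores.

    For each unordered subject pair the estimator adds the
    model-implied probability that the higher-risk subject fails
    first; pairs with equal risk scores contribute 1/2.  Depends only
    on differences of linear predictors — no censoring terms.  The
    optional ``bandwidth`` activates the kernel-smoothed variant
    (normal CDF weights on the pair ordering); off by default.
    """
    eta = np.asarray(linear_predictor, dtype=float)
    n = eta.size
    if n < 2:
        raise ValueError("CPE needs at least 2 subjects")
    diff = eta[:, None] - eta[None, :]
    iu = np.triu_indices(n, k=1)
    d = diff[iu]
    if np.all(d == 0):
        return CPEResult(value=0.5, degenerate=True)
    if bandwidth is None:
        w_neg = np.where(d < 0, 1.0, np.where(d == 0, 0.5, 0.0))
        w_pos = 1.0 - w_neg
    else:
        w_neg = stats.norm.cdf(-d / bandwidth)
        w_pos = 1.0 - w_neg
    contrib = w_neg * expit(-d) + w_pos * expit(d)
    return CPEResult(value=float(contrib.mean()), degenerate=False)


def cpe_of_model(records: pd.DataFrame, covariates: list[str],
                 duration_col: str = "time_months", event_col: str = "event",
                 bandwidth: float | None = None) -> tuple[CoxFit, CPEResult]:
    """Fit a Cox model and return its Gönen–Heller CPE."""
    fit = cox_fit(records, covariates, duration_col, event_col)
    return fit, gonen_heller_cpe(fit.linear_predictor(records), bandwidth)


@dataclass
class CPEComparison:
    cpe_a: float
    cpe_b: float
    delta: float
    z: float
    p_value: float
    n_replicates: int
    n_dropped: int


def compare_cpe_bootstrap(records: pd.DataFrame, covariates_a: list[str],
                          covariates_b: list[str],
                          duration_col: str = "time_months",
                          event_col: str = "event",
                          n_replicates: int = 1000, seed: int = 0,
                          max_dropped_frac: float = 0.2) -> CPEComparison:
    """Bootstrap Gauss test for a difference in Gönen–Heller CPE.

    Patients are resampled with replacement; each replicate refits both
    models and records the CPE difference.  The test statistic is
    ``z = mean(delta) / SD(delta)`` against a standard normal.
    Replicates where either model fails to converge are dropped and
    counted; more than ``max_dropped_frac`` dropped is an error.  A
    degenerate spread (model compared with itself) yields p = 1.
    """
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=int)
    Xa = records[list(covariates_a)].to_numpy(dtype=float)
    Xb = records[list(covariates_b)].to_numpy(dtype=float)
    n = len(records)

    beta_a, _, _ = _newton_fit(time, event, Xa, names=list(covariates_a))
    beta_b, _, _ = _newton_fit(time, event, Xb, names=list(covariates_b))
    cpe_a = gonen_heller_cpe(Xa @ beta_a).value
    cpe_b = gonen_heller_cpe(Xb @ beta_b).value

    rng = np.random.default_rng(seed)
    deltas = []
    dropped = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, n, n)
        t, d = time[idx], event[idx]
        try:
            ba, _, _ = _newton_fit(t, d, Xa[idx], beta0=beta_a)
            bb, _, _ = _newton_fit(t, d, Xb[idx], beta0=beta_b)
        except (ConvergenceError, CollinearityError, ValueError):
            dropped += 1
            continue
        deltas.append(gonen_heller_cpe(Xa[idx] @ ba).value
                      - gonen_heller_cpe(Xb[idx] @ bb).value)
    if dropped > max_dropped_frac * n_replicates:
        raise ConvergenceError(
            f"{dropped}/{n_replicates} bootstrap replicates failed to converge")
    deltas = np.asarray(deltas)
    sd = float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0
    if sd == 0.0:
        z, p = 0.0, 1.0
    else:
        z = float(deltas.mean() / sd)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return CPEComparison(cpe_a=cpe_a, cpe_b=cpe_b, delta=cpe_a - cpe_b,
                         z=z, p_value=p, n_replicates=int(deltas.size),
                         n_dropped=dropped)


# --------------------------------------------------------------------------
# Kaplan–Meier, log-rank, cutoffs, quartiles
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray             # event times (steps)
    survival: np.ndarray          # S(t) just after each step
    at_risk: np.ndarray           # number at risk entering each step
    median: float | None          # earliest t with S(t) <= 0.5; None if never
    n: int
    n_events: int


def km_estimate(records: pd.DataFrame, groups,
                duration_col: str = "time_months",
                event_col: str = "event") -> dict[str, KMCurve]:
    """Kaplan–Meier curves per group (product-limit estimator)."""
    groups = np.asarray(groups)
    out: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        t = records.loc[sel, duration_col].to_numpy(dtype=float)
        d = records.loc[sel, event_col].to_numpy(dtype=int)
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=d)
        table = kmf.event_table
        ev = table[table["observed"] > 0]
        median = kmf.median_survival_time_
        out[str(g)] = KMCurve(
            group=str(g),
            times=ev.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.loc[ev.index, "KM_estimate"]
                        .to_numpy(dtype=float),
            at_risk=ev["at_risk"].to_numpy(dtype=int),
            median=None if np.isinf(median) else float(median),
            n=int(sel.sum()), n_events=int(d.sum()),
        )
    return out


def logrank_test(records: pd.DataFrame, groups,
                 duration_col: str = "time_months",
                 event_col: str = "event") -> tuple[float, int, float]:
    """Log-rank test across groups; returns (chi-square, df, p)."""
    groups = np.asarray(groups)
    if pd.unique(groups).size < 2:
        raise ValueError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(
        records[duration_col].to_numpy(dtype=float), groups,
        records[event_col].to_numpy(dtype=int))
    df = int(pd.unique(groups).size - 1)
    return float(res.test_statistic), df, float(res.p_value)


def _two_group_logrank(time: np.ndarray, event: np.ndarray,
                       in_group1: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank chi-square and p, vectorised over event times.

    Used by the cutoff scan, which evaluates the statistic for every
    admissible split of a covariate.
    """
    order = np.argsort(time, kind="stable")
    t, d, g = time[order], event[order].astype(float), in_group1[order].astype(float)
    _, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    n = t.size
    # subjects at risk entering each unique time
    left = np.r_[0, np.cumsum(counts)][:-1]
    at_risk = n - left
    g_cum = np.r_[0, np.cumsum(np.bincount(inv, weights=g))][:-1]
    at_risk1 = g.sum() - g_cum
    deaths = np.bincount(inv, weights=d)
    deaths1 = np.bincount(inv, weights=d * g)
    mask = deaths > 0
    N, N1, D, D1 = at_risk[mask], at_risk1[mask], deaths[mask], deaths1[mask]
    frac = N1 / N
    o_minus_e = float((D1 - D * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(N > 1, D * frac * (1 - frac) * (N - D) / (N - 1), 0.0)
    v = float(var.sum())
    if v <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / v
    return chi2, float(stats.chi2.sf(chi2, 1))


@dataclass
class CutoffResult:
    cutoff: float
    chi2: float
    p_naive: float                # selection-inflated; not a valid test level
    n_low: int
    n_high: int


def optimal_logrank_cutoff(values, records: pd.DataFrame,
                           duration_col: str = "time_months",
                           event_col: str = "event",
                           min_arm_frac: float = 0.10) -> CutoffResult:
    """Covariate split maximising the log-rank chi-square.

    Scans the midpoints between consecutive distinct values (which
    includes the 0-vs-positive split when zeros are present), subject
    to both arms holding at least ``min_arm_frac`` of the patients.
    The reported p-value is naive: the scan maximises the statistic,
    so it is selection-inflated and must not be read at face value.
    Ties in the maximal chi-square resolve to the smallest cutoff.
    """
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct values to split")
    n = values.size
    min_arm = max(1, int(math.ceil(min_arm_frac * n)))
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=int)

    best: CutoffResult | None = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = 0.5 * (lo + hi)
        high = values > cut
        n_high = int(high.sum())
        if n_high < min_arm or n - n_high < min_arm:
            continue
        chi2, p = _two_group_logrank(time, event, high)
        if best is None or chi2 > best.chi2 + 1e-12:
            best = CutoffResult(cutoff=float(cut), chi2=chi2, p_naive=p,
                                n_low=n - n_high, n_high=n_high)
    if best is None:
        raise ValueError("no admissible split satisfies the arm-size floor")
    return best


def quartile_groups(values) -> tuple[np.ndarray, bool]:
    """Quartile labels Q1..Q4 by linear-interpolation quantiles.

    Values tied with a quartile boundary fall in the lower group.
    Returns ``(labels, collapsed)`` where ``collapsed`` flags fewer
    than four realised groups.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("quartile grouping needs n >= 4")
    qs = np.quantile(values, [0.25, 0.5, 0.75])
    idx = np.sum(values[:, None] > qs[None, :], axis=1)
    labels = np.array([f"Q{i + 1}" for i in idx])
    collapsed = np.unique(labels).size < 4
    return labels, collapsed


# --------------------------------------------------------------------------
# paired MTV agreement
# --------------------------------------------------------------------------

def mtv_agreement(mtv_a, mtv_b) -> dict:
    """Agreement between two paired per-patient MTV series.

    Reports the Wilcoxon signed-rank p-value on the raw paired
    differences (zero differences dropped; exact for small untied
    samples, otherwise normal approximation with tie correction, via
    scipy), the squared Pearson correlation of the log2(x+1)-scale
    pairs, and Bland–Altman statistics of ``a - b`` (bias and
    bias ± 1.96 SD limits of agreement).
    """
    a = np.asarray(mtv_a, dtype=float)
    b = np.asarray(mtv_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D series required")
    if a.size < 3:
        raise ValueError("agreement statistics need n >= 3")
    diff = a - b
    report: dict = {
        "n": int(a.size),
        "bias": float(diff.mean()),
        "loa_lower": float(diff.mean() - 1.96 * diff.std(ddof=1)),
        "loa_upper": float(diff.mean() + 1.96 * diff.std(ddof=1)),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
    if np.all(diff == 0):
        report["wilcoxon_p"] = None
        report["wilcoxon_applicable"] = False
    else:
        res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
        report["wilcoxon_p"] = float(res.pvalue)
        report["wilcoxon_applicable"] = True
    ta, tb = log2p1(a), log2p1(b)
    if np.ptp(ta) == 0 or np.ptp(tb) == 0:
        report["r_squared_log2"] = None
        report["r_squared_defined"] = False
    else:
        r = stats.pearsonr(ta, tb)
        report["r_squared_log2"] = float(r.statistic ** 2)
        report["pearson_p"] = float(r.pvalue)
        report["r_squared_defined"] = True
    return report
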