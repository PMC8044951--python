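"""Clinical validation statistics for a candidate marker.

Implements the validation stage of the prioritization study: dichotomize a
marker (H-score or expression) at the median, test association with
clinicopathological features by Pearson chi-square, estimate survival with
Kaplan-Meier / log-rank, and fit Cox proportional-hazards models (all
covariates entered jointly for the multivariable model — the "Enter"
convention, no stepwise selection).

The Cox partial likelihood is maximized by Newton-Raphson with Breslow tie
handling by default (the SPSS convention); Efron is available. Wald
confidence intervals are on the log-hazard scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dichotomize",
    "ContingencyResult",
    "pearson_chi2",
    "SurvivalCurve",
    "km_fit",
    "logrank_test",
    "CoxResult",
    "cox_fit",
]

_Z_95 = 1.959964  # two-sided 95% normal quantile


def dichotomize(values, cutoff="median") -> np.ndarray:
    """Split marker values into ``"Low"``/``"High"`` groups.

    ``"High"`` means strictly above the cutoff (default: the median), so
    ties at the median are Low — the ``<=median / >median`` convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    cut = float(np.median(v)) if cutoff == "median" else float(cutoff)
    labels = np.where(v > cut, "High", "Low")
    if (labels == "Low").all():
        warnings.warn("no values exceed the cutoff; every subject labeled Low")
    return labels


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


def pearson_chi2(observed) -> ContingencyResult:
    """Uncorrected Pearson chi-square test on an r x c contingency table.

    X^2 = sum (O - E)^2 / E with expected counts from the margins,
    df = (r-1)(c-1). No Yates continuity correction is applied.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("observed counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(obs.astype(int), expected, float(chi2), int(df), float(p))


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``event_times``/``n_risk``/``n_events`` tabulate each distinct time with
    at least one death; ``survival`` is S(t) just after that time.
    ``median`` is the smallest event time with S(t) <= 0.5 (None if the
    curve never drops that far).
    """

    event_times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    median: float | None

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_fit(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no observations")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")

    uniq = np.unique(t[e == 1])
    n_risk = np.array([(t >= u).sum() for u in uniq])
    n_events = np.array([((t == u) & (e == 1)).sum() for u in uniq])
    surv = np.cumprod(1.0 - n_events / n_risk) if uniq.size else np.array([])
    below = np.nonzero(surv <= 0.5)[0] if uniq.size else []
    median = float(uniq[below[0]]) if len(below) else None
    return SurvivalCurve(uniq, n_risk, n_events, surv, median)


def logrank_test(group_labels, times, events):
    """Multi-group log-rank test; returns ``(chi2, df, p)``.

    At each distinct event time the observed group deaths are compared with
    their expectation under a common hazard, with the hypergeometric
    variance-covariance; df = number of groups - 1.
    """
    g = np.asarray(group_labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    groups = sorted(pd.unique(g).tolist())
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    k = len(groups)
    gi = np.array([groups.index(x) for x in g])

    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = t >= u
        n = at_risk.sum()
        d = ((t == u) & (e == 1)).sum()
        n_g = np.array([(at_risk & (gi == j)).sum() for j in range(k)])
        d_g = np.array([((t == u) & (e == 1) & (gi == j)).sum() for j in range(k)])
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            V += (d * (n - d) / (n - 1)) * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    chi2 = float(z @ np.linalg.pinv(V[:-1, :-1]) @ z)
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class CoxResult:
    """Cox proportional-hazards fit: per-covariate table and diagnostics."""

    summary: pd.DataFrame  # beta, se, hr, ci_low, ci_high, p (index: covariate)
    log_likelihood: float
    ties: str
    n: int
    n_events: int
    warnings: list[str]

    @property
    def beta(self) -> pd.Series:
        return self.summary["beta"]

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]


def _cox_loglik(beta, X, times, events, ties):
    """Log partial likelihood with gradient and Hessian (negative info)."""
    order = np.argsort(times, kind="stable")
    Xo, to, eo = X[order], times[order], events[order]
    n, p = Xo.shape
    eta = Xo @ beta
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # walk distinct times from the largest down, accumulating risk-set sums
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        u = to[i]
        j = i
        while j >= 0 and to[j] == u:
            j -= 1
        for idx in range(j + 1, i + 1):
            s0 += w[idx]
            s1 += w[idx] * Xo[idx]
            s2 += w[idx] * np.outer(Xo[idx], Xo[idx])
        died = [idx for idx in range(j + 1, i + 1) if eo[idx] == 1]
        d = len(died)
        if d:
            xsum = Xo[died].sum(axis=0)
            ll += eta[died].sum()
            grad += xsum
            if ties == "breslow":
                ll -= d * np.log(s0)
                grad -= d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            else:  # efron
                wd = w[died].sum()
                wd1 = (w[died, None] * Xo[died]).sum(axis=0)
                wd2 = sum(w[idx] * np.outer(Xo[idx], Xo[idx]) for idx in died)
                for l in range(d):
                    f = l / d
                    den = s0 - f * wd
                    num1 = s1 - f * wd1
                    num2 = s2 - f * wd2
                    ll -= np.log(den)
                    grad -= num1 / den
                    info += num2 / den - np.outer(num1 / den, num1 / den)
        i = j
    return ll, grad, info


def cox_fit(design, times, events, ties: str = "breslow") -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``design`` is a DataFrame (or 2-D array) of numeric covariates; all
    supplied covariates are entered jointly. Standard errors come from the
    inverse observed information; 95% CIs are Wald on the log scale.

    Raises on constant covariates, zero events, a singular information
    matrix, or non-convergence; warns when |beta| > 15 (monotone likelihood
    / perfect separation).
    """
    if ties not in {"breslow", "efron"}:
        raise ValueError("ties must be 'breslow' or 'efron'")
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1 and np.asarray(times).size > 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 1:
        raise ValueError("no events observed")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    Xc = X - X.mean(axis=0)  # centering stabilizes the Newton steps

    beta = np.zeros(X.shape[1])
    msgs: list[str] = []
    converged = False
    for _ in range(50):
        ll, grad, info = _cox_loglik(beta, Xc, t, e, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            worst = names[int(np.argmax(np.abs(grad)))]
            raise ValueError(f"singular information matrix (covariate {worst!r})") from err
        # halve the step until the likelihood does not decrease
        for _ in range(30):
            cand = beta + step
            ll_new = _cox_loglik(cand, Xc, t, e, ties)[0]
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = cand
        if np.linalg.norm(grad) < 1e-8:
            converged = True
            break
    if not converged:
        ll, grad, info = _cox_loglik(beta, Xc, t, e, ties)
        if np.linalg.norm(grad) >= 1e-6:
            worst = names[int(np.argmax(np.abs(grad)))]
            raise ValueError(f"Cox fit did not converge (covariate {worst!r})")

    ll, grad, info = _cox_loglik(beta, Xc, t, e, ties)
    if np.any(np.abs(beta) > 15):
        msgs.append("some |beta| > 15: likely monotone likelihood / separation")
        warnings.warn(msgs[-1])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular information matrix at the optimum") from err
    se = np.sqrt(np.diag(cov))
    z = beta / se
    summary = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - _Z_95 * se),
            "ci_high": np.exp(beta + _Z_95 * se),
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxResult(summary, float(ll), ties, int(t.size), int(e.sum()), msgs)
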