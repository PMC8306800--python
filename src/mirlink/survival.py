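"""Self-contained survival-analysis primitives.

Product-limit (Kaplan-Meier) estimation, restricted mean survival time
(area under the KM curve), the two-group log-rank test, a univariate Cox
proportional-hazards fit with Breslow tie handling, and the expression
cutoff scan used to dichotomize a cohort at the most discriminating
threshold.

All functions are deterministic, operate on plain numpy arrays, and are
vectorized so they can be called thousands of times inside the marker
selection loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateDesignError(ValueError):
    """Raised when a covariate carries no information (constant, too few events)."""


@dataclass(frozen=True)
class SurvivalCurve:
    """A right-continuous Kaplan-Meier step function.

    ``survival_probs[i]`` is S(t) for t in [event_times[i], next event time);
    S(t) = 1 for t below the first event time.
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray
    max_follow_up: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass(frozen=True)
class CoxFit:
    beta: float
    hazard_ratio: float
    se: float
    p_value: float
    converged: bool
    n: int
    n_events: int


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class CutoffScanResult:
    best_cutoff: float
    min_logrank_p: float
    direction: int  # +1 if the over-expression arm survives longer
    n_cutoffs_tested: int


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times <= 0) or np.any(~np.isfinite(times)):
        raise ValueError("survival times must be positive and finite")
    if not np.all(np.isin(events, (0.0, 1.0))):
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimate of the survival function.

    Censored observations at time t leave the risk set after t, i.e. they
    are counted at risk for an event occurring exactly at t.
    """
    times, events = _check_times_events(times, events)
    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order]
    n = t.size
    # distinct event times and the number of deaths / at-risk at each
    ev_times = np.unique(t[d == 1])
    if ev_times.size == 0:
        return SurvivalCurve(
            event_times=np.empty(0),
            survival_probs=np.empty(0),
            n_at_risk=np.empty(0, dtype=int),
            max_follow_up=float(t[-1]),
        )
    # at risk just before each event time: count of t >= ev
    at_risk = n - np.searchsorted(t, ev_times, side="left")
    deaths = np.bincount(
        np.searchsorted(ev_times, t[d == 1]), minlength=ev_times.size
    ).astype(float)
    surv = np.cumprod(1.0 - deaths / at_risk)
    return SurvivalCurve(
        event_times=ev_times,
        survival_probs=surv,
        n_at_risk=at_risk.astype(int),
        max_follow_up=float(t[-1]),
    )


def rmst(curve: SurvivalCurve, tau: float) -> float:
    """Restricted mean survival time: integral of S(t) over [0, min(tau, max follow-up)]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t_end = min(float(tau), curve.max_follow_up)
    knots = curve.event_times[curve.event_times < t_end]
    probs = curve.survival_probs[: knots.size]
    grid = np.concatenate(([0.0], knots, [t_end]))
    s_vals = np.concatenate(([1.0], probs))
    return float(np.sum(np.diff(grid) * s_vals))


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (1 df), symmetric in group order."""
    ta, da = _check_times_events(times_a, events_a)
    tb, db = _check_times_events(times_b, events_b)
    t = np.concatenate([ta, tb])
    d = np.concatenate([da, db])
    g = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])

    order = np.argsort(t, kind="stable")
    t, d, g = t[order], d[order], g[order]
    ev_times = np.unique(t[d == 1])
    if ev_times.size == 0:
        return LogrankResult(0.0, 1.0)

    ta_sorted = np.sort(ta)
    idx = np.searchsorted(ev_times, t[d == 1])
    dj = np.bincount(idx, minlength=ev_times.size).astype(float)
    d1j = np.bincount(idx, weights=(g[d == 1] == 0), minlength=ev_times.size)
    nj = t.size - np.searchsorted(t, ev_times, side="left")
    n1j = ta.size - np.searchsorted(ta_sorted, ev_times, side="left")

    frac = n1j / nj
    o_minus_e = float(np.sum(d1j - dj * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = dj * frac * (1.0 - frac) * (nj - dj) / (nj - 1.0)
    var = float(np.sum(v_terms[nj > 1]))
    if var <= 0:
        return LogrankResult(0.0, 1.0)
    chi = o_minus_e * o_minus_e / var
    return LogrankResult(float(chi), float(stats.chi2.sf(chi, 1)))


def _cox_loglik_terms(beta: float, t_desc, d_desc, x_desc, tie_last_idx):
    """Breslow partial log-likelihood, score and information at beta.

    Inputs are pre-sorted by descending time so the risk set for the event
    at position i is positions 0..tie_last_idx[i].
    """
    w = np.exp(beta * x_desc)
    s0 = np.cumsum(w)[tie_last_idx]
    s1 = np.cumsum(w * x_desc)[tie_last_idx]
    s2 = np.cumsum(w * x_desc * x_desc)[tie_last_idx]
    ev = d_desc == 1
    mu = s1[ev] / s0[ev]
    loglik = float(np.sum(beta * x_desc[ev] - np.log(s0[ev])))
    score = float(np.sum(x_desc[ev] - mu))
    info = float(np.sum(s2[ev] / s0[ev] - mu * mu))
    return loglik, score, info


def breslow_partial_loglik(times, events, x, beta: float) -> float:
    """Breslow partial log-likelihood at a given coefficient (used by oracles)."""
    times, events = _check_times_events(times, events)
    x = np.asarray(x, dtype=float)
    order = np.argsort(-times, kind="stable")
    t, d, xs = times[order], events[order], x[order]
    tie_last = np.searchsorted(-t, -t, side="right") - 1
    return _cox_loglik_terms(beta, t, d, xs, tie_last)[0]


_BETA_BOUND = 50.0


def cox_univariate(times, events, x, tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Univariate Cox proportional-hazards fit.

    Maximizes the Breslow partial likelihood by damped Newton iteration.
    A monotone likelihood (perfect separation of risk by the covariate)
    is reported as ``converged=False`` rather than an exception.
    """
    times, events = _check_times_events(times, events)
    x = np.asarray(x, dtype=float)
    if x.shape != times.shape:
        raise ValueError("x must match times in length")
    n_events = int(np.sum(events))
    if n_events < 2:
        raise DegenerateDesignError("need at least two events for a Cox fit")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant covariate")

    order = np.argsort(-times, kind="stable")
    t, d, xs = times[order], events[order], x[order]
    # standardize for numerical stability; beta rescales exactly
    x_mean, x_sd = float(np.mean(xs)), float(np.std(xs))
    xs_std = (xs - x_mean) / x_sd
    tie_last = np.searchsorted(-t, -t, side="right") - 1

    beta = 0.0
    loglik, score, info = _cox_loglik_terms(beta, t, d, xs_std, tie_last)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = score / info
        # damped update: halve until the partial likelihood does not decrease
        new_beta = beta + step
        for _half in range(30):
            new_ll, new_score, new_info = _cox_loglik_terms(new_beta, t, d, xs_std, tie_last)
            if new_ll >= loglik - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if abs(new_beta - beta) < tol:
            beta, loglik, score, info = new_beta, new_ll, new_score, new_info
            converged = True
            break
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > _BETA_BOUND:  # monotone likelihood
            converged = False
            break

    se_std = float(np.sqrt(1.0 / info)) if info > 0 else float("inf")
    beta_raw = beta / x_sd
    se_raw = se_std / x_sd
    if converged and np.isfinite(se_raw):
        z = beta_raw / se_raw
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = float("nan")
    return CoxFit(
        beta=float(beta_raw),
        hazard_ratio=float(np.exp(beta_raw)),
        se=float(se_raw),
        p_value=p,
        converged=converged,
        n=int(times.size),
        n_events=n_events,
    )


def km_cutoff_scan(
    x,
    times,
    events,
    q_lo: float = 0.05,
    q_hi: float = 0.95,
    n_grid: int = 20,
    min_group: int = 3,
) -> CutoffScanResult:
    """Scan expression cutoffs between the q_lo and q_hi quantiles.

    Each candidate cutoff splits the cohort into an over-expression arm
    (x > cutoff) and an under-expression arm; the log-rank p-value is
    recorded and the minimum over the scan returned (smallest cutoff on
    ties).  No multiplicity correction is applied; ``n_cutoffs_tested``
    exposes the multiplicity to the caller.
    """
    times, events = _check_times_events(times, events)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant covariate, nothing to scan")
    lo, hi = np.quantile(x, [q_lo, q_hi])
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    if candidates.size > n_grid:
        qs = np.linspace(q_lo, q_hi, n_grid)
        candidates = np.unique(np.quantile(x, qs))

    best_p, best_cut, best_dir = np.inf, None, 0
    n_tested = 0
    tau = float(np.max(times))
    for c in candidates:
        hi_mask = x > c
        n_hi = int(np.sum(hi_mask))
        if n_hi < min_group or (x.size - n_hi) < min_group:
            continue
        res = logrank_test(times[hi_mask], events[hi_mask], times[~hi_mask], events[~hi_mask])
        n_tested += 1
        if res.p_value < best_p - 1e-15:
            best_p = res.p_value
            best_cut = float(c)
            r_hi = rmst(km_estimate(times[hi_mask], events[hi_mask]), tau)
            r_lo = rmst(km_estimate(times[~hi_mask], events[~hi_mask]), tau)
            best_dir = 1 if r_hi >= r_lo else -1
    if best_cut is None:
        raise DegenerateDesignError("all candidate cutoffs left one side below the minimum group size")
    return CutoffScanResult(
        best_cutoff=best_cut,
        min_logrank_p=float(best_p),
        direction=best_dir,
        n_cutoffs_tested=n_tested,
    )
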