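"""Finite Poisson mixtures fitted by non-parametric maximum likelihood.

The mixing distribution of per-unit event rates is estimated on a grid
of candidate rates with the Vertex Exchange Method (VEM), refined by EM
on the active support with support-point insertion, and near-duplicate
support points are collapsed.  At the optimum the directional-derivative
(gradient) function satisfies ``sup_lam d(lam) <= 1`` with equality at
the support points; that bound is the convergence certificate.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import nnls
from scipy.special import gammaln, logsumexp, xlogy

from .core import CountVector, FitResult, GofReport, MixtureDistribution

__all__ = [
    "poisson_logpmf",
    "poisson_pmf",
    "loglik",
    "gradient_function",
    "fit_npmle",
    "fit_fixed_k",
    "fit_parsimonious",
    "bootstrap_lrt",
    "simulate_counts",
]

_WEIGHT_FLOOR = 1e-8


def poisson_logpmf(h, lam):
    """Log Poisson point mass, exact at ``lam == 0``.

    ``pmf(0, 0) = 1`` and ``pmf(h > 0, 0) = 0`` so that a zero-rate
    mixture component is handled without special-casing by callers.
    Broadcasts over both arguments.
    """
    h = np.asarray(h)
    lam = np.asarray(lam, dtype=float)
    if np.any(h < 0) or not np.all(np.equal(np.mod(h, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    h = h.astype(np.int64)
    # xlogy(0, 0) = 0 gives the exact zero-rate limit; other h with
    # lam == 0 produce -inf via log(0).
    with np.errstate(divide="ignore"):
        out = xlogy(h, lam) - lam - gammaln(h + 1)
    return out


def poisson_pmf(h, lam):
    """Poisson point mass ``exp(-lam) lam^h / h!`` (log-space internally)."""
    return np.exp(poisson_logpmf(h, lam))


def _as_counts(counts: Union[CountVector, Sequence[int]]) -> np.ndarray:
    if isinstance(counts, CountVector):
        return counts.counts
    return CountVector(np.asarray(counts)).counts


class _Workspace:
    """Unique count values, multiplicities and cached log-factorials.

    All fit internals operate on the unique-value representation, which
    makes every EM/VEM step O(n_unique * k) regardless of N.
    """

    def __init__(self, h: np.ndarray):
        self.values, self.mult = np.unique(h, return_counts=True)
        self.n = int(self.mult.sum())
        self._lgam = gammaln(self.values + 1.0)

    def log_matrix(self, lam: np.ndarray) -> np.ndarray:
        """(n_values, k) matrix of log pmfs."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (
                xlogy(self.values[:, None], lam[None, :])
                - lam[None, :]
                - self._lgam[:, None]
            )
        return out

    def loglik_and_resp(self, q: np.ndarray, lam: np.ndarray):
        """Log-likelihood and (multiplicity-weighted) responsibilities."""
        with np.errstate(divide="ignore"):
            logp = self.log_matrix(lam) + np.log(q)[None, :]
        m = logp.max(axis=1)
        p = np.exp(logp - m[:, None])
        s = p.sum(axis=1)
        ll = float(self.mult @ (m + np.log(s)))
        r = (p / s[:, None]) * self.mult[:, None]
        return ll, r

    def gradient(self, q: np.ndarray, lam: np.ndarray, at: np.ndarray) -> np.ndarray:
        """Directional derivative d(at) given the current mixture."""
        f = np.exp(self.log_matrix(lam)) @ q
        p = np.exp(self.log_matrix(at))
        return (self.mult / self.n) @ (p / f[:, None])


def loglik(counts, mix: MixtureDistribution) -> float:
    """Mixture log-likelihood ``sum_i log sum_j q_j pmf(H_i, lam_j)``.

    Returns ``-inf`` if some count has zero density under every
    component (e.g. a positive count under an all-zero-rate mixture).
    """
    h = _as_counts(counts)
    if h.size == 0:
        raise ValueError("counts must be non-empty")
    ws = _Workspace(h)
    with np.errstate(divide="ignore"):
        logf = logsumexp(ws.log_matrix(np.asarray(mix.lam)) + np.log(mix.q)[None, :], axis=1)
    if np.any(np.isneginf(logf)):
        return -math.inf
    return float(np.dot(ws.mult, logf))


def gradient_function(lam, counts, mix: MixtureDistribution):
    """NPMLE directional derivative ``d(lam) = N^-1 sum_i pmf(H_i, lam)/f_mix(H_i)``.

    At the NPMLE, ``d(lam) <= 1`` everywhere with equality at the
    support points.  Vectorised over ``lam``.
    """
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam_arr < 0):
        raise ValueError("rates must be non-negative")
    h = _as_counts(counts)
    if h.size == 0:
        raise ValueError("counts must be non-empty")
    ws = _Workspace(h)
    f = np.exp(ws.log_matrix(np.asarray(mix.lam))) @ np.asarray(mix.q)
    if np.any(f <= 0):
        raise ValueError("mixture assigns zero density to an observed count")
    d = (ws.mult / ws.n) @ (np.exp(ws.log_matrix(lam_arr)) / f[:, None])
    return d if np.ndim(lam) else float(d[0])


def _vem(ws: _Workspace, grid: np.ndarray, tol: float, max_iter: int):
    """Vertex Exchange Method for grid weights; returns (w, n_iter)."""
    p = np.exp(ws.log_matrix(grid))  # (n_values, n_grid)
    w = np.full(grid.size, 1.0 / grid.size)
    f = p @ w
    scale = ws.mult / ws.n
    for it in range(1, max_iter + 1):
        d = scale @ (p / f[:, None])
        j_add = int(np.argmax(d))
        if d[j_add] <= 1.0 + tol:
            return w, it
        active = np.flatnonzero(w > _WEIGHT_FLOOR)
        j_rem = int(active[np.argmin(d[active])])
        if j_rem == j_add:
            return w, it
        delta = p[:, j_add] - p[:, j_rem]
        t_max = w[j_rem]
        # step maximising sum m log(f + t*delta); the derivative is
        # monotone decreasing in t, so bisect for its root
        if float(ws.mult @ (delta / (f + t_max * delta))) >= 0:
            t = t_max
        else:
            lo_t, hi_t = 0.0, t_max
            for _ in range(40):
                mid = 0.5 * (lo_t + hi_t)
                if float(ws.mult @ (delta / (f + mid * delta))) > 0:
                    lo_t = mid
                else:
                    hi_t = mid
            t = 0.5 * (lo_t + hi_t)
        w = w.copy()
        w[j_add] += t
        w[j_rem] -= t
        np.clip(w, 0.0, None, out=w)
        f = f + t * delta
    return w, max_iter


def _em(ws: _Workspace, q, lam, tol, max_iter):
    """EM refinement of (q, lam) jointly; returns (q, lam, loglik trace)."""
    trace = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, r = ws.loglik_and_resp(q, lam)
        trace.append(ll)
        if len(trace) > 1 and ll - ll_prev < tol:
            break
        ll_prev = ll
        nk = r.sum(axis=0)
        keep = nk > _WEIGHT_FLOOR * ws.n
        r, nk = r[:, keep], nk[keep]
        q = nk / ws.n
        lam = (ws.values @ r) / nk
    return q, lam, np.asarray(trace)


def _local_maxima(d: np.ndarray, grid: np.ndarray, threshold: float):
    """Grid points that are strict local maxima of d with d > threshold."""
    interior = (d[1:-1] >= d[:-2]) & (d[1:-1] >= d[2:]) & (d[1:-1] > threshold)
    idx = np.flatnonzero(interior) + 1
    if d[0] > max(d[1], threshold):
        idx = np.append(idx, 0)
    if d[-1] > max(d[-2], threshold):
        idx = np.append(idx, d.size - 1)
    return grid[idx]


def _cnm_weights(ws: _Workspace, q, lam, max_steps=30):
    """Constrained-Newton weight update over a fixed support.

    Each step solves the NNLS problem arising from the second-order
    expansion of the log-likelihood in the mixture density (minimise
    ``|| sqrt(m)/f * (P w - 2 f) ||`` over ``w >= 0``), backtracking on
    the true log-likelihood; weights hit exactly zero at kills, unlike
    the EM/multiplicative update which only decays them geometrically.
    Returns the active ``(q, lam)``.
    """
    p = np.exp(ws.log_matrix(lam))

    def ll(w):
        with np.errstate(divide="ignore"):
            return float(ws.mult @ np.log(p @ w))

    sqrt_m = np.sqrt(ws.mult)
    # the simplex constraint must enter the least-squares system itself
    # (otherwise w = 2q is an exact, useless solution); Wang's device is
    # a heavily weighted extra row enforcing sum(w) = 1
    gamma = 1e3 * float(np.sqrt(ws.n))
    ll_cur = ll(q)
    for _ in range(max_steps):
        f = p @ q
        a = np.vstack([(sqrt_m / f)[:, None] * p, np.full((1, lam.size), gamma)])
        b = np.append(2.0 * sqrt_m, gamma)
        try:
            w_new, _ = nnls(a, b)
        except RuntimeError:  # pragma: no cover - nnls rarely fails
            break
        s = w_new.sum()
        if s <= 0:
            break
        w_new = w_new / s
        # backtracking line search on the true log-likelihood
        step = 1.0
        ll_cand = -np.inf
        for _ in range(25):
            cand = q + step * (w_new - q)
            ll_cand = ll(cand)
            if ll_cand >= ll_cur - 1e-12:
                break
            step *= 0.5
        if ll_cand < ll_cur - 1e-12:
            break
        gain = ll_cand - ll_cur
        q, ll_cur = cand, ll_cand
        if gain < 1e-11:
            break
    keep = q > 1e-14
    return q[keep] / q[keep].sum(), lam[keep]


def _merge_within(q, lam, gap=None, rel=None):
    """Merge sorted support points closer than a threshold.

    ``gap`` is an absolute threshold; ``rel`` scales it as
    ``rel * (1 + lam)`` per pair.  Used for numerical duplicates (EM
    crawls asymptotically when two support points merge).
    """
    order = np.argsort(lam)
    q, lam = q[order], lam[order]
    out_q, out_lam = [q[0]], [lam[0]]
    for w, l in zip(q[1:], lam[1:]):
        threshold = gap if gap is not None else rel * (1.0 + out_lam[-1])
        if l - out_lam[-1] < threshold:
            tot = out_q[-1] + w
            out_lam[-1] = (out_q[-1] * out_lam[-1] + w * l) / tot
            out_q[-1] = tot
        else:
            out_q.append(w)
            out_lam.append(l)
    return np.asarray(out_q), np.asarray(out_lam)


def _collapse(q, lam, collapse_delta):
    """Merge support points closer than the collapse threshold.

    Weights are summed and rates weight-averaged; the threshold for a
    sorted adjacent pair (a, b) is ``collapse_delta`` if given, else
    ``0.05 * (1 + lam_a)``.
    """
    order = np.argsort(lam)
    q, lam = q[order], lam[order]
    out_q, out_lam = [q[0]], [lam[0]]
    for w, l in zip(q[1:], lam[1:]):
        delta = collapse_delta if collapse_delta is not None else 0.05 * (1.0 + out_lam[-1])
        if l - out_lam[-1] < delta:
            tot = out_q[-1] + w
            out_lam[-1] = (out_q[-1] * out_lam[-1] + w * l) / tot
            out_q[-1] = tot
        else:
            out_q.append(w)
            out_lam.append(l)
    return np.asarray(out_q), np.asarray(out_lam)


def fit_npmle(
    counts,
    grid_size: int = 50,
    tol: float = 1e-7,
    max_iter: int = 5000,
    collapse_delta: Optional[float] = None,
    em_tol: float = 1e-10,
    em_max_iter: int = 400,
    window_years: Optional[float] = None,
) -> FitResult:
    """Fit the NPMLE of the Poisson mixing distribution.

    Three phases: (1) VEM over ``grid_size`` equally spaced candidate
    rates on ``[0, max(count)]``; (2) EM refinement of weights and
    rates jointly, inserting the gradient maximiser as a new support
    point until the optimality certificate ``sup d(lam) <= 1 + tol``
    holds; (3) collapsing of near-duplicate support points (weights
    summed, rates weight-averaged), kept only if the certificate
    survives it.  Non-convergence within the iteration budgets is
    flagged on the result, not raised.

    Returns a :class:`FitResult` whose mixture has strictly increasing
    rates and weights summing to one.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    h = _as_counts(counts)
    if h.size == 0:
        raise ValueError("counts must be non-empty")
    if window_years is None:
        window_years = counts.window_years if isinstance(counts, CountVector) else 1.0

    if h.max() == 0:
        mix = MixtureDistribution((1.0,), (0.0,), window_years=window_years)
        return FitResult(mix, 0.0, 0, 0, 1.0, True, [np.zeros(1)])

    ws = _Workspace(h)
    hi = float(h.max())
    grid = np.linspace(0.0, hi, grid_size)
    w, n_vem = _vem(ws, grid, max(tol, 1e-3), min(max_iter, 1000))

    active = w > _WEIGHT_FLOOR
    q, lam = w[active], grid[active]
    q = q / q.sum()
    # adjacent active grid atoms describe the same support point; merge
    # them at grid resolution so EM does not crawl toward the merge
    q, lam = _merge_within(q, lam, 1.5 * (grid[1] - grid[0]))

    grad_tol = max(tol, 1e-9)
    check_grid = np.linspace(0.0, hi, 2000)
    traces = []
    max_grad = np.inf
    converged = False
    for _ in range(60):
        # local rate refinement (EM moves support points off the grid)
        q, lam, extra = _em(ws, q, lam, em_tol, min(em_max_iter, 200))
        traces.append(extra)
        # EM approaches a merge of two support points only asymptotically;
        # fold numerical duplicates so the loop does not crawl
        q, lam = _merge_within(q, lam, rel=1e-4)
        # support augmentation: every local maximiser of the gradient
        # above 1 is a candidate support point (weight 0, raised by CNM)
        d = ws.gradient(q, lam, check_grid)
        cand = _local_maxima(d, check_grid, 1.0)
        if cand.size:
            cand = cand[np.min(np.abs(cand[:, None] - lam[None, :]), axis=1) > 1e-10]
        if cand.size:
            lam = np.concatenate([lam, cand])
            q = np.concatenate([q, np.zeros(cand.size)])
        q, lam = _cnm_weights(ws, q, lam)
        max_grad = float(np.max(ws.gradient(q, lam, check_grid)))
        if max_grad <= 1.0 + grad_tol:
            converged = True
            break

    # presentation-level collapse of near-duplicate support points;
    # keep it only when the NPMLE certificate survives
    qc, lamc = _collapse(q, lam, collapse_delta)
    if lamc.size < lam.size:
        qc, lamc, extra = _em(ws, qc, lamc, em_tol, em_max_iter)
        qc, lamc = _cnm_weights(ws, qc, lamc)
        max_grad_c = float(np.max(ws.gradient(qc, lamc, check_grid)))
        if not converged or max_grad_c <= 1.0 + max(grad_tol, 1e-6):
            q, lam, max_grad = qc, lamc, max_grad_c
            traces.append(extra)

    mix = MixtureDistribution.from_components(q, lam, window_years=window_years, normalise=True)
    ll = loglik(CountVector(h), mix)
    final_grid = np.unique(np.concatenate([check_grid, np.asarray(mix.lam)]))
    max_grad = float(np.max(gradient_function(final_grid, CountVector(h), mix)))
    converged = max_grad <= 1.0 + max(grad_tol, 1e-6)
    n_iter_em = int(sum(t.size for t in traces))
    return FitResult(mix, ll, n_vem, n_iter_em, max_grad, converged, traces)


def fit_fixed_k(
    counts,
    k: int,
    em_tol: float = 1e-10,
    em_max_iter: int = 5000,
    window_years: Optional[float] = None,
) -> FitResult:
    """Maximum-likelihood fit of a Poisson mixture with exactly ``k`` groups.

    ``k == 1`` is the closed-form sample mean; otherwise EM from a
    quantile-spread initialisation.  Used as the null model of the
    bootstrap likelihood-ratio test.  Components that collapse onto
    the same rate during EM are merged, so the result can have fewer
    than ``k`` groups.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    h = _as_counts(counts)
    if h.size == 0:
        raise ValueError("counts must be non-empty")
    if window_years is None:
        window_years = counts.window_years if isinstance(counts, CountVector) else 1.0

    if k == 1 or h.max() == 0:
        lam_hat = float(h.mean())
        mix = MixtureDistribution((1.0,), (lam_hat,), window_years=window_years)
        return FitResult(mix, loglik(CountVector(h), mix), 0, 0, math.nan, True, [])

    ws = _Workspace(h)
    qs = np.quantile(h, np.linspace(0.05, 0.95, k))
    lam0 = np.maximum(qs + np.linspace(0.0, 1e-3, k), 1e-6)  # break ties
    q0 = np.full(k, 1.0 / k)
    q, lam, trace = _em(ws, q0, lam0, em_tol, em_max_iter)
    q, lam = _merge_within(q, lam, 1e-9)
    mix = MixtureDistribution.from_components(q, lam, window_years=window_years, normalise=True)
    return FitResult(mix, loglik(CountVector(h), mix), 0, int(trace.size), math.nan, True, [trace])


def simulate_counts(
    mix: MixtureDistribution,
    n_units: int,
    seed=None,
    window_years: Optional[float] = None,
) -> CountVector:
    """Draw per-unit counts from a mixture.

    Each unit is independently assigned a group with probabilities
    ``q`` and then a Poisson count with that group's rate.  ``seed``
    may be an int or a :class:`numpy.random.Generator`.
    """
    if n_units < 1:
        raise ValueError("n_units must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = rng.choice(mix.k, size=n_units, p=np.asarray(mix.q))
    counts = rng.poisson(np.asarray(mix.lam)[groups])
    return CountVector(
        counts,
        window_years=window_years if window_years is not None else mix.window_years,
    )


def bootstrap_lrt(
    counts,
    k_null: int,
    n_boot: int = 99,
    seed=None,
    grid_size: int = 50,
) -> GofReport:
    """Parametric-bootstrap likelihood-ratio test of a ``k_null``-group fit.

    The null model (``k_null`` groups, fixed-k MLE) is tested against
    the unconstrained NPMLE.  ``n_boot`` datasets are simulated from the
    null fit, both models refitted on each, and
    ``p = (1 + #{LRT* >= LRT_obs}) / (n_boot + 1)``.
    """
    if k_null < 1:
        raise ValueError("k_null must be at least 1")
    if n_boot < 19:
        raise ValueError("n_boot must be at least 19 for usable p-value resolution")
    h = _as_counts(counts)
    cv = CountVector(h)
    rng = np.random.default_rng(seed)

    null_fit = fit_fixed_k(cv, k_null)
    alt_fit = fit_npmle(cv, grid_size=grid_size)
    lrt_obs = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))

    exceed = 0
    for _ in range(n_boot):
        sim = simulate_counts(null_fit.mixture, cv.n_units, seed=rng)
        null_b = fit_fixed_k(sim, k_null)
        alt_b = fit_npmle(sim, grid_size=grid_size)
        lrt_b = max(0.0, 2.0 * (alt_b.loglik - null_b.loglik))
        if lrt_b >= lrt_obs:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return GofReport(lrt_obs, p, k_null, alt_fit.mixture.k, n_boot)


def fit_parsimonious(
    counts,
    alpha: float = 0.05,
    n_boot: int = 19,
    seed=None,
    grid_size: int = 50,
) -> FitResult:
    """NPMLE fit followed by the model-acceptance test.

    The unconstrained NPMLE overfits sampling noise in short,
    low-frequency count vectors (any chance overdispersion splits the
    support).  This wrapper fits the NPMLE and then searches for the
    smallest number of groups whose fixed-k fit is *not* rejected
    against the NPMLE by the parametric-bootstrap likelihood-ratio
    test at level ``alpha``; the accepted model is returned.  If every
    smaller model is rejected, the NPMLE itself is returned.
    """
    rng = np.random.default_rng(seed)
    npmle = fit_npmle(counts, grid_size=grid_size)
    for k_null in range(1, npmle.mixture.k):
        report = bootstrap_lrt(counts, k_null, n_boot=n_boot, seed=rng, grid_size=grid_size)
        if report.p_value > alpha:
            return fit_fixed_k(counts, k_null,
                               window_years=npmle.mixture.window_years)
    return npmle
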