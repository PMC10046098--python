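"""A No-U-Turn sampler with dual-averaging step size and diagonal metric.

Standalone gradient-based MCMC used by :mod:`xciskew.infer`.  The target is
any callable ``logp_and_grad(x) -> (float, ndarray)`` on an unconstrained
parameter vector; constrained parameters are handled by the model layer via
change-of-variables Jacobians.

The implementation follows the classic recursive tree-doubling scheme with a
slice variable, a Stan-style warmup (fast start, expanding variance-estimation
windows, fast tail) adapting a diagonal metric, and dual averaging tuned to a
target acceptance statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "sample_nuts"]

_DELTA_MAX = 1000.0  # divergence threshold on the energy error


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_kept, dim), post-warmup
    accept_stat: np.ndarray    # per kept iteration mean acceptance statistic
    n_divergent: int
    step_size: float
    inv_metric: np.ndarray


class _Target:
    """Caches the last evaluation; counts gradient calls."""

    def __init__(self, logp_and_grad):
        self._f = logp_and_grad
        self.n_evals = 0

    def __call__(self, x):
        self.n_evals += 1
        # extreme warmup positions overflow harmlessly to -inf log-density
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            logp, grad = self._f(x)
        if not np.isfinite(logp):
            return -np.inf, np.zeros_like(x)
        return logp, grad


def _leapfrog(target, x, r, grad, eps, inv_metric):
    r = r + 0.5 * eps * grad
    x = x + eps * inv_metric * r
    logp, grad = target(x)
    r = r + 0.5 * eps * grad
    return x, r, logp, grad


def _kinetic(r, inv_metric):
    return 0.5 * float(np.dot(r * inv_metric, r))


def _find_initial_step(target, x, logp, grad, rng, inv_metric):
    eps = 1.0
    r = rng.standard_normal(len(x)) / np.sqrt(inv_metric)
    h0 = logp - _kinetic(r, inv_metric)
    _, r1, logp1, _ = _leapfrog(target, x, r, grad, eps, inv_metric)
    h1 = logp1 - _kinetic(r1, inv_metric)
    d = h1 - h0
    if not np.isfinite(d):
        d = -np.inf
    direction = 1.0 if d > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, logp1, _ = _leapfrog(target, x, r, grad, eps, inv_metric)
        h1 = logp1 - _kinetic(r1, inv_metric)
        d = h1 - h0 if np.isfinite(logp1) else -np.inf
        if direction == 1.0 and d <= np.log(0.5):
            break
        if direction == -1.0 and d >= np.log(0.5):
            break
    return eps


class _DualAveraging:
    def __init__(self, eps0, target_accept, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target_accept
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat):
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** -self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self):
        return np.exp(self.log_eps_bar)


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # shrink toward unit scale, as is conventional for short windows
        w = self.n / (self.n + 5.0)
        return w * var + (1.0 - w) * 1e-3


def _warmup_windows(n_warmup):
    """(init_buffer, window starts, term_buffer) Stan-style schedule."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init = max(int(0.15 * n_warmup), 1)
    term = max(int(0.10 * n_warmup), 1)
    base = max(int(0.25 * (n_warmup - init - term)), 1)
    bounds = []
    start = init
    width = base
    while start + width < n_warmup - term:
        bounds.append((start, min(start + width, n_warmup - term)))
        start += width
        width *= 2
    if bounds:
        bounds[-1] = (bounds[-1][0], n_warmup - term)
    else:
        bounds = [(init, n_warmup - term)]
    return init, bounds, term


def _build_tree(target, x, r, grad, logu, v, j, eps, h0, inv_metric, rng, stats):
    if j == 0:
        x1, r1, logp1, grad1 = _leapfrog(target, x, r, grad, v * eps, inv_metric)
        h1 = logp1 - _kinetic(r1, inv_metric)
        delta = h1 - h0
        if not np.isfinite(delta):
            delta = -np.inf
        n1 = int(logu <= h1)
        diverged = logu - _DELTA_MAX >= h1
        if diverged:
            stats["divergent"] = True
        stats["sum_accept"] += np.exp(min(delta, 0.0))
        stats["n_leapfrog"] += 1
        return x1, r1, grad1, x1, r1, grad1, x1, logp1, grad1, n1, not diverged
    # recursion: build left and right subtrees
    xm, rm, gm, xp, rp, gp, x1, logp1, g1, n1, s1 = _build_tree(
        target, x, r, grad, logu, v, j - 1, eps, h0, inv_metric, rng, stats
    )
    if s1:
        if v == -1:
            xm, rm, gm, _, _, _, x2, logp2, g2, n2, s2 = _build_tree(
                target, xm, rm, gm, logu, v, j - 1, eps, h0, inv_metric, rng, stats
            )
        else:
            _, _, _, xp, rp, gp, x2, logp2, g2, n2, s2 = _build_tree(
                target, xp, rp, gp, logu, v, j - 1, eps, h0, inv_metric, rng, stats
            )
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            x1, logp1, g1 = x2, logp2, g2
        dx = xp - xm
        s1 = (
            s2
            and float(dx @ (inv_metric * rm)) >= 0.0
            and float(dx @ (inv_metric * rp)) >= 0.0
        )
        n1 += n2
    return xm, rm, gm, xp, rp, gp, x1, logp1, g1, n1, s1


def sample_nuts(
    logp_and_grad,
    x0: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws."""
    target = _Target(logp_and_grad)
    x = np.asarray(x0, dtype=float).copy()
    dim = len(x)
    logp, grad = target(x)
    if not np.isfinite(logp):
        raise ValueError("non-finite log-density at the initial position")
    inv_metric = np.ones(dim)

    eps = _find_initial_step(target, x, logp, grad, rng, inv_metric)
    da = _DualAveraging(eps, target_accept)
    init_buf, windows, term_buf = _warmup_windows(n_warmup)
    window_ends = {end: True for _, end in windows}
    welford = _Welford(dim)
    in_window = lambda i: any(a <= i < b for a, b in windows)

    n_kept = n_iter - n_warmup
    draws = np.empty((n_kept, dim))
    accept_kept = np.empty(n_kept)
    n_divergent = 0

    for it in range(n_iter):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_metric)
        h0 = logp - _kinetic(r0, inv_metric)
        logu = h0 - rng.exponential(1.0)
        xm = xp = x
        rm = rp = r0
        gm = gp = grad
        n = 1
        s = True
        stats = {"sum_accept": 0.0, "n_leapfrog": 0, "divergent": False}
        j = 0
        while s and j < max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                xm, rm, gm, _, _, _, x1, logp1, g1, n1, s1 = _build_tree(
                    target, xm, rm, gm, logu, v, j, eps, h0, inv_metric, rng, stats
                )
            else:
                _, _, _, xp, rp, gp, x1, logp1, g1, n1, s1 = _build_tree(
                    target, xp, rp, gp, logu, v, j, eps, h0, inv_metric, rng, stats
                )
            if s1 and rng.random() < min(1.0, n1 / n):
                x, logp, grad = x1, logp1, g1
            n += n1
            dx = xp - xm
            s = (
                s1
                and float(dx @ (inv_metric * rm)) >= 0.0
                and float(dx @ (inv_metric * rp)) >= 0.0
            )
            j += 1
        accept_stat = (
            stats["sum_accept"] / stats["n_leapfrog"] if stats["n_leapfrog"] else 0.0
        )
        if stats["divergent"]:
            n_divergent += 1

        if it < n_warmup:
            eps = da.update(accept_stat)
            if in_window(it):
                welford.update(x)
            if window_ends.pop(it + 1, False):
                inv_metric = welford.variance()
                welford = _Welford(dim)
                eps = _find_initial_step(target, x, logp, grad, rng, inv_metric)
                da = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            draws[it - n_warmup] = x
            accept_kept[it - n_warmup] = accept_stat

    return NutsResult(
        draws=draws,
        accept_stat=accept_kept,
        n_divergent=n_divergent,
        step_size=float(eps),
        inv_metric=inv_metric,
    )
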