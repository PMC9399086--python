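"""Adaptive Hamiltonian Monte Carlo with a diagonal mass matrix.

Warmup follows the usual three-phase schedule: an initial buffer adapting
only the step size, a sequence of doubling "slow" windows each of which
re-estimates the diagonal inverse mass from that window's sample variance
(resetting step-size adaptation after every update), and a terminal buffer
that re-tunes the step size under the final metric.  Trajectory lengths are
jittered uniformly to avoid resonance.  Non-finite energies or an energy
error above a large threshold are treated as divergences (proposal
rejected, counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MCMCConfig", "run_chain"]

_DIVERGENCE_ENERGY = 1000.0


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler budget.  ``draws`` is per chain; the default mirrors a
    4-chain / 10,000-total-retained configuration."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 2500
    seed: int = 0
    target_accept: float = 0.9
    trajectory_length: float = 3.0
    max_leapfrog: int = 64
    scaled_down: bool = False   # flag reduced-budget runs in metadata


def _leapfrog(logp_grad, x, p, eps, inv_mass, grad, n_steps):
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, grad
        if i < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _kinetic(inv_mass, p):
    with np.errstate(over="ignore"):
        ke = 0.5 * np.sum(inv_mass * p**2)
    return ke if np.isfinite(ke) else np.inf


def _find_initial_step(logp_grad, x0, inv_mass, rng, eps=0.1):
    """Heuristic: double/halve eps until a single step's acceptance crosses 0.5."""
    lp0, grad0 = logp_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = lp0 - _kinetic(inv_mass, p0)

    def joint(eps):
        x, p, lp, _ = _leapfrog(logp_grad, x0, p0, eps, inv_mass, grad0, 1)
        if not np.isfinite(lp):
            return -np.inf
        return lp - _kinetic(inv_mass, p)

    direction = 1 if joint(eps) - h0 > np.log(0.5) else -1
    for _ in range(50):
        eps_new = eps * (2.0 if direction == 1 else 0.5)
        delta = joint(eps_new) - h0
        if (direction == 1 and delta < np.log(0.5)) or (
                direction == -1 and delta > np.log(0.5)):
            return eps_new if direction == -1 else eps
        eps = eps_new
    return eps


class _DualAveraging:
    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_prob):
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)


def _adaptation_schedule(warmup):
    """(init_end, window_ends, term_start): doubling slow windows a la Stan."""
    if warmup < 200:
        init_end = int(0.15 * warmup)
        term_start = int(0.9 * warmup)
        return init_end, [term_start], term_start
    init_end, term = 75, 50
    term_start = warmup - term
    ends, size, pos = [], 25, init_end
    while pos + size < term_start:
        # widen the last window to absorb the remainder
        if pos + 3 * size >= term_start:
            ends.append(term_start)
            pos = term_start
            break
        pos += size
        ends.append(pos)
        size *= 2
    if not ends or ends[-1] != term_start:
        ends.append(term_start)
    return init_end, ends, term_start


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        return self.m2 / max(self.n - 1, 1)


def run_chain(logp_grad, x0, config: MCMCConfig, rng: np.random.Generator):
    """One HMC chain; returns (draws array (draws, dim), stats dict)."""
    dim = x0.size
    warmup, draws = config.warmup, config.draws
    inv_mass = np.ones(dim)
    x = x0.copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the chain's starting point")

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    da = _DualAveraging(eps, config.target_accept)
    init_end, window_ends, term_start = _adaptation_schedule(warmup)
    window_ends = list(window_ends)
    acc = _Welford(dim)

    out = np.empty((draws, dim))
    divergences = 0
    accepts = []

    for it in range(warmup + draws):
        adapting = it < warmup
        n_nominal = int(np.clip(round(config.trajectory_length / eps), 1,
                                config.max_leapfrog))
        lo = max(1, n_nominal // 2)
        n_steps = int(rng.integers(lo, n_nominal + 1))

        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(inv_mass, p0)
        x_new, p_new, lp_new, grad_new = _leapfrog(
            logp_grad, x, p0, eps, inv_mass, grad, n_steps)

        if np.isfinite(lp_new):
            delta = (lp_new - _kinetic(inv_mass, p_new)) - h0
        else:
            delta = -np.inf
        if not np.isfinite(delta) or delta < -_DIVERGENCE_ENERGY:
            accept_prob = 0.0
            if not adapting:
                divergences += 1
        else:
            accept_prob = min(1.0, float(np.exp(min(delta, 0.0))))
            if rng.random() < accept_prob:
                x, lp, grad = x_new, lp_new, grad_new

        if adapting:
            eps = da.update(accept_prob)
            if it >= init_end and it < term_start:
                acc.push(x)
            if window_ends and it == window_ends[0] - 1:
                window_ends.pop(0)
                if acc.n > 10:
                    var = acc.variance()
                    n = acc.n
                    inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                    eps = _find_initial_step(logp_grad, x, inv_mass, rng,
                                             eps=max(eps, 1e-6))
                    da = _DualAveraging(eps, config.target_accept)
                acc = _Welford(dim)
            if it == warmup - 1:
                eps = float(np.exp(da.log_eps_bar))
        else:
            accepts.append(accept_prob)
            out[it - warmup] = x

    stats = {
        "step_size": float(eps),
        "mean_accept": float(np.mean(accepts)) if accepts else float("nan"),
        "divergences": int(divergences),
        "inv_mass": inv_mass,
    }
    return out, stats
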