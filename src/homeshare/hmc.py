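"""A compact No-U-Turn Sampler (NUTS) with dual-averaging step-size and
diagonal mass-matrix adaptation.

Implements the efficient-NUTS recursion of Hoffman & Gelman (2014, JMLR 15),
Algorithm 6, over a user-supplied log-density with analytic gradient.  Warmup
follows the usual three-phase schedule: an initial step-size-only phase, a
mass-estimation window accumulating posterior variances, and a final
step-size re-adaptation phase.

The target callable must return ``(logp, grad)`` for a parameter vector; the
sampler is generic and knows nothing about any particular model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

MAX_TREEDEPTH = 10
DELTA_MAX = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class SampleStats:
    """Per-chain sampler bookkeeping."""

    divergences: int
    step_size: float
    inv_mass: np.ndarray
    mean_accept: float
    max_treedepth_hits: int


def _find_reasonable_step_size(logp_grad, q, rng, inv_mass):
    """Heuristic initial step size: double/halve until accept prob crosses 0.5."""
    eps = 1.0
    lp, grad = logp_grad(q)
    p = rng.standard_normal(len(q)) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(inv_mass * p**2)
    q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * np.log(0.5):
            break
    return eps


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    q_new = q + eps * inv_mass * p_half
    lp_new, grad_new = logp_grad(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return q_new, p_new, lp_new, grad_new


def _build_tree(logp_grad, q, p, grad, logu, v, depth, eps, h0, inv_mass, rng):
    """Recursive doubling; returns the subtree summary (Hoffman-Gelman Alg. 6)."""
    if depth == 0:
        q1, p1, lp1, grad1 = _leapfrog(logp_grad, q, p, grad, v * eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
        if not np.isfinite(h1):
            h1 = -np.inf
        n1 = int(logu <= h1)
        diverged = logu - DELTA_MAX >= h1
        alpha = min(1.0, np.exp(min(h1 - h0, 0.0)))
        return q1, p1, grad1, q1, p1, grad1, q1, n1, (not diverged), alpha, 1, int(diverged)
    (qm, pm, gm, qp, pp, gp, q1, n1, s1, a1, na1, d1) = _build_tree(
        logp_grad, q, p, grad, logu, v, depth - 1, eps, h0, inv_mass, rng
    )
    if s1:
        if v == -1:
            (qm, pm, gm, _, _, _, q2, n2, s2, a2, na2, d2) = _build_tree(
                logp_grad, qm, pm, gm, logu, v, depth - 1, eps, h0, inv_mass, rng
            )
        else:
            (_, _, _, qp, pp, gp, q2, n2, s2, a2, na2, d2) = _build_tree(
                logp_grad, qp, pp, gp, logu, v, depth - 1, eps, h0, inv_mass, rng
            )
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            q1 = q2
        a1 += a2
        na1 += na2
        d1 += d2
        dq = qp - qm
        s1 = s2 and (np.dot(dq, inv_mass * pm) >= 0) and (np.dot(dq, inv_mass * pp) >= 0)
        n1 += n2
    return qm, pm, gm, qp, pp, gp, q1, n1, s1, a1, na1, d1


def nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.8,
    max_treedepth: int = MAX_TREEDEPTH,
) -> tuple[np.ndarray, SampleStats]:
    """Run one NUTS chain; returns ``(draws, stats)`` with draws ``(n_draws, dim)``.

    Deterministic given ``seed``.  Divergences are counted over the sampling
    phase only.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        return _nuts_impl(logp_grad, q0, n_warmup, n_draws, seed, target_accept, max_treedepth)


def _nuts_impl(logp_grad, q0, n_warmup, n_draws, seed, target_accept, max_treedepth):
    # overflow at extreme trial step sizes is expected and handled via -inf
    rng = np.random.default_rng(seed)
    q = np.asarray(q0, dtype=float).copy()
    dim = len(q)
    inv_mass = np.ones(dim)

    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_step_size(logp_grad, q, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass window: [25%, 90%] of warmup, when warmup is long enough
    win_lo = int(0.25 * n_warmup)
    win_hi = int(0.90 * n_warmup)
    adapt_mass = n_warmup >= 100
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    divergences = 0
    accept_sum = 0.0
    depth_hits = 0
    da_iter = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
        logu = h0 + np.log(rng.random())
        qm = qp = q
        pm = pp = p0
        gm = gp = grad
        q_new = q
        n_tot, s, depth = 1, True, 0
        alpha_sum, n_alpha, n_div = 0.0, 0, 0
        while s and depth < max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                (qm, pm, gm, _, _, _, q2, n2, s2, a2, na2, d2) = _build_tree(
                    logp_grad, qm, pm, gm, logu, v, depth, eps, h0, inv_mass, rng
                )
            else:
                (_, _, _, qp, pp, gp, q2, n2, s2, a2, na2, d2) = _build_tree(
                    logp_grad, qp, pp, gp, logu, v, depth, eps, h0, inv_mass, rng
                )
            if s2 and rng.random() < min(1.0, n2 / max(n_tot, 1)):
                q_new = q2
            n_tot += n2
            alpha_sum += a2
            n_alpha += na2
            n_div += d2
            dq = qp - qm
            s = s2 and (np.dot(dq, inv_mass * pm) >= 0) and (np.dot(dq, inv_mass * pp) >= 0)
            depth += 1
        if depth == max_treedepth and not warming:
            depth_hits += 1
        q = q_new
        lp, grad = logp_grad(q)
        accept = alpha_sum / max(n_alpha, 1)

        if warming:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (target_accept - accept) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            eta = da_iter**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if adapt_mass and win_lo <= it < win_hi:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
            if adapt_mass and it == win_hi - 1 and welford_n > 10:
                var = welford_m2 / (welford_n - 1)
                # regularize toward unit scale, as Stan does
                var = (welford_n / (welford_n + 5.0)) * var + (5.0 / (welford_n + 5.0)) * 1e-3
                inv_mass = np.maximum(var, 1e-10)
                eps = _find_reasonable_step_size(logp_grad, q, rng, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            divergences += n_div
            accept_sum += accept
            draws[it - n_warmup] = q

    stats = SampleStats(
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
        mean_accept=accept_sum / max(n_draws, 1),
        max_treedepth_hits=depth_hits,
    )
    return draws, stats
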