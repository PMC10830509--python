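"""No-U-Turn sampler and convergence diagnostics.

A self-contained gradient-based MCMC engine used by both Bayesian models in
the pipeline. The sampler is the slice-variable NUTS of Hoffman & Gelman
(2014) with dual-averaging step-size adaptation and windowed diagonal
mass-matrix estimation during warmup. Retained draws honour the
chains/iterations/warmup/thin contract of :class:`SamplerConfig`.

Diagnostics are split-R-hat and a Geyer initial-monotone-sequence effective
sample size, computed on split chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .datatypes import SamplerConfig

__all__ = ["run_nuts", "split_rhat", "ess_mean", "DiagnosticsReport", "diagnose"]

# target log-density and its gradient at a point
LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_MAX_ENERGY_CHANGE = 1000.0


# ---------------------------------------------------------------------------
# sampler internals


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def _find_initial_step(logp_grad, q, rng, inv_mass):
    """Heuristic of Hoffman & Gelman: double/halve until accept prob crosses 0.5."""
    eps = 1.0
    logp, grad = logp_grad(q)
    p = rng.normal(size=q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) < direction * math.log(0.5):
            break
    return max(eps, 1e-10)


class _DualAveraging:
    """Nesterov dual averaging on log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m**-self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted_step(self) -> float:
        return math.exp(self.log_eps_bar)


def _build_tree(logp_grad, q, p, grad, logp, log_u, v, depth, eps, inv_mass, h0, rng):
    """Recursive doubling; returns the standard NUTS tuple."""
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, v * eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        n1 = int(log_u <= h1)
        s1 = int(log_u < h1 + _MAX_ENERGY_CHANGE)
        alpha = min(1.0, math.exp(min(0.0, h1 - h0)))
        return q1, p1, grad1, logp1, q1, p1, grad1, logp1, q1, logp1, n1, s1, alpha, 1
    (qm, pm, gm, lm, qp, pp, gp, lp, q1, l1, n1, s1, a1, na1) = _build_tree(
        logp_grad, q, p, grad, logp, log_u, v, depth - 1, eps, inv_mass, h0, rng
    )
    if s1 == 1:
        if v == -1:
            (qm, pm, gm, lm, _, _, _, _, q2, l2, n2, s2, a2, na2) = _build_tree(
                logp_grad, qm, pm, gm, lm, log_u, v, depth - 1, eps, inv_mass, h0, rng
            )
        else:
            (_, _, _, _, qp, pp, gp, lp, q2, l2, n2, s2, a2, na2) = _build_tree(
                logp_grad, qp, pp, gp, lp, log_u, v, depth - 1, eps, inv_mass, h0, rng
            )
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            q1, l1 = q2, l2
        a1 += a2
        na1 += na2
        dq = qp - qm
        s1 = s2 * int(np.dot(dq, inv_mass * pm) >= 0) * int(np.dot(dq, inv_mass * pp) >= 0)
        n1 += n2
    return qm, pm, gm, lm, qp, pp, gp, lp, q1, l1, n1, s1, a1, na1


def _nuts_step(logp_grad, q, logp, grad, eps, inv_mass, max_depth, rng):
    p0 = rng.normal(size=q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)
    log_u = h0 + math.log1p(-rng.random())  # log of u ~ Uniform(0, exp(h0))
    qm = qp = q
    pm = pp = p0
    gm = gp = grad
    lm = lp = logp
    q_new, logp_new = q, logp
    depth, n, s = 0, 1, 1
    alpha_sum, n_alpha = 0.0, 0
    while s == 1 and depth < max_depth:
        v = 1 if rng.random() < 0.5 else -1
        if v == -1:
            (qm, pm, gm, lm, _, _, _, _, q1, l1, n1, s1, a1, na1) = _build_tree(
                logp_grad, qm, pm, gm, lm, log_u, v, depth, eps, inv_mass, h0, rng
            )
        else:
            (_, _, _, _, qp, pp, gp, lp, q1, l1, n1, s1, a1, na1) = _build_tree(
                logp_grad, qp, pp, gp, lp, log_u, v, depth, eps, inv_mass, h0, rng
            )
        if s1 == 1 and rng.random() < min(1.0, n1 / n):
            q_new, logp_new = q1, l1
        alpha_sum += a1
        n_alpha += na1
        n += n1
        dq = qp - qm
        s = s1 * int(np.dot(dq, inv_mass * pm) >= 0) * int(np.dot(dq, inv_mass * pp) >= 0)
        depth += 1
    accept_stat = alpha_sum / max(n_alpha, 1)
    _, grad_new = logp_grad(q_new)  # cheap relative to tree; keeps bookkeeping simple
    return q_new, logp_new, grad_new, accept_stat


def _mass_windows(warmup: int) -> list[tuple[int, int]]:
    """(start, end) covariance-accumulation windows within warmup, Stan-style."""
    init_buf = min(max(75, int(0.15 * warmup)), warmup // 2)
    term_buf = min(max(50, int(0.1 * warmup)), warmup // 4)
    windows = []
    start, size = init_buf, 25
    while start + size < warmup - term_buf:
        end = start + size
        if end + 2 * size >= warmup - term_buf:
            end = warmup - term_buf
        windows.append((start, end))
        start, size = end, 2 * size
    return windows


def run_nuts(
    logp_grad: LogpGrad,
    init: np.ndarray | Sequence[np.ndarray],
    config: SamplerConfig,
) -> tuple[np.ndarray, dict]:
    """Sample a target density; returns (chains, retained, dim) draws and stats.

    ``init`` is either one starting point (jittered per chain) or one point
    per chain. Fully deterministic given ``config.seed``.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(config.n_chains)
    init = np.atleast_2d(np.asarray(init, dtype=float))
    dim = init.shape[1]
    if init.shape[0] == 1:
        init = np.repeat(init, config.n_chains, axis=0)
    all_draws = np.empty((config.n_chains, config.n_retained, dim))
    stats: dict = {"step_size": [], "mean_accept": [], "divergences": 0}

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        q = init[c] + 0.1 * rng.normal(size=dim)
        logp, grad = logp_grad(q)
        if not np.isfinite(logp):
            raise ValueError("log posterior is not finite at the initial point")
        inv_mass = np.ones(dim)
        eps = _find_initial_step(logp_grad, q, rng, inv_mass)
        da = _DualAveraging(eps, target=config.target_accept)
        windows = _mass_windows(config.warmup)
        win_idx = 0
        acc_sum = np.zeros(dim)
        acc_sq = np.zeros(dim)
        acc_n = 0
        accepts = []
        kept = 0
        for it in range(config.n_iterations):
            q, logp, grad, a_stat = _nuts_step(
                logp_grad, q, logp, grad, eps, inv_mass, config.max_treedepth, rng
            )
            if it < config.warmup:
                eps = da.update(a_stat)
                if win_idx < len(windows):
                    w_start, w_end = windows[win_idx]
                    if w_start <= it < w_end:
                        acc_sum += q
                        acc_sq += q * q
                        acc_n += 1
                    if it == w_end - 1 and acc_n > 2:
                        var = (acc_sq - acc_sum**2 / acc_n) / (acc_n - 1)
                        # regularize towards unit scale as Stan does
                        var = (acc_n / (acc_n + 5.0)) * var + 1e-3 * (
                            5.0 / (acc_n + 5.0)
                        )
                        inv_mass = np.maximum(var, 1e-10)
                        acc_sum[:] = 0.0
                        acc_sq[:] = 0.0
                        acc_n = 0
                        win_idx += 1
                        eps = _find_initial_step(logp_grad, q, rng, inv_mass)
                        da = _DualAveraging(eps, target=config.target_accept)
                if it == config.warmup - 1:
                    eps = da.adapted_step
            else:
                accepts.append(a_stat)
                post_it = it - config.warmup
                if (post_it + 1) % config.thin == 0 and kept < config.n_retained:
                    all_draws[c, kept] = q
                    kept += 1
        stats["step_size"].append(eps)
        stats["mean_accept"].append(float(np.mean(accepts)) if accepts else np.nan)
    return all_draws, stats


# ---------------------------------------------------------------------------
# diagnostics


def _split_chains(x: np.ndarray) -> np.ndarray:
    """(chains, draws) -> (2*chains, draws//2), dropping an odd draw."""
    m, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half :]], axis=0)


def split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction factor on split chains (Gelman et al.)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (chains, draws)")
    if x.shape[0] < 2:
        return float("nan")
    z = _split_chains(x)
    m, n = z.shape
    if n < 2:
        return float("nan")
    chain_means = z.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = z.var(axis=1, ddof=1).mean()
    if w == 0:
        return float("nan") if b == 0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess_mean(x: np.ndarray) -> float:
    """Effective sample size for the mean, via Geyer's initial monotone sequence."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    z = _split_chains(x) if x.shape[0] >= 1 and x.shape[1] >= 4 else x
    m, n = z.shape
    if n < 4:
        return float("nan")
    w = z.var(axis=1, ddof=1).mean()
    if w == 0:
        return float("nan")
    chain_means = z.mean(axis=1)
    b_over_n = chain_means.var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + b_over_n
    acov = np.empty((m, n))
    for i in range(m):
        acov[i] = _autocov_fft(z[i])
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (w - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 0.0
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += pair
        prev_pair = pair
        t += 2
    ess = m * n / (1.0 + 2.0 * tau)
    return float(min(ess, m * n * math.log10(max(m * n, 10))))


def _autocov_fft(y: np.ndarray) -> np.ndarray:
    n = y.size
    yc = y - y.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(yc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence summary with an overall pass flag."""

    parameter_names: Sequence[str]
    rhat: np.ndarray
    ess: np.ndarray
    rhat_max: float
    ess_min: float
    passed: bool
    notes: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"parameter": list(self.parameter_names), "rhat": self.rhat, "ess": self.ess}
        )


def diagnose(draws, rhat_max: float = 1.01, ess_min: float = 400.0) -> DiagnosticsReport:
    """Split-R-hat and ESS for every parameter of a posterior.

    With a single chain R-hat is undefined and reported as NaN; the pass
    flag then rests on ESS alone and the note says so.
    """
    arr = draws.draws
    n_par = arr.shape[2]
    rhats = np.array([split_rhat(arr[:, :, j]) for j in range(n_par)])
    esss = np.array([ess_mean(arr[:, :, j]) for j in range(n_par)])
    notes = ""
    if arr.shape[0] < 2:
        notes = "single chain: split R-hat undefined (NaN); pass based on ESS only"
        rhat_ok = True
    else:
        rhat_ok = bool(np.all(rhats < rhat_max))
    passed = rhat_ok and bool(np.all(esss > ess_min))
    return DiagnosticsReport(
        parameter_names=list(draws.parameter_names),
        rhat=rhats,
        ess=esss,
        rhat_max=rhat_max,
        ess_min=ess_min,
        passed=passed,
        notes=notes,
    )
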