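"""No-U-turn sampler with dual-averaging step size and diagonal mass adaptation.

Multinomial variant of NUTS (progressive sampling proportional to the
exponentiated Hamiltonian along the trajectory), with Stan-style warmup
windows: a fast initial interval adapting only the step size, doubling
slow windows that re-estimate the diagonal metric, and a terminal fast
interval. The implementation is self-contained on top of a
``logp_grad(theta) -> (float, ndarray)`` callable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_kept, dim), post-warmup, unthinned
    n_divergent: int
    n_max_treedepth: int
    step_size: float
    inv_mass: np.ndarray
    accept_mean: float


@dataclass
class _Tree:
    theta_minus: np.ndarray
    r_minus: np.ndarray
    grad_minus: np.ndarray
    theta_plus: np.ndarray
    r_plus: np.ndarray
    grad_plus: np.ndarray
    theta_prop: np.ndarray
    grad_prop: np.ndarray
    logp_prop: float
    log_sum_w: float
    sum_accept: float
    n_leapfrog: int
    turning: bool
    diverging: bool


def _logaddexp(a: float, b: float) -> float:
    if a == -math.inf:
        return b
    if b == -math.inf:
        return a
    m = a if a > b else b
    return m + math.log(math.exp(a - m) + math.exp(b - m))


class _Hamiltonian:
    def __init__(self, logp_grad: Callable, inv_mass: np.ndarray) -> None:
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass

    def joint(self, logp: float, r: np.ndarray) -> float:
        # overflow on extreme excursions is handled as divergence
        with np.errstate(over="ignore", invalid="ignore"):
            return logp - 0.5 * float(r @ (self.inv_mass * r))

    def leapfrog(
        self, theta: np.ndarray, r: np.ndarray, grad: np.ndarray, eps: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        with np.errstate(over="ignore", invalid="ignore"):
            r_half = r + 0.5 * eps * grad
            theta_new = theta + eps * (self.inv_mass * r_half)
            logp_new, grad_new = self.logp_grad(theta_new)
            r_new = r_half + 0.5 * eps * grad_new
        return theta_new, r_new, grad_new, logp_new

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        return rng.standard_normal(dim) / np.sqrt(self.inv_mass)


def _is_turning(ham: _Hamiltonian, tree: _Tree) -> bool:
    span = tree.theta_plus - tree.theta_minus
    return (
        float(span @ (ham.inv_mass * tree.r_minus)) < 0.0
        or float(span @ (ham.inv_mass * tree.r_plus)) < 0.0
    )


def _build_tree(
    ham: _Hamiltonian,
    theta: np.ndarray,
    r: np.ndarray,
    grad: np.ndarray,
    logp: float,
    depth: int,
    direction: int,
    eps: float,
    joint0: float,
    rng: np.random.Generator,
) -> _Tree:
    if depth == 0:
        theta_n, r_n, grad_n, logp_n = ham.leapfrog(theta, r, grad, direction * eps)
        joint = ham.joint(logp_n, r_n)
        if not math.isfinite(joint):
            joint = -math.inf
        delta = joint - joint0
        diverging = delta < -_DIVERGENCE_THRESHOLD
        accept = math.exp(min(0.0, delta)) if delta > -math.inf else 0.0
        return _Tree(
            theta_n, r_n, grad_n, theta_n, r_n, grad_n,
            theta_n, grad_n, logp_n,
            delta if not diverging else -math.inf,
            accept, 1, False, diverging,
        )

    first = _build_tree(
        ham, theta, r, grad, logp, depth - 1, direction, eps, joint0, rng
    )
    if first.turning or first.diverging:
        return first

    if direction == 1:
        second = _build_tree(
            ham, first.theta_plus, first.r_plus, first.grad_plus,
            first.logp_prop, depth - 1, direction, eps, joint0, rng,
        )
        theta_minus, r_minus, grad_minus = (
            first.theta_minus, first.r_minus, first.grad_minus,
        )
        theta_plus, r_plus, grad_plus = (
            second.theta_plus, second.r_plus, second.grad_plus,
        )
    else:
        second = _build_tree(
            ham, first.theta_minus, first.r_minus, first.grad_minus,
            first.logp_prop, depth - 1, direction, eps, joint0, rng,
        )
        theta_minus, r_minus, grad_minus = (
            second.theta_minus, second.r_minus, second.grad_minus,
        )
        theta_plus, r_plus, grad_plus = (
            first.theta_plus, first.r_plus, first.grad_plus,
        )

    log_sum_w = _logaddexp(first.log_sum_w, second.log_sum_w)
    # progressive multinomial sampling between subtrees
    if math.log(rng.uniform()) < second.log_sum_w - log_sum_w:
        theta_prop, grad_prop, logp_prop = (
            second.theta_prop, second.grad_prop, second.logp_prop,
        )
    else:
        theta_prop, grad_prop, logp_prop = (
            first.theta_prop, first.grad_prop, first.logp_prop,
        )

    tree = _Tree(
        theta_minus, r_minus, grad_minus, theta_plus, r_plus, grad_plus,
        theta_prop, grad_prop, logp_prop, log_sum_w,
        first.sum_accept + second.sum_accept,
        first.n_leapfrog + second.n_leapfrog,
        False, second.diverging,
    )
    tree.turning = second.turning or _is_turning(ham, tree)
    return tree


def _find_reasonable_step(
    ham: _Hamiltonian,
    theta: np.ndarray,
    logp: float,
    grad: np.ndarray,
    eps: float,
    rng: np.random.Generator,
) -> float:
    """Heuristic doubling/halving so the one-step accept ratio is near 0.8."""
    r = ham.sample_momentum(rng, theta.size)
    joint0 = ham.joint(logp, r)
    for _ in range(50):
        _, r_n, _, logp_n = ham.leapfrog(theta, r, grad, eps)
        joint = ham.joint(logp_n, r_n)
        delta = joint - joint0 if math.isfinite(joint) else -math.inf
        if delta > math.log(0.8):
            eps *= 2.0
        elif delta < math.log(0.2):
            eps *= 0.5
        else:
            break
    return eps


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) of the slow metric-adaptation windows, Stan-style."""
    if n_warmup < 20:
        return []
    init_buffer = max(int(0.15 * n_warmup), 10)
    term_buffer = max(int(0.10 * n_warmup), 10)
    base = max(int(0.25 * n_warmup) // 4, 5)
    windows = []
    start = init_buffer
    size = base
    while start + size < n_warmup - term_buffer:
        # last window absorbs the remainder
        if start + 3 * size >= n_warmup - term_buffer:
            size = n_warmup - term_buffer - start
        windows.append((start, start + size))
        start += size
        size *= 2
    if not windows and n_warmup - term_buffer > init_buffer:
        windows.append((init_buffer, n_warmup - term_buffer))
    return windows


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan defaults)."""

    def __init__(self, eps0: float, target: float) -> None:
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return math.exp(self.log_eps)

    def restart(self, eps0: float) -> None:
        self.mu = math.log(10.0 * eps0)
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    n_iterations: int,
    n_warmup: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.95,
    init_step_size: float = 0.05,
    max_tree_depth: int = 15,
) -> NutsResult:
    """Run one NUTS chain; returns the post-warmup draws (unthinned)."""
    if n_warmup >= n_iterations:
        raise ValueError("n_warmup must be smaller than n_iterations")
    theta = np.array(init, dtype=float)
    dim = theta.size
    inv_mass = np.ones(dim)
    ham = _Hamiltonian(logp_grad, inv_mass)
    logp, grad = logp_grad(theta)
    if not math.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_step(ham, theta, logp, grad, init_step_size, rng)
    da = _DualAveraging(eps, target_accept)
    windows = _adaptation_windows(n_warmup)
    window_iter = iter(windows)
    window = next(window_iter, None)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_iterations - n_warmup, dim))
    n_divergent = 0
    n_max_depth = 0
    accept_sum = 0.0

    for it in range(n_iterations):
        r = ham.sample_momentum(rng, dim)
        joint0 = ham.joint(logp, r)
        tree = _Tree(
            theta, r, grad, theta, r, grad, theta, grad, logp,
            0.0, 0.0, 0, False, False,
        )
        depth = 0
        log_sum_w = 0.0
        sum_accept = 0.0
        n_leapfrog = 0
        diverged = False
        while depth < max_tree_depth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(
                    ham, tree.theta_plus, tree.r_plus, tree.grad_plus,
                    tree.logp_prop, depth, direction, eps, joint0, rng,
                )
                tree.theta_plus, tree.r_plus, tree.grad_plus = (
                    sub.theta_plus, sub.r_plus, sub.grad_plus,
                )
            else:
                sub = _build_tree(
                    ham, tree.theta_minus, tree.r_minus, tree.grad_minus,
                    tree.logp_prop, depth, direction, eps, joint0, rng,
                )
                tree.theta_minus, tree.r_minus, tree.grad_minus = (
                    sub.theta_minus, sub.r_minus, sub.grad_minus,
                )
            sum_accept += sub.sum_accept
            n_leapfrog += sub.n_leapfrog
            if sub.diverging:
                diverged = True
                break
            if sub.turning:
                break
            # biased progressive sampling: favour the new subtree
            if math.log(rng.uniform()) < sub.log_sum_w - log_sum_w:
                tree.theta_prop = sub.theta_prop
                tree.grad_prop = sub.grad_prop
                tree.logp_prop = sub.logp_prop
            log_sum_w = _logaddexp(log_sum_w, sub.log_sum_w)
            if _is_turning(ham, tree):
                break
            depth += 1
        else:
            n_max_depth += 1

        theta = tree.theta_prop
        grad = tree.grad_prop
        logp = tree.logp_prop
        accept_prob = sum_accept / max(n_leapfrog, 1)
        if diverged and it >= n_warmup:
            n_divergent += 1

        if it < n_warmup:
            eps = da.update(accept_prob)
            if window is not None and window[0] <= it < window[1]:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
                if it == window[1] - 1:
                    var = welford_m2 / max(welford_n - 1, 1)
                    n = welford_n
                    inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    ham.inv_mass = inv_mass
                    eps = _find_reasonable_step(ham, theta, logp, grad, eps, rng)
                    da.restart(eps)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    window = next(window_iter, None)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            draws[it - n_warmup] = theta
            accept_sum += accept_prob

    n_kept = n_iterations - n_warmup
    return NutsResult(
        draws=draws,
        n_divergent=n_divergent,
        n_max_treedepth=n_max_depth,
        step_size=eps,
        inv_mass=inv_mass,
        accept_mean=accept_sum / max(n_kept, 1),
    )
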