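"""Temporal receptive-field estimation by reverse correlation.

Random binary stimulus drive is injected into a model unit over many
independent simulations; the per-lag correlation between the stimulus bit
and the final-time excitatory drive, suppressive drive, and response
measures how input at each past time point moves each quantity — the
temporal receptive field (TRF).  The excitatory-drive TRF follows the
tau_E exponential window; the suppressive-drive TRF follows the
convolution of the two windows (equivalently the absolute difference of
the two exponentials); the response TRF is biphasic — positive at recent
lags, negative further back — and is summarized by fitting a difference
of Gamma functions

    h(l) = l * exp(-l / tau1) - k * l * exp(-l / tau2)

up to a free scale factor, by multi-restart Nelder-Mead least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter

from .model import SensoryParams, exp_filter
from .protocols import random_binary_batch

__all__ = [
    "RFEstimate",
    "GammaFit",
    "FitError",
    "reverse_correlate",
    "shuffled_null",
    "hS_shape",
    "gamma_difference",
    "fit_gamma_difference",
]


class FitError(RuntimeError):
    """All optimizer restarts failed to produce a finite fit."""


@dataclass
class RFEstimate:
    """Per-lag reverse-correlation weights (lag 0 = current time)."""

    lags_ms: np.ndarray
    weights_excitatory: np.ndarray
    weights_suppressive: np.ndarray
    weights_response: np.ndarray
    weights_shuffled: np.ndarray
    n_sims: int
    seed: int | None
    params: SensoryParams


@dataclass
class GammaFit:
    tau1_ms: float
    tau2_ms: float
    k: float
    scale: float
    rss: float
    n_restarts: int

    def predict(self, lags_ms: np.ndarray) -> np.ndarray:
        return self.scale * gamma_difference(lags_ms, self.tau1_ms, self.tau2_ms, self.k)


def _simulate_direct_batch(bits: np.ndarray, params: SensoryParams):
    """Vectorized single-unit simulation for a batch of direct-drive trials."""
    mode = params.filter_mode
    e = exp_filter(bits**params.n_exp, params.tau_E_ms, params.dt_ms, mode=mode)
    s = exp_filter(e, params.tau_S_ms, params.dt_ms, mode=mode)
    g = e / (s + params.sigma_pow_n)
    lam = params.dt_ms / params.tau_R_ms
    r = lfilter([lam], [1.0, -(1.0 - lam)], g, axis=-1)
    return e, s, r


def _per_lag_correlation(bits: np.ndarray, final_values: np.ndarray) -> np.ndarray:
    """Pearson correlation of each stimulus time point with the final value.

    Returned in lag order: index l is the correlation for input l steps
    before the final time point.
    """
    b = bits - bits.mean(axis=0)
    v = final_values - final_values.mean()
    cov = b.T @ v / bits.shape[0]
    denom = bits.std(axis=0) * final_values.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    return corr[::-1]


def reverse_correlate(
    params: SensoryParams | None = None,
    n_sims: int = 10_000,
    n_steps: int = 600,
    seed: int | None = 0,
    p_on: float = 0.5,
) -> RFEstimate:
    """Estimate temporal receptive fields from random binary drive.

    Runs ``n_sims`` independent trials of ``n_steps`` steps (default
    1,200 ms at 2 ms), correlating the stimulus bit at each time point with
    the excitatory drive, suppressive drive, and response at the final
    time point.  The shuffled null re-pairs stimuli with responses from
    different simulations.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    params = params or SensoryParams()
    bits = random_binary_batch(n_sims, n_steps, seed=seed, p_on=p_on)
    e, s, r = _simulate_direct_batch(bits, params)
    w_e = _per_lag_correlation(bits, e[:, -1])
    w_s = _per_lag_correlation(bits, s[:, -1])
    w_r = _per_lag_correlation(bits, r[:, -1])
    w_shuf = shuffled_null(bits, r[:, -1], seed=None if seed is None else seed + 1)
    lags = np.arange(n_steps) * params.dt_ms
    return RFEstimate(
        lags_ms=lags,
        weights_excitatory=w_e,
        weights_suppressive=w_s,
        weights_response=w_r,
        weights_shuffled=w_shuf,
        n_sims=n_sims,
        seed=seed,
        params=params,
    )


def shuffled_null(
    bits: np.ndarray, final_values: np.ndarray, seed: int | None = None
) -> np.ndarray:
    """Null weights: correlate responses with stimuli from other simulations.

    Stimulus rows are re-paired by a fixed-point-free rotation of a random
    permutation, so no simulation keeps its own stimulus.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(bits.shape[0])
    rotated = np.roll(perm, 1)  # derangement: maps perm[i] -> perm[i-1]
    reorder = np.empty_like(perm)
    reorder[perm] = rotated
    return _per_lag_correlation(bits[reorder], final_values)


def hS_shape(
    tau_E_ms: float, tau_S_ms: float, lags_ms: np.ndarray
) -> np.ndarray:
    """Predicted shape of the suppressive-drive TRF (up to scale).

    The suppressive window acts on the already tau_E-filtered drive, so the
    TRF is the causal convolution of the two exponential windows; for
    tau_E != tau_S that convolution is proportional to
    |exp(-l/tau_E) - exp(-l/tau_S)|.  Zero at lag 0 by construction.
    """
    if tau_E_ms <= 0 or tau_S_ms <= 0:
        raise ValueError("time constants must be > 0")
    if tau_E_ms == tau_S_ms:
        raise ValueError(
            "tau_E == tau_S is degenerate for the closed form; "
            "use the numeric convolution (l * exp(-l/tau))"
        )
    lags = np.asarray(lags_ms, dtype=float)
    return np.abs(np.exp(-lags / tau_E_ms) - np.exp(-lags / tau_S_ms))


def gamma_difference(
    lags_ms: np.ndarray, tau1_ms: float, tau2_ms: float, k: float
) -> np.ndarray:
    """h(l) = l exp(-l/tau1) - k l exp(-l/tau2), l = lag into the past (ms)."""
    lags = np.asarray(lags_ms, dtype=float)
    return lags * np.exp(-lags / tau1_ms) - k * lags * np.exp(-lags / tau2_ms)


def fit_gamma_difference(
    weights: np.ndarray,
    lags_ms: np.ndarray,
    n_restarts: int = 100,
    seed: int | None = 0,
    init_range: tuple[float, float] = (0.0, 900.0),
) -> GammaFit:
    """Least-squares fit of the difference-of-Gammas form, up to scale.

    For each candidate (tau1, tau2, k) the optimal scale is solved in
    closed form; the best of ``n_restarts`` Nelder-Mead runs (tau1, tau2
    initialized uniformly in ``init_range``, k at 0) is returned, with the
    convention tau1 >= tau2.  Nonpositive time constants are rejected with
    a large penalty.
    """
    w = np.asarray(weights, dtype=float)
    lags = np.asarray(lags_ms, dtype=float)
    if w.shape != lags.shape:
        raise ValueError("weights and lags must have the same shape")
    rng = np.random.default_rng(seed)

    def objective(p: np.ndarray) -> float:
        tau1, tau2, k = p
        if tau1 <= 0 or tau2 <= 0:
            return 1e12
        h = gamma_difference(lags, tau1, tau2, k)
        denom = float(h @ h)
        if denom <= 0 or not np.isfinite(denom):
            return float(w @ w)
        a = float(h @ w) / denom
        resid = w - a * h
        return float(resid @ resid)

    best = None
    failures = []
    for _ in range(n_restarts):
        x0 = [rng.uniform(*init_range), rng.uniform(*init_range), 0.0]
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": 3000, "xatol": 1e-6, "fatol": 1e-14},
        )
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {n_restarts} restarts failed: {failures[:3]}")
    tau1, tau2, k = best.x
    if tau2 > tau1:
        # label switch: swap the lobes; the free scale absorbs the sign
        tau1, tau2, k = tau2, tau1, (1.0 / k if k != 0 else np.inf)
    h = gamma_difference(lags, tau1, tau2, k)
    denom = float(h @ h)
    scale = float(h @ w) / denom if denom > 0 else 0.0
    return GammaFit(
        tau1_ms=float(tau1),
        tau2_ms=float(tau2),
        k=float(k),
        scale=scale,
        rss=float(best.fun),
        n_restarts=n_restarts,
    )
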