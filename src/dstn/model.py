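"""Sensory layer of the dynamic spatiotemporal normalization (DSTN) model.

A population of orientation-tuned units receives a time-varying stimulus
drive.  Each unit's excitatory drive is an exponentially weighted sum of its
recent stimulus drive (time constant ``tau_E``); the suppressive drive is an
exponentially weighted sum (``tau_S``) of the *pooled* excitatory drives of
the population.  The response of unit *i* follows the dynamic normalization
equation

    tau_R * dr_i/dt = -r_i + e_i / (s + sigma**n)

integrated with forward Euler on a fixed grid (default 2 ms).  Because the
suppressive drive is a filtered copy of the already-filtered excitatory
drives, suppression always acts later and over longer intervals than
excitation — the property that gives the model its biphasic temporal
receptive fields and its temporal-context effects (adaptation, masking,
contrast-dependent suppression).

Spatial (surround-suppression) variants are expressed by giving stimulus
channels distinct location labels: each location gets its own copy of the
tuning bank, excitatory drives are location-specific, and suppression is
pooled across locations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "TuningBank",
    "SensoryParams",
    "StimulusSequence",
    "SimulationTrace",
    "tuned_drive",
    "exp_filter",
    "exp_filter_weights",
    "pooling_matrix",
    "suppressive_drive",
    "step_response",
    "simulate",
]


@dataclass(frozen=True)
class TuningBank:
    """Evenly spaced orientation tuning curves on [0, pi).

    ``tuning_exponent`` is the raised-cosine exponent m; the default
    m = 2N - 1 = 23 gives curves whose half-width matches the channel
    spacing for N = 12.
    """

    n_units: int = 12
    tuning_exponent: float = 23.0

    @property
    def preferred_orientations(self) -> np.ndarray:
        """Preferred orientations phi_i = pi*(i-1)/N, radians."""
        return np.pi * np.arange(self.n_units) / self.n_units

    def drive(self, orientation: float, contrast: float) -> np.ndarray:
        return tuned_drive(orientation, contrast, self)


def tuned_drive(orientation: float, contrast: float, bank: TuningBank) -> np.ndarray:
    """Stimulus drive d_i = |cos(theta - phi_i)|**m * c for every unit.

    Orientation has period pi (|cos| handles the wrap).  Contrast must lie
    in [0, 1]; a grating at a unit's preferred orientation drives it with
    exactly ``contrast``.
    """
    if not np.isfinite(orientation):
        raise ValueError("orientation must be finite")
    if contrast < 0:
        raise ValueError(f"contrast must be nonnegative, got {contrast}")
    if contrast > 1:
        raise ValueError(f"contrast must be <= 1, got {contrast}")
    phi = bank.preferred_orientations
    return np.abs(np.cos(orientation - phi)) ** bank.tuning_exponent * contrast


@dataclass(frozen=True)
class SensoryParams:
    """Constants of the sensory layer.

    Time constants are in milliseconds.  ``tau_R = 52``, ``n_exp = 1.5`` and
    ``sigma = 0.1`` are the single-layer defaults; the surround-suppression
    preset lowers ``sigma`` to 0.02 so contrast-response functions span the
    units' response range.  ``pooling_exponent`` p tunes the suppressive
    pool: p = inf pools uniformly, p = 0 restricts suppression to each
    unit's own drive.

    ``filter_mode`` selects the discretization of the exponential windows:
    ``"gain"`` (default) uses the gain-normalized recursion so a sustained
    unit input converges to 1 and tau -> 0 recovers the instantaneous
    drive; ``"literal"`` keeps the raw 1/tau-weighted per-step sum.
    """

    tau_E_ms: float = 400.0
    tau_S_ms: float = 100.0
    tau_R_ms: float = 52.0
    sigma: float = 0.1
    n_exp: float = 1.5
    pooling_exponent: float = np.inf
    dt_ms: float = 2.0
    filter_mode: str = "gain"

    def __post_init__(self) -> None:
        if self.tau_E_ms < 0 or self.tau_S_ms < 0 or self.tau_R_ms < 0:
            raise ValueError("time constants must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_exp <= 0:
            raise ValueError("n_exp must be > 0")
        if self.pooling_exponent < 0:
            raise ValueError("pooling_exponent must be >= 0 (inf allowed)")
        if self.filter_mode not in ("gain", "literal"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.dt_ms >= self.tau_R_ms:
            warnings.warn(
                "dt_ms >= tau_R_ms: forward-Euler response update may be unstable",
                RuntimeWarning,
                stacklevel=2,
            )

    def with_(self, **kwargs) -> "SensoryParams":
        return replace(self, **kwargs)

    @property
    def sigma_pow_n(self) -> float:
        return self.sigma**self.n_exp

    def to_dict(self) -> dict:
        return {
            "tau_E_ms": self.tau_E_ms,
            "tau_S_ms": self.tau_S_ms,
            "tau_R_ms": self.tau_R_ms,
            "sigma": self.sigma,
            "n_exp": self.n_exp,
            "pooling_exponent": self.pooling_exponent,
            "dt_ms": self.dt_ms,
            "filter_mode": self.filter_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensoryParams":
        d = dict(d)
        if d.get("pooling_exponent") in ("inf", "Infinity", None):
            d["pooling_exponent"] = np.inf
        return cls(**d)


@dataclass
class StimulusSequence:
    """Stimulus drive matrix X over discrete time.

    Rows are stimulus channels; each channel carries an orientation (and
    optionally a location label) and its row holds the contrast presented
    through that channel at each time step.  ``direct_drive=True`` marks
    sequences whose rows are injected directly as per-unit stimulus drive,
    bypassing orientation tuning (used by the reverse-correlation
    protocol).
    """

    drive_matrix: np.ndarray
    dt_ms: float = 2.0
    orientation_of_channel: np.ndarray | None = None
    location_of_channel: list[str] | None = None
    direct_drive: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.drive_matrix = np.asarray(self.drive_matrix, dtype=float)
        if self.drive_matrix.ndim != 2:
            raise ValueError("drive_matrix must be 2-D (channels x time)")
        if np.isnan(self.drive_matrix).any():
            raise ValueError("stimulus contains NaN entries")
        if (self.drive_matrix < 0).any():
            raise ValueError("stimulus contrasts must be nonnegative")
        if (self.drive_matrix > 1).any():
            raise ValueError("stimulus contrasts must be <= 1")
        n_ch = self.drive_matrix.shape[0]
        if self.orientation_of_channel is None:
            self.orientation_of_channel = np.zeros(n_ch)
        else:
            self.orientation_of_channel = np.asarray(self.orientation_of_channel, dtype=float)
        if len(self.orientation_of_channel) != n_ch:
            raise ValueError("orientation_of_channel length mismatch")
        if self.location_of_channel is None:
            self.location_of_channel = ["center"] * n_ch
        if len(self.location_of_channel) != n_ch:
            raise ValueError("location_of_channel length mismatch")

    @property
    def n_steps(self) -> int:
        return self.drive_matrix.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt_ms

    @property
    def locations(self) -> list[str]:
        seen: list[str] = []
        for loc in self.location_of_channel:
            if loc not in seen:
                seen.append(loc)
        return seen

    def total_energy(self) -> float:
        """Sum of contrast x steps over all channels (event bookkeeping)."""
        return float(self.drive_matrix.sum())


@dataclass
class SimulationTrace:
    """Full record of one sensory-layer simulation."""

    excitatory: np.ndarray  # units x time
    suppressive: np.ndarray  # units x time (rows equal under uniform pooling)
    response: np.ndarray  # units x time
    stimulus: StimulusSequence
    params: SensoryParams
    unit_orientations: np.ndarray = field(default=None)  # type: ignore[assignment]
    unit_locations: list[str] = field(default=None)  # type: ignore[assignment]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.response.shape[1]) * self.params.dt_ms

    def unit_index(self, orientation: float, location: str | None = None) -> int:
        """Index of the unit maximally tuned to ``orientation`` (and location)."""
        d = np.abs(np.angle(np.exp(2j * (self.unit_orientations - orientation)))) / 2
        if location is not None:
            d = np.where(np.asarray(self.unit_locations) == location, d, np.inf)
        return int(np.argmin(d))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: unit, location, time_ms, drives and response."""
        n_units, n_t = self.response.shape
        t = self.time_ms
        return pd.DataFrame(
            {
                "unit": np.repeat(np.arange(n_units), n_t),
                "location": np.repeat(np.asarray(self.unit_locations, dtype=object), n_t),
                "time_ms": np.tile(t, n_units),
                "excitatory": self.excitatory.ravel(),
                "suppressive": self.suppressive.ravel(),
                "response": self.response.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def meta_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "stimulus_name": self.stimulus.name,
                "n_units": int(self.response.shape[0]),
                "n_steps": int(self.response.shape[1]),
            },
            default=float,
        )


# ---------------------------------------------------------------------------
# temporal windows


def _filter_coeffs(tau_ms: float, dt_ms: float, mode: str) -> tuple[float, float]:
    """(b0, a1) of the one-pole recursion y_t = a1*y_{t-1} + b0*x_t."""
    alpha = np.exp(-dt_ms / tau_ms)
    b0 = (1.0 - alpha) if mode == "gain" else 1.0 / tau_ms
    return b0, alpha

def exp_filter(
    signal: np.ndarray,
    tau_ms: float,
    dt_ms: float = 2.0,
    axis: int = -1,
    mode: str = "gain",
) -> np.ndarray:
    """Causal exponentially weighted running sum of ``signal``.

    Implemented as the one-pole recursion y_t = alpha*y_{t-1} + b0*x_t with
    alpha = exp(-dt/tau).  In ``"gain"`` mode b0 = 1 - alpha, so a sustained
    unit input converges to 1 and tau = 0 degenerates continuously to the
    identity; ``"literal"`` mode keeps b0 = 1/tau, the raw per-step sum of
    the 1/tau-weighted exponential window.  tau = 0 returns the input
    unchanged (unit impulse window) in both modes.
    """
    signal = np.asarray(signal, dtype=float)
    if tau_ms < 0:
        raise ValueError("tau_ms must be >= 0")
    if tau_ms == 0:
        return signal.copy()
    b0, alpha = _filter_coeffs(tau_ms, dt_ms, mode)
    return lfilter([b0], [1.0, -alpha], signal, axis=axis)


def exp_filter_weights(
    n_lags: int, tau_ms: float, dt_ms: float = 2.0, mode: str = "gain"
) -> np.ndarray:
    """Explicit window weights w[l] applied to the input l steps in the past.

    The recursion in :func:`exp_filter` is exactly the weighted sum
    y_t = sum_l w[l] * x_{t-l}; these weights feed the brute-force
    direct-summation oracle used in tests.
    """
    if tau_ms < 0:
        raise ValueError("tau_ms must be >= 0")
    lags = np.arange(n_lags)
    if tau_ms == 0:
        w = np.zeros(n_lags)
        w[0] = 1.0
        return w
    b0, alpha = _filter_coeffs(tau_ms, dt_ms, mode)
    return b0 * alpha**lags


# ---------------------------------------------------------------------------
# suppressive pooling


def pooling_matrix(bank: TuningBank, p: float) -> np.ndarray:
    """Suppressive pooling weights S_ij = |cos(phi_i - phi_j)|**(1/p).

    p = inf gives uniform pooling (all ones); p = 0 gives the identity
    (units suppressed only by themselves); intermediate p weights
    similarly tuned units more strongly.
    """
    if p < 0:
        raise ValueError("pooling exponent must be >= 0 (inf allowed)")
    phi = bank.preferred_orientations
    c = np.abs(np.cos(phi[:, None] - phi[None, :]))
    if np.isinf(p):
        return np.ones_like(c)
    if p == 0:
        return np.eye(bank.n_units)
    with np.errstate(divide="ignore"):
        out = c ** (1.0 / p)
    return out


def suppressive_drive(
    excitatory: np.ndarray,
    pool: np.ndarray,
    tau_S_ms: float,
    dt_ms: float = 2.0,
    mode: str = "gain",
) -> np.ndarray:
    """Per-unit suppressive drive: exp-filtered pool-weighted excitatory drives.

    Filtering and the (linear) pool weighting commute; the filter is applied
    to the pooled signal.  Under uniform pooling every row is the same
    shared time series.
    """
    excitatory = np.asarray(excitatory, dtype=float)
    if pool.shape != (excitatory.shape[0], excitatory.shape[0]):
        raise ValueError(
            f"pool matrix shape {pool.shape} does not match unit count {excitatory.shape[0]}"
        )
    return exp_filter(pool @ excitatory, tau_S_ms, dt_ms, axis=-1, mode=mode)


# ---------------------------------------------------------------------------
# response dynamics


def step_response(
    r_prev: np.ndarray, e: np.ndarray, s: np.ndarray | float, params: SensoryParams
) -> np.ndarray:
    """One forward-Euler step of tau_R dr/dt = -r + e/(s + sigma**n)."""
    r_prev = np.asarray(r_prev, dtype=float)
    g = np.asarray(e, dtype=float) / (np.asarray(s, dtype=float) + params.sigma_pow_n)
    return r_prev + (params.dt_ms / params.tau_R_ms) * (-r_prev + g)


def _unit_layout(
    stimulus: StimulusSequence, bank: TuningBank
) -> tuple[np.ndarray, list[str]]:
    locations = stimulus.locations
    phi = bank.preferred_orientations
    orientations = np.tile(phi, len(locations))
    unit_locs = [loc for loc in locations for _ in range(bank.n_units)]
    return orientations, unit_locs


def _stimulus_drive(
    stimulus: StimulusSequence, bank: TuningBank
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Map the channel matrix X to the per-unit stimulus drive d (units x time)."""
    if stimulus.direct_drive:
        d = stimulus.drive_matrix
        n_units = d.shape[0]
        orientations = np.zeros(n_units)
        return d, orientations, ["center"] * n_units
    orientations, unit_locs = _unit_layout(stimulus, bank)
    n_units = len(orientations)
    d = np.zeros((n_units, stimulus.n_steps))
    for ch in range(stimulus.drive_matrix.shape[0]):
        theta = stimulus.orientation_of_channel[ch]
        loc = stimulus.location_of_channel[ch]
        gain = np.abs(np.cos(theta - orientations)) ** bank.tuning_exponent
        gain = gain * (np.asarray(unit_locs, dtype=object) == loc)
        d += gain[:, None] * stimulus.drive_matrix[ch][None, :]
    return d, orientations, unit_locs


def _full_pool(bank: TuningBank, p: float, n_locations: int) -> np.ndarray:
    """Pooling over the whole population: tuned within a location, weight 1 across."""
    within = pooling_matrix(bank, p)
    n = bank.n_units
    total = n * n_locations
    pool = np.ones((total, total))
    for a in range(n_locations):
        pool[a * n : (a + 1) * n, a * n : (a + 1) * n] = within
    return pool


def simulate(
    stimulus: StimulusSequence,
    params: SensoryParams | None = None,
    bank: TuningBank | None = None,
) -> SimulationTrace:
    """Run the sensory layer over a stimulus sequence, strictly causally.

    The chain is: tuned stimulus drive -> excitatory temporal window
    (tau_E) on d**n -> pooled suppressive window (tau_S) -> forward-Euler
    normalization dynamics (tau_R).  Every stage is a causal one-pole
    recursion, so truncating the stimulus after time t cannot change any
    value at or before t.
    """
    params = params or SensoryParams()
    bank = bank or TuningBank()
    if stimulus.dt_ms != params.dt_ms:
        raise ValueError("stimulus dt_ms does not match params dt_ms")
    d, orientations, unit_locs = _stimulus_drive(stimulus, bank)
    mode = params.filter_mode
    e = exp_filter(d**params.n_exp, params.tau_E_ms, params.dt_ms, axis=-1, mode=mode)
    if stimulus.direct_drive:
        pool = np.ones((d.shape[0], d.shape[0]))
    else:
        pool = _full_pool(bank, params.pooling_exponent, len(stimulus.locations))
    s = suppressive_drive(e, pool, params.tau_S_ms, params.dt_ms, mode=mode)
    g = e / (s + params.sigma_pow_n)
    lam = params.dt_ms / params.tau_R_ms
    r = lfilter([lam], [1.0, -(1.0 - lam)], g, axis=-1)
    return SimulationTrace(
        excitatory=e,
        suppressive=s,
        response=r,
        stimulus=stimulus,
        params=params,
        unit_orientations=orientations,
        unit_locations=unit_locs,
    )
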