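"""Decision layer: linear readout, evidence accumulation, and d-prime.

Two decision units (one per target, T1 and T2) each read out the sensory
population through a fixed weight vector — the difference between the
noiseless population templates for the clockwise- and counterclockwise-
tilted stimulus on that target's axis.  Evidence is therefore signed:
positive for CW, negative for CCW.  Each unit accumulates its normalized
drive over the whole trial through the same dynamic normalization equation
as the sensory layer, with a very long time constant (tau_D = 1e5 ms) so
the leak is negligible and the unit integrates.  Sensitivity d' is the
absolute final evidence times a fixed scale factor.

The decision units' drives are instantaneous functions of the sensory
response (no excitatory/suppressive temporal windows within this layer);
their suppressive drive is the summed magnitude of both units' drives,
pooled across the two units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .model import SensoryParams, SimulationTrace, TuningBank, tuned_drive

__all__ = [
    "DecisionParams",
    "EvidenceTrace",
    "readout_weights",
    "accumulate",
    "evidence_to_dprime",
]

_AXIS_ANGLE = {"vertical": np.pi / 2, "horizontal": 0.0}


@dataclass(frozen=True)
class DecisionParams:
    """Decision-layer constants.

    ``scale_T1``/``scale_T2`` convert accumulated evidence to d'; the
    default 1e5 matches the generic presets, 1e4 the contrast-interaction
    preset.  ``tilt_deg`` is the CW/CCW tilt magnitude away from the
    stimulus axis used to build the readout templates.
    """

    tau_D_ms: float = 1e5
    sigma_D: float = 0.7
    scale_T1: float = 1e5
    scale_T2: float = 1e5
    tilt_deg: float = 10.0


@dataclass
class EvidenceTrace:
    """Accumulated evidence per decision unit plus the derived d'."""

    evidence: dict[str, np.ndarray]  # target -> time series
    final_evidence: dict[str, float]
    dprime: dict[str, float]
    dt_ms: float


def readout_weights(
    bank: TuningBank, axis: str, tilt_deg: float
) -> np.ndarray:
    """CW-minus-CCW template difference for one stimulus axis.

    Templates are the noiseless tuned-drive population vectors at unit
    contrast for the two tilted orientations.  A population response that
    matches the CW template projects positively; swapping CW and CCW flips
    the sign.
    """
    if axis not in _AXIS_ANGLE:
        raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")
    if tilt_deg == 0:
        raise ValueError("tilt_deg = 0 produces a degenerate (all-zero) readout")
    base = _AXIS_ANGLE[axis]
    tilt = np.deg2rad(tilt_deg)
    cw = tuned_drive(base + tilt, 1.0, bank)
    ccw = tuned_drive(base - tilt, 1.0, bank)
    return cw - ccw


def accumulate(
    trace: SimulationTrace,
    weights: dict[str, np.ndarray],
    params: DecisionParams | None = None,
    sensory_params: SensoryParams | None = None,
) -> EvidenceTrace:
    """Accumulate readout evidence for each target over the whole trial.

    ``weights`` maps target names (e.g. "T1", "T2") to readout vectors over
    the sensory units.  Per step, each decision unit's excitatory drive is
    w . r_t; the shared suppressive drive is sum_j |w_j . r_t|; the update
    is the forward-Euler normalization equation with tau_D and sigma_D**n.
    """
    params = params or DecisionParams()
    sensory_params = sensory_params or trace.params
    n_units = trace.response.shape[0]
    for name, w in weights.items():
        if np.shape(w) != (n_units,):
            raise ValueError(f"readout weights for {name!r} do not match unit count")
    drives = {name: np.asarray(w) @ trace.response for name, w in weights.items()}
    s_pool = np.sum([np.abs(d) for d in drives.values()], axis=0)
    denom = s_pool + params.sigma_D**sensory_params.n_exp
    dt = sensory_params.dt_ms
    lam = dt / params.tau_D_ms
    evidence = {
        name: lfilter([lam], [1.0, -(1.0 - lam)], d / denom)
        for name, d in drives.items()
    }
    final = {name: float(ev[-1]) for name, ev in evidence.items()}
    scales = {"T1": params.scale_T1, "T2": params.scale_T2}
    dprime = {
        name: evidence_to_dprime(final[name], scales.get(name, params.scale_T1))
        for name in evidence
    }
    return EvidenceTrace(evidence=evidence, final_evidence=final, dprime=dprime, dt_ms=dt)


def evidence_to_dprime(final_evidence: float, scale: float) -> float:
    """d' = scale * |final evidence| (sign encodes the choice, not sensitivity)."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return scale * abs(final_evidence)
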