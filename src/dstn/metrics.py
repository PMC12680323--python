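"""Scalar summary statistics over simulated response time courses.

Temporal sums run over the full trial (prestimulus zeros contribute
nothing).  Threshold-crossing metrics return ``None`` rather than
extrapolating when the threshold is never reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricRecord",
    "UndefinedMetricError",
    "time_to_peak",
    "time_to_half_max",
    "stable_activity_level",
    "auc",
    "subadditivity_ratio",
    "adaptation_index",
    "adaptation_index_nonidentical",
    "masking_index",
    "suppression_index",
    "joint_suppression",
    "records_to_frame",
]


class UndefinedMetricError(ValueError):
    """Raised when a ratio metric's denominator vanishes."""


@dataclass
class MetricRecord:
    """A named scalar with the protocol/parameters that produced it."""

    metric_name: str
    value: float | None
    protocol: str = ""
    params: dict = field(default_factory=dict)
    unit: int | None = None


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Tidy table: one row per metric x parameter combination."""
    rows = []
    for rec in records:
        row = {
            "metric": rec.metric_name,
            "value": np.nan if rec.value is None else rec.value,
            "protocol": rec.protocol,
            "unit": np.nan if rec.unit is None else rec.unit,
        }
        row.update(rec.params)
        rows.append(row)
    return pd.DataFrame(rows)


def time_to_peak(
    response: np.ndarray,
    dt_ms: float,
    onset_ms: float,
    offset_ms: float | None = None,
    frac: float = 0.99,
) -> float:
    """First time (ms from onset) the response reaches ``frac`` of its
    within-stimulus maximum.

    The 99% criterion is used because responses approach but need not hit
    the numerical maximum until late in the window.
    """
    i0 = int(round(onset_ms / dt_ms))
    i1 = int(round(offset_ms / dt_ms)) if offset_ms is not None else len(response)
    window = np.asarray(response[i0:i1], dtype=float)
    peak = window.max()
    if peak <= 0:
        return float("nan")
    idx = int(np.argmax(window >= frac * peak))
    return idx * dt_ms


def time_to_half_max(
    response: np.ndarray, dt_ms: float, offset_ms: float
) -> float | None:
    """First post-offset time (ms from offset) at or below 50% of the peak.

    Returns None when the response never falls below half maximum within
    the trial.
    """
    response = np.asarray(response, dtype=float)
    peak = response.max()
    i_off = int(round(offset_ms / dt_ms))
    post = response[i_off:]
    below = post <= 0.5 * peak
    if not below.any():
        return None
    return int(np.argmax(below)) * dt_ms


def stable_activity_level(
    response: np.ndarray, dt_ms: float, onset_ms: float, at_ms: float = 2000.0
) -> float:
    """Response ``at_ms`` after stimulus onset, as a fraction of the peak."""
    response = np.asarray(response, dtype=float)
    peak = response.max()
    if peak <= 0:
        return float("nan")
    idx = min(int(round((onset_ms + at_ms) / dt_ms)), len(response) - 1)
    return float(response[idx] / peak)


def auc(response: np.ndarray, dt_ms: float) -> float:
    """Total response: step sum times dt (area under the curve)."""
    return float(np.asarray(response, dtype=float).sum() * dt_ms)


def subadditivity_ratio(auc_2x: float, auc_x: float) -> float:
    """Response at duration 2x over response at duration x; 2 = additive."""
    if auc_x == 0:
        raise UndefinedMetricError("reference response is zero")
    return auc_2x / auc_x


def adaptation_index(
    r_t2_present: np.ndarray, r_t2_absent: np.ndarray
) -> float:
    """AI = 1 - sum(r_present - r_absent) / sum(r_absent)  (identical stimuli).

    The isolated T2 response is the difference between the two-stimulus and
    the T1-only trials; AI = 0 means it equals the single-stimulus
    response, AI = 1 means total suppression.
    """
    r_p = np.asarray(r_t2_present, dtype=float)
    r_a = np.asarray(r_t2_absent, dtype=float)
    denom = r_a.sum()
    if denom == 0:
        raise UndefinedMetricError("T2-absent response sums to zero")
    return 1.0 - (r_p - r_a).sum() / denom


def adaptation_index_nonidentical(
    r_both: np.ndarray, r_adapt: np.ndarray, r_test: np.ndarray
) -> float:
    """AI = 1 - sum(r_both - r_adapt) / sum(r_test)  (non-identical stimuli).

    Three simulations: test alone, adapter alone, both; the isolated test
    response is r_both - r_adapt.
    """
    denom = np.asarray(r_test, dtype=float).sum()
    if denom == 0:
        raise UndefinedMetricError("test-alone response sums to zero")
    return 1.0 - (np.asarray(r_both) - np.asarray(r_adapt)).sum() / denom


def masking_index(
    r_t1_with_t2: np.ndarray, r_t1_without_t2: np.ndarray
) -> float:
    """MI = 1 - sum(r with mask) / sum(r without mask), for the T1 unit."""
    denom = np.asarray(r_t1_without_t2, dtype=float).sum()
    if denom == 0:
        raise UndefinedMetricError("mask-absent response sums to zero")
    return 1.0 - np.asarray(r_t1_with_t2).sum() / denom


def suppression_index(dprime_nt_low: float, dprime_nt_high: float) -> float:
    """SI = (d'_NTlow - d'_NThigh) / (d'_NTlow + d'_NThigh).

    Positive SI: a higher-contrast non-target lowers the target's d'.
    """
    total = dprime_nt_low + dprime_nt_high
    if total == 0:
        raise UndefinedMetricError("both d' values are zero")
    return (dprime_nt_low - dprime_nt_high) / total


def joint_suppression(si_t1: float, si_t2: float) -> float:
    """Product of the two targets' suppression indices."""
    return si_t1 * si_t2
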