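"""Experiment presets: the simulation campaigns behind each phenomenon.

Each preset composes protocol builders, the sensory layer, the decision
layer and the metric functions into a tidy results table.  Presets are
deterministic given their configuration (the reverse-correlation preset
additionally takes a seed), so re-running a configuration reproduces the
table byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as mt
from .decision import DecisionParams, accumulate, readout_weights
from .model import SensoryParams, TuningBank, simulate
from .protocols import (
    DEFAULT_CONTRAST,
    center_contrast_grid,
    center_surround,
    contrast_pair_trial,
    pulse_pair,
    single_pulse,
)
from .rf import fit_gamma_difference, reverse_correlate

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "sweep_joint_suppression",
    "contrast_pair_dprimes",
    "suppression_indices",
    "elimination_soa",
    "export",
    "EXPERIMENTS",
]

#: tau sweep used by the single-time-constant analyses (ms)
TAU_SWEEP = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0)
#: short/long combination grid used by the interaction analyses (ms)
TAU_COMBO_E = (100.0, 500.0)
TAU_COMBO_S = (50.0, 500.0)


@dataclass
class ExperimentConfig:
    """Configuration for one preset run."""

    experiment: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"experiment": self.experiment, "seed": self.seed, "overrides": self.overrides}

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


# ---------------------------------------------------------------------------
# building blocks


def _response_of_preferred(stim, params, orientation=0.0, location=None):
    trace = simulate(stim, params)
    idx = trace.unit_index(orientation, location)
    return trace.response[idx], trace


def contrast_pair_dprimes(
    soa_ms: float,
    t1_contrast: float,
    t2_contrast: float,
    params: SensoryParams,
    decision: DecisionParams,
    bank: TuningBank | None = None,
) -> tuple[float, float]:
    """(d'_T1, d'_T2) for one two-target contrast-pair trial."""
    bank = bank or TuningBank()
    stim = contrast_pair_trial(
        t1_contrast=t1_contrast,
        t2_contrast=t2_contrast,
        soa_ms=soa_ms,
        tilt_deg=decision.tilt_deg,
        dt_ms=params.dt_ms,
    )
    trace = simulate(stim, params, bank)
    weights = {
        "T1": readout_weights(bank, "vertical", decision.tilt_deg),
        "T2": readout_weights(bank, "horizontal", decision.tilt_deg),
    }
    ev = accumulate(trace, weights, decision, params)
    return ev.dprime["T1"], ev.dprime["T2"]


def suppression_indices(
    soa_ms: float,
    params: SensoryParams,
    decision: DecisionParams | None = None,
    high: float = DEFAULT_CONTRAST,
    low: float = 0.16,
) -> tuple[float, float]:
    """(SI_T1, SI_T2): each target at high contrast, non-target low vs high."""
    decision = decision or DecisionParams(scale_T1=1e4, scale_T2=1e4)
    d1_low, _ = contrast_pair_dprimes(soa_ms, high, low, params, decision)
    d1_high, d2_high = contrast_pair_dprimes(soa_ms, high, high, params, decision)
    _, d2_low = contrast_pair_dprimes(soa_ms, low, high, params, decision)
    return (
        mt.suppression_index(d1_low, d1_high),
        mt.suppression_index(d2_low, d2_high),
    )


def elimination_soa(
    params: SensoryParams,
    decision: DecisionParams | None = None,
    soa_start_ms: float = 250.0,
    soa_stop_ms: float = 2050.0,
    soa_step_ms: float = 100.0,
    threshold: float = 0.01,
) -> tuple[float | None, pd.DataFrame]:
    """First SOA at which both targets' |SI| fall below ``threshold``.

    Sweeps SOA upward in fixed steps; returns (SOA or None, full SI table).
    """
    rows = []
    found = None
    for soa in np.arange(soa_start_ms, soa_stop_ms + 1e-9, soa_step_ms):
        si1, si2 = suppression_indices(float(soa), params, decision)
        rows.append({"soa_ms": float(soa), "SI_T1": si1, "SI_T2": si2})
        if found is None and abs(si1) < threshold and abs(si2) < threshold:
            found = float(soa)
            break
    return found, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets


def _preset_rf_map(seed: int, o: dict) -> pd.DataFrame:
    params = SensoryParams(
        tau_E_ms=o.get("tau_E_ms", 400.0), tau_S_ms=o.get("tau_S_ms", 100.0)
    )
    est = reverse_correlate(
        params,
        n_sims=o.get("n_sims", 10_000),
        n_steps=o.get("n_steps", 600),
        seed=seed,
        p_on=o.get("p_on", 0.5),
    )
    fit = fit_gamma_difference(
        est.weights_response,
        est.lags_ms,
        n_restarts=o.get("n_restarts", 100),
        seed=seed + 1,
    )
    recs = [
        mt.MetricRecord("gamma_tau1_ms", fit.tau1_ms, "rf_map", params.to_dict()),
        mt.MetricRecord("gamma_tau2_ms", fit.tau2_ms, "rf_map", params.to_dict()),
        mt.MetricRecord("gamma_k", fit.k, "rf_map", params.to_dict()),
        mt.MetricRecord("gamma_rss", fit.rss, "rf_map", params.to_dict()),
    ]
    return mt.records_to_frame(recs)


def _preset_surround(seed: int, o: dict) -> pd.DataFrame:
    params = SensoryParams(tau_E_ms=400.0, tau_S_ms=100.0, sigma=o.get("sigma", 0.02))
    centers = center_contrast_grid(o.get("n_center_levels", 20))
    surrounds = o.get("surround_contrasts", (0.0, 0.12, 0.25, 0.5, 1.0))
    recs = []
    for cs in surrounds:
        for cc in centers:
            stim = center_surround(float(cc), float(cs), dt_ms=params.dt_ms)
            resp, _ = _response_of_preferred(stim, params, location="center")
            recs.append(
                mt.MetricRecord(
                    "center_response_auc",
                    mt.auc(resp, params.dt_ms),
                    "center_surround",
                    {"center_contrast": float(cc), "surround_contrast": float(cs)},
                )
            )
    return mt.records_to_frame(recs)


def _preset_transient_sustained(seed: int, o: dict) -> pd.DataFrame:
    taus = o.get("tau_sweep", TAU_SWEEP[1:])  # nonzero sweep values
    dur, trial, prestim = 2000.0, 8100.0, 500.0
    recs = []
    for tau_e in taus:
        params = SensoryParams(tau_E_ms=tau_e, tau_S_ms=0.0)
        stim = single_pulse(dur, trial_duration_ms=trial, prestimulus_ms=prestim)
        resp, _ = _response_of_preferred(stim, params)
        common = {"tau_E_ms": tau_e, "tau_S_ms": 0.0}
        recs.append(
            mt.MetricRecord(
                "time_to_peak_ms",
                mt.time_to_peak(resp, params.dt_ms, prestim, prestim + dur),
                "single_pulse_2000ms",
                common,
            )
        )
        recs.append(
            mt.MetricRecord(
                "time_to_half_max_ms",
                mt.time_to_half_max(resp, params.dt_ms, prestim + dur),
                "single_pulse_2000ms",
                common,
            )
        )
        recs.append(
            mt.MetricRecord(
                "stable_level",
                resp[int((prestim + dur) / params.dt_ms) - 1],
                "single_pulse_2000ms",
                common,
            )
        )
    for tau_s in taus:
        params = SensoryParams(tau_E_ms=0.0, tau_S_ms=tau_s)
        stim = single_pulse(dur, trial_duration_ms=trial, prestimulus_ms=prestim)
        resp, _ = _response_of_preferred(stim, params)
        common = {"tau_E_ms": 0.0, "tau_S_ms": tau_s}
        recs.append(
            mt.MetricRecord(
                "time_to_peak_ms",
                mt.time_to_peak(resp, params.dt_ms, prestim, prestim + dur, frac=1.0),
                "single_pulse_2000ms",
                common,
            )
        )
        recs.append(
            mt.MetricRecord(
                "stable_activity_level",
                mt.stable_activity_level(resp, params.dt_ms, prestim),
                "single_pulse_2000ms",
                common,
            )
        )
    return mt.records_to_frame(recs)


def _preset_subadditivity(seed: int, o: dict) -> pd.DataFrame:
    durations = o.get("durations_ms", (30.0, 60.0, 120.0, 240.0, 480.0))
    grid_e = o.get("tau_E_grid", TAU_COMBO_E)
    grid_s = o.get("tau_S_grid", TAU_COMBO_S)
    recs = []
    for tau_e in grid_e:
        for tau_s in grid_s:
            params = SensoryParams(tau_E_ms=tau_e, tau_S_ms=tau_s)
            aucs = []
            for dur in durations:
                stim = single_pulse(dur, trial_duration_ms=o.get("trial_ms", 6000.0))
                resp, _ = _response_of_preferred(stim, params)
                a = mt.auc(resp, params.dt_ms)
                aucs.append(a)
                recs.append(
                    mt.MetricRecord(
                        "response_auc",
                        a,
                        "single_pulse",
                        {"tau_E_ms": tau_e, "tau_S_ms": tau_s, "duration_ms": dur},
                    )
                )
            for i in range(1, len(durations)):
                recs.append(
                    mt.MetricRecord(
                        "doubling_ratio",
                        mt.subadditivity_ratio(aucs[i], aucs[i - 1]),
                        "single_pulse",
                        {
                            "tau_E_ms": tau_e,
                            "tau_S_ms": tau_s,
                            "duration_ms": durations[i],
                        },
                    )
                )
    return mt.records_to_frame(recs)


def _adaptation_ai(params: SensoryParams, isi_ms: float, dur: float = 300.0) -> float:
    both = pulse_pair(isi_ms, "ISI", (dur, dur), dt_ms=params.dt_ms)
    alone = pulse_pair(isi_ms, "ISI", (dur, dur), dt_ms=params.dt_ms, drop_second=True)
    r_both, tr = _response_of_preferred(both, params)
    r_alone, _ = _response_of_preferred(alone, params)
    return mt.adaptation_index(r_both, r_alone)


def _preset_adaptation(seed: int, o: dict) -> pd.DataFrame:
    isis = o.get("isi_ms", tuple(range(100, 1600, 100)))
    taus = o.get("tau_sweep", TAU_SWEEP)
    recs = []
    for tau_e in taus:
        for isi in isis:
            ai = _adaptation_ai(SensoryParams(tau_E_ms=tau_e, tau_S_ms=0.0), isi)
            recs.append(
                mt.MetricRecord(
                    "adaptation_index", ai, "pulse_pair_isi",
                    {"tau_E_ms": tau_e, "tau_S_ms": 0.0, "isi_ms": isi},
                )
            )
    for tau_s in taus:
        for isi in isis:
            ai = _adaptation_ai(SensoryParams(tau_E_ms=0.0, tau_S_ms=tau_s), isi)
            recs.append(
                mt.MetricRecord(
                    "adaptation_index", ai, "pulse_pair_isi",
                    {"tau_E_ms": 0.0, "tau_S_ms": tau_s, "isi_ms": isi},
                )
            )
    for tau_e in o.get("tau_E_grid", TAU_COMBO_E):
        for tau_s in o.get("tau_S_grid", TAU_COMBO_S):
            for isi in isis:
                ai = _adaptation_ai(SensoryParams(tau_E_ms=tau_e, tau_S_ms=tau_s), isi)
                recs.append(
                    mt.MetricRecord(
                        "adaptation_index", ai, "pulse_pair_isi",
                        {"tau_E_ms": tau_e, "tau_S_ms": tau_s, "isi_ms": isi},
                    )
                )
    return mt.records_to_frame(recs)


def _preset_adaptation_nonidentical(seed: int, o: dict) -> pd.DataFrame:
    pooling = o.get("pooling_exponents", (np.inf, 1.0, 0.4, 0.2, 0.1, 0.04, 0.0))
    dthetas = o.get("dtheta_deg", tuple(range(0, 100, 10)))
    isi, dur = o.get("isi_ms", 100.0), 300.0
    recs = []
    for p in pooling:
        params = SensoryParams(tau_E_ms=400.0, tau_S_ms=100.0, pooling_exponent=p)
        for dth in dthetas:
            th = np.deg2rad(dth)
            both = pulse_pair(isi, "ISI", (dur, dur), orientations=(th, 0.0))
            adapt = pulse_pair(isi, "ISI", (dur, dur), orientations=(th, 0.0), drop_second=True)
            test = pulse_pair(isi, "ISI", (dur, dur), orientations=(th, 0.0), drop_first=True)
            r_b, _ = _response_of_preferred(both, params, orientation=0.0)
            r_a, _ = _response_of_preferred(adapt, params, orientation=0.0)
            r_t, _ = _response_of_preferred(test, params, orientation=0.0)
            ai = mt.adaptation_index_nonidentical(r_b, r_a, r_t)
            recs.append(
                mt.MetricRecord(
                    "adaptation_index_nonidentical", ai, "pulse_pair_isi",
                    {"pooling_exponent": p, "dtheta_deg": dth, "isi_ms": isi},
                )
            )
    return mt.records_to_frame(recs)


def _masking_mi(params: SensoryParams, soa_ms: float, dur: float = 30.0) -> float:
    kw = dict(
        mode="SOA",
        durations=(dur, dur),
        orientations=(0.0, np.pi / 2),
        dt_ms=params.dt_ms,
    )
    both = pulse_pair(soa_ms, **kw)
    alone = pulse_pair(soa_ms, drop_second=True, **kw)
    r_both, _ = _response_of_preferred(both, params, orientation=0.0)
    r_alone, _ = _response_of_preferred(alone, params, orientation=0.0)
    return mt.masking_index(r_both, r_alone)


def _preset_masking(seed: int, o: dict) -> pd.DataFrame:
    soas = o.get("soa_ms", tuple(range(100, 1100, 100)))
    taus = o.get("tau_sweep", TAU_SWEEP)
    recs = []
    for tau_e in taus:
        for soa in soas:
            mi = _masking_mi(SensoryParams(tau_E_ms=tau_e, tau_S_ms=0.0), soa)
            recs.append(
                mt.MetricRecord(
                    "masking_index", mi, "pulse_pair_soa",
                    {"tau_E_ms": tau_e, "tau_S_ms": 0.0, "soa_ms": soa},
                )
            )
    for tau_s in taus:
        for soa in soas:
            mi = _masking_mi(SensoryParams(tau_E_ms=0.0, tau_S_ms=tau_s), soa)
            recs.append(
                mt.MetricRecord(
                    "masking_index", mi, "pulse_pair_soa",
                    {"tau_E_ms": 0.0, "tau_S_ms": tau_s, "soa_ms": soa},
                )
            )
    return mt.records_to_frame(recs)


def _preset_contrast_interaction(seed: int, o: dict) -> pd.DataFrame:
    soas = o.get("soa_ms", tuple(range(250, 1550, 100)))
    params = SensoryParams(
        tau_E_ms=o.get("tau_E_ms", 400.0), tau_S_ms=o.get("tau_S_ms", 100.0)
    )
    decision = DecisionParams(scale_T1=1e4, scale_T2=1e4, tilt_deg=o.get("tilt_deg", 10.0))
    recs = []
    for soa in soas:
        si1, si2 = suppression_indices(float(soa), params, decision)
        base = {"tau_E_ms": params.tau_E_ms, "tau_S_ms": params.tau_S_ms, "soa_ms": soa}
        recs.append(mt.MetricRecord("SI_T1", si1, "contrast_pair", base))
        recs.append(mt.MetricRecord("SI_T2", si2, "contrast_pair", base))
        recs.append(
            mt.MetricRecord("SI_joint", mt.joint_suppression(si1, si2), "contrast_pair", base)
        )
    return mt.records_to_frame(recs)


EXPERIMENTS = {
    "rf_map": _preset_rf_map,
    "surround": _preset_surround,
    "transient_sustained": _preset_transient_sustained,
    "subadditivity": _preset_subadditivity,
    "adaptation": _preset_adaptation,
    "adaptation_nonidentical": _preset_adaptation_nonidentical,
    "masking": _preset_masking,
    "contrast_interaction": _preset_contrast_interaction,
}


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run one preset and return its tidy metric table."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; "
            f"choose from {sorted(EXPERIMENTS)}"
        )
    return EXPERIMENTS[config.experiment](config.seed, dict(config.overrides))


def sweep_joint_suppression(
    tau_grid_ms: tuple[float, ...] | None = None,
    soa_ms: float = 250.0,
    decision: DecisionParams | None = None,
) -> pd.DataFrame:
    """SI_T1, SI_T2 and their product over a (tau_E, tau_S) grid.

    The default grid spans 0-1,000 ms in 50 ms steps; pass a coarser grid
    for quick looks.
    """
    if tau_grid_ms is None:
        tau_grid_ms = tuple(np.arange(0.0, 1050.0, 50.0))
    rows = []
    for tau_e in tau_grid_ms:
        for tau_s in tau_grid_ms:
            params = SensoryParams(tau_E_ms=tau_e, tau_S_ms=tau_s)
            si1, si2 = suppression_indices(soa_ms, params, decision)
            rows.append(
                {
                    "tau_E_ms": tau_e,
                    "tau_S_ms": tau_s,
                    "SI_T1": si1,
                    "SI_T2": si2,
                    "SI_joint": mt.joint_suppression(si1, si2),
                }
            )
    return pd.DataFrame(rows)


def export(
    results: pd.DataFrame,
    out_dir,
    config: ExperimentConfig | None = None,
    name: str = "metrics",
) -> dict[str, Path]:
    """Write the results table (CSV) and a run-metadata echo (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{name}.csv"
    results.to_csv(csv_path, index=False)
    meta = {
        "config": config.to_dict() if config else None,
        "n_rows": int(len(results)),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    json_path = out / f"{name}.json"
    json_path.write_text(json.dumps(meta, indent=2, default=float))
    return {"csv": csv_path, "json": json_path}
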