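"""Stimulus protocol builders.

Every simulation in the package is driven by one of these deterministic,
seedable builders.  Events are placed on the integration grid with
half-open intervals: an event with onset ``t0`` and duration ``d`` fills
steps [t0, t0 + d).  The standard pulse is 30 ms at 64% contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .model import StimulusSequence

__all__ = [
    "Event",
    "ProtocolSpec",
    "single_pulse",
    "pulse_pair",
    "center_surround",
    "random_binary",
    "random_binary_batch",
    "contrast_pair_trial",
    "DEFAULT_CONTRAST",
    "DEFAULT_PULSE_MS",
]

DEFAULT_CONTRAST = 0.64
DEFAULT_PULSE_MS = 30.0
#: default padding after the last offset so traces decay back to baseline
DEFAULT_TAIL_MS = 3000.0
DEFAULT_PRESTIM_MS = 500.0


@dataclass(frozen=True)
class Event:
    onset_ms: float
    duration_ms: float
    orientation: float  # radians
    contrast: float
    location: str = "center"

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class ProtocolSpec:
    """Declarative description of a trial: named list of timed events."""

    name: str
    trial_duration_ms: float
    events: list[Event] = field(default_factory=list)
    prestimulus_ms: float = DEFAULT_PRESTIM_MS
    dt_ms: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda ev: ev.onset_ms)
        for ev in self.events:
            if ev.offset_ms > self.trial_duration_ms + 1e-9:
                raise ValueError(f"event {ev} extends past the trial end")
            if ev.onset_ms < 0:
                raise ValueError(f"event {ev} has negative onset")

    def build(self) -> StimulusSequence:
        """Render the events into a channel x time drive matrix.

        One channel per distinct (orientation, location) pair.
        """
        keys: list[tuple[float, str]] = []
        for ev in self.events:
            key = (ev.orientation, ev.location)
            if key not in keys:
                keys.append(key)
        if not keys:
            keys = [(0.0, "center")]
        n_steps = int(round(self.trial_duration_ms / self.dt_ms))
        X = np.zeros((len(keys), n_steps))
        for ev in self.events:
            ch = keys.index((ev.orientation, ev.location))
            i0 = int(round(ev.onset_ms / self.dt_ms))
            i1 = int(round(ev.offset_ms / self.dt_ms))
            X[ch, i0:i1] += ev.contrast
        return StimulusSequence(
            drive_matrix=X,
            dt_ms=self.dt_ms,
            orientation_of_channel=np.array([k[0] for k in keys]),
            location_of_channel=[k[1] for k in keys],
            name=self.name,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "trial_duration_ms": self.trial_duration_ms,
            "prestimulus_ms": self.prestimulus_ms,
            "dt_ms": self.dt_ms,
            "seed": self.seed,
            "events": [
                {
                    "onset_ms": ev.onset_ms,
                    "duration_ms": ev.duration_ms,
                    "orientation": ev.orientation,
                    "contrast": ev.contrast,
                    "location": ev.location,
                }
                for ev in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        d["events"] = [Event(**ev) for ev in d.get("events", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ProtocolSpec":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# builders


def single_pulse(
    duration_ms: float = DEFAULT_PULSE_MS,
    contrast: float = DEFAULT_CONTRAST,
    orientation: float = 0.0,
    trial_duration_ms: float | None = None,
    prestimulus_ms: float = DEFAULT_PRESTIM_MS,
    dt_ms: float = 2.0,
) -> StimulusSequence:
    """One pulse after a prestimulus period; zeros elsewhere."""
    if trial_duration_ms is None:
        trial_duration_ms = prestimulus_ms + duration_ms + DEFAULT_TAIL_MS
    if duration_ms > trial_duration_ms - prestimulus_ms:
        raise ValueError("pulse does not fit inside the trial")
    spec = ProtocolSpec(
        name="single_pulse",
        trial_duration_ms=trial_duration_ms,
        prestimulus_ms=prestimulus_ms,
        dt_ms=dt_ms,
        events=[Event(prestimulus_ms, duration_ms, orientation, contrast)],
    )
    return spec.build()


def pulse_pair(
    gap_ms: float,
    mode: str = "ISI",
    durations: tuple[float, float] = (300.0, 300.0),
    contrasts: tuple[float, float] = (DEFAULT_CONTRAST, DEFAULT_CONTRAST),
    orientations: tuple[float, float] = (0.0, 0.0),
    prestimulus_ms: float = DEFAULT_PRESTIM_MS,
    tail_ms: float = DEFAULT_TAIL_MS,
    dt_ms: float = 2.0,
    drop_first: bool = False,
    drop_second: bool = False,
) -> StimulusSequence:
    """Two pulses separated by an exact ISI (offset-to-onset) or SOA (onset-to-onset).

    ``drop_first``/``drop_second`` omit one pulse while keeping the identical
    trial timing — the single-stimulus control conditions of the adaptation
    and masking analyses.
    """
    if mode not in ("ISI", "SOA"):
        raise ValueError("mode must be 'ISI' or 'SOA'")
    on1 = prestimulus_ms
    if mode == "ISI":
        on2 = on1 + durations[0] + gap_ms
    else:
        on2 = on1 + gap_ms
    if on2 < on1 + durations[0]:
        raise ValueError("pulses overlap in time")
    trial = on2 + durations[1] + tail_ms
    events = []
    if not drop_first:
        events.append(Event(on1, durations[0], orientations[0], contrasts[0]))
    if not drop_second:
        events.append(Event(on2, durations[1], orientations[1], contrasts[1]))
    spec = ProtocolSpec(
        name=f"pulse_pair_{mode.lower()}{gap_ms:g}",
        trial_duration_ms=trial,
        prestimulus_ms=prestimulus_ms,
        dt_ms=dt_ms,
        events=events,
    )
    return spec.build()


def center_surround(
    center_contrast: float,
    surround_contrast: float,
    duration_ms: float = 100.0,
    orientation: float = 0.0,
    prestimulus_ms: float = DEFAULT_PRESTIM_MS,
    tail_ms: float = DEFAULT_TAIL_MS,
    dt_ms: float = 2.0,
) -> StimulusSequence:
    """Simultaneous pulses at the center and surround locations."""
    events = [Event(prestimulus_ms, duration_ms, orientation, center_contrast, "center")]
    if surround_contrast > 0:
        events.append(
            Event(prestimulus_ms, duration_ms, orientation, surround_contrast, "surround")
        )
    else:
        # keep the surround channel present (all-zero) so the population
        # layout is identical across surround-contrast conditions
        events.append(Event(prestimulus_ms, 0.0, orientation, 0.0, "surround"))
    spec = ProtocolSpec(
        name="center_surround",
        trial_duration_ms=prestimulus_ms + duration_ms + tail_ms,
        prestimulus_ms=prestimulus_ms,
        dt_ms=dt_ms,
        events=events,
    )
    return spec.build()


def center_contrast_grid(n_levels: int = 20) -> np.ndarray:
    """The log-spaced center-contrast grid spanning [0.05, 1.0]."""
    return np.geomspace(0.05, 1.0, n_levels)


def random_binary(
    n_steps: int = 600,
    seed: int | None = 0,
    p_on: float = 0.5,
    dt_ms: float = 2.0,
) -> StimulusSequence:
    """Random binary direct-drive sequence (reverse-correlation stimulus).

    Each step is Bernoulli(p_on) in {0, 1}; the single channel is injected
    directly as stimulus drive, bypassing orientation tuning.
    """
    bits = random_binary_batch(1, n_steps, seed=seed, p_on=p_on)
    return StimulusSequence(
        drive_matrix=bits,
        dt_ms=dt_ms,
        direct_drive=True,
        name=f"random_binary_seed{seed}",
    )


def random_binary_batch(
    n_sims: int, n_steps: int, seed: int | None = 0, p_on: float = 0.5
) -> np.ndarray:
    """n_sims x n_steps array of Bernoulli(p_on) bits, reproducible under seed."""
    if not 0 <= p_on <= 1:
        raise ValueError("p_on must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((n_sims, n_steps)) < p_on).astype(float)


def contrast_pair_trial(
    t1_contrast: float = DEFAULT_CONTRAST,
    t2_contrast: float = 0.16,
    soa_ms: float = 250.0,
    tilts: tuple[str, str] = ("CW", "CW"),
    tilt_deg: float = 10.0,
    duration_ms: float = DEFAULT_PULSE_MS,
    prestimulus_ms: float = DEFAULT_PRESTIM_MS,
    tail_ms: float = DEFAULT_TAIL_MS,
    dt_ms: float = 2.0,
) -> StimulusSequence:
    """Two-target discrimination trial: T1 on the vertical axis, T2 horizontal.

    Each target is tilted CW or CCW from its axis by ``tilt_deg``; the pair
    is separated by ``soa_ms`` onset-to-onset.  A contrast of 0 omits that
    target (single-target control).
    """
    tilt = np.deg2rad(tilt_deg)
    axes = (np.pi / 2, 0.0)  # T1 vertical, T2 horizontal
    signs = []
    for t in tilts:
        if t not in ("CW", "CCW"):
            raise ValueError("tilts entries must be 'CW' or 'CCW'")
        signs.append(1.0 if t == "CW" else -1.0)
    events = []
    if t1_contrast > 0:
        events.append(
            Event(prestimulus_ms, duration_ms, axes[0] + signs[0] * tilt, t1_contrast)
        )
    if t2_contrast > 0:
        events.append(
            Event(
                prestimulus_ms + soa_ms, duration_ms, axes[1] + signs[1] * tilt, t2_contrast
            )
        )
    spec = ProtocolSpec(
        name=f"contrast_pair_soa{soa_ms:g}",
        trial_duration_ms=prestimulus_ms + soa_ms + duration_ms + tail_ms,
        prestimulus_ms=prestimulus_ms,
        dt_ms=dt_ms,
        events=events,
    )
    return spec.build()
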