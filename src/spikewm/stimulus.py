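"""Sensory input currents, frozen background noise, and event schedules.

The sensory drive is a bimodal mixture of Gaussians on the ring of unit
indices: a baseline ``R_b`` plus a higher peak ``R_p`` centred on the
preferred unit and a lower peak ``R_n`` centred half the ring away.  The two
stimulus configurations (clockwise / counter-clockwise) are exact images of
each other under the half-ring swap, so their mean over units is identical —
only the placement of the higher peak distinguishes them.

Keyboard semantics of the original experiments are abstracted into
timestamped event schedules: ``STIM_RIGHT`` centres the higher peak on unit
125 (clockwise rotations), ``STIM_LEFT`` on unit 375 (counter-clockwise),
``STIM_OFF`` removes the drive entirely.

Each presynaptic unit additionally carries an independent homogeneous Poisson
background train (default 10 Hz), generated once per run from its seed and
then frozen: the identical realization drives both evoked and spontaneous
phases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusConfig",
    "StimulusParams",
    "EventSchedule",
    "BackgroundNoise",
    "Durations",
    "bimodal_input",
    "make_background",
    "schedule_for_experiment",
    "EXPERIMENT_NAMES",
]

EXPERIMENT_NAMES = ("exp1", "exp2", "exp3", "exp4", "exp5", "exp6")


class StimulusConfig(str, enum.Enum):
    """Stimulus configurations; values double as the on-disk spelling."""

    LEFT = "STIM_LEFT"    # higher peak at unit 375, counter-clockwise rotation
    RIGHT = "STIM_RIGHT"  # higher peak at unit 125, clockwise rotation
    OFF = "STIM_OFF"


def i_pref(config: StimulusConfig, n: int) -> int:
    """Preferred (1-based) unit of the higher peak: N/4 for the clockwise
    configuration and 3N/4 for the counter-clockwise one (125 and 375 for the
    default 500-unit network)."""
    if config is StimulusConfig.RIGHT:
        return n // 4
    if config is StimulusConfig.LEFT:
        return 3 * n // 4
    raise ValueError("OFF has no preferred unit")


@dataclass(frozen=True)
class StimulusParams:
    r_b: float = 0.5             # baseline amplitude, nA
    r_p: float = 2.5             # higher peak amplitude, nA
    r_n: float = 1.0             # lower peak amplitude, nA
    sigma: float = 35.0          # tuning width, unit-index units
    n: int = 500                 # number of units
    intensity_scale: float = 1.0  # multiplies the whole vector (distractors)

    def __post_init__(self) -> None:
        # equality of the two peaks is allowed as a degenerate (unbiased) input
        if not (self.r_p >= self.r_n >= 0.0) or self.r_b < 0.0:
            raise ValueError("amplitudes must satisfy R_p >= R_n >= 0 and R_b >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")


def _ring_gaussian(n: int, centre_1based: int, sigma: float) -> np.ndarray:
    """Unit-height Gaussian on the index ring 1..n."""
    i = np.arange(1, n + 1)
    d = np.abs(i - centre_1based)
    d = np.minimum(d, n - d)
    return np.exp(-(d.astype(float) ** 2) / (2.0 * sigma**2))


def bimodal_input(config: StimulusConfig, sp: StimulusParams) -> np.ndarray:
    """Per-unit external current vector in nA.

    For an active configuration the higher peak sits on the preferred unit
    and the lower peak on the antipodal unit ``(i_pref + N/2 - 1) mod N + 1``;
    indices are treated modulo N so both peaks always fall inside the ring.
    OFF returns exactly zero.
    """
    if config is StimulusConfig.OFF:
        return np.zeros(sp.n)
    centre = i_pref(config, sp.n)
    anti = (centre + sp.n // 2 - 1) % sp.n + 1
    vec = (
        sp.r_b
        + sp.r_p * _ring_gaussian(sp.n, centre, sp.sigma)
        + sp.r_n * _ring_gaussian(sp.n, anti, sp.sigma)
    )
    return sp.intensity_scale * vec


# ----------------------------------------------------------- background

@dataclass
class BackgroundNoise:
    """One frozen Poisson realization per presynaptic unit."""

    rate_hz: float
    horizon_ms: float
    seed: int
    trains: list[np.ndarray] = field(repr=False)  # sorted spike times, ms

    @property
    def n(self) -> int:
        return len(self.trains)

    def grand_mean_rate_hz(self) -> float:
        total = sum(len(t) for t in self.trains)
        return total / (self.n * self.horizon_ms / 1000.0)


def make_background(n: int, rate_hz: float, horizon_ms: float, seed: int) -> BackgroundNoise:
    """Independent homogeneous Poisson trains, frozen for the whole run."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if horizon_ms <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    trains: list[np.ndarray] = []
    rate_per_ms = rate_hz / 1000.0
    for _ in range(n):
        if rate_per_ms == 0.0:
            trains.append(np.empty(0))
            continue
        count = rng.poisson(rate_per_ms * horizon_ms)
        trains.append(np.sort(rng.uniform(0.0, horizon_ms, size=count)))
    return BackgroundNoise(rate_hz=rate_hz, horizon_ms=horizon_ms, seed=seed, trains=trains)


# ------------------------------------------------------------ schedules

@dataclass(frozen=True)
class Durations:
    """Default phase durations (ms).  The original experiments were
    user-paced; these are the package's fixed, config-overridable stand-ins,
    sized so every protocol completes within minutes of simulated time."""

    cue_ms: float = 20_000.0
    recall_ms: float = 10_000.0
    washout_ms: float = 60_000.0
    interferer_ms: float = 4_000.0
    incremental_cues_ms: tuple[float, ...] = (5_000.0, 10_000.0, 20_000.0)
    distractor_intensity: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        vals = (self.cue_ms, self.recall_ms, self.washout_ms, self.interferer_ms,
                *self.incremental_cues_ms)
        if any(v <= 0 for v in vals):
            raise ValueError("durations must be positive")
        if not 0 < self.distractor_intensity < 1:
            raise ValueError("distractor intensity must lie in (0, 1)")


@dataclass(frozen=True)
class Event:
    t_ms: float
    config: StimulusConfig
    intensity: float = 1.0


@dataclass(frozen=True)
class EventSchedule:
    """Timestamped stimulus events plus the total run horizon."""

    events: tuple[Event, ...]
    horizon_ms: float

    def __post_init__(self) -> None:
        times = [e.t_ms for e in self.events]
        if not self.events or times[0] < 0:
            raise ValueError("schedule must start at t >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.horizon_ms <= times[-1]:
            raise ValueError("horizon must exceed the last event time")

    def phases(self) -> list[tuple[float, float, StimulusConfig, float]]:
        """(t0, t1, config, intensity) segments covering [0, horizon)."""
        out = []
        evs = list(self.events)
        if evs[0].t_ms > 0:
            evs.insert(0, Event(0.0, StimulusConfig.OFF))
        for k, ev in enumerate(evs):
            t1 = evs[k + 1].t_ms if k + 1 < len(evs) else self.horizon_ms
            out.append((ev.t_ms, t1, ev.config, ev.intensity))
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_ms": [e.t_ms for e in self.events],
                "event": [e.config.value for e in self.events],
                "intensity": [e.intensity for e in self.events],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventSchedule":
        df = pd.read_csv(path)
        events = tuple(
            Event(float(r.time_ms), StimulusConfig(r.event),
                  float(getattr(r, "intensity", 1.0)))
            for r in df.itertuples()
        )
        # the trailing OFF segment runs as long as the preceding phase did
        tail = events[-1].t_ms - (events[-2].t_ms if len(events) > 1 else 0.0)
        return cls(events=events, horizon_ms=events[-1].t_ms + max(tail, 1000.0))


def schedule_for_experiment(name: str, durations: Durations | None = None) -> EventSchedule:
    """Deterministic event schedule for one of the six protocols.

    exp1 single cue/recall; exp2 incremental cues of growing duration;
    exp3 task switching; exp4 brief opposite interferer after the cue;
    exp5 interferer after a washout long enough to erase the cue;
    exp6 equal-duration opposite distractor at one third of the cue intensity.
    """
    d = durations or Durations()
    t = 0.0

    def seq(*items: tuple[StimulusConfig, float, float]) -> EventSchedule:
        nonlocal t
        events = []
        for config, dur, intensity in items:
            events.append(Event(t, config, intensity))
            t += dur
        return EventSchedule(events=tuple(events), horizon_ms=t)

    L, R, OFF = StimulusConfig.LEFT, StimulusConfig.RIGHT, StimulusConfig.OFF
    if name == "exp1":
        return seq((L, d.cue_ms, 1.0), (OFF, d.recall_ms, 1.0))
    if name == "exp2":
        items = []
        for cue in d.incremental_cues_ms:
            items += [(L, cue, 1.0), (OFF, d.recall_ms, 1.0)]
        return seq(*items)
    if name == "exp3":
        return seq((L, d.cue_ms, 1.0), (OFF, d.recall_ms, 1.0),
                   (R, d.cue_ms, 1.0), (OFF, d.recall_ms, 1.0))
    if name == "exp4":
        return seq((L, d.cue_ms, 1.0), (OFF, d.recall_ms, 1.0),
                   (R, d.interferer_ms, 1.0), (OFF, d.recall_ms, 1.0))
    if name == "exp5":
        return seq((L, d.cue_ms, 1.0), (OFF, d.washout_ms, 1.0),
                   (R, d.interferer_ms, 1.0), (OFF, d.recall_ms, 1.0))
    if name == "exp6":
        return seq((L, d.cue_ms, 1.0), (OFF, d.recall_ms, 1.0),
                   (R, d.cue_ms, d.distractor_intensity), (OFF, d.recall_ms, 1.0))
    raise ValueError(f"unknown experiment {name!r}; expected one of {EXPERIMENT_NAMES}")
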