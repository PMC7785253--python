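"""Spike-to-motor decoding and differential-drive pose integration.

Spike counts are taken in consecutive non-overlapping 40 ms bins, separately
for the two subpopulations: units 1-250 drive the left wheel and units
251-500 the right wheel, the unique assignment under which a bump centred on
unit 125 speeds up the left wheel and turns the virtual agent clockwise.
Each wheel holds its speed (``gain`` mm/s per spike) for the whole bin; the
planar pose is advanced by the exact constant-speed arc within each bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DecoderParams", "Dominance", "SpikeRecord",
           "decode_wheel_speeds", "integrate_pose", "dominance"]


@dataclass(frozen=True)
class SpikeRecord:
    """Somatic spike events of one run: times in ms, unit ids 0-based."""

    t_ms: np.ndarray
    unit: np.ndarray

    def __post_init__(self) -> None:
        if self.t_ms.shape != self.unit.shape:
            raise ValueError("time and unit arrays must have equal length")

    def in_window(self, t0: float, t1: float) -> "SpikeRecord":
        m = (self.t_ms >= t0) & (self.t_ms < t1)
        return SpikeRecord(self.t_ms[m], self.unit[m])

    def to_dataframe(self) -> pd.DataFrame:
        # 1-based unit indices at the I/O boundary
        return pd.DataFrame({"t_ms": self.t_ms, "unit_1based": self.unit + 1})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpikeRecord":
        return cls(df["t_ms"].to_numpy(float), df["unit_1based"].to_numpy(np.int64) - 1)


@dataclass(frozen=True)
class DecoderParams:
    bin_width_ms: float = 40.0
    gain_mm_s: float = 0.5        # wheel speed per spike in a bin, mm/s
    wheelbase_mm: float = 48.0
    n_units: int = 500
    tie_margin: float = 0.05      # dominance margin on the count difference

    def __post_init__(self) -> None:
        if self.bin_width_ms <= 0 or self.gain_mm_s <= 0 or self.wheelbase_mm <= 0:
            raise ValueError("bin width, gain and wheelbase must be positive")
        if self.n_units % 2:
            raise ValueError("n_units must be even (two equal subpopulations)")

    @property
    def left_units(self) -> range:
        """0-based index range of the left-wheel subpopulation (units 1..N/2)."""
        return range(0, self.n_units // 2)

    @property
    def right_units(self) -> range:
        return range(self.n_units // 2, self.n_units)


class Dominance:
    LEFT_SUBPOP = "LEFT_SUBPOP"
    RIGHT_SUBPOP = "RIGHT_SUBPOP"
    NONE = "NONE"


def decode_wheel_speeds(spikes: SpikeRecord, dp: DecoderParams,
                        horizon_ms: float) -> pd.DataFrame:
    """Per-bin wheel speeds: ``gain`` times the subpopulation spike count.

    Bins are half-open ``[t, t + bin)`` anchored at t = 0, so a spike exactly
    on a boundary belongs to the later bin; no spike is lost or double
    counted.  Returns columns t_ms (bin start), v_left, v_right (mm/s).
    """
    n_bins = int(np.ceil(horizon_ms / dp.bin_width_ms))
    idx = np.floor(spikes.t_ms / dp.bin_width_ms).astype(np.int64)
    if idx.size:
        n_bins = max(n_bins, int(idx.max()) + 1)  # keep a spike landing on the horizon
    half = dp.n_units // 2
    is_left = spikes.unit < half
    counts_l = np.bincount(idx[is_left], minlength=n_bins)
    counts_r = np.bincount(idx[~is_left], minlength=n_bins)
    return pd.DataFrame(
        {
            "t_ms": np.arange(n_bins) * dp.bin_width_ms,
            "v_left": dp.gain_mm_s * counts_l,
            "v_right": dp.gain_mm_s * counts_r,
        }
    )


def integrate_pose(speeds: pd.DataFrame, dp: DecoderParams) -> pd.DataFrame:
    """Exact arc integration of the differential-drive kinematics.

    Within each constant-speed bin the agent moves with linear velocity
    ``(v_l + v_r)/2`` and angular velocity ``(v_r - v_l)/wheelbase`` (positive
    = counter-clockwise), tracing a circular arc.  Returns per-bin rows with
    the pose at the *start* of each bin plus a terminal row.
    """
    vl = speeds["v_left"].to_numpy(float)
    vr = speeds["v_right"].to_numpy(float)
    t = speeds["t_ms"].to_numpy(float)
    dt_s = np.diff(np.append(t, t[-1] + dp.bin_width_ms)) / 1000.0

    x = np.zeros(len(t) + 1)
    y = np.zeros(len(t) + 1)
    heading = np.zeros(len(t) + 1)
    for k in range(len(t)):
        v = 0.5 * (vl[k] + vr[k])
        omega = (vr[k] - vl[k]) / dp.wheelbase_mm
        th0 = heading[k]
        if abs(omega) < 1e-12:
            x[k + 1] = x[k] + v * dt_s[k] * np.cos(th0)
            y[k + 1] = y[k] + v * dt_s[k] * np.sin(th0)
            heading[k + 1] = th0
        else:
            th1 = th0 + omega * dt_s[k]
            r = v / omega
            x[k + 1] = x[k] + r * (np.sin(th1) - np.sin(th0))
            y[k + 1] = y[k] - r * (np.cos(th1) - np.cos(th0))
            heading[k + 1] = th1
    return pd.DataFrame(
        {
            "t_ms": np.append(t, t[-1] + dp.bin_width_ms),
            "v_left": np.append(vl, 0.0),
            "v_right": np.append(vr, 0.0),
            "x_mm": x,
            "y_mm": y,
            "heading_rad": heading,
        }
    )


def dominance(spikes: SpikeRecord, window: tuple[float, float], dp: DecoderParams) -> str:
    """Which wheel's subpopulation fired more in ``window = (t0, t1)``.

    Returns NONE when the counts differ by no more than ``tie_margin`` of the
    total (and always when the window is silent).  This is the behavioural
    readout used by every experiment's success criterion.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    sub = spikes.in_window(t0, t1)
    half = dp.n_units // 2
    c_left = int(np.sum(sub.unit < half))
    c_right = sub.unit.size - c_left
    total = c_left + c_right
    if total == 0 or abs(c_left - c_right) <= dp.tie_margin * total:
        return Dominance.NONE
    return Dominance.LEFT_SUBPOP if c_left > c_right else Dominance.RIGHT_SUBPOP
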