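"""Punch-velocity indicator.

Peak hand speed is estimated by trapezoidal integration of the
acceleration up to the striking sample.  Gravity and sensor bias are
approximated by the per-axis mean over the pre-strike window and removed
before integrating (the wrist orientation is roughly constant until the
strike, so a constant offset is a reasonable proxy); optional moving-average
smoothing suppresses sensor noise.  Speed is the Euclidean norm of the
integrated velocity vector; the reported value is its maximum over the
window, converted to km/h when the trace unit is m/s².

Single integration over a sub-second window keeps drift from residual bias
small; no gyroscope-based gravity rotation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .detector import detect_striking_index
from .io import AccelTrace

__all__ = ["SpeedEstimate", "estimate_punch_speed", "MPS_TO_KMH"]

MPS_TO_KMH = 3.6

#: Unit strings accepted as metres per second squared.
_SI_UNITS = {"m/s^2", "m/s2", "m·s^-2", "mps2"}

Detrend = Literal["mean", "none"]


@dataclass(frozen=True)
class SpeedEstimate:
    """Peak speed with its unit.

    ``converted`` is true when the value is in km/h; when the trace unit is
    not m/s² the conversion is refused, the value stays in native
    (unit·s) and ``converted`` is false — a warning flag for the caller.
    """

    value: float
    unit: str
    converted: bool


def estimate_punch_speed(
    trace: AccelTrace,
    detrend: Detrend = "mean",
    *,
    smooth_width: int | None = None,
    strike_index: int | None | Literal["auto"] = "auto",
) -> SpeedEstimate:
    """Peak punch speed from a single punch trace.

    Parameters
    ----------
    trace
        The punch recording; ``trace.unit`` must be m/s² for a km/h result.
    detrend
        ``"mean"`` removes the per-axis mean over the integration window
        (gravity + bias proxy); ``"none"`` integrates the raw signal.
    smooth_width
        Optional moving-average width (samples) applied before integration.
    strike_index
        ``"auto"`` detects the striking sample and integrates up to and
        including it; an int uses that sample; ``None`` integrates the whole
        trace (useful for analytically defined signals without a strike).
    """
    if strike_index == "auto":
        mu = detect_striking_index(trace)
    elif strike_index is None:
        mu = len(trace) - 1
    else:
        mu = int(strike_index)
        if not (0 <= mu < len(trace)):
            raise ValueError(f"strike_index {mu} out of range")

    window = trace.samples[: mu + 1].astype(np.float64)
    if window.shape[0] < 2:
        raise ValueError("integration window shorter than 2 samples")

    if detrend == "mean":
        window = window - window.mean(axis=0, keepdims=True)
    elif detrend != "none":
        raise ValueError(f"unknown detrend method {detrend!r}")

    if smooth_width is not None and smooth_width > 1:
        kernel = np.ones(int(smooth_width)) / float(smooth_width)
        window = np.stack(
            [np.convolve(window[:, k], kernel, mode="same") for k in range(3)],
            axis=1,
        )

    # cumulative trapezoid per axis, v[0] = 0
    dt = 1.0 / trace.sample_rate_hz
    increments = 0.5 * (window[1:] + window[:-1]) * dt
    velocity = np.vstack([np.zeros(3), np.cumsum(increments, axis=0)])
    speed = float(np.max(np.linalg.norm(velocity, axis=1)))

    if trace.unit in _SI_UNITS:
        return SpeedEstimate(value=speed * MPS_TO_KMH, unit="km/h", converted=True)
    return SpeedEstimate(value=speed, unit=f"{trace.unit}*s", converted=False)
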