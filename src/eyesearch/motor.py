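"""Oculomotor and manual motor mechanisms.

Saccades undershoot and are noisy: the realized length for an intended
eccentricity ``e`` is drawn from ``N(g*e, s*g*e)`` (gain g = 0.95, spread
s = 10% by default), truncated at zero, and the polar angle gets Gaussian
noise with a 1 deg standard deviation. Saccade duration follows the classic
linear main-sequence function ``21 + 2.2 * length`` ms.

Key presses take a fixed 125 ms; with probability ``slip_er`` the executed
response is the opposite of the intended one (an action slip), without any
effect on timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class OculomotorParams:
    gain: float = 0.95
    spread: float = 0.10  # sd of realized length as a fraction of its mean
    angular_sd: float = 1.0  # degrees of polar angle
    duration_intercept: float = 21.0  # ms
    duration_slope: float = 2.2  # ms per degree

    def __post_init__(self) -> None:
        if not 0.0 < self.gain <= 1.5:
            raise ValueError(f"gain must be in (0, 1.5], got {self.gain}")
        if self.spread < 0:
            raise ValueError(f"spread must be >= 0, got {self.spread}")
        if self.angular_sd < 0:
            raise ValueError(f"angular_sd must be >= 0, got {self.angular_sd}")


@dataclass
class ManualParams:
    response_time: float = 125.0  # ms, identical for present and absent
    slip_er: float = 0.0

    def __post_init__(self) -> None:
        if self.response_time <= 0:
            raise ValueError(f"response_time must be > 0, got {self.response_time}")
        if not 0.0 <= self.slip_er < 0.5:
            raise ValueError(f"slip_er must be in [0, 0.5), got {self.slip_er}")


def saccade_duration(length: float, params: OculomotorParams) -> float:
    """Main-sequence duration in ms for a saccade of ``length`` degrees."""
    if length < 0:
        raise ValueError(f"saccade length must be >= 0, got {length}")
    return params.duration_intercept + params.duration_slope * length


def execute_saccade(
    eye: tuple[float, float],
    target: tuple[float, float],
    params: OculomotorParams,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], float, float]:
    """Execute a noisy saccade from ``eye`` toward ``target``.

    Returns ``(landing, duration_ms, realized_length_deg)``. Negative
    length draws (possible only for large spreads) are resampled, which
    truncates the distribution at zero.
    """
    dx = target[0] - eye[0]
    dy = target[1] - eye[1]
    e = math.hypot(dx, dy)
    if e == 0.0:
        raise ValueError("saccade target coincides with the current eye position")
    mu = params.gain * e
    sd = params.spread * mu
    length = mu if sd == 0.0 else float(rng.normal(mu, sd))
    while length < 0.0:
        length = float(rng.normal(mu, sd))
    angle = math.atan2(dy, dx)
    if params.angular_sd > 0.0:
        angle += math.radians(float(rng.normal(0.0, params.angular_sd)))
    landing = (eye[0] + length * math.cos(angle), eye[1] + length * math.sin(angle))
    return landing, saccade_duration(length, params), length


def manual_response(
    intended: str,
    params: ManualParams,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Execute a key press; slips flip the response, never the timing."""
    if intended not in ("present", "absent"):
        raise ValueError(f"intended response must be present|absent, got {intended!r}")
    actual = intended
    if params.slip_er > 0.0 and rng.random() < params.slip_er:
        actual = "absent" if intended == "present" else "present"
    return actual, params.response_time
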