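"""Kinematic features of linear-motor trajectories used to grade impacts.

A concussive insult is delivered by decelerating the larva-holding capsule
along a programmed position-time trajectory (millimetres at a 1 kHz
command rate).  The severity of the insult is summarised by five features
of that trajectory: path length, duration of motion, and the peaks of
velocity, acceleration and jerk obtained by successive finite
differencing.  A small synthesiser produces smooth test profiles with a
prescribed length and duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryFeatures",
    "trajectory_features",
    "synthesize_trajectory",
]


@dataclass
class Trajectory:
    """Uniformly sampled position-time series (seconds, millimetres)."""

    t_s: np.ndarray
    pos_mm: np.ndarray

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.pos_mm = np.asarray(self.pos_mm, dtype=float)
        if len(self.t_s) != len(self.pos_mm):
            raise ValueError("time and position must have equal length")
        if len(self.t_s) >= 2:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "pos_mm": self.pos_mm})

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["pos_mm"].to_numpy())


@dataclass
class TrajectoryFeatures:
    """Severity summary of one motion profile (all non-negative, SI peaks)."""

    length_mm: float
    duration_ms: float
    peak_velocity_m_s: float
    peak_acceleration_m_s2: float
    peak_jerk_m_s3: float

    def to_dict(self) -> dict:
        return {
            "length_mm": self.length_mm,
            "duration_ms": self.duration_ms,
            "peak_velocity_m_s": self.peak_velocity_m_s,
            "peak_acceleration_m_s2": self.peak_acceleration_m_s2,
            "peak_jerk_m_s3": self.peak_jerk_m_s3,
        }


def trajectory_features(
    traj: Trajectory, smooth_window: int = 0
) -> TrajectoryFeatures:
    """Length, motion duration and peak |velocity|/|acceleration|/|jerk|.

    Velocity, acceleration and jerk are successive central differences
    (one-sided at the boundaries).  Length is the magnitude of the net
    displacement; duration is the span of the interval on which the
    velocity is non-negligible (relative threshold 1e-6 of the peak),
    extended to the bracketing at-rest samples so a profile that starts
    and ends at rest reports its full programmed duration.  An optional
    moving-average window (odd, in samples) smooths the position first.
    """
    if len(traj.t_s) < 4:
        raise ValueError("need at least 4 samples")
    dt = traj.dt
    pos = traj.pos_mm
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pos = np.convolve(pos, kernel, mode="same")

    # second-order one-sided boundary stencils: first-order edges compound
    # to >10% error on the third derivative
    pos_m = pos / 1000.0
    vel = np.gradient(pos_m, dt, edge_order=2)
    acc = np.gradient(vel, dt, edge_order=2)
    jerk = np.gradient(acc, dt, edge_order=2)

    length_mm = float(abs(pos[-1] - pos[0]))

    speed = np.abs(vel)
    vmax = speed.max()
    if vmax == 0.0:
        duration_ms = 0.0
    else:
        moving = np.flatnonzero(speed > 1e-6 * vmax)
        lo = max(moving[0] - 1, 0)
        hi = min(moving[-1] + 1, len(pos) - 1)
        duration_ms = float((traj.t_s[hi] - traj.t_s[lo]) * 1000.0)

    return TrajectoryFeatures(
        length_mm=length_mm,
        duration_ms=duration_ms,
        peak_velocity_m_s=float(vmax),
        peak_acceleration_m_s2=float(np.abs(acc).max()),
        peak_jerk_m_s3=float(np.abs(jerk).max()),
    )


def synthesize_trajectory(
    length_mm: float,
    duration_ms: float,
    shape: str = "raised-cosine",
    fs_hz: float = 1000.0,
) -> Trajectory:
    """Smooth motion profile reaching ``length_mm`` in ``duration_ms``.

    Shapes:

    * ``raised-cosine`` -- position L/2 (1 - cos(pi t / T)); velocity is a
      half-sine, zero at both ends.
    * ``trapezoidal-velocity`` -- linear ramp-up for T/4, cruise for T/2,
      ramp-down for T/4.

    A zero-length request yields a flat trajectory over the requested
    span.
    """
    if length_mm < 0 or duration_ms <= 0:
        raise ValueError("need non-negative length and positive duration")
    T = duration_ms / 1000.0
    n = int(round(T * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    if length_mm == 0:
        return Trajectory(t, np.zeros(n))
    if shape == "raised-cosine":
        pos = length_mm / 2.0 * (1.0 - np.cos(np.pi * t / T))
    elif shape == "trapezoidal-velocity":
        t1, t2 = T / 4.0, 3.0 * T / 4.0
        v_peak = 1.0 / (0.75 * T)  # unit displacement; rescaled below
        vel = np.where(
            t < t1, v_peak * t / t1,
            np.where(t < t2, v_peak, v_peak * np.clip((T - t) / t1, 0, 1)),
        )
        pos = np.concatenate(([0.0], np.cumsum((vel[1:] + vel[:-1]) / 2.0)
                              / fs_hz))
        pos = pos / pos[-1] * length_mm
    else:
        raise ValueError(f"unsupported trajectory shape {shape!r}")
    # pin the endpoint exactly to the requested displacement
    pos[-1] = length_mm
    return Trajectory(t, pos)
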