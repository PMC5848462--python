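"""Synthetic patient generator: stenotic geometries, angiographic bolus frame
series, multi-delay ASL signals and noisy pressure-wire pull-backs.

Every generator carries an explicit seed and a known ground truth, so the
full analysis chain can be validated by parameter recovery.  The bolus
transport model is plug flow of the contrast front — the opacified lumen
volume grows at exactly the volumetric flow rate while the front is inside
the vessel — which makes the frame-based flow estimate exact by
construction.  ASL difference signals are the kinetic forward model of the
quantification chain plus additive Gaussian noise; wire pressures are the
simulated profile plus additive Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .asl import ASLAcquisition, ASLParams, CBF_UNIT_SCALE, kinetic_decay_factor
from .geometry import VesselGeometry
from .hemodynamics import PressureProfile, PullbackCurve

__all__ = [
    "DSAFrameSeries",
    "GroundTruth",
    "simulate_dsa_frames",
    "simulate_asl_signals",
    "simulate_pressure_wire",
    "write_frames_csv",
    "read_frames_csv",
]


@dataclass(frozen=True)
class DSAFrameSeries:
    """Angiographic frame series: times and cumulative opacified lumen volume."""

    t: np.ndarray  # frame acquisition times, s
    V: np.ndarray  # cumulative opacified volume, m^3, nondecreasing
    frame_rate: float
    truncated: bool = False  # bolus left the vessel before the last frame

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        V = np.asarray(self.V, dtype=float)
        if t.shape != V.shape or t.ndim != 1:
            raise ValueError("t and V must be 1-D with one volume per frame")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(np.diff(V) < -1e-18):
            raise ValueError("opacified volume must be nondecreasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "V", V)


@dataclass(frozen=True)
class GroundTruth:
    """Truth store for recovery tests: flow, CBF/ATT maps, seed."""

    Q_true: float
    cbf_true: np.ndarray
    att_true: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.Q_true <= 0:
            raise ValueError("true flow must be positive")
        if np.any(np.asarray(self.cbf_true) < 0):
            raise ValueError("true CBF must be nonnegative")
        if np.any(np.asarray(self.att_true) <= 0):
            raise ValueError("true ATT must be positive")


def simulate_dsa_frames(
    g: VesselGeometry, Q: float, frame_rate: float = 10.0, t_end: float = 0.4
) -> DSAFrameSeries:
    """Simulate the opacified-volume frame series for a bolus at flow ``Q``.

    Plug flow: the contrast front z_f(t) advances at dz_f/dt = Q/A(z_f), so
    the opacified volume is V(t) = Q*t until the front exits the vessel,
    after which V saturates at the total lumen volume and the series is
    flagged truncated.
    """
    if Q <= 0 or frame_rate <= 0:
        raise ValueError("flow and frame rate must be positive")
    n_frames = int(np.floor(t_end * frame_rate)) + 1
    t = np.arange(n_frames) / frame_rate
    V_total = g.lumen_volume()
    V = np.minimum(Q * t, V_total)
    truncated = bool(Q * t[-1] > V_total)
    if truncated:
        warnings.warn(
            "bolus exits the vessel before the last frame; series truncated",
            stacklevel=2,
        )
    return DSAFrameSeries(t=t, V=V, frame_rate=frame_rate, truncated=truncated)


def bolus_front_position(g: VesselGeometry, Q: float, t: float) -> float:
    """Axial position of the plug-flow contrast front at time t, m."""
    cumvol = g.cumulative_volume()
    return float(np.interp(Q * t, cumvol, g.z))


def simulate_asl_signals(
    cbf_true: np.ndarray,
    att_true: np.ndarray,
    M0: np.ndarray,
    params: ASLParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ASLAcquisition:
    """Generate per-PLD difference-signal maps from known CBF/ATT truth.

    Forward kinetic model (the inverse of the quantification chain):

        dM_i = 2 * alpha * M0 * (f/6000) * B_i(delta) / (lam * R1a) + noise

    with ``f`` in ml/100 g/min, ``delta`` in s and ``noise`` Gaussian with
    standard deviation ``noise_sd`` times the mean noiseless |dM|.
    """
    params = params or ASLParams()
    cbf = np.asarray(cbf_true, dtype=float)
    att = np.asarray(att_true, dtype=float)
    M0 = np.asarray(M0, dtype=float)
    if cbf.shape != att.shape or cbf.shape != M0.shape:
        raise ValueError("cbf_true, att_true and M0 must share one shape")
    if np.any(cbf < 0) or np.any(att < 0):
        raise ValueError("true CBF and ATT must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    f_per_s = cbf / CBF_UNIT_SCALE  # ml/g/s
    dM = np.stack(
        [
            2 * params.alpha * M0 * f_per_s * kinetic_decay_factor(att, i, params)
            / (params.lam * params.R1a)
            for i in range(params.n_delays)
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * np.mean(np.abs(dM))
        dM = dM + rng.normal(0.0, scale, size=dM.shape)
    return ASLAcquisition(dM=dM, M0=M0, params=params)


def simulate_pressure_wire(
    profile: PressureProfile,
    pullback_speed: float = 0.005,
    sample_rate: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    z_start: float | None = None,
    n_samples: int | None = None,
) -> PullbackCurve:
    """Simulate a pressure-wire pull-back through the solved pressure field.

    The wire starts distal (``z_start``, default the vessel end) and is
    withdrawn at ``pullback_speed`` while sampling at ``sample_rate``; each
    sample is the local pressure plus Gaussian noise of SD ``noise_sd`` (Pa),
    expressed as Pd/Pa against the profile's proximal reference p(0).
    Positions that would leave the profile are clipped with a warning and
    the curve flagged truncated.
    """
    if pullback_speed <= 0 or sample_rate <= 0:
        raise ValueError("pull-back speed and sample rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    z0 = profile.z[-1] if z_start is None else float(z_start)
    if n_samples is None:
        n_samples = int(np.floor((z0 - profile.z[0]) / pullback_speed * sample_rate)) + 1
    t = np.arange(n_samples) / sample_rate
    z_k = z0 - pullback_speed * t
    truncated = bool(np.any(z_k < profile.z[0] - 1e-12) or z0 > profile.z[-1] + 1e-12)
    if truncated:
        warnings.warn("pull-back positions outside the profile were clipped", stacklevel=2)
    z_k = np.clip(z_k, profile.z[0], profile.z[-1])
    p_k = np.interp(z_k, profile.z, profile.p)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p_k = p_k + rng.normal(0.0, noise_sd, size=p_k.shape)
    return PullbackCurve(z=z_k, t=t, ratio=p_k / profile.p[0], truncated=truncated)


def write_frames_csv(frames: DSAFrameSeries, path: str | Path) -> None:
    pd.DataFrame({"t_s": frames.t, "volume_ml": frames.V * 1e6}).to_csv(path, index=False)


def read_frames_csv(path: str | Path, frame_rate: float | None = None) -> DSAFrameSeries:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    return DSAFrameSeries(t=t, V=df["volume_ml"].to_numpy() * 1e-6, frame_rate=frame_rate)
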