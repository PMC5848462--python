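"""Reduced-order steady hemodynamics of a stenotic vessel and the CAFA index.

The trans-stenotic pressure field is computed from a steady axisymmetric 1-D
momentum balance for an incompressible Newtonian fluid:

* distributed Poiseuille friction  dp_visc = 8*mu*Q / (pi*r^4) dz,
* the Bernoulli area term          (rho*Q^2/2) * (A^-2 - A_in^-2),
* an irreversible expansion loss (Young/Tsai-type)
  dp_loss = K_t * (rho/2) * (1/A_throat - 1/A_ref)^2 * Q^2,
  accumulated linearly over the diverging half of the stenosis.

This reduction of the full Navier-Stokes problem admits closed-form oracles
(Hagen-Poiseuille in a uniform tube) and captures the pressure drop that the
functional index quantifies:

* CAFA_p = mPd / mPa   (mean distal over mean proximal pressure), the
  FFR-style pressure ratio across the stenosis;
* CAFA_v = Q_S / Q_N   (flow through the stenotic vessel over flow through
  the same vessel with the stenosis removed, under a fixed perfusion
  pressure and distal bed resistance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .geometry import GeometryError, VesselGeometry

#: Default inlet reference pressure: 100 mmHg in Pa.
DEFAULT_P_INLET = 13332.0


class NonphysicalRegimeError(RuntimeError):
    """The solved pressure fell to or below zero somewhere along the vessel."""


@dataclass(frozen=True)
class BloodModel:
    """Incompressible Newtonian blood: density 1046 kg/m^3, viscosity 0.004 Pa*s."""

    rho: float = 1046.0
    mu: float = 0.004
    K_t: float = 1.52  # expansion (turbulent) loss coefficient

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")
        if self.K_t < 0:
            raise ValueError("loss coefficient must be nonnegative")


@dataclass(frozen=True)
class PressureProfile:
    """Pressure, mean velocity, WSS and pressure ratio along the centerline."""

    z: np.ndarray
    p: np.ndarray
    u_mean: np.ndarray
    wss: np.ndarray
    Q: float
    p_inlet: float

    @property
    def p_ratio(self) -> np.ndarray:
        return self.p / self.p[0]

    def interp_pressure(self, z: np.ndarray | float) -> np.ndarray | float:
        return np.interp(z, self.z, self.p)


@dataclass(frozen=True)
class CAFAResult:
    """Pressure-ratio (mPd/mPa) and/or flow-ratio (Q_S/Q_N) functional index."""

    cafa_p: float
    mPa: float
    mPd: float
    z_d: float
    cafa_v: float | None = None


@dataclass(frozen=True)
class PullbackCurve:
    """Pd/Pa samples along the pulled-back segment (distal end -> inlet)."""

    z: np.ndarray
    t: np.ndarray
    ratio: np.ndarray
    truncated: bool = False

    @property
    def n(self) -> int:
        return int(self.z.size)


def wall_shear_stress_profile(
    g: VesselGeometry, blood: BloodModel, Q: float
) -> np.ndarray:
    """Poiseuille wall-shear closure: wss(z) = 4*mu*Q / (pi*r(z)^3), Pa.

    Maximal at the throat; the throat/inlet ratio is (1 - degree)^-3.
    """
    if Q <= 0:
        raise ValueError("flow must be positive")
    return 4 * blood.mu * Q / (np.pi * g.r**3)


def _expansion_loss_profile(g: VesselGeometry, blood: BloodModel, Q: float) -> np.ndarray:
    """Irreversible loss accumulated linearly across the diverging half."""
    d = g.stenosis.degree
    if d <= 0:
        return np.zeros_like(g.z)
    i_throat = int(np.argmin(g.r))
    A_s = np.pi * g.r[i_throat] ** 2
    A_0 = np.pi * g.r_ref[i_throat] ** 2
    dp_total = blood.K_t * (blood.rho / 2) * (1 / A_s - 1 / A_0) ** 2 * Q**2
    z_start = g.z[i_throat]
    z_end = g.stenosis.z_c + g.stenosis.length / 2
    if z_end <= z_start:  # degenerate: throat at or past the distal edge
        return np.where(g.z >= z_start, dp_total, 0.0)
    frac = np.clip((g.z - z_start) / (z_end - z_start), 0.0, 1.0)
    return dp_total * frac


def solve_pressure_profile(
    g: VesselGeometry,
    blood: BloodModel,
    Q: float,
    p_inlet: float = DEFAULT_P_INLET,
) -> PressureProfile:
    """Solve the steady 1-D pressure field for a prescribed inlet flow.

    p(z) = p_inlet - int_0^z 8*mu*Q/(pi*r^4) ds
                   - (rho*Q^2/2) * (A(z)^-2 - A(0)^-2)
                   - dp_loss(z)

    Mass is conserved exactly: u_mean(z) = Q / A(z).
    """
    if Q <= 0:
        raise ValueError("flow must be positive")
    if p_inlet <= 0:
        raise ValueError("inlet pressure must be positive")
    A = g.area
    visc = cumulative_trapezoid(8 * blood.mu * Q / (np.pi * g.r**4), g.z, initial=0.0)
    bern = (blood.rho * Q**2 / 2) * (A**-2 - A[0] ** -2)
    loss = _expansion_loss_profile(g, blood, Q)
    p = p_inlet - visc - bern - loss
    if np.any(p <= 0):
        i = int(np.argmax(p <= 0))
        raise NonphysicalRegimeError(
            f"pressure fell to {p[i]:.1f} Pa at z = {g.z[i]*1e3:.1f} mm; "
            f"flow {Q*1e6:.2f} ml/s exceeds the physical regime for this "
            f"geometry at inlet pressure {p_inlet:.0f} Pa"
        )
    return PressureProfile(
        z=g.z.copy(),
        p=p,
        u_mean=Q / A,
        wss=wall_shear_stress_profile(g, blood, Q),
        Q=Q,
        p_inlet=p_inlet,
    )


def total_pressure_drop(g: VesselGeometry, blood: BloodModel, Q: float) -> float:
    """Inlet-to-outlet pressure drop at flow Q, Pa (independent of p_inlet)."""
    A = g.area
    visc = np.trapezoid(8 * blood.mu * Q / (np.pi * g.r**4), g.z)
    bern = (blood.rho * Q**2 / 2) * (A[-1] ** -2 - A[0] ** -2)
    loss = _expansion_loss_profile(g, blood, Q)[-1]
    return float(visc + bern + loss)


def compute_cafa_p(
    profile: PressureProfile,
    g: VesselGeometry,
    distal_offset: float = 0.03,
) -> CAFAResult:
    """Pressure-ratio index mPd/mPa.

    mPa is the proximal reference pressure p(0); mPd is sampled at the
    stenosis distal edge plus ``distal_offset`` (default 3 cm downstream of
    the lesion, matching wire placement practice).
    """
    z_d = g.stenosis.z_c + g.stenosis.length / 2 + distal_offset
    if z_d > g.z[-1] + 1e-12:
        raise GeometryError(
            f"distal measurement site z = {z_d*1e3:.1f} mm exceeds vessel end "
            f"{g.z[-1]*1e3:.1f} mm; extend the geometry or reduce the offset"
        )
    mPa = float(profile.p[0])
    mPd = float(profile.interp_pressure(z_d))
    return CAFAResult(cafa_p=mPd / mPa, mPa=mPa, mPd=mPd, z_d=float(z_d))


def compute_cafa_v(
    g_sten: VesselGeometry,
    g_norm: VesselGeometry,
    blood: BloodModel,
    p_perf: float,
    R_dist: float = 0.0,
) -> float:
    """Flow-ratio index Q_S/Q_N at a fixed perfusion pressure.

    For each geometry the flow solves dp_vessel(Q) + R_dist*Q = p_perf by
    monotone root finding; the bracket upper end is the uniform-tube
    Poiseuille flow, an upper bound on any resistive configuration.
    """
    if p_perf <= 0:
        raise ValueError("perfusion pressure must be positive")
    if R_dist < 0:
        raise ValueError("distal resistance must be nonnegative")

    def flow_for(g: VesselGeometry) -> float:
        def balance(Q: float) -> float:
            return total_pressure_drop(g, blood, Q) + R_dist * Q - p_perf

        r_min_ref = float(np.min(g.r_ref))
        L = g.length
        Q_hi = p_perf * np.pi * r_min_ref**4 / (8 * blood.mu * L)
        # widen until the balance is positive (guards loose reference radii)
        for _ in range(60):
            if balance(Q_hi) >= 0:
                break
            Q_hi *= 2
        else:
            raise RuntimeError(
                f"no flow bracket found up to {Q_hi*1e6:.3g} ml/s for "
                f"perfusion pressure {p_perf:.0f} Pa"
            )
        return brentq(balance, 0.0, Q_hi, xtol=1e-15, rtol=1e-12)

    Q_S = flow_for(g_sten)
    Q_N = flow_for(g_norm)
    return Q_S / Q_N


def sample_pullback(profile: PressureProfile, n: int = 18) -> PullbackCurve:
    """Sample the simulated Pd/Pa curve at n points uniform in arc length.

    Points span distal end -> inlet (the direction of a wire pull-back);
    the ratio uses the proximal reference pressure p(0).
    """
    if n < 2:
        raise ValueError("need at least 2 pull-back samples")
    z_k = np.linspace(profile.z[-1], profile.z[0], n)
    ratio = np.interp(z_k, profile.z, profile.p) / profile.p[0]
    return PullbackCurve(z=z_k, t=np.arange(n, dtype=float), ratio=ratio)


def write_profile_csv(profile: PressureProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "z_m": profile.z,
            "p_pa": profile.p,
            "p_ratio": profile.p_ratio,
            "u_m_s": profile.u_mean,
            "wss_pa": profile.wss,
        }
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path, Q: float = float("nan")) -> PressureProfile:
    df = pd.read_csv(path)
    p = df["p_pa"].to_numpy()
    return PressureProfile(
        z=df["z_m"].to_numpy(),
        p=p,
        u_mean=df["u_m_s"].to_numpy(),
        wss=df["wss_pa"].to_numpy(),
        Q=Q,
        p_inlet=float(p[0]),
    )


def write_pullback_csv(curve: PullbackCurve, path: str | Path) -> None:
    pd.DataFrame({"z_m": curve.z, "t_s": curve.t, "ratio": curve.ratio}).to_csv(
        path, index=False
    )


def read_pullback_csv(path: str | Path) -> PullbackCurve:
    df = pd.read_csv(path)
    return PullbackCurve(
        z=df["z_m"].to_numpy(), t=df["t_s"].to_numpy(), ratio=df["ratio"].to_numpy()
    )
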