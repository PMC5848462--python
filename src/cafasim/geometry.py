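"""Axisymmetric vessel geometry: centerline grid, lumen radius, stenosis descriptor.

The lumen is described by a strictly increasing axial grid ``z`` (meters,
origin at the inlet) and a radius profile ``r(z)``.  A stenosis is a smooth
cosine-shaped constriction whose severity follows the NASCET convention,
``degree = 1 - r_min / r_ref``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class GeometryError(ValueError):
    """Invalid vessel geometry (non-positive radius, out-of-domain stenosis...)."""


@dataclass(frozen=True)
class StenosisDescriptor:
    """Location and severity of a single axisymmetric constriction.

    Attributes
    ----------
    z_c : float
        Axial position of the throat (stenosis center), m.
    length : float
        Axial extent of the constriction, m.
    degree : float
        NASCET-style severity, ``1 - r_min/r_ref``, in [0, 1).
    """

    z_c: float = 0.0
    length: float = 0.0
    degree: float = 0.0


@dataclass(frozen=True)
class VesselGeometry:
    """Axisymmetric lumen: axial grid, radius profile, healthy reference profile."""

    z: np.ndarray
    r: np.ndarray
    r_ref: np.ndarray
    stenosis: StenosisDescriptor = field(default_factory=StenosisDescriptor)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        r = np.asarray(self.r, dtype=float)
        r_ref = np.asarray(self.r_ref, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise GeometryError("axial grid must be 1-D with at least 2 points")
        if not (z.shape == r.shape == r_ref.shape):
            raise GeometryError("z, r and r_ref must share one shape")
        if np.any(np.diff(z) <= 0):
            raise GeometryError("axial grid must be strictly increasing")
        if np.any(r <= 0) or np.any(r_ref <= 0):
            raise GeometryError("all radii must be positive")
        if np.any(r > r_ref * (1 + 1e-12)):
            raise GeometryError("lumen radius may not exceed the reference radius")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "r_ref", r_ref)

    @property
    def area(self) -> np.ndarray:
        """Cross-sectional area A(z) = pi * r(z)^2, m^2."""
        return np.pi * self.r**2

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])

    def lumen_volume(self) -> float:
        """Total lumen volume, m^3 (trapezoidal integral of A over z)."""
        return float(np.trapezoid(self.area, self.z))

    def cumulative_volume(self) -> np.ndarray:
        """Lumen volume from the inlet up to each grid point, m^3."""
        from scipy.integrate import cumulative_trapezoid

        return cumulative_trapezoid(self.area, self.z, initial=0.0)


def make_stenotic_geometry(
    r0: float,
    degree: float,
    z_c: float,
    L_s: float,
    L_total: float,
    n: int = 400,
) -> VesselGeometry:
    """Build a straight tube of radius ``r0`` with a cosine-shaped stenosis.

    Within ``|z - z_c| <= L_s/2`` the radius is

        r(z) = r0 * [1 - (degree/2) * (1 + cos(2*pi*(z - z_c)/L_s))]

    so the minimal radius ``r0*(1 - degree)`` sits exactly at the throat
    ``z_c`` and the profile blends smoothly (C1) into the healthy tube.

    Parameters
    ----------
    r0 : float
        Healthy (reference) lumen radius, m.
    degree : float
        NASCET severity in [0, 1).
    z_c, L_s : float
        Stenosis center and axial length, m.
    L_total : float
        Vessel length, m; the grid spans [0, L_total].
    n : int
        Number of grid points (>= 50).
    """
    if not 0 <= degree < 1:
        raise GeometryError(f"stenosis degree must be in [0, 1), got {degree}")
    if r0 <= 0 or L_total <= 0:
        raise GeometryError("r0 and L_total must be positive")
    if L_s <= 0:
        raise GeometryError("stenosis length must be positive")
    if z_c - L_s / 2 < 0 or z_c + L_s / 2 > L_total:
        raise GeometryError(
            f"stenosis [{z_c - L_s/2:.4g}, {z_c + L_s/2:.4g}] m extends past "
            f"the vessel ends [0, {L_total:.4g}] m"
        )
    if n < 50:
        raise GeometryError("need at least 50 grid points")

    z = np.linspace(0.0, L_total, n)
    r = np.full(n, r0)
    inside = np.abs(z - z_c) <= L_s / 2
    r[inside] = r0 * (1 - (degree / 2) * (1 + np.cos(2 * np.pi * (z[inside] - z_c) / L_s)))
    sten = StenosisDescriptor(z_c=z_c, length=L_s, degree=degree)
    return VesselGeometry(z=z, r=r, r_ref=np.full(n, r0), stenosis=sten)


def remove_stenosis(g: VesselGeometry) -> VesselGeometry:
    """Return the healthy counterpart: radius restored to the reference profile.

    Idempotent; the stenosis descriptor degree is reset to 0.
    """
    sten = StenosisDescriptor(z_c=g.stenosis.z_c, length=g.stenosis.length, degree=0.0)
    return VesselGeometry(z=g.z.copy(), r=g.r_ref.copy(), r_ref=g.r_ref.copy(), stenosis=sten)


def write_geometry_csv(g: VesselGeometry, path: str | Path) -> None:
    """Write geometry as CSV (z_m, r_m, r_ref_m) plus a JSON stenosis sidecar."""
    path = Path(path)
    pd.DataFrame({"z_m": g.z, "r_m": g.r, "r_ref_m": g.r_ref}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"z_c": g.stenosis.z_c, "length": g.stenosis.length, "degree": g.stenosis.degree},
            indent=2,
        )
    )


def read_geometry_csv(path: str | Path) -> VesselGeometry:
    """Read geometry written by :func:`write_geometry_csv` (sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path)
    sten = StenosisDescriptor()
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        sten = StenosisDescriptor(z_c=d["z_c"], length=d["length"], degree=d["degree"])
    return VesselGeometry(
        z=df["z_m"].to_numpy(),
        r=df["r_m"].to_numpy(),
        r_ref=df["r_ref_m"].to_numpy(),
        stenosis=sten,
    )
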