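"""Inlet boundary condition from an angiographic frame series.

The volumetric flow rate is the opacified lumen volume between two frames
divided by the transport time; the inlet mean velocity is that flow divided
by the inlet cross-sectional area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VesselGeometry
from .synthetic import DSAFrameSeries


class NoTransportError(ValueError):
    """No contrast volume moved between the selected frames."""


@dataclass(frozen=True)
class InletBoundary:
    """Flow-prescribed inlet: Q, mean velocity and inlet area."""

    Q: float  # m^3/s
    u_in: float  # m/s
    A_in: float  # m^2
    frames_used: tuple[int, int] = (-1, -1)


def default_frame_pair(frames: DSAFrameSeries) -> tuple[int, int]:
    """First frame with opacified volume and the last before bolus exit.

    Bolus exit shows as the volume curve saturating; the pair brackets the
    longest interval over which transport is still observable.
    """
    nonzero = np.nonzero(frames.V > 0)[0]
    if nonzero.size == 0:
        raise NoTransportError("no frame shows opacified volume")
    i_a = int(nonzero[0]) - 1 if nonzero[0] > 0 else int(nonzero[0])
    growing = np.nonzero(np.diff(frames.V) > 0)[0]
    if growing.size == 0:
        raise NoTransportError("opacified volume never increases")
    i_b = int(growing[-1]) + 1
    return i_a, i_b


def estimate_flow_rate(frames: DSAFrameSeries, i_a: int, i_b: int) -> float:
    """Q = (V(i_b) - V(i_a)) / (t(i_b) - t(i_a)), m^3/s."""
    if i_a >= i_b:
        raise IndexError(f"frame order must satisfy i_a < i_b, got {i_a} >= {i_b}")
    dV = frames.V[i_b] - frames.V[i_a]
    if dV <= 0:
        raise NoTransportError(
            f"no volume transported between frames {i_a} and {i_b} "
            f"(dV = {dV*1e6:.4g} ml)"
        )
    return float(dV / (frames.t[i_b] - frames.t[i_a]))


def inlet_velocity(Q: float, g: VesselGeometry) -> InletBoundary:
    """Bundle the inlet boundary: u_in = Q / (pi * r(0)^2)."""
    if Q <= 0:
        raise ValueError("flow must be positive")
    A_in = float(np.pi * g.r[0] ** 2)
    return InletBoundary(Q=Q, u_in=Q / A_in, A_in=A_in)


def boundary_from_frames(
    frames: DSAFrameSeries,
    g: VesselGeometry,
    i_a: int | None = None,
    i_b: int | None = None,
) -> InletBoundary:
    """Estimate the inlet boundary from a frame series (default frame pair)."""
    if i_a is None or i_b is None:
        i_a, i_b = default_frame_pair(frames)
    Q = estimate_flow_rate(frames, i_a, i_b)
    bundle = inlet_velocity(Q, g)
    return InletBoundary(Q=bundle.Q, u_in=bundle.u_in, A_in=bundle.A_in, frames_used=(i_a, i_b))
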