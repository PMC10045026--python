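"""Wall shear stress, wall shear force, TAWSS, OSI and y+.

The wall-gradient discretization is a one-sided first-order difference
between the no-slip wall (zero velocity) and a supplied near-wall sample
at distance ``d`` along the inward normal, mirroring a first-cell-center
evaluation in a low-Reynolds wall treatment.

Cycle integrals use periodic trapezoidal quadrature on a uniform grid
covering exactly one period: with samples at t_k = k T / n the rule
reduces to the plain sample mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hemodyn.fluids import FluidProperties

__all__ = [
    "FieldSnapshot",
    "WallPatch",
    "WSSHistory",
    "HemodynamicIndices",
    "compute_wss",
    "compute_wsf",
    "tawss",
    "osi",
    "yplus",
]


@dataclass
class FieldSnapshot:
    """Velocity (and optional pressure / turbulent kinetic energy)
    sampled at a point set at one instant.

    ``lattice_shape``/``lattice_spacing`` are set when the points form a
    structured lattice (row-major order), enabling finite-difference
    gradients downstream.
    """

    time: float
    points: np.ndarray  # (N, 3) m
    velocity: np.ndarray  # (N, 3) m/s
    pressure: np.ndarray | None = None  # (N,) Pa
    k: np.ndarray | None = None  # (N,) m^2/s^2
    lattice_shape: tuple[int, ...] | None = None
    lattice_spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.velocity = np.atleast_2d(np.asarray(self.velocity, dtype=float))
        if self.points.shape != self.velocity.shape or self.points.shape[1] != 3:
            raise ValueError("points and velocity must both be (N, 3)")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity contains non-finite values")
        for name in ("pressure", "k"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(self.points),):
                    raise ValueError(f"{name} must have one value per point")
                setattr(self, name, arr)


@dataclass
class WallPatch:
    """Discrete wall: per-face area, outward unit normal, wall point,
    the index of the paired near-wall sample, and the wall distance."""

    wall_points: np.ndarray  # (F, 3) m
    normals: np.ndarray  # (F, 3) unit outward
    areas: np.ndarray  # (F,) m^2
    distances: np.ndarray  # (F,) m
    near_indices: np.ndarray  # (F,) indices into FieldSnapshot points

    def __post_init__(self) -> None:
        self.wall_points = np.atleast_2d(np.asarray(self.wall_points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        self.distances = np.atleast_1d(np.asarray(self.distances, dtype=float))
        self.near_indices = np.atleast_1d(np.asarray(self.near_indices, dtype=int))
        f = len(self.wall_points)
        for name in ("normals", "areas", "distances", "near_indices"):
            if len(getattr(self, name)) != f:
                raise ValueError(f"{name} must have one entry per face")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("normals must be unit vectors")
        if np.any(self.areas <= 0):
            raise ValueError("face areas must be positive")
        if np.any(self.distances <= 0):
            raise ValueError("wall distances must be positive")

    @property
    def n_faces(self) -> int:
        return len(self.wall_points)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class WSSHistory:
    """Per-face WSS vector time series over exactly one period.

    ``wss`` is (n_faces, n_times, 3) Pa on a uniform grid
    t_k = k * period / n_times (the closing sample t = T is implied by
    periodicity and must not be included).
    """

    times: np.ndarray
    wss: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        if self.wss.ndim != 3 or self.wss.shape[2] != 3:
            raise ValueError("wss must be (n_faces, n_times, 3)")
        if self.wss.shape[1] != len(self.times):
            raise ValueError("time axis mismatch between times and wss")
        if len(self.times) < 4:
            raise ValueError("need at least 4 time samples per period")
        if self.period <= 0:
            raise ValueError("period must be positive")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.wss)):
            raise ValueError("wss contains non-finite values")

    @property
    def n_faces(self) -> int:
        return self.wss.shape[0]


@dataclass
class HemodynamicIndices:
    """Per-face cycle-averaged indices."""

    tawss: np.ndarray  # (F,) Pa
    osi: np.ndarray  # (F,) dimensionless

    def __post_init__(self) -> None:
        self.tawss = np.asarray(self.tawss, dtype=float)
        self.osi = np.asarray(self.osi, dtype=float)


def compute_wss(
    snapshot: FieldSnapshot,
    patch: WallPatch,
    fluid: FluidProperties,
    tangential: bool = False,
) -> np.ndarray:
    """Wall shear stress vectors, (F, 3) Pa.

    One-sided difference from the no-slip wall: WSS = mu * u_near / d,
    directed along the near-wall velocity. With ``tangential=True`` the
    wall-normal component is removed (tangential traction only).
    """
    v = snapshot.velocity[patch.near_indices]
    wss = fluid.viscosity * v / patch.distances[:, None]
    if tangential:
        wss = wss - (np.sum(wss * patch.normals, axis=1, keepdims=True)) * patch.normals
    return wss


def compute_wsf(wss: np.ndarray, patch: WallPatch) -> tuple[np.ndarray, float]:
    """Wall shear force: area-weighted sum of the WSS vectors.

    Returns the force vector (N) and its magnitude.
    """
    wss = np.atleast_2d(np.asarray(wss, dtype=float))
    if len(wss) != patch.n_faces:
        raise ValueError("one WSS vector per face required")
    force = np.sum(wss * patch.areas[:, None], axis=0)
    return force, float(np.linalg.norm(force))


def tawss(history: WSSHistory) -> np.ndarray:
    """Time-averaged WSS magnitude per face (periodic trapezoid = mean)."""
    return np.linalg.norm(history.wss, axis=2).mean(axis=1)


def osi(history: WSSHistory) -> np.ndarray:
    """Oscillatory shear index per face.

    OSI = 1/2 (1 - |mean WSS vector| / mean |WSS|), in [0, 0.5]. Faces
    with an identically zero history get OSI = 0 with a warning.
    """
    mean_vec = history.wss.mean(axis=1)
    mean_mag = np.linalg.norm(history.wss, axis=2).mean(axis=1)
    out = np.zeros(history.n_faces)
    dead = mean_mag == 0.0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} face(s) with identically zero WSS: OSI set to 0",
            stacklevel=2,
        )
    live = ~dead
    out[live] = 0.5 * (1.0 - np.linalg.norm(mean_vec[live], axis=1) / mean_mag[live])
    # guard tiny negative round-off
    return np.clip(out, 0.0, 0.5)


def indices_from_history(history: WSSHistory) -> HemodynamicIndices:
    """Convenience bundle of TAWSS and OSI."""
    return HemodynamicIndices(tawss=tawss(history), osi=osi(history))


def yplus(
    wss_magnitude: np.ndarray | float,
    wall_distance: np.ndarray | float,
    fluid: FluidProperties,
) -> np.ndarray | float:
    """Non-dimensional wall distance y+ = y * u_tau / nu with
    u_tau = sqrt(WSS / rho)."""
    tau = np.asarray(wss_magnitude, dtype=float)
    y = np.asarray(wall_distance, dtype=float)
    if np.any(tau < 0) or np.any(y < 0):
        raise ValueError("wss magnitude and wall distance must be >= 0")
    u_tau = np.sqrt(tau / fluid.density)
    result = y * u_tau / fluid.kinematic_viscosity
    return float(result) if result.ndim == 0 else result
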