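"""Velocity-gradient tensors, Q-criterion vortex identification,
turbulence intensity and axial-velocity / backflow diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from hemodyn.wall import FieldSnapshot

__all__ = [
    "GradientField",
    "velocity_gradient",
    "analytic_gradient",
    "q_criterion",
    "count_vortex_regions",
    "turbulence_intensity",
    "axial_backflow",
]


@dataclass
class GradientField:
    """Per-sample velocity-gradient tensors G[i, a, b] = d u_a / d x_b,
    with the symmetric (strain-rate) / antisymmetric (vorticity)
    decomposition available as properties."""

    tensors: np.ndarray  # (N, 3, 3) 1/s
    lattice_shape: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("tensors must be (N, 3, 3)")

    @property
    def strain(self) -> np.ndarray:
        """Symmetric part S."""
        return 0.5 * (self.tensors + np.swapaxes(self.tensors, 1, 2))

    @property
    def vorticity(self) -> np.ndarray:
        """Antisymmetric part Omega."""
        return 0.5 * (self.tensors - np.swapaxes(self.tensors, 1, 2))

    @property
    def divergence(self) -> np.ndarray:
        """trace(G); ~0 for incompressible fields."""
        return np.trace(self.tensors, axis1=1, axis2=2)


def velocity_gradient(snapshot: FieldSnapshot) -> GradientField:
    """Finite-difference gradient on a structured lattice.

    Central differences in the interior, one-sided second-order at the
    boundary (``numpy.gradient`` stencils). Rejects snapshots without lattice
    metadata: unstructured samples need the generator's analytic
    gradient callback instead.
    """
    if snapshot.lattice_shape is None or snapshot.lattice_spacing is None:
        raise ValueError(
            "snapshot has no lattice metadata; for unstructured samples "
            "use the analytic gradient supplied by the field generator"
        )
    shape = tuple(snapshot.lattice_shape)
    n = int(np.prod(shape))
    if len(snapshot.points) < n:
        raise ValueError("snapshot holds fewer points than the lattice shape")
    v = snapshot.velocity[:n].reshape(*shape, 3)
    tensors = np.zeros((n, 3, 3))
    for comp in range(3):
        grads = np.gradient(v[..., comp], *snapshot.lattice_spacing, edge_order=2)
        for axis in range(len(shape)):
            tensors[:, comp, axis] = grads[axis].reshape(-1)
    return GradientField(tensors=tensors, lattice_shape=shape)


def analytic_gradient(
    callback: Callable[[np.ndarray, float], np.ndarray],
    points: np.ndarray,
    t: float = 0.0,
) -> GradientField:
    """Exact gradients via a generator-supplied callback."""
    return GradientField(tensors=callback(np.atleast_2d(points), t))


def q_criterion(grad: GradientField) -> np.ndarray:
    """Second invariant Q = 1/2 (||Omega||_F^2 - ||S||_F^2) per sample.

    Vortexes are the connected regions with Q > 0.
    """
    s2 = np.sum(grad.strain**2, axis=(1, 2))
    o2 = np.sum(grad.vorticity**2, axis=(1, 2))
    return 0.5 * (o2 - s2)


def count_vortex_regions(
    q: np.ndarray,
    lattice_shape: tuple[int, ...],
    threshold: float = 0.0,
) -> int:
    """Number of connected Q > threshold regions (6-connectivity)."""
    field = np.asarray(q, dtype=float).reshape(lattice_shape)
    positive = field > threshold
    structure = ndimage.generate_binary_structure(field.ndim, 1)
    _, n = ndimage.label(positive, structure=structure)
    return int(n)


def turbulence_intensity(
    k: np.ndarray | float, speed: np.ndarray | float
) -> np.ndarray | float:
    """T = sqrt(2 k / 3) / |u|, dimensionless (multiply by 100 for %).

    Samples with zero speed are undefined and returned as NaN with a
    warning; they are excluded from threshold statistics.
    """
    k = np.asarray(k, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if np.any(k < 0):
        raise ValueError("turbulent kinetic energy must be >= 0")
    zero = speed == 0
    if np.any(zero):
        warnings.warn(
            "turbulence intensity undefined at zero-velocity samples (NaN)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(2.0 * k / 3.0) / speed
    out = np.where(zero, np.nan, out)
    return float(out) if out.ndim == 0 else out


def intensity_fraction_above(
    intensity: np.ndarray, threshold: float = 0.70
) -> float:
    """Fraction of defined samples with T > threshold (reporting
    convention for high-turbulence regions)."""
    t = np.asarray(intensity, dtype=float)
    valid = np.isfinite(t)
    if not valid.any():
        return 0.0
    return float(np.mean(t[valid] > threshold))


def axial_backflow(
    snapshot: FieldSnapshot, axis: np.ndarray = (0.0, 0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Axial velocity component u_axis = u . axis and the backflow mask
    (u_axis < 0)."""
    axis = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0):
        raise ValueError("axis must be a unit vector")
    u_ax = snapshot.velocity @ axis
    return u_ax, u_ax < 0
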