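"""Synthetic inputs for the whole pipeline.

Everything downstream is testable without external data: CT-like lumen
phantoms with exact ground truth, analytic pulsatile pipe flows with
closed-form wall shear and velocity-gradient references, physiologic
inlet waveforms and outlet flow-rate series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy.special import jv

from hemodyn.fluids import FluidProperties
from hemodyn.segmentation import Contour, ImageStack, boundary_pixels
from hemodyn.wall import FieldSnapshot, WallPatch

__all__ = [
    "LumenSpec",
    "PhantomSpec",
    "PhantomResult",
    "AnalyticFieldSpec",
    "AnalyticField",
    "gen_phantom_ct",
    "gen_analytic_field",
    "gen_inlet_waveform",
    "gen_outlet_flow",
]


# ---------------------------------------------------------------------------
# CT-like phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LumenSpec:
    """One elliptical lumen: center (row, col) at slice 0, per-slice
    center drift, semi-axes (row, col) in pixels, intensity level."""

    center: tuple[float, float]
    radii: tuple[float, float]
    intensity: float
    drift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.radii) <= 0:
            raise ValueError("lumen radii must be positive")

    def center_at(self, slice_index: int) -> tuple[float, float]:
        return (
            self.center[0] + slice_index * self.drift[0],
            self.center[1] + slice_index * self.drift[1],
        )


@dataclass(frozen=True)
class PhantomSpec:
    """CT-like acquisition of bright lumens on a dark background."""

    image_size: tuple[int, int] = (128, 128)
    n_slices: int = 4
    pixel_spacing: float = 0.8125  # mm
    slice_thickness: float = 1.5  # mm
    lumens: tuple[LumenSpec, ...] = ()
    background: float = 40.0
    noise_sd: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_spacing and slice_thickness must be positive")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if not self.lumens:
            raise ValueError("at least one lumen is required")
        for lum in self.lumens:
            if lum.intensity <= self.background:
                raise ValueError("lumen intensity must exceed the background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomResult:
    """Generated stack plus exact ground truth.

    ``truth_masks`` is the noiseless inside-lumen indicator (slice, row,
    col); ``truth_contours`` holds per slice the boundary-pixel contours
    of the truth mask (foreground pixels with a background 4-neighbor).
    """

    stack: ImageStack
    truth_masks: np.ndarray
    truth_contours: dict[int, list[Contour]]


def gen_phantom_ct(spec: PhantomSpec) -> PhantomResult:
    """Render the phantom; additive Gaussian noise clipped to bit depth."""
    nr, nc = spec.image_size
    vmax = 2**spec.bit_depth - 1
    rows, cols = np.mgrid[0:nr, 0:nc]
    rng = np.random.default_rng(spec.seed)

    images = np.empty((spec.n_slices, nr, nc), dtype=np.int32)
    masks = np.zeros((spec.n_slices, nr, nc), dtype=np.uint8)
    contours: dict[int, list[Contour]] = {}
    for s in range(spec.n_slices):
        clean = np.full((nr, nc), float(spec.background))
        for lum in spec.lumens:
            cr, cc = lum.center_at(s)
            ar, ac = lum.radii
            if cr - ar < 0 or cr + ar > nr - 1 or cc - ac < 0 or cc + ac > nc - 1:
                raise ValueError(
                    f"lumen at ({cr:.1f}, {cc:.1f}) with radii {lum.radii} "
                    f"leaves the {nr}x{nc} image on slice {s}"
                )
            inside = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0
            clean[inside] = lum.intensity
            masks[s][inside] = 1
        if spec.noise_sd > 0:
            clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
        images[s] = np.clip(np.rint(clean), 0, vmax).astype(np.int32)
        contours[s] = [Contour(boundary_pixels(masks[s]))] if masks[s].any() else []

    stack = ImageStack(
        intensities=images,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        bit_depth=spec.bit_depth,
    )
    return PhantomResult(stack=stack, truth_masks=masks, truth_contours=contours)


# ---------------------------------------------------------------------------
# analytic flow fields
# ---------------------------------------------------------------------------

FieldKind = Literal["poiseuille", "womersley", "rigid_rotation", "pure_shear"]


@dataclass(frozen=True)
class AnalyticFieldSpec:
    """Analytic velocity field on a cylinder (pipe kinds) or a cube
    lattice (rotation / shear kinds).

    For ``womersley``, ``harmonics`` lists (amplitude, phase, frequency)
    of the cross-section *mean* velocity; a zero-frequency harmonic is a
    steady Poiseuille contribution. ``rate`` is the rotation rate (rad/s)
    or the shear rate (1/s) for the linear kinds.
    """

    kind: FieldKind
    radius: float = 0.0175  # m
    mean_velocity: float = 0.25  # m/s (poiseuille)
    harmonics: tuple[tuple[float, float, float], ...] = ()
    rate: float = 1.0
    fluid: FluidProperties = FluidProperties()
    n_radial: int = 16
    n_theta: int = 16
    n_axial: int = 3
    n_time: int = 16
    period: float = 0.96  # s
    near_wall_distance: float | None = None  # default radius / 200
    turbulent_k: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.kind not in ("poiseuille", "womersley", "rigid_rotation", "pure_shear"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.kind == "womersley":
            if not self.harmonics:
                raise ValueError("womersley requires at least one harmonic")
            if self.n_time < 2:
                raise ValueError("unsteady fields need n_time >= 2")


@dataclass
class AnalyticField:
    """Sampled snapshots plus closed-form references.

    ``ref_wall_shear`` is (n_faces, n_times, 3) Pa (None for the linear
    kinds, whose viscous wall traction is not represented by a one-sided
    difference); ``gradient`` maps (points (N,3), t) to exact velocity
    gradient tensors (N, 3, 3) with G[i, a, b] = d u_a / d x_b.
    """

    spec: AnalyticFieldSpec
    times: np.ndarray
    snapshots: list[FieldSnapshot]
    wall: WallPatch
    ref_wall_shear: np.ndarray | None
    gradient: Callable[[np.ndarray, float], np.ndarray]
    velocity: Callable[[np.ndarray, float], np.ndarray]


def _womersley_terms(
    spec: AnalyticFieldSpec,
) -> list[tuple[complex, float, Callable, Callable]]:
    """Per harmonic: complex amplitude A e^{i phi}, angular frequency,
    normalized radial profile h(r) (cross-section mean 1, complex) and
    its derivative h'(r)."""
    terms = []
    nu = spec.fluid.kinematic_viscosity
    R = spec.radius
    for amp, phase, freq in spec.harmonics:
        a = amp * np.exp(1j * phase)
        omega = 2 * np.pi * freq
        if freq == 0:
            # steady limit: parabolic profile, mean 1
            h = lambda r, R=R: 2.0 * (1.0 - (r / R) ** 2) + 0j
            dh = lambda r, R=R: -4.0 * r / R**2 + 0j
            terms.append((a, 0.0, h, dh))
            continue
        alpha = R * np.sqrt(omega / nu)  # Womersley number
        beta = alpha * np.exp(1j * 3 * np.pi / 4)  # i^{3/2} alpha
        j0b = jv(0, beta)
        gbar = 1.0 - 2.0 * jv(1, beta) / (beta * j0b)

        def h(r, beta=beta, j0b=j0b, gbar=gbar, R=R):
            return (1.0 - jv(0, beta * r / R) / j0b) / gbar

        def dh(r, beta=beta, j0b=j0b, gbar=gbar, R=R):
            return (beta / R) * jv(1, beta * r / R) / j0b / gbar

        terms.append((a, omega, h, dh))
    return terms


def gen_analytic_field(spec: AnalyticFieldSpec) -> AnalyticField:
    """Build snapshots, a wall patch and closed-form references."""
    if spec.kind in ("poiseuille", "womersley"):
        return _gen_pipe_field(spec)
    return _gen_linear_field(spec)


def _pipe_axial_velocity(spec: AnalyticFieldSpec):
    """Return u(r, t) and du/dr(r, t) for the axial pipe kinds."""
    if spec.kind == "poiseuille":
        u_max = 2.0 * spec.mean_velocity

        def u(r, t):
            return u_max * (1.0 - (r / spec.radius) ** 2)

        def dudr(r, t):
            return -2.0 * u_max * r / spec.radius**2

        return u, dudr

    terms = _womersley_terms(spec)

    def u(r, t):
        total = np.zeros_like(np.asarray(r, dtype=float))
        for a, omega, h, _ in terms:
            total = total + np.real(a * h(r) * np.exp(1j * omega * t))
        return total

    def dudr(r, t):
        total = np.zeros_like(np.asarray(r, dtype=float))
        for a, omega, _, dh in terms:
            total = total + np.real(a * dh(r) * np.exp(1j * omega * t))
        return total

    return u, dudr


def _gen_pipe_field(spec: AnalyticFieldSpec) -> AnalyticField:
    R = spec.radius
    d = spec.near_wall_distance if spec.near_wall_distance is not None else R / 200.0
    if not 0 < d < R:
        raise ValueError("near_wall_distance must lie in (0, radius)")
    u_of_r, dudr = _pipe_axial_velocity(spec)

    theta = np.linspace(0.0, 2 * np.pi, spec.n_theta, endpoint=False)
    z_levels = np.arange(spec.n_axial) * (R / max(spec.n_axial - 1, 1))
    radii = np.linspace(0.0, R * (1.0 - 2.0 / spec.n_radial), spec.n_radial)

    # interior samples: rings at each (r, z)
    interior = []
    for z in z_levels:
        for r in radii:
            interior.append(
                np.column_stack(
                    [r * np.cos(theta), r * np.sin(theta), np.full_like(theta, z)]
                )
            )
    interior_pts = np.vstack(interior)

    # wall faces: one ring of faces per axial level
    wall_pts, normals, near_pts = [], [], []
    for z in z_levels:
        wall_pts.append(
            np.column_stack(
                [R * np.cos(theta), R * np.sin(theta), np.full_like(theta, z)]
            )
        )
        normals.append(
            np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        )
        near_pts.append(
            np.column_stack(
                [
                    (R - d) * np.cos(theta),
                    (R - d) * np.sin(theta),
                    np.full_like(theta, z),
                ]
            )
        )
    wall_pts = np.vstack(wall_pts)
    normals = np.vstack(normals)
    near_pts = np.vstack(near_pts)
    n_faces = len(wall_pts)
    dz = R / max(spec.n_axial - 1, 1)
    face_area = (2 * np.pi * R / spec.n_theta) * dz

    points = np.vstack([interior_pts, near_pts])
    near_indices = np.arange(len(interior_pts), len(points))
    patch = WallPatch(
        wall_points=wall_pts,
        normals=normals,
        areas=np.full(n_faces, face_area),
        distances=np.full(n_faces, d),
        near_indices=near_indices,
    )

    steady = spec.kind == "poiseuille"
    n_time = 1 if steady else spec.n_time
    times = (
        np.zeros(1)
        if steady
        else np.arange(n_time) * (spec.period / n_time)
    )

    def velocity(pts: np.ndarray, t: float) -> np.ndarray:
        pts = np.atleast_2d(pts)
        r = np.hypot(pts[:, 0], pts[:, 1])
        v = np.zeros_like(pts)
        v[:, 2] = u_of_r(r, t)
        return v

    def gradient(pts: np.ndarray, t: float) -> np.ndarray:
        pts = np.atleast_2d(pts)
        r = np.hypot(pts[:, 0], pts[:, 1])
        g = np.zeros((len(pts), 3, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r > 0, pts[:, 0] / r, 0.0)
            uy = np.where(r > 0, pts[:, 1] / r, 0.0)
        du = dudr(r, t)
        g[:, 2, 0] = du * ux  # d u_z / d x
        g[:, 2, 1] = du * uy  # d u_z / d y
        return g

    snapshots = []
    for t in times:
        v = velocity(points, float(t))
        k_arr = np.full(len(points), spec.turbulent_k) if spec.turbulent_k else None
        snapshots.append(
            FieldSnapshot(time=float(t), points=points, velocity=v, k=k_arr)
        )

    # closed-form wall shear: axial traction mu * (-du/dr at R), along +z
    ref = np.zeros((n_faces, n_time, 3))
    for j, t in enumerate(times):
        tau = -spec.fluid.viscosity * dudr(np.full(n_faces, R), float(t))
        ref[:, j, 2] = tau
    return AnalyticField(
        spec=spec,
        times=times,
        snapshots=snapshots,
        wall=patch,
        ref_wall_shear=ref,
        gradient=gradient,
        velocity=velocity,
    )


def _gen_linear_field(spec: AnalyticFieldSpec) -> AnalyticField:
    """Rigid rotation (u = omega x r) or pure shear (u_x = gamma * y) on
    a cubic lattice of side 2R centered at the origin."""
    n = max(spec.n_radial, 3)
    axis = np.linspace(-spec.radius, spec.radius, n)
    spacing = axis[1] - axis[0]
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rate = spec.rate

    if spec.kind == "rigid_rotation":

        def velocity(pts, t):
            pts = np.atleast_2d(pts)
            return np.column_stack(
                [-rate * pts[:, 1], rate * pts[:, 0], np.zeros(len(pts))]
            )

        tensor = np.array([[0.0, -rate, 0.0], [rate, 0.0, 0.0], [0.0, 0.0, 0.0]])
    else:  # pure_shear

        def velocity(pts, t):
            pts = np.atleast_2d(pts)
            return np.column_stack(
                [rate * pts[:, 1], np.zeros(len(pts)), np.zeros(len(pts))]
            )

        tensor = np.array([[0.0, rate, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])

    def gradient(pts, t):
        pts = np.atleast_2d(pts)
        return np.broadcast_to(tensor, (len(pts), 3, 3)).copy()

    snapshot = FieldSnapshot(
        time=0.0,
        points=points,
        velocity=velocity(points, 0.0),
        k=np.full(len(points), spec.turbulent_k) if spec.turbulent_k else None,
        lattice_shape=(n, n, n),
        lattice_spacing=(spacing, spacing, spacing),
    )
    # token wall patch on the lattice boundary plane x = +R (not a no-slip
    # wall; ref_wall_shear is None for these kinds)
    face_ids = np.arange(len(points))[np.isclose(points[:, 0], spec.radius)][:4]
    patch = WallPatch(
        wall_points=points[face_ids] + [spacing, 0.0, 0.0],
        normals=np.tile([1.0, 0.0, 0.0], (len(face_ids), 1)),
        areas=np.full(len(face_ids), spacing**2),
        distances=np.full(len(face_ids), spacing),
        near_indices=face_ids,
    )
    return AnalyticField(
        spec=spec,
        times=np.zeros(1),
        snapshots=[snapshot],
        wall=patch,
        ref_wall_shear=None,
        gradient=gradient,
        velocity=velocity,
    )


# ---------------------------------------------------------------------------
# inlet waveform and outlet flows
# ---------------------------------------------------------------------------


@dataclass
class SampledWaveformData:
    """Uniformly sampled periodic waveform (times in [0, T))."""

    times: np.ndarray
    values: np.ndarray
    period: float


def gen_inlet_waveform(
    period: float = 0.96,
    peak: float = 0.5,
    mean_velocity: float = 0.104,
    backflow_depth: float = 0.05,
    n_samples: int = 128,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SampledWaveformData:
    """Physiologic inlet velocity waveform.

    A systolic squared-sine pulse plus a diastolic dip, scaled so that on
    the sample grid the maximum equals ``peak``, the mean equals
    ``mean_velocity`` and the minimum equals ``-backflow_depth`` (a
    baseline offset takes up the slack). Raises when the constraints are
    infeasible. ``noise_sd`` adds seeded Gaussian jitter (off by
    default; the summary constraints are then only approximate).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0 < mean_velocity < peak:
        raise ValueError("require 0 < mean_velocity < peak")
    if backflow_depth < 0:
        raise ValueError("backflow_depth must be >= 0")
    if n_samples < 8:
        raise ValueError("need at least 8 samples")

    t = np.arange(n_samples) * (period / n_samples)
    ts = 0.35 * period  # systolic duration
    td = 0.25 * period  # dip duration
    pulse = np.where(t < ts, np.sin(np.pi * t / ts) ** 2, 0.0)
    in_dip = (t >= ts) & (t < ts + td)
    dip = np.where(in_dip, np.sin(np.pi * (t - ts) / td) ** 2, 0.0)

    p_max, p_mean = pulse.max(), pulse.mean()
    d_max, d_mean = dip.max(), dip.mean()
    # solve a*pulse - b*dip + c for max=peak, min=-backflow, mean=mean
    denom = 1.0 - p_mean / p_max - d_mean / d_max
    c = (
        mean_velocity
        - peak * p_mean / p_max
        + backflow_depth * d_mean / d_max
    ) / denom
    a = (peak - c) / p_max
    b = (backflow_depth + c) / d_max
    if a <= 0 or b < 0:
        raise ValueError(
            "infeasible waveform constraints: "
            f"peak={peak}, mean={mean_velocity}, backflow={backflow_depth}"
        )
    values = a * pulse - b * dip + c
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    if noise_sd == 0:
        if abs(values.max() - peak) > 0.02 * peak:
            raise ValueError("waveform construction failed to hit the peak")
        if abs(values.mean() - mean_velocity) > 0.02 * mean_velocity:
            raise ValueError("waveform construction failed to hit the mean")
        if backflow_depth > 0 and values.min() >= 0:
            raise ValueError("waveform construction failed to produce backflow")
    return SampledWaveformData(times=t, values=values, period=period)


def gen_outlet_flow(
    kind: Literal["constant", "half_sine"] = "half_sine",
    level: float = 1e-4,
    amplitude: float = 3e-4,
    systole_fraction: float = 0.35,
    period: float = 0.96,
    n_samples: int = 128,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SampledWaveformData:
    """Outlet volume flow series in m^3/s.

    ``constant``: all samples equal ``level``. ``half_sine``: a systolic
    half-sine pulse of the given amplitude on top of ``level``, zero
    added flow in diastole; its pulse integral is
    amplitude * systole_fraction * period * 2 / pi.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    t = np.arange(n_samples) * (period / n_samples)
    if kind == "constant":
        q = np.full(n_samples, float(level))
    elif kind == "half_sine":
        ts = systole_fraction * period
        q = level + np.where(t < ts, amplitude * np.sin(np.pi * t / ts), 0.0)
    else:
        raise ValueError(f"unknown outlet flow kind {kind!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=q.shape)
    return SampledWaveformData(times=t, values=q, period=period)


# ---------------------------------------------------------------------------
# text-format writers (stacks, fields, series)
# ---------------------------------------------------------------------------


def write_phantom(result: PhantomResult, outdir: str | Path) -> None:
    """Write slices as PNG, truth masks as PNG, contours as CSV, and a
    JSON metadata sidecar."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = result.stack
    mode = "I;16" if stack.bit_depth > 8 else "L"
    dtype = np.uint16 if stack.bit_depth > 8 else np.uint8
    for s in range(stack.n_slices):
        Image.fromarray(stack.intensities[s].astype(dtype), mode=mode).save(
            outdir / f"slice_{s:04d}.png"
        )
        Image.fromarray((result.truth_masks[s] * 255).astype(np.uint8)).save(
            outdir / f"truth_{s:04d}.png"
        )
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(
            {
                "pixel_spacing_mm": stack.pixel_spacing,
                "slice_thickness_mm": stack.slice_thickness,
                "bit_depth": stack.bit_depth,
                "n_slices": stack.n_slices,
            },
            fh,
            indent=2,
        )
    with open(outdir / "truth_contours.csv", "w") as fh:
        fh.write("slice,row,col\n")
        for s, contour_list in sorted(result.truth_contours.items()):
            for contour in contour_list:
                for r, c in contour.pixels:
                    fh.write(f"{s},{r},{c}\n")


def write_series_csv(series: SampledWaveformData, path: str | Path) -> None:
    """Two-column (t, value) CSV."""
    with open(path, "w") as fh:
        fh.write("t,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.9g},{v:.9g}\n")


def read_series_csv(path: str | Path, period: float | None = None) -> SampledWaveformData:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = data[:, 0], data[:, 1]
    if period is None:
        period = float(t[-1] + (t[1] - t[0]))
    return SampledWaveformData(times=t, values=v, period=period)
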