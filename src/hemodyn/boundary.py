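"""Inlet/outlet boundary-condition mathematics.

Harmonic (trigonometric least-squares) interpolation of the sampled
inlet waveform, the 3-element Windkessel outflow model integrated with
the explicit Euler method, Windkessel parameter estimation from a target
mean pressure, k-epsilon turbulence initialization and Reynolds-number
bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hemodyn.fluids import PA_PER_MMHG, FluidProperties

__all__ = [
    "SampledWaveform",
    "FourierSeries",
    "WindkesselParams",
    "OutletSeries",
    "TurbulenceInitState",
    "fit_fourier",
    "eval_fourier",
    "wk3_integrate",
    "wk3_estimate",
    "init_turbulence",
    "reynolds",
]


@dataclass
class SampledWaveform:
    """Sampled periodic velocity waveform; times strictly increasing in
    [0, T)."""

    times: np.ndarray  # s
    values: np.ndarray  # m/s
    period: float  # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if len(self.times) < 4:
            raise ValueError("need at least 4 samples")
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ValueError("times must lie within [0, period)")


@dataclass
class FourierSeries:
    """Truncated trigonometric series
    u(t) = a0 + sum_k a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T)."""

    period: float
    a0: float
    cos_coeffs: np.ndarray  # a_k, k = 1..N
    sin_coeffs: np.ndarray  # b_k

    def __post_init__(self) -> None:
        self.cos_coeffs = np.atleast_1d(np.asarray(self.cos_coeffs, dtype=float))
        self.sin_coeffs = np.atleast_1d(np.asarray(self.sin_coeffs, dtype=float))
        if self.period <= 0:
            raise ValueError("period must be positive")
        if len(self.cos_coeffs) != len(self.sin_coeffs):
            raise ValueError("cos/sin coefficient count mismatch")
        if len(self.cos_coeffs) < 1:
            raise ValueError("need at least one harmonic")

    @property
    def n_modes(self) -> int:
        return len(self.cos_coeffs)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.hypot(self.cos_coeffs, self.sin_coeffs)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "period": self.period,
                    "a0": self.a0,
                    "cos_coeffs": self.cos_coeffs.tolist(),
                    "sin_coeffs": self.sin_coeffs.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "FourierSeries":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["period"], d["a0"], d["cos_coeffs"], d["sin_coeffs"])


def _design_matrix(times: np.ndarray, period: float, n_modes: int) -> np.ndarray:
    w = 2 * np.pi / period
    cols = [np.ones_like(times)]
    for k in range(1, n_modes + 1):
        cols.append(np.cos(k * w * times))
        cols.append(np.sin(k * w * times))
    return np.column_stack(cols)


def fit_fourier(
    waveform: SampledWaveform, n_modes: int = 8
) -> tuple[FourierSeries, float]:
    """Least-squares trigonometric fit at multiples of 1/T.

    Returns the fitted series and the coefficient of determination
    R^2 = 1 - SS_res / SS_tot. On a uniform grid this reduces to the
    discrete Fourier transform truncated to ``n_modes`` harmonics.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    n = len(waveform.times)
    if 2 * n_modes + 1 > n:
        raise ValueError(
            f"{n_modes} modes need {2 * n_modes + 1} samples, got {n}"
        )
    X = _design_matrix(waveform.times, waveform.period, n_modes)
    coeffs, *_ = np.linalg.lstsq(X, waveform.values, rcond=None)
    fitted = X @ coeffs
    ss_res = float(np.sum((waveform.values - fitted) ** 2))
    ss_tot = float(np.sum((waveform.values - waveform.values.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    series = FourierSeries(
        period=waveform.period,
        a0=float(coeffs[0]),
        cos_coeffs=coeffs[1::2],
        sin_coeffs=coeffs[2::2],
    )
    return series, r2


def eval_fourier(series: FourierSeries, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the series; exactly T-periodic by reducing t mod T."""
    t = np.asarray(t, dtype=float)
    tm = np.mod(t, series.period)
    w = 2 * np.pi / series.period
    out = np.full_like(tm, series.a0, dtype=float)
    for k in range(1, series.n_modes + 1):
        out += series.cos_coeffs[k - 1] * np.cos(k * w * tm)
        out += series.sin_coeffs[k - 1] * np.sin(k * w * tm)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# 3-element Windkessel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindkesselParams:
    """Proximal resistance R1, distal resistance R2 (Pa.s/m^3) and
    compliance C (m^3/Pa)."""

    r1: float
    r2: float
    c: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0 or self.c <= 0:
            raise ValueError("R1, R2 and C must all be positive")

    @property
    def total_resistance(self) -> float:
        return self.r1 + self.r2

    @property
    def time_constant(self) -> float:
        return self.r2 * self.c

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"R1": self.r1, "R2": self.r2, "C": self.c}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "WindkesselParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["R1"], d["R2"], d["C"])


@dataclass
class OutletSeries:
    """Coupled flow/pressure series at one outlet on a uniform grid."""

    times: np.ndarray  # s
    flow: np.ndarray  # m^3/s
    pressure: np.ndarray  # Pa
    label: str = "O1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if not len(self.times) == len(self.flow) == len(self.pressure):
            raise ValueError("times, flow and pressure must share a length")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-14):
            raise ValueError("time step must be uniform")


def wk3_integrate(
    params: WindkesselParams,
    flow: np.ndarray,
    dt: float,
    p_initial: float = 0.0,
    n_cycles: int = 1,
    label: str = "O1",
) -> OutletSeries:
    """Explicit-Euler integration of the 3-element Windkessel.

    The model is integrated in the distal pressure p2 = p - R1 Q:
    dp2/dt = Q/C - p2/(R2 C), then p = p2 + R1 Q. ``flow`` holds one
    cycle of Q samples at spacing ``dt`` and is tiled over ``n_cycles``.
    ``p_initial`` is the initial distal (compliance) pressure
    p2(0) = p(0) - R1 Q(0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= 2.0 * params.time_constant:
        raise ValueError(
            f"dt={dt:g} exceeds the explicit-Euler stability bound "
            f"2 R2 C = {2 * params.time_constant:g}"
        )
    q_cycle = np.asarray(flow, dtype=float)
    if q_cycle.ndim != 1 or len(q_cycle) < 1:
        raise ValueError("flow must be a 1D sample array")
    q = np.tile(q_cycle, n_cycles)
    n = len(q)
    p2 = np.empty(n)
    p2[0] = p_initial
    inv_tau = 1.0 / params.time_constant
    for i in range(n - 1):
        p2[i + 1] = p2[i] + dt * (q[i] / params.c - p2[i] * inv_tau)
    pressure = p2 + params.r1 * q
    times = np.arange(n) * dt
    return OutletSeries(times=times, flow=q, pressure=pressure, label=label)


def wk3_estimate(
    target_mean_pressure: float,
    flow: np.ndarray,
    period: float,
    r1_fraction: float = 0.1,
    time_constant_fraction: float = 0.35,
) -> WindkesselParams:
    """Estimate Windkessel constants from a target cycle-mean pressure.

    Total resistance RT = target / mean(Q); R1 = r1_fraction * RT;
    R2 = RT - R1; C = time_constant_fraction * period / R2.
    """
    q = np.asarray(flow, dtype=float)
    q_mean = float(q.mean())
    if q_mean <= 0:
        raise ValueError("mean flow must be positive for estimation")
    if not 0 < r1_fraction < 1:
        raise ValueError("r1_fraction must lie in (0, 1)")
    if time_constant_fraction <= 0:
        raise ValueError("time_constant_fraction must be positive")
    if target_mean_pressure <= 0:
        raise ValueError("target mean pressure must be positive")
    rt = target_mean_pressure / q_mean
    r1 = r1_fraction * rt
    r2 = rt - r1
    c = time_constant_fraction * period / r2
    return WindkesselParams(r1=r1, r2=r2, c=c)


# ---------------------------------------------------------------------------
# turbulence initialization and Reynolds number
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurbulenceInitState:
    """k-epsilon initialization bundle (kinematic turbulent viscosity)."""

    k: float  # m^2/s^2
    epsilon: float  # m^2/s^3
    nu_t: float  # m^2/s
    length_scale: float  # m
    c_mu: float = 0.09


def init_turbulence(
    u0_max: float,
    diameter: float,
    fluid: FluidProperties = FluidProperties(),
    c_mu: float = 0.09,
    dynamic: bool = False,
) -> TurbulenceInitState:
    """Initial turbulence state from the peak inlet velocity.

    k = u0_max^2 / 2; L = 0.038 D; epsilon = c_mu^0.75 k^1.5 / L;
    nu_t = c_mu k^2 / epsilon. ``dynamic=True`` returns the dynamic
    turbulent viscosity mu_t = rho * nu_t in the ``nu_t`` slot.
    """
    if u0_max <= 0 or diameter <= 0:
        raise ValueError("u0_max and diameter must be positive")
    k = 0.5 * u0_max**2
    length = 0.038 * diameter
    epsilon = c_mu**0.75 * k**1.5 / length
    nu_t = c_mu * k**2 / epsilon
    if dynamic:
        nu_t *= fluid.density
    return TurbulenceInitState(
        k=k, epsilon=epsilon, nu_t=nu_t, length_scale=length, c_mu=c_mu
    )


def reynolds(
    velocity: float,
    diameter: float,
    fluid: FluidProperties = FluidProperties(),
) -> float:
    """Re = u rho D / mu."""
    if velocity < 0:
        raise ValueError("velocity must be >= 0")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return velocity * fluid.density * diameter / fluid.viscosity


def mmhg_to_pa(mmhg: float) -> float:
    return mmhg * PA_PER_MMHG


def pa_to_mmhg(pa: float) -> float:
    return pa / PA_PER_MMHG
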