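"""Scalar verification and comparison statistics.

Cycle-to-cycle convergence error of a surface-averaged pressure,
mesh-sensitivity of the wall shear force, per-outlet volume-flow
distribution shares with relative perfusion changes against a baseline
geometry, and cycle-averaged pressure drops.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from hemodyn.fluids import PA_PER_MMHG

__all__ = [
    "PressureSeries",
    "WSFSeries",
    "FlowDistribution",
    "cycle_convergence",
    "mesh_sensitivity_wsf",
    "flow_distribution",
    "relative_change",
    "mean_pressure_drop",
    "load_flow_distribution_table",
    "OUTLET_GROUPS",
]

#: Grouped reporting roles: superior, abdominal and iliac branches.
OUTLET_GROUPS = {
    "superior": tuple(f"O{i}" for i in range(1, 6)),
    "abdominal": tuple(f"O{i}" for i in range(6, 13)),
    "iliac": tuple(f"O{i}" for i in range(13, 17)),
}


@dataclass
class PressureSeries:
    """Area-averaged surface pressure on a uniform time grid."""

    times: np.ndarray  # s
    values: np.ndarray  # Pa
    period: float  # s
    label: str = "I"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if self.period <= 0:
            raise ValueError("period must be positive")
        dt = np.diff(self.times)
        if dt.size == 0:
            raise ValueError("need at least 2 samples")
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-14):
            raise ValueError("time grid must be uniform")
        self.dt = float(dt[0])

    @property
    def samples_per_cycle(self) -> int:
        ns = self.period / self.dt
        if abs(ns - round(ns)) > 1e-6:
            raise ValueError("period must be an integer multiple of the time step")
        return int(round(ns))


@dataclass
class WSFSeries:
    """Wall-shear-force magnitude over one cycle for one grid."""

    times: np.ndarray  # s
    values: np.ndarray  # N
    grid: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-14):
            raise ValueError("time grid must be uniform")


@dataclass
class FlowDistribution:
    """Per-outlet share of the inlet volume flow, in percent."""

    shares: dict[str, float]
    geometry: str = ""

    def __post_init__(self) -> None:
        for outlet, share in self.shares.items():
            if share < 0:
                warnings.warn(
                    f"negative share at {outlet} (net backflow)", stacklevel=2
                )
        total = sum(self.shares.values())
        if total > 100.0 + 0.5:
            raise ValueError(f"shares sum to {total:.2f}% > 100%")

    def group_shares(self) -> dict[str, float]:
        return {
            name: sum(self.shares.get(o, 0.0) for o in outlets)
            for name, outlets in OUTLET_GROUPS.items()
        }


def cycle_convergence(series: PressureSeries) -> float:
    """Mean relative cycle-to-cycle pressure change over the last cycle.

    Delta_T = (1/Ns) sum_l |P(t_l) - P(t_l - T)| / |P(t_l)| where the
    t_l are the Ns samples of the final cycle. Each summand is taken in
    absolute value.
    """
    ns = series.samples_per_cycle
    if len(series.values) < 2 * ns:
        raise ValueError("series must cover at least 2 full cycles")
    cur = series.values[-ns:]
    prev = series.values[-2 * ns : -ns]
    if np.any(cur == 0):
        raise ValueError("zero pressure sample: relative error undefined")
    return float(np.mean(np.abs(cur - prev) / np.abs(cur)))


def cycle_convergence_history(series: PressureSeries) -> np.ndarray:
    """Convergence error for every consecutive cycle pair."""
    ns = series.samples_per_cycle
    n_cycles = len(series.values) // ns
    if n_cycles < 2:
        raise ValueError("series must cover at least 2 full cycles")
    out = []
    for c in range(1, n_cycles):
        cur = series.values[c * ns : (c + 1) * ns]
        prev = series.values[(c - 1) * ns : c * ns]
        out.append(float(np.mean(np.abs(cur - prev) / np.abs(cur))))
    return np.array(out)


def mesh_sensitivity_wsf(reference: WSFSeries, other: WSFSeries) -> float:
    """Mean absolute WSF difference normalized by the reference range.

    Delta_WSF = (1/Ns) sum_l |WSF_j(t_l) - WSF_m(t_l)| /
    (max WSF_j - min WSF_j). The first argument supplies the
    normalizing range, so the metric is asymmetric: pass the finer
    (reference) grid first.
    """
    if len(reference.values) != len(other.values) or not np.allclose(
        reference.times, other.times, rtol=1e-8, atol=1e-12
    ):
        raise ValueError("series must share the same time base")
    rng = float(reference.values.max() - reference.values.min())
    if rng == 0:
        raise ValueError("flat reference series: range normalization undefined")
    return float(np.mean(np.abs(reference.values - other.values)) / rng)


def flow_distribution(
    outlet_volumes: dict[str, float],
    inlet_volume: float,
    geometry: str = "",
) -> FlowDistribution:
    """Per-outlet percentage shares of the inlet cycle volume."""
    if inlet_volume <= 0:
        raise ValueError("inlet volume must be positive")
    shares = {o: 100.0 * v / inlet_volume for o, v in outlet_volumes.items()}
    return FlowDistribution(shares=shares, geometry=geometry)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class ShareChange:
    """Signed percentage change of one outlet share versus baseline;
    positive values are reductions."""

    raw: float
    rounded: int


def relative_change(
    dist: FlowDistribution, baseline: FlowDistribution
) -> dict[str, ShareChange]:
    """Per-outlet perfusion change relative to a baseline geometry.

    change = 100 * (1 - share / baseline_share); positive = reduction,
    negative = increase. Outlets missing from the baseline are skipped
    with a warning. Rounded values use half-away-from-zero.
    """
    out: dict[str, ShareChange] = {}
    for outlet, share in dist.shares.items():
        base = baseline.shares.get(outlet)
        if base is None or base <= 0:
            warnings.warn(
                f"outlet {outlet} missing from baseline; skipped", stacklevel=2
            )
            continue
        raw = 100.0 * (1.0 - share / base)
        out[outlet] = ShareChange(raw=raw, rounded=_round_half_away(raw))
    return out


def mean_pressure_drop(
    series_in: PressureSeries, series_out: PressureSeries
) -> float:
    """Cycle-averaged pressure drop <P_in - P_out> in mmHg."""
    if len(series_in.values) != len(series_out.values) or not np.allclose(
        series_in.times, series_out.times, rtol=1e-8, atol=1e-12
    ):
        raise ValueError("series must share the same time base")
    return float(np.mean(series_in.values - series_out.values) / PA_PER_MMHG)


def load_flow_distribution_table(
    path: str | Path | None = None,
) -> dict[str, FlowDistribution]:
    """Load per-geometry outlet shares from CSV.

    Layout: rows = geometry (HA/FPA/PTA/FTA), columns = O1..O16, "-"
    for outlets absent in a geometry. With no ``path``, the packaged
    reference table ships with the library.
    """
    if path is None:
        ref = resources.files("hemodyn.data") / "flow_shares.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, na_values=["-"])
    else:
        df = pd.read_csv(path, na_values=["-"])
    out: dict[str, FlowDistribution] = {}
    for _, row in df.iterrows():
        shares = {
            col: float(row[col])
            for col in df.columns
            if col != "geometry" and pd.notna(row[col])
        }
        out[str(row["geometry"])] = FlowDistribution(
            shares=shares, geometry=str(row["geometry"])
        )
    return out
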