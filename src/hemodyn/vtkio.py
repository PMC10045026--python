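"""Minimal legacy-ASCII VTK I/O plus PLY/XYZ point-cloud writers.

Only the subset needed by this toolkit is supported: unstructured point
sets (VTK ``UNSTRUCTURED_GRID`` with vertex cells) carrying named scalar
or 3-vector point-data arrays. Files are plain text and round-trip
through :func:`read_vtk_points`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "write_vtk_points",
    "read_vtk_points",
    "write_snapshot_vtk",
    "read_snapshot_vtk",
    "write_ply",
    "write_xyz",
]


def write_vtk_points(
    path: str | Path,
    points: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    comment: str = "hemodyn point set",
) -> None:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        comment,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}" for p in points]
    lines.append(f"CELLS {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    lines.append(f"CELL_TYPES {n}")
    lines += ["1"] * n  # VTK_VERTEX
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}" for v in arr]
            else:
                raise ValueError(f"array {name!r} must be (N,) or (N, 3)")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_points(
    path: str | Path,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read back a file written by :func:`write_vtk_points`."""
    tokens = Path(path).read_text().split("\n")
    i = 0
    points = None
    data: dict[str, np.ndarray] = {}
    n = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            block = [tokens[i + 1 + j].split() for j in range(n)]
            points = np.array(block, dtype=float)
            i += n + 1
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = [float(tokens[i + 2 + j]) for j in range(n)]
            data[name] = np.array(vals)
            i += n + 2
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            block = [tokens[i + 1 + j].split() for j in range(n)]
            data[name] = np.array(block, dtype=float)
            i += n + 1
        else:
            i += 1
    if points is None:
        raise ValueError(f"no POINTS section found in {path}")
    return points, data


def write_snapshot_vtk(path: str | Path, snapshot) -> None:
    """Write a :class:`~hemodyn.wall.FieldSnapshot` with its named
    arrays ("velocity", optional "pressure", "k")."""
    point_data: dict[str, np.ndarray] = {"velocity": snapshot.velocity}
    if snapshot.pressure is not None:
        point_data["pressure"] = snapshot.pressure
    if snapshot.k is not None:
        point_data["k"] = snapshot.k
    write_vtk_points(
        path, snapshot.points, point_data, comment=f"t={snapshot.time:.9g}"
    )


def read_snapshot_vtk(path: str | Path):
    """Read a snapshot written by :func:`write_snapshot_vtk`."""
    from hemodyn.wall import FieldSnapshot

    text = Path(path).read_text().split("\n")
    time = 0.0
    if len(text) > 1 and text[1].startswith("t="):
        time = float(text[1][2:])
    points, data = read_vtk_points(path)
    return FieldSnapshot(
        time=time,
        points=points,
        velocity=data["velocity"],
        pressure=data.get("pressure"),
        k=data.get("k"),
    )


def write_ply(path: str | Path, points: np.ndarray) -> None:
    """ASCII PLY point cloud."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(points)}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    body = [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in points]
    Path(path).write_text("\n".join(header + body) + "\n")


def write_xyz(path: str | Path, points: np.ndarray) -> None:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    Path(path).write_text(
        "\n".join(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in points) + "\n"
    )
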