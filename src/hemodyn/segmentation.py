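"""Minimally supervised lumen segmentation of CT-like image stacks.

The chain is: crop to a region of interest, histogram equalization,
an optional adaptive-threshold smoothing filter, binarization,
Moore-neighbor boundary tracing with Jacob's stopping criterion, and
assembly of the per-slice contours into a 3D point cloud in physical
(mm) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "RegionOfInterest",
    "Contour",
    "PointCloud3D",
    "SegmentationConfig",
    "equalize",
    "adaptive_smooth",
    "binarize",
    "boundary_pixels",
    "trace_boundary",
    "stack_to_cloud",
    "segment_pipeline",
]


@dataclass
class ImageStack:
    """Stack of grayscale slices with acquisition metadata.

    ``intensities`` is indexed (slice, row, col); values are integers in
    ``[0, 2**bit_depth - 1]``. ``pixel_spacing`` is the in-plane
    resolution in mm, ``slice_thickness`` the inter-slice spacing in mm.
    """

    intensities: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (slice, row, col) array")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_spacing and slice_thickness must be positive")
        lo, hi = self.intensities.min(), self.intensities.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] exceed {self.bit_depth}-bit range"
            )

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Per-slice rectangle, half-open on the max edges."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("ROI minima must be non-negative")
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("ROI must be non-empty")

    def validate_for(self, image_shape: tuple[int, int]) -> None:
        if self.row_max > image_shape[0] or self.col_max > image_shape[1]:
            raise ValueError(f"ROI {self} exceeds image bounds {image_shape}")

    def crop(self, image: np.ndarray) -> np.ndarray:
        self.validate_for(image.shape)
        return image[self.row_min : self.row_max, self.col_min : self.col_max]


@dataclass
class Contour:
    """Ordered closed boundary of one connected component.

    ``pixels`` is an (n, 2) integer array of (row, col) coordinates in
    tracing order; consecutive pixels are 8-connected and the loop is
    closed (last pixel is 8-adjacent to the first).
    """

    pixels: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pixels)

    def pixel_set(self) -> set[tuple[int, int]]:
        return {tuple(p) for p in self.pixels}


@dataclass
class PointCloud3D:
    """Point cloud in mm; provenance records (slice, contour) per point."""

    points: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.provenance is None:
            self.provenance = np.zeros((len(self.points), 2), dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=int).reshape(-1, 2)
        if len(self.provenance) != len(self.points):
            raise ValueError("provenance length must match point count")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# per-slice operations
# ---------------------------------------------------------------------------


def equalize(image: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Histogram equalization stretched to the full bit-depth range.

    Monotone remapping ``v -> round((cdf(v) - cdf_min) / (1 - cdf_min) *
    (L - 1))`` with L = 2**bit_depth. A constant image has a degenerate
    histogram and is returned unchanged.
    """
    image = np.asarray(image)
    levels = 2**bit_depth
    hist = np.bincount(image.ravel(), minlength=levels)
    cdf = np.cumsum(hist) / image.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min >= 1.0:  # constant image
        return image.copy()
    lut = np.rint((cdf - cdf_min) / (1.0 - cdf_min) * (levels - 1)).astype(
        image.dtype
    )
    return lut[image]


def adaptive_smooth(
    image: np.ndarray,
    mean_threshold: float,
    decrement: float,
) -> np.ndarray:
    """Threshold-mask smoothing filter on a 4-connected neighborhood.

    The mean over the plus-shaped 5-pixel neighborhood (center plus its
    4-connected neighbors, replicate padding at edges) is compared with
    ``mean_threshold``; where it exceeds the threshold, ``decrement`` is
    subtracted from the central pixel. Output is clipped at 0.
    """
    if mean_threshold < 0 or decrement < 0:
        raise ValueError("mean_threshold and decrement must be >= 0")
    image = np.asarray(image)
    kernel = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=float) / 5.0
    local_mean = ndimage.convolve(image.astype(float), kernel, mode="nearest")
    out = image.astype(float)
    out[local_mean > mean_threshold] -= decrement
    np.clip(out, 0, None, out=out)
    return out.astype(image.dtype)


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Mask = 1 where intensity >= threshold, else 0 (uint8)."""
    return (np.asarray(image) >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order starting at West, for an image
# with rows increasing downward: W, NW, N, NE, E, SE, S, SW.
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Brute-force boundary oracle: foreground pixels with a background
    4-neighbor (image border counts as background). Returns an (n, 2)
    array of (row, col)."""
    m = np.asarray(mask).astype(bool)
    padded = np.pad(m, 1)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return np.argwhere(m & ~interior)


def _trace_component(mask: np.ndarray) -> Contour:
    """Moore-neighbor tracing of the outer boundary of a single
    8-connected component, with Jacob's stopping criterion.

    The tracer state is (current pixel p, backtrack pixel b) where b is
    the background neighbor examined just before p was found; the Moore
    ring of p is scanned clockwise starting from b. Tracing stops when
    the start pixel is about to be re-entered with the original
    backtrack state (the start is "entered from the west" by the
    top-down / left-right scan convention).
    """
    rows, cols = np.nonzero(mask)
    # start at the top-most then left-most foreground pixel
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    h, w = mask.shape

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and bool(mask[p])

    def advance(
        p: tuple[int, int], dir_b: int
    ) -> tuple[tuple[int, int], int] | None:
        """First clockwise foreground neighbor after the backtrack
        direction; returns (c, direction of the new backtrack cell)."""
        for k in range(1, 9):
            d = (dir_b + k) % 8
            q = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if fg(q):
                return q, (d - 1) % 8
        return None

    b0 = (start[0], start[1] - 1)  # west neighbor, background
    step = advance(start, 0)
    if step is None:  # isolated pixel: degenerate loop of length 1
        return Contour(np.array([start]))

    contour = [start]
    p, prev_dir = step
    b = (start[0] + _MOORE[prev_dir][0], start[1] + _MOORE[prev_dir][1])
    max_steps = 4 * int(mask.sum()) + 4
    for _ in range(max_steps):
        contour.append(p)
        # direction from p to its backtrack cell
        delta = (b[0] - p[0], b[1] - p[1])
        dir_b = int(np.flatnonzero((_MOORE == delta).all(axis=1))[0])
        step = advance(p, dir_b)
        assert step is not None  # p has a foreground neighbor by construction
        c, prev_dir = step
        b_new = (p[0] + _MOORE[prev_dir][0], p[1] + _MOORE[prev_dir][1])
        if c == start and b_new == b0:
            # Jacob's criterion: the tracer is about to re-enter the
            # start pixel in its original state — the loop is closed.
            break
        p, b = c, b_new
    return Contour(np.array(contour))


def trace_boundary(mask: np.ndarray, min_size: int = 8) -> list[Contour]:
    """Trace the outer boundary of every foreground component.

    Components are 8-connected; those smaller than ``min_size`` pixels
    are discarded. Returns one closed :class:`Contour` per component,
    ordered by the component's top-most/left-most pixel.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return []
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    contours = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < min_size:
            continue
        contours.append(_trace_component(comp))
    contours.sort(key=lambda c: (c.pixels[0, 0], c.pixels[0, 1]))
    return contours


# ---------------------------------------------------------------------------
# 3D assembly and the full pipeline
# ---------------------------------------------------------------------------


def stack_to_cloud(
    contours_per_slice: dict[int, list[Contour]],
    pixel_spacing: float,
    slice_thickness: float,
    n_slices: int | None = None,
) -> PointCloud3D:
    """Map contour pixels to 3D points.

    x = col * pixel_spacing, y = row * pixel_spacing,
    z = slice * slice_thickness (all mm).
    """
    pts: list[np.ndarray] = []
    prov: list[np.ndarray] = []
    for s in sorted(contours_per_slice):
        if s < 0 or (n_slices is not None and s >= n_slices):
            raise ValueError(f"slice index {s} outside stack of {n_slices}")
        for ci, contour in enumerate(contours_per_slice[s]):
            rc = contour.pixels
            xyz = np.column_stack(
                [
                    rc[:, 1] * pixel_spacing,
                    rc[:, 0] * pixel_spacing,
                    np.full(len(rc), s * slice_thickness),
                ]
            )
            pts.append(xyz)
            prov.append(np.column_stack([np.full(len(rc), s), np.full(len(rc), ci)]))
    if not pts:
        return PointCloud3D(np.empty((0, 3)), np.empty((0, 2), dtype=int))
    return PointCloud3D(np.vstack(pts), np.vstack(prov))


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of :func:`segment_pipeline`.

    ``threshold`` is either the string ``"otsu"`` or a fixed intensity.
    The adaptive filter defaults derive from the bit depth: mean
    threshold 60% of the intensity maximum, decrement 10%.
    """

    adaptive: bool = False
    threshold: str | float = "otsu"
    mean_threshold: float | None = None
    decrement: float | None = None
    min_component_size: int = 8


def segment_pipeline(
    stack: ImageStack,
    roi: RegionOfInterest,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[PointCloud3D, np.ndarray]:
    """Run the full segmentation chain on every slice.

    Returns the 3D point cloud (in full-image physical coordinates) and
    the per-slice binary masks re-embedded in the full image frame, with
    sub-threshold components removed.
    """
    roi.validate_for(stack.shape[1:])
    vmax = 2**stack.bit_depth - 1
    mean_thr = config.mean_threshold if config.mean_threshold is not None else 0.6 * vmax
    dec = config.decrement if config.decrement is not None else 0.1 * vmax

    masks = np.zeros(stack.shape, dtype=np.uint8)
    contours: dict[int, list[Contour]] = {}
    for s in range(stack.n_slices):
        raw = roi.crop(stack.intensities[s])
        img = equalize(raw, stack.bit_depth)
        if config.adaptive:
            img = adaptive_smooth(img, mean_thr, dec)
        if config.threshold == "otsu":
            # Equalization flattens the histogram, so Otsu must see the
            # raw class structure; the threshold is then carried through
            # the (monotone) equalization map, and lowered by the
            # adaptive decrement (lumen neighborhoods are decremented).
            if raw.min() == raw.max():
                thr = float(img.max()) + 1.0
            else:
                t_raw = threshold_otsu(raw)
                above = equalize(raw, stack.bit_depth)[raw > t_raw]
                thr = float(above.min()) if above.size else float(img.max()) + 1.0
                if config.adaptive:
                    thr -= dec
        else:
            thr = float(config.threshold)
        mask = binarize(img, thr)
        # drop sub-threshold components so masks and contours agree
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        for i in range(1, n + 1):
            comp = labels == i
            if comp.sum() < config.min_component_size:
                mask[comp] = 0
        traced = trace_boundary(mask, min_size=config.min_component_size)
        # shift back into full-frame pixel coordinates
        contours[s] = [
            Contour(c.pixels + [roi.row_min, roi.col_min]) for c in traced
        ]
        masks[s, roi.row_min : roi.row_max, roi.col_min : roi.col_max] = mask
    cloud = stack_to_cloud(
        contours, stack.pixel_spacing, stack.slice_thickness, stack.n_slices
    )
    return cloud, masks


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
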