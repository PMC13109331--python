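"""Reference-pin extraction from a colored tuber cloud.

A single colored round-head push pin (≈11 mm diameter, ≈1 mm head
thickness) is the shared landmark between the partial RGB-D scan and the
complete SfM reconstruction. This module isolates the pin by iteratively
thresholded HSV color distance, denoises it with a radius outlier filter,
and fits the pin disk — center, radius, plane and outward normal — giving
the :class:`~pinreg3d.geometry.PinFrame` that anchors the registration.

The color distance to the reference pin color c_ref = (h, s, v) is

    d = (0.5·Δh + 0.1·Δs + 0.3·Δv) / 0.65,     Δh ← 1 − Δh if Δh > 0.5

where the hue difference wraps around the hue circle and the divisor is the
maximum attainable weighted sum (Δh ≤ 0.5), so d ∈ [0, 1]. Starting from a
threshold of 0.35, the threshold is lowered in 0.05 steps until the convex
hull of the surviving points fits within a 60 mm³ volume limit — the sign
that only the pin head, not color-bled body points, remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.color import rgb2hsv

from .circle_fit import hyper_fit
from .geometry import ColoredCloud, PinFrame

__all__ = [
    "PinReference",
    "PinSegmentation",
    "PinNotFoundError",
    "reference_from_swatch",
    "color_distance",
    "radius_outlier_filter",
    "segment_pin_iterative",
    "fit_pin_frame",
    "convex_hull_volume",
]

DEFAULT_WEIGHTS = (0.5, 0.1, 0.3)


class PinNotFoundError(RuntimeError):
    """Raised when the iterative segmentation cannot isolate a pin."""


@dataclass
class PinReference:
    """Median HSV of a background-free pin swatch, plus channel weights."""

    hsv: tuple[float, float, float]
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        hsv = np.asarray(self.hsv, dtype=np.float64)
        if hsv.shape != (3,) or hsv.min() < 0 or hsv.max() > 1:
            raise ValueError("reference HSV components must lie in [0, 1]")
        self.hsv = tuple(float(c) for c in hsv)
        self.weights = tuple(float(w) for w in self.weights)

    @property
    def normalizer(self) -> float:
        """Maximum attainable weighted sum (hue wraps, so Δh ≤ 0.5)."""
        wh, ws, wv = self.weights
        return wh * 0.5 + ws + wv


@dataclass
class PinSegmentation:
    """Result of the iterative pin isolation.

    ``pin_indices`` is the denoised (radius-filtered) set used for the
    hull-volume check and the pin-frame fit. ``selected_indices`` is the
    raw color selection at the accepted threshold, before the outlier
    filter; the filter can erode the pin rim unevenly, so the raw selection
    is the better definition of the red label set for the color ICP.
    """

    pin_indices: np.ndarray
    final_threshold: float
    hull_volume: float
    selected_indices: np.ndarray | None = None
    frame: PinFrame | None = None
    threshold_trace: list = field(default_factory=list)


def reference_from_swatch(swatch: np.ndarray,
                          weights=DEFAULT_WEIGHTS) -> PinReference:
    """Channel-wise median HSV over the opaque pixels of a pin swatch.

    ``swatch`` is an 8-bit RGBA (alpha > 0 marks the pin) or RGB (all pixels
    used) image.
    """
    swatch = np.asarray(swatch)
    if swatch.ndim != 3 or swatch.shape[2] not in (3, 4):
        raise ValueError("swatch must be an RGB or RGBA image")
    if swatch.shape[2] == 4:
        opaque = swatch[..., 3] > 0
        if not opaque.any():
            raise ValueError("swatch is fully transparent — no pin pixels")
        rgb = swatch[opaque][:, :3]
    else:
        rgb = swatch.reshape(-1, 3)
    if swatch.dtype == np.uint8:
        rgb = rgb.astype(np.float64) / 255.0
    hsv = rgb2hsv(rgb[None, :, :])[0]
    return PinReference(tuple(np.median(hsv, axis=0)), weights)


def color_distance(hsv: np.ndarray, ref: PinReference) -> np.ndarray:
    """Normalized weighted HSV distance d ∈ [0, 1] to the reference color.

    Works on a single (3,) HSV triple or an (N, 3) array. The hue term is
    wrap-aware: Δh ← 1 − Δh when Δh > 0.5.
    """
    hsv = np.asarray(hsv, dtype=np.float64)
    single = hsv.ndim == 1
    hsv = hsv.reshape(-1, 3)
    if hsv.size and (hsv.min() < 0 or hsv.max() > 1):
        raise ValueError("HSV components must lie in [0, 1]")
    delta = np.abs(hsv - np.asarray(ref.hsv))
    wrap = delta[:, 0] > 0.5
    delta[wrap, 0] = 1.0 - delta[wrap, 0]
    d = delta @ np.asarray(ref.weights) / ref.normalizer
    return float(d[0]) if single else d


def radius_outlier_filter(points: np.ndarray,
                          min_points: int = 40,
                          radius: float = 5.0) -> np.ndarray:
    """Boolean keep-mask: a point survives iff it has >= ``min_points``
    neighbors (itself excluded) within ``radius`` mm."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=radius, return_length=True)
    return counts - 1 >= min_points


def convex_hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume in mm³; 0 for degenerate (coplanar/collinear) sets.

    A flat pin disk is a legitimate zero-volume hull, so degeneracy is not
    an error here.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 4:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def segment_pin_iterative(cloud: ColoredCloud,
                          ref: PinReference,
                          t0: float = 0.35,
                          dt: float = 0.05,
                          volume_limit: float = 60.0,
                          min_points: int = 40,
                          filter_radius: float = 5.0,
                          tuber_id: str = "?") -> PinSegmentation:
    """Isolate pin points by iteratively tightened color-distance threshold.

    At each threshold t (0.35, 0.30, ...): select points with d <= t,
    denoise with the radius outlier filter, and accept if the convex hull of
    the survivors is within ``volume_limit`` mm³; otherwise lower t by
    ``dt`` and repeat. The returned segmentation has ``frame`` unset — call
    :func:`fit_pin_frame` on the selected points to complete it.
    """
    if not cloud.has_colors:
        raise ValueError("pin segmentation needs a colored cloud")
    d = color_distance(cloud.hsv, ref)
    trace = []
    t = t0
    while t > 1e-9:
        selected = np.nonzero(d <= t)[0]
        if len(selected) >= 1:
            keep = radius_outlier_filter(cloud.points[selected],
                                         min_points=min_points,
                                         radius=filter_radius)
            survivors = selected[keep]
        else:
            survivors = selected
        if len(survivors) < 4:
            raise PinNotFoundError(
                f"tuber {tuber_id}: pin not found — only {len(survivors)} "
                f"points survive at threshold {t:.2f} (degenerate hull)"
            )
        volume = convex_hull_volume(cloud.points[survivors])
        trace.append((round(t, 6), len(survivors), volume))
        if volume <= volume_limit:
            return PinSegmentation(survivors, round(t, 6), volume,
                                   selected_indices=selected,
                                   threshold_trace=trace)
        t -= dt
    raise PinNotFoundError(
        f"tuber {tuber_id}: pin not found — threshold exhausted without the "
        f"hull volume dropping below {volume_limit} mm³ (trace: {trace})"
    )


def _pca_axes(points: np.ndarray) -> np.ndarray:
    """Principal axes of a point set, columns sorted by decreasing extent
    of the axis-aligned bounding box in the rotated frame."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt.T  # columns are principal directions
    local = centered @ axes
    extents = local.max(axis=0) - local.min(axis=0)
    order = np.argsort(extents)[::-1]
    return axes[:, order]


def fit_pin_frame(pin_points: np.ndarray,
                  tuber_centroid: np.ndarray) -> PinFrame:
    """Fit the pin disk: center, radius, plane, and outward normal.

    Procedure: (1) principal-axis oriented bounding box of the pin's convex
    hull points (a thin disk, so PCA is stable); (2) project all pin points
    onto the perpendicular bisector plane of the shortest box axis; (3)
    hyperaccurate algebraic circle fit on the 2D convex-hull points of the
    projection; (4) lift the center back to 3D; (5) sign the plane normal to
    point away from the tuber centroid; (6) complete a deterministic
    right-handed tangent pair (u, v).
    """
    pin_points = np.asarray(pin_points, dtype=np.float64).reshape(-1, 3)
    if len(pin_points) < 3:
        raise ValueError("need at least 3 pin points")
    tuber_centroid = np.asarray(tuber_centroid, dtype=np.float64).ravel()

    try:
        hull_pts = pin_points[np.unique(ConvexHull(pin_points).vertices)]
    except QhullError:
        hull_pts = pin_points
    axes = _pca_axes(hull_pts)
    if np.linalg.norm(pin_points - pin_points.mean(axis=0), axis=1).max() < 1e-12:
        raise ValueError("rank-deficient pin point set")
    e_a, e_b, n_axis = axes[:, 0], axes[:, 1], axes[:, 2]

    # bisector plane of the shortest OBB axis
    heights = pin_points @ n_axis
    plane_h = 0.5 * (heights.min() + heights.max())

    local = (pin_points - plane_h * n_axis) @ np.column_stack([e_a, e_b])
    try:
        from scipy.spatial import ConvexHull as _Hull2
        rim = local[np.unique(_Hull2(local).vertices)]
    except QhullError:
        rim = local
    cx, cy, radius = hyper_fit(rim)
    center = plane_h * n_axis + cx * e_a + cy * e_b

    normal = n_axis if n_axis @ (center - tuber_centroid) >= 0 else -n_axis
    # deterministic tangent pair, right-handed with u x v = normal
    ref_axis = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref_axis) > 0.9:
        ref_axis = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref_axis, normal)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return PinFrame(center=center, normal=normal, u=u, v=v, radius=radius)
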