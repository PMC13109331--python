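"""Core geometric types and distance metrics.

Everything in this package works in millimetres. The two central containers
are :class:`ColoredCloud` (points + per-point RGB) and :class:`RigidTransform`
(a validated 4x4 homogeneous matrix). The registration error metric is the
one-way Chamfer distance (:func:`rmsd_one_way`): the RMS of distances from
each source point to its *nearest* target point. It is asymmetric by design —
the partial, low-quality RGB-D cloud is always the source and the complete
SfM reconstruction the target, so holes in the source do not penalise the
score and the computation is half the cost of a bidirectional Chamfer
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.color import rgb2hsv

__all__ = [
    "ColoredCloud",
    "RigidTransform",
    "PinFrame",
    "apply_transform",
    "rmsd_one_way",
    "rmse_correspondence",
]


@dataclass
class ColoredCloud:
    """A 3D point cloud with optional per-point RGB colors.

    Parameters
    ----------
    points:
        (N, 3) float array of coordinates in mm.
    colors:
        (N, 3) float array of RGB values in [0, 1], or None.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    _hsv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("cloud coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError(
                    f"points ({len(self.points)}) and colors ({len(self.colors)}) "
                    "must have equal length"
                )
            if self.colors.size and (
                self.colors.min() < -1e-12 or self.colors.max() > 1 + 1e-12
            ):
                raise ValueError("colors must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    @property
    def hsv(self) -> np.ndarray:
        """Per-point HSV in [0,1]^3, converted lazily and cached."""
        if self.colors is None:
            raise ValueError("cloud has no colors")
        if self._hsv is None or len(self._hsv) != len(self.colors):
            if len(self.colors) == 0:
                self._hsv = np.empty((0, 3))
            else:
                self._hsv = rgb2hsv(self.colors[None, :, :])[0]
        return self._hsv

    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("empty cloud has no centroid")
        return self.points.mean(axis=0)

    def select(self, indices) -> "ColoredCloud":
        """Sub-cloud at the given indices (boolean or integer)."""
        colors = self.colors[indices] if self.colors is not None else None
        return ColoredCloud(self.points[indices], colors)

    def transformed(self, transform: "RigidTransform") -> "ColoredCloud":
        return apply_transform(self, transform)


class RigidTransform:
    """A rigid (rotation + translation) transform as a 4x4 homogeneous matrix.

    The rotation block must be orthonormal with det = +1; the last row must
    be (0, 0, 0, 1). Non-rigid matrices are rejected at construction.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray, *, tol: float = 1e-6):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got {matrix.shape}")
        R = matrix[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has det = -1 (reflection)")
        if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0], atol=tol):
            raise ValueError("last row must be (0, 0, 0, 1)")
        self.matrix = matrix.copy()
        self.matrix[3] = (0.0, 0.0, 0.0, 1.0)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(R, dtype=np.float64)
        m[:3, 3] = np.asarray(t, dtype=np.float64).ravel()
        return cls(m)

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), t)

    @classmethod
    def about_axis(cls, axis, angle_deg: float, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a line through ``center`` along ``axis``."""
        axis = np.asarray(axis, dtype=np.float64)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be nonzero")
        axis = axis / n
        R = _rodrigues(axis * np.deg2rad(angle_deg))
        center = np.asarray(center, dtype=np.float64)
        return cls.from_rotation_translation(R, center - R @ center)

    # -- algebra ------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation_vector(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        m = np.eye(4)
        m[:3, :3] = R.T
        m[:3, 3] = -R.T @ self.translation_vector
        return RigidTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        single = points.ndim == 1
        pts = points.reshape(-1, 3) @ self.rotation.T + self.translation_vector
        return pts[0] if single else pts

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def __repr__(self) -> str:
        return f"RigidTransform(angle={self.rotation_angle_deg():.3f}°, t={self.translation_vector})"


def _rodrigues(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle vector (angle = |rotvec| in rad)."""
    theta = np.linalg.norm(rotvec)
    if theta < 1e-12:
        K = _skew(rotvec)
        return np.eye(3) + K  # first-order, exact enough below 1e-12
    k = rotvec / theta
    K = _skew(k)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


@dataclass
class PinFrame:
    """Orthonormal frame anchored at the reference-pin center.

    ``normal`` points outward, away from the tuber body; ``u`` and ``v``
    span the pin-disk plane with u × v = normal (right-handed). Aligning
    the two pin frames fixes five of the six rigid degrees of freedom —
    the residual ambiguity is the rotation about ``normal``.
    """

    center: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).ravel()
        self.normal = np.asarray(self.normal, dtype=np.float64).ravel()
        self.u = np.asarray(self.u, dtype=np.float64).ravel()
        self.v = np.asarray(self.v, dtype=np.float64).ravel()
        B = self.basis
        if not np.allclose(B.T @ B, np.eye(3), atol=1e-8):
            raise ValueError("pin frame axes are not orthonormal")
        if np.linalg.det(B) < 0:
            raise ValueError("pin frame is left-handed")
        if not self.radius > 0:
            raise ValueError("pin radius must be positive")

    @property
    def basis(self) -> np.ndarray:
        """3x3 with columns (u, v, normal)."""
        return np.column_stack([self.u, self.v, self.normal])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express points in pin coordinates (u, v, normal)."""
        return (np.asarray(points, dtype=np.float64) - self.center) @ self.basis


def apply_transform(cloud: ColoredCloud, transform: RigidTransform) -> ColoredCloud:
    """Map cloud points by a rigid transform; colors are untouched."""
    return ColoredCloud(transform.apply(cloud.points), cloud.colors)


def rmsd_one_way(source: ColoredCloud | np.ndarray,
                 target: ColoredCloud | np.ndarray,
                 target_tree: cKDTree | None = None) -> float:
    """One-way Chamfer distance: RMS of source→nearest-target distances (mm).

    RMSD = sqrt( (1/n) Σ_i ||s_i − nearest(s_i, target)||² )

    Asymmetric: only source points are scored, so a partial source against a
    complete target is not penalised for missing regions.
    A prebuilt KD-tree on the target may be passed to amortise repeated
    evaluations against the same target.
    """
    src = source.points if isinstance(source, ColoredCloud) else np.asarray(source)
    if target_tree is None:
        tgt = target.points if isinstance(target, ColoredCloud) else np.asarray(target)
        if len(tgt) == 0:
            raise ValueError("target cloud is empty")
        target_tree = cKDTree(tgt)
    if len(src) == 0:
        raise ValueError("source cloud is empty")
    d, _ = target_tree.query(src.reshape(-1, 3))
    return float(np.sqrt(np.mean(d ** 2)))


def rmse_correspondence(source: ColoredCloud | np.ndarray,
                        target: ColoredCloud | np.ndarray,
                        max_dist: float = 1.0) -> tuple[float, float]:
    """Inlier-correspondence RMSE between two clouds.

    Pairs each source point with its nearest target point and keeps pairs
    with distance <= ``max_dist`` (default 1.0 mm, twice the ICP convergence
    threshold). Returns ``(rmse_mm, inlier_fraction)``.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    src = source.points if isinstance(source, ColoredCloud) else np.asarray(source)
    tgt = target.points if isinstance(target, ColoredCloud) else np.asarray(target)
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("clouds must be non-empty")
    d, _ = cKDTree(tgt).query(src)
    inliers = d <= max_dist
    n_in = int(inliers.sum())
    if n_in == 0:
        raise ValueError(
            f"no correspondences within {max_dist} mm "
            f"(closest pair at {d.min():.3f} mm) — alignment too poor to score"
        )
    rmse = float(np.sqrt(np.mean(d[inliers] ** 2)))
    return rmse, n_in / len(src)
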