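"""Morphological trait extraction from watertight tuber meshes.

Seven indices are computed from a closed triangle mesh (vertices in mm;
reported traits in cm units):

* major / intermediate / minor axis lengths — sorted extents of the
  axis-aligned bounding box (cm);
* surface area A (cm²) — sum of triangle areas;
* volume V (cm³) — divergence-theorem sum of signed tetrahedra;
* volume-to-surface ratio V/A (cm) — highest for spheres;
* aspect ratio L_max / L_min (≥ 1; 1 ≈ spherical);
* sphericity (36 π V²)^(1/3) / A ∈ (0, 1], 1 for a perfect sphere;
* convexity V / V_hull ∈ (0, 1], 1 for convex shapes, lower with valleys.

The axis-aligned bounding box is orientation-dependent and tends to
overestimate the thinnest section; a PCA pre-alignment flag is available
for analysis use, but the default stays axis-aligned for fidelity to
datasets produced that way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

__all__ = [
    "WatertightMesh",
    "TuberTraits",
    "bbox_axes",
    "mesh_surface_area",
    "mesh_volume",
    "shape_indices",
    "compute_traits",
    "load_mesh",
]


@dataclass
class WatertightMesh:
    """A closed 2-manifold triangle mesh, vertices in mm, outward winding."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def open_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces (0 if closed)."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts != 2).sum())

    def is_watertight(self) -> bool:
        return self.open_edge_count() == 0 and self.as_trimesh().is_winding_consistent


def load_mesh(path) -> WatertightMesh:
    """Load a triangle mesh (OBJ, PLY, ...) as a WatertightMesh."""
    tm = trimesh.load(str(path), force="mesh", process=False)
    return WatertightMesh(tm.vertices, tm.faces)


@dataclass
class TuberTraits:
    """The seven morphological indices, in cm-based units."""

    length_max: float      # cm
    length_mid: float      # cm
    length_min: float      # cm
    surface_area: float    # cm²
    volume: float          # cm³
    vs_ratio: float        # cm
    aspect_ratio: float
    sphericity: float
    convexity: float

    def as_dict(self) -> dict:
        return {
            "length_max_cm": self.length_max,
            "length_mid_cm": self.length_mid,
            "length_min_cm": self.length_min,
            "surface_area_cm2": self.surface_area,
            "volume_cm3": self.volume,
            "vs_ratio_cm": self.vs_ratio,
            "aspect_ratio": self.aspect_ratio,
            "sphericity": self.sphericity,
            "convexity": self.convexity,
        }


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, WatertightMesh):
        return obj.vertices
    if hasattr(obj, "points"):
        return np.asarray(obj.points)
    if hasattr(obj, "vertices"):
        return np.asarray(obj.vertices)
    return np.asarray(obj, dtype=np.float64).reshape(-1, 3)


def bbox_axes(obj, pca_align: bool = False) -> tuple[float, float, float]:
    """Sorted (L_max, L_mid, L_min) bounding-box extents, in the input units.

    Default: axis-aligned box in the object's own frame. With
    ``pca_align``, the point set is rotated to its principal axes first,
    which removes the orientation dependence.
    """
    pts = _as_points(obj)
    if len(pts) == 0:
        raise ValueError("empty geometry")
    if pca_align:
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        pts = centered @ vt.T
    extents = pts.max(axis=0) - pts.min(axis=0)
    lmax, lmid, lmin = np.sort(extents)[::-1]
    return float(lmax), float(lmid), float(lmin)


def mesh_surface_area(mesh: WatertightMesh) -> float:
    """Total triangle area, in the square of the vertex units."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    if np.any(areas == 0):
        warnings.warn(f"{int((areas == 0).sum())} degenerate zero-area faces")
    return float(areas.sum())


def mesh_volume(mesh: WatertightMesh) -> float:
    """Enclosed volume by the divergence theorem: (1/6) Σ v₁·(v₂×v₃).

    Requires a watertight mesh; the absolute value is returned (a negative
    signed sum just means inward winding).
    """
    open_edges = mesh.open_edge_count()
    if open_edges:
        raise ValueError(f"mesh is not watertight: {open_edges} open edges")
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]],
                       np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0
    return float(abs(signed))


def shape_indices(volume: float, area: float,
                  axes: tuple[float, float, float],
                  hull_volume: float) -> dict:
    """Dimensionless shape indices from already-computed measurements.

    All inputs in a consistent unit system. Returns vs_ratio (length
    units), aspect_ratio, sphericity = (36 π V²)^(1/3) / A, and
    convexity = V / V_hull.
    """
    lmax, _, lmin = axes
    return {
        "vs_ratio": volume / area,
        "aspect_ratio": lmax / lmin,
        "sphericity": (36.0 * np.pi * volume ** 2) ** (1.0 / 3.0) / area,
        "convexity": volume / hull_volume,
    }


def compute_traits(mesh: WatertightMesh, pca_align: bool = False) -> TuberTraits:
    """All seven traits for a watertight mesh with vertices in mm.

    Unit conversion is exact: lengths /10 → cm, area /100 → cm²,
    volume /1000 → cm³.
    """
    axes_mm = bbox_axes(mesh, pca_align=pca_align)
    area_mm2 = mesh_surface_area(mesh)
    vol_mm3 = mesh_volume(mesh)
    hull_mm3 = float(ConvexHull(mesh.vertices).volume)
    idx = shape_indices(vol_mm3, area_mm2, axes_mm, hull_mm3)
    return TuberTraits(
        length_max=axes_mm[0] / 10.0,
        length_mid=axes_mm[1] / 10.0,
        length_min=axes_mm[2] / 10.0,
        surface_area=area_mm2 / 100.0,
        volume=vol_mm3 / 1000.0,
        vs_ratio=(vol_mm3 / 1000.0) / (area_mm2 / 100.0),
        aspect_ratio=idx["aspect_ratio"],
        sphericity=idx["sphericity"],
        convexity=idx["convexity"],
    )
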