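"""Readers and writers for the on-disk artifacts of a paired tuber dataset.

Covers: colored PLY point clouds (binary little-endian written, ASCII also
read), masked RGB-D frames (RGBA PNG with the tuber mask in the alpha layer
plus a 16-bit depth PNG), camera-intrinsics JSON, rigid-transform JSON
("tmatrix" files), COCO-style polygon region masks, conveyor frame ordering,
and the CIELAB b* rough tuber mask.

Conventions (stated explicitly because the dataset's frame position key
inverts the row axis): image coordinates are (column u, row v), origin at
the top-left, 0-based; the camera frame has +Z into the scene, +X right,
+Y down. Depth PNGs are uint16 with ``depth_scale`` mm per unit (default
1 mm/unit; the intrinsics JSON may override, e.g. 0.1 for sensors storing
100 µm units).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely
import trimesh
from skimage.color import rgb2lab

from .geometry import ColoredCloud, RigidTransform

__all__ = [
    "CameraIntrinsics",
    "MaskedFrame",
    "frame_to_cloud",
    "read_ply",
    "write_ply",
    "read_transform_json",
    "write_transform_json",
    "read_region_masks",
    "rasterize_polygon",
    "frame_sort_key",
    "lab_rough_mask",
    "read_frame",
    "write_frame",
]


@dataclass
class CameraIntrinsics:
    """Pinhole camera intrinsics with the depth-unit scale."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    depth_scale: float = 1.0  # mm per stored depth unit

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    @classmethod
    def from_json(cls, path) -> "CameraIntrinsics":
        data = json.loads(Path(path).read_text())
        return cls(**{k: data[k] for k in
                      ("fx", "fy", "cx", "cy", "width", "height")},
                   depth_scale=data.get("depth_scale", 1.0))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class MaskedFrame:
    """One annotated RGB-D frame: RGB, alpha mask (255 = tuber), uint16 depth."""

    rgb: np.ndarray
    alpha: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        self.alpha = np.asarray(self.alpha, dtype=np.uint8)
        self.depth = np.asarray(self.depth, dtype=np.uint16)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        hw = self.rgb.shape[:2]
        if self.alpha.shape != hw or self.depth.shape != hw:
            raise ValueError("rgb, alpha and depth must share the same H x W")
        if not np.isin(self.alpha, (0, 255)).all():
            raise ValueError("alpha must contain only 0 and 255")


def frame_to_cloud(frame: MaskedFrame, intrinsics: CameraIntrinsics) -> ColoredCloud:
    """Back-project a masked depth frame to a colored cloud (camera frame, mm).

    For each pixel (u, v) with alpha = 255 and depth > 0:
    Z = depth * depth_scale, X = (u − cx) Z / fx, Y = (v − cy) Z / fy.
    """
    if frame.rgb.shape[:2] != (intrinsics.height, intrinsics.width):
        raise ValueError(
            f"frame is {frame.rgb.shape[:2]}, intrinsics expect "
            f"{(intrinsics.height, intrinsics.width)}"
        )
    keep = (frame.alpha == 255) & (frame.depth > 0)
    v, u = np.nonzero(keep)
    z = frame.depth[v, u].astype(np.float64) * intrinsics.depth_scale
    x = (u - intrinsics.cx) * z / intrinsics.fx
    y = (v - intrinsics.cy) * z / intrinsics.fy
    colors = frame.rgb[v, u].astype(np.float64) / 255.0
    return ColoredCloud(np.column_stack([x, y, z]), colors)


def read_frame(rgb_path, depth_path) -> MaskedFrame:
    """Load an RGBA PNG (mask in alpha) + 16-bit depth PNG pair."""
    rgba = iio.imread(rgb_path)
    if rgba.ndim != 3 or rgba.shape[2] != 4:
        raise ValueError(f"{rgb_path}: expected an RGBA image")
    depth = iio.imread(depth_path)
    if depth.dtype != np.uint16:
        raise ValueError(f"{depth_path}: expected a 16-bit depth PNG")
    return MaskedFrame(rgba[..., :3], rgba[..., 3], depth)


def write_frame(frame: MaskedFrame, rgb_path, depth_path) -> None:
    rgba = np.dstack([frame.rgb, frame.alpha])
    iio.imwrite(rgb_path, rgba)
    iio.imwrite(depth_path, frame.depth)


# ---------------------------------------------------------------- PLY

def read_ply(path) -> ColoredCloud:
    """Read a PLY point cloud (binary LE or ASCII); colors optional."""
    loaded = trimesh.load(str(path), process=False)
    if isinstance(loaded, trimesh.Scene):  # empty-vertex PLY loads as Scene
        return ColoredCloud(np.empty((0, 3)))
    if isinstance(loaded, trimesh.Trimesh):
        verts = np.asarray(loaded.vertices)
        vc = loaded.visual.vertex_colors if loaded.visual.kind == "vertex" else None
    else:
        verts = np.asarray(loaded.vertices)
        vc = np.asarray(loaded.colors) if len(getattr(loaded, "colors", [])) else None
    colors = None
    if vc is not None and len(vc) == len(verts):
        colors = np.asarray(vc, dtype=np.float64)[:, :3] / 255.0
    return ColoredCloud(verts, colors)


def write_ply(cloud: ColoredCloud, path) -> None:
    """Write a binary little-endian PLY. Colors are stored as 8-bit."""
    path = str(path)
    if len(cloud) == 0:
        # trimesh rejects empty geometries; emit a minimal valid header.
        props = ("property float x\nproperty float y\nproperty float z\n"
                 + ("property uchar red\nproperty uchar green\nproperty uchar blue\n"
                    if cloud.has_colors else ""))
        Path(path).write_text(
            "ply\nformat ascii 1.0\nelement vertex 0\n" + props + "end_header\n"
        )
        return
    colors = None
    if cloud.has_colors:
        colors = np.clip(np.rint(cloud.colors * 255), 0, 255).astype(np.uint8)
    trimesh.PointCloud(cloud.points, colors=colors).export(path)


# ------------------------------------------------------- transform JSON

def write_transform_json(transform: RigidTransform, path, **extras) -> None:
    """Serialize a transform under key ``tmatrix`` (row-major 4x4 list).

    Extra keyword arguments (rough-stage angles, rmsd, rmse, ...) are stored
    alongside the matrix.
    """
    payload = {"tmatrix": transform.matrix.tolist(), **extras}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_transform_json(path, strict: bool = True):
    """Read a ``tmatrix`` JSON. Returns ``(RigidTransform, extras_dict)``.

    A non-rigid matrix triggers a warning; with ``strict`` it is rejected
    (ValueError), otherwise ``(None, extras)`` is returned.
    """
    data = json.loads(Path(path).read_text())
    if "tmatrix" not in data:
        raise KeyError(f"{path}: no 'tmatrix' key")
    extras = {k: v for k, v in data.items() if k != "tmatrix"}
    try:
        transform = RigidTransform(np.asarray(data["tmatrix"], dtype=np.float64))
    except ValueError as exc:
        warnings.warn(f"{path}: stored matrix is not rigid ({exc})")
        if strict:
            raise
        return None, extras
    return transform, extras


# ------------------------------------------------------- region masks

def read_region_masks(json_path) -> dict:
    """Parse a COCO-style region-mask JSON into per-image polygon lists.

    Returns ``{image_id: {"file_name": str, "height": int, "width": int,
    "polygons": [ (K,2) float arrays of (x, y) ]}}``. Run-length-encoded
    segmentations are not supported and raise explicitly.
    """
    data = json.loads(Path(json_path).read_text())
    images = {img["id"]: {"file_name": img.get("file_name", ""),
                          "height": img["height"], "width": img["width"],
                          "polygons": []}
              for img in data.get("images", [])}
    for ann in data.get("annotations", []):
        seg = ann.get("segmentation", [])
        if isinstance(seg, dict):
            raise ValueError(
                f"annotation {ann.get('id')}: RLE segmentation is not supported; "
                "export polygon segmentations"
            )
        entry = images.get(ann["image_id"])
        if entry is None:
            continue
        for flat in seg:
            poly = np.asarray(flat, dtype=np.float64).reshape(-1, 2)
            entry["polygons"].append(poly)
    return images


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (x, y) polygon onto an (H, W) boolean mask.

    Inclusive convention: a pixel is set when its integer center lies inside
    the polygon *or on its boundary* (so the square (10,10)-(20,20) covers
    11 x 11 = 121 pixels). Vertices outside the image are clipped to the
    raster with a warning.
    """
    h, w = shape
    polygon = np.asarray(polygon, dtype=np.float64)
    if (polygon[:, 0].min() < 0 or polygon[:, 1].min() < 0
            or polygon[:, 0].max() > w - 1 or polygon[:, 1].max() > h - 1):
        warnings.warn("polygon extends outside the image; clipping to bounds")
    poly = shapely.Polygon(polygon)
    mask = np.zeros(shape, dtype=bool)
    x0 = max(int(np.floor(polygon[:, 0].min())), 0)
    x1 = min(int(np.ceil(polygon[:, 0].max())), w - 1)
    y0 = max(int(np.floor(polygon[:, 1].min())), 0)
    y1 = min(int(np.ceil(polygon[:, 1].max())), h - 1)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    covered = shapely.covers(poly, shapely.points(xs.ravel(), ys.ravel()))
    mask[y0:y1 + 1, x0:x1 + 1] = covered.reshape(ys.shape)
    return mask


# ------------------------------------------------------- misc

_FRAME_RE = re.compile(r"^(?P<tuber>.+)_(?P<kind>[A-Za-z]+)_(?P<pos>\d+)\.[A-Za-z]+$")


def frame_sort_key(filename) -> int:
    """Extract the conveyor position key from ``{tuber_id}_{type}_{pos}.ext``.

    Sorting by this key reproduces temporal order along the belt. Note the
    axis inversion relative to image rows: pos 0 is the *bottom* of the
    image (row = height), pos = height is the top (row 0); i.e.
    pos = height − row.
    """
    name = Path(str(filename)).name
    m = _FRAME_RE.match(name)
    if m is None:
        raise ValueError(f"filename {name!r} does not match "
                         "'{{tuber_id}}_{{type}}_{{pos}}.ext'")
    return int(m.group("pos"))


def lab_rough_mask(rgb_image: np.ndarray, b_threshold: float = 15.0) -> np.ndarray:
    """Rough tuber mask by thresholding the CIELAB b* (blue-yellow) channel.

    Tuber skin is yellow-brown, i.e. strongly positive b*; the background of
    a controlled imaging studio is near-achromatic. Standard sRGB→CIELAB
    (D65) conversion; returns the raw boolean mask (b* > threshold) without
    refinement.
    """
    rgb_image = np.asarray(rgb_image)
    if rgb_image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image")
    lab = rgb2lab(rgb_image[..., :3].astype(np.float64) / 255.0)
    return lab[..., 2] > b_threshold
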