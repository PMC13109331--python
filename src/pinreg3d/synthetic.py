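"""Synthetic paired fixtures: tuber meshes, clouds, pins, and RGB-D renders.

Stands in for a real paired dataset so every pipeline stage is testable
offline. A tuber is a superellipsoid (semi-axes a ≥ b ≥ c in mm, exponents
controlling squareness) with smooth low-order radial bumps — this family
spans the aspect-ratio and sphericity ranges of real market-size tubers
(longest axis roughly 50–140 mm). A colored round-head pin (radius 5.5 mm,
head thickness 1 mm) is attached at a chosen surface direction, present in
both the complete "SfM-like" cloud and the partial "RGB-D-like" one.

The RGB-D path is emulated end to end: the mesh (tuber + pin) is rendered
with a small z-buffer rasterizer into an RGBA frame (mask in alpha) plus a
16-bit depth PNG with Gaussian depth noise, and the partial cloud is
obtained by back-projecting that frame through the same pinhole model the
I/O module uses — so the frame→cloud round trip is exercised, not mocked.

All randomness flows through explicitly passed seeds / generators; the
same seed reproduces the same fixture bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage.color import hsv2rgb

from .geometry import ColoredCloud, RigidTransform
from .io_formats import CameraIntrinsics, MaskedFrame, frame_to_cloud
from .traits import WatertightMesh

__all__ = [
    "TuberSpec",
    "FixturePair",
    "PIN_PALETTE",
    "generate_tuber_mesh",
    "attach_pin",
    "pin_mesh",
    "sample_full",
    "sample_partial_rgbd",
    "make_fixture_pair",
    "make_pin_swatch",
    "random_tuber_spec",
    "default_camera",
    "render_mesh",
]

# pin colors kept hue-separated (wrap-aware) from the yellow-brown tuber
# body (h ≈ 0.10) by at least 0.2, so color segmentation has a real margin
PIN_PALETTE = {
    "green": (0.33, 0.85, 0.80),
    "cyan": (0.50, 0.85, 0.80),
    "blue": (0.66, 0.90, 0.85),
    "purple": (0.74, 0.80, 0.75),
    "magenta": (0.88, 0.85, 0.80),
}

BODY_HSV = (0.10, 0.55, 0.55)  # potato-skin yellow-brown


@dataclass
class TuberSpec:
    """Parameters of one synthetic tuber."""

    semi_axes: tuple[float, float, float] = (45.0, 35.0, 28.0)  # mm, a>=b>=c
    exponents: tuple[float, float] = (1.1, 1.1)                 # e1 (z), e2 (xy)
    bump_amplitude: float = 1.5   # mm
    bump_frequency: float = 4.0
    pin_direction: tuple[float, float, float] = (0.35, 0.25, 1.0)
    pin_radius: float = 5.5       # mm (11 mm diameter head)
    pin_thickness: float = 1.0    # mm
    pin_hsv: tuple[float, float, float] = PIN_PALETTE["blue"]
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError("semi-axes must satisfy a >= b >= c > 0")
        if not all(0.6 <= e <= 1.6 for e in self.exponents):
            raise ValueError("exponents must lie in [0.6, 1.6]")
        if self.bump_amplitude < 0:
            raise ValueError("bump amplitude must be non-negative")
        d = np.asarray(self.pin_direction, dtype=np.float64)
        self.pin_direction = tuple(d / np.linalg.norm(d))


def _superellipsoid_radius(directions: np.ndarray, spec: TuberSpec) -> np.ndarray:
    """Radial distance to the superellipsoid surface along unit directions.

    Solves F(r d) = 1 by bisection, where
    F(p) = (|x/a|^(2/e2) + |y/b|^(2/e2))^(e2/e1) + |z/c|^(2/e1).
    F is monotone in r, so bisection is safe.
    """
    a, b, c = spec.semi_axes
    e1, e2 = spec.exponents
    d = np.asarray(directions, dtype=np.float64).reshape(-1, 3)

    def implicit(r):
        p = d * r[:, None]
        xy = (np.abs(p[:, 0] / a) ** (2.0 / e2)
              + np.abs(p[:, 1] / b) ** (2.0 / e2))
        return xy ** (e2 / e1) + np.abs(p[:, 2] / c) ** (2.0 / e1)

    lo = np.full(len(d), 1e-6)
    hi = np.full(len(d), 2.0 * a)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        inside = implicit(mid) < 1.0
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    return 0.5 * (lo + hi)


def _bump_field(directions: np.ndarray, spec: TuberSpec) -> np.ndarray:
    """Smooth radial perturbation in [-1, 1] (zero if amplitude is 0)."""
    if spec.bump_amplitude == 0:
        return np.zeros(len(directions))
    rng = np.random.default_rng(spec.seed)
    g = rng.normal(size=(3, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    d = np.asarray(directions, dtype=np.float64)
    vals = [np.sin(spec.bump_frequency * (d @ g[j]) + phases[j])
            for j in range(3)]
    return np.mean(vals, axis=0)


def _radial_surface(directions: np.ndarray, spec: TuberSpec) -> np.ndarray:
    r = _superellipsoid_radius(directions, spec)
    return r + spec.bump_amplitude * _bump_field(directions, spec)


def generate_tuber_mesh(spec: TuberSpec, subdivisions: int = 4) -> WatertightMesh:
    """Superellipsoid-with-bumps tuber mesh; watertight by construction.

    Built by radially morphing an icosphere: the sphere topology is closed
    and 2-manifold, and a pure radial morph preserves that.
    """
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    r = _radial_surface(dirs, spec)
    return WatertightMesh(dirs * r[:, None], np.asarray(ico.faces))


# ------------------------------------------------------------------ pin

def _pin_pose(mesh: WatertightMesh, spec: TuberSpec):
    """(surface point, outward unit normal) at the pin direction."""
    d = np.asarray(spec.pin_direction)
    r = _radial_surface(d[None, :], spec)[0]
    p0 = d * r
    tm = mesh.as_trimesh()
    nearest = np.argmin(np.linalg.norm(mesh.vertices - p0, axis=1))
    normal = np.asarray(tm.vertex_normals[nearest], dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    if normal @ d < 0:
        normal = -normal
    return p0, normal


def pin_mesh(mesh: WatertightMesh, spec: TuberSpec) -> trimesh.Trimesh:
    """The pin head as a cylinder sitting on the tuber surface."""
    p0, normal = _pin_pose(mesh, spec)
    cyl = trimesh.creation.cylinder(radius=spec.pin_radius,
                                    height=spec.pin_thickness,
                                    sections=32)
    T = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], normal)
    T = np.asarray(T, dtype=np.float64)
    T[:3, 3] = p0 + normal * (spec.pin_thickness / 2.0)
    cyl.apply_transform(T)
    return cyl


def _jitter_hsv(base_hsv, n: int, rng: np.random.Generator,
                sigma=(0.01, 0.05, 0.05), clip=(0.03, 0.10, 0.10)) -> np.ndarray:
    """RGB colors around a base HSV with small clipped jitter."""
    base = np.asarray(base_hsv, dtype=np.float64)
    jit = rng.normal(scale=sigma, size=(n, 3))
    jit = np.clip(jit, -np.asarray(clip), np.asarray(clip))
    hsv = base + jit
    hsv[:, 0] = np.mod(hsv[:, 0], 1.0)
    hsv[:, 1:] = np.clip(hsv[:, 1:], 0.0, 1.0)
    return hsv2rgb(hsv[None, :, :])[0]


def attach_pin(mesh: WatertightMesh, spec: TuberSpec,
               pin_hsv=None, density: float = 1.3,
               rng: np.random.Generator | None = None):
    """Sample the pin's exposed top disk face as colored points.

    ``density`` is points per mm² (match the body sampling density so the
    pin does not stand out geometrically). Only the exposed top face is
    sampled — the underside presses against the tuber and is invisible to
    both sensors. Returns ``(points, colors)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if pin_hsv is None:
        pin_hsv = spec.pin_hsv
    p0, normal = _pin_pose(mesh, spec)
    n_pts = max(int(round(density * np.pi * spec.pin_radius ** 2)), 8)
    rad = spec.pin_radius * np.sqrt(rng.uniform(size=n_pts))
    ang = rng.uniform(0, 2 * np.pi, size=n_pts)
    t1 = np.cross([1.0, 0.0, 0.0], normal)
    if np.linalg.norm(t1) < 0.3:
        t1 = np.cross([0.0, 1.0, 0.0], normal)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    offsets = (rad * np.cos(ang))[:, None] * t1 + (rad * np.sin(ang))[:, None] * t2
    height = spec.pin_thickness + rng.normal(scale=0.05, size=n_pts)
    points = p0 + offsets + height[:, None] * normal
    colors = _jitter_hsv(pin_hsv, n_pts, rng)
    return points, colors


def make_pin_swatch(pin_hsv, size: int = 16,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """A small synthetic RGBA pin swatch (background-free reference image)."""
    if rng is None:
        rng = np.random.default_rng(0)
    rgb = _jitter_hsv(pin_hsv, size * size, rng).reshape(size, size, 3)
    rgba = np.dstack([np.clip(np.rint(rgb * 255), 0, 255).astype(np.uint8),
                      np.full((size, size), 255, dtype=np.uint8)])
    return rgba


# ----------------------------------------------------------- sampling

def sample_full(mesh: WatertightMesh, n_points: int = 20000,
                seed: int = 0, body_hsv=BODY_HSV) -> ColoredCloud:
    """Uniform area-weighted surface sampling of the tuber body, exactly
    ``n_points``, colored with the tuber skin distribution."""
    tm = mesh.as_trimesh()
    pts, _ = trimesh.sample.sample_surface(tm, n_points, seed=seed)
    rng = np.random.default_rng(seed + 7)
    colors = _jitter_hsv(body_hsv, n_points, rng)
    return ColoredCloud(np.asarray(pts), colors)


# ----------------------------------------------------------- rendering

def default_camera() -> CameraIntrinsics:
    """A small top-view RGB-D camera for fixtures.

    320x240 at f = 320 px gives ≈1.25 mm pixel footprint at the 420 mm
    working distance — deliberately coarse, like a conveyor-mounted depth
    camera. depth_scale = 0.1 mm/unit (100 µm depth units).
    """
    return CameraIntrinsics(fx=320.0, fy=320.0, cx=160.0, cy=120.0,
                            width=320, height=240, depth_scale=0.1)


def render_mesh(vertices: np.ndarray, faces: np.ndarray,
                face_labels: np.ndarray, intr: CameraIntrinsics):
    """Z-buffer rasterization of a triangle mesh in the camera frame.

    Returns ``(depth_mm, labels)``: per-pixel depth in mm (0 where no hit)
    and the label of the front-most face (0 where no hit). Screen-space
    barycentric depth interpolation — adequate for the small triangles of
    these fixtures.
    """
    h, w = intr.height, intr.width
    depth = np.full((h, w), np.inf)
    labels = np.zeros((h, w), dtype=np.int32)
    z = vertices[:, 2]
    valid_v = z > 1e-6
    u = np.where(valid_v, intr.fx * vertices[:, 0] / np.where(valid_v, z, 1.0)
                 + intr.cx, 0.0)
    v = np.where(valid_v, intr.fy * vertices[:, 1] / np.where(valid_v, z, 1.0)
                 + intr.cy, 0.0)
    for fi, (i0, i1, i2) in enumerate(faces):
        if not (valid_v[i0] and valid_v[i1] and valid_v[i2]):
            continue
        xs = np.array([u[i0], u[i1], u[i2]])
        ys = np.array([v[i0], v[i1], v[i2]])
        x_min = max(int(np.floor(xs.min())), 0)
        x_max = min(int(np.ceil(xs.max())), w - 1)
        y_min = max(int(np.floor(ys.min())), 0)
        y_max = min(int(np.ceil(ys.max())), h - 1)
        if x_max < x_min or y_max < y_min:
            continue
        area = ((xs[1] - xs[0]) * (ys[2] - ys[0])
                - (xs[2] - xs[0]) * (ys[1] - ys[0]))
        if abs(area) < 1e-12:
            continue
        gx, gy = np.meshgrid(np.arange(x_min, x_max + 1),
                             np.arange(y_min, y_max + 1))
        w0 = ((xs[1] - gx) * (ys[2] - gy) - (xs[2] - gx) * (ys[1] - gy)) / area
        w1 = ((xs[2] - gx) * (ys[0] - gy) - (xs[0] - gx) * (ys[2] - gy)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        zi = w0 * z[i0] + w1 * z[i1] + w2 * z[i2]
        sub = depth[y_min:y_max + 1, x_min:x_max + 1]
        closer = inside & (zi < sub)
        sub[closer] = zi[closer]
        labels[y_min:y_max + 1, x_min:x_max + 1][closer] = face_labels[fi]
    depth[np.isinf(depth)] = 0.0
    return depth, labels


def sample_partial_rgbd(mesh: WatertightMesh, camera: CameraIntrinsics,
                        pose: RigidTransform, depth_noise_sigma: float = 0.3,
                        seed: int = 0, spec: TuberSpec | None = None,
                        body_hsv=BODY_HSV):
    """Render a top-view RGB-D frame of the (posed) tuber and back-project.

    ``pose`` maps tuber coordinates to the camera frame (+Z into the
    scene). If ``spec`` is given, the pin-head cylinder is rendered too and
    its pixels are labeled. Gaussian depth noise (σ in mm) is applied
    before quantization to the depth PNG's integer units.

    Returns ``(frame, cloud, pin_indices)``: the MaskedFrame, the partial
    cloud obtained by back-projecting the frame (camera coordinates), and
    the indices of pin pixels within that cloud.
    """
    rng = np.random.default_rng(seed)
    verts = [mesh.vertices]
    faces = [mesh.faces]
    labels = [np.ones(len(mesh.faces), dtype=np.int32)]
    if spec is not None:
        pm = pin_mesh(mesh, spec)
        faces.append(np.asarray(pm.faces) + len(mesh.vertices))
        verts.append(np.asarray(pm.vertices))
        labels.append(np.full(len(pm.faces), 2, dtype=np.int32))
    all_verts = pose.apply(np.vstack(verts))
    all_faces = np.vstack(faces)
    all_labels = np.concatenate(labels)

    depth_mm, pix_labels = render_mesh(all_verts, all_faces, all_labels, camera)
    hit = depth_mm > 0
    if depth_noise_sigma > 0:
        depth_mm = np.where(
            hit, depth_mm + rng.normal(scale=depth_noise_sigma,
                                       size=depth_mm.shape), 0.0)
    depth_png = np.zeros(depth_mm.shape, dtype=np.uint16)
    depth_png[hit] = np.clip(np.rint(depth_mm[hit] / camera.depth_scale),
                             1, 65535).astype(np.uint16)

    rgb = np.zeros(depth_mm.shape + (3,), dtype=np.uint8)
    for label, base in ((1, body_hsv), (2, spec.pin_hsv if spec else None)):
        if base is None:
            continue
        sel = hit & (pix_labels == label)
        n = int(sel.sum())
        if n:
            rgb[sel] = np.clip(np.rint(_jitter_hsv(base, n, rng) * 255),
                               0, 255).astype(np.uint8)
    alpha = np.where(hit & (depth_png > 0), 255, 0).astype(np.uint8)
    frame = MaskedFrame(rgb, alpha, depth_png)
    cloud = frame_to_cloud(frame, camera)
    vv, uu = np.nonzero((alpha == 255) & (depth_png > 0))
    pin_indices = np.nonzero(pix_labels[vv, uu] == 2)[0]
    return frame, cloud, pin_indices


# ----------------------------------------------------------- fixture pair

@dataclass
class FixturePair:
    """A complete+partial cloud pair with known ground-truth transform.

    ``true_transform`` maps the (displaced) partial cloud onto the full
    cloud's canonical frame; applying it superposes the partial cloud on
    the full surface to within the depth noise.
    """

    spec: TuberSpec
    full_cloud: ColoredCloud
    partial_cloud: ColoredCloud
    full_mesh: WatertightMesh
    pin_indices_full: np.ndarray
    pin_indices_partial: np.ndarray
    true_transform: RigidTransform
    depth_noise_sigma: float
    frame: MaskedFrame
    camera: CameraIntrinsics
    camera_pose: RigidTransform
    pin_swatch: np.ndarray = field(repr=False, default=None)


def random_tuber_spec(rng: np.random.Generator) -> TuberSpec:
    """A realistic random tuber: market-size axes, mild squareness, bumps,
    a tilted pin, and a palette pin color."""
    a = rng.uniform(35.0, 60.0)
    b = a * rng.uniform(0.70, 0.95)
    c = b * rng.uniform(0.70, 0.95)
    e1, e2 = rng.uniform(0.85, 1.35, size=2)
    tilt = rng.uniform(0.0, 0.45)
    ang = rng.uniform(0, 2 * np.pi)
    pin_dir = (tilt * np.cos(ang), tilt * np.sin(ang), 1.0)
    color = list(PIN_PALETTE)[rng.integers(len(PIN_PALETTE))]
    return TuberSpec(
        semi_axes=(a, b, c),
        exponents=(float(e1), float(e2)),
        bump_amplitude=float(rng.uniform(1.0, 2.5)),
        bump_frequency=float(rng.uniform(3.0, 6.0)),
        pin_direction=pin_dir,
        pin_hsv=PIN_PALETTE[color],
        seed=int(rng.integers(2 ** 31 - 1)),
    )


def _random_rigid(rng: np.random.Generator, max_rotation_deg: float,
                  max_translation: float = 15.0) -> RigidTransform:
    if max_rotation_deg == 0:
        R = np.eye(3)
    else:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, max_rotation_deg)
        R = RigidTransform.about_axis(axis, angle).rotation
    t = rng.uniform(-max_translation, max_translation, size=3)
    if max_rotation_deg == 0:
        t = np.zeros(3)
    return RigidTransform.from_rotation_translation(R, t)


def make_fixture_pair(spec: TuberSpec | None = None,
                      transform_magnitude: float = 30.0,
                      seed: int = 0,
                      n_full: int = 20000,
                      depth_noise_sigma: float = 0.3,
                      camera: CameraIntrinsics | None = None) -> FixturePair:
    """Build one paired fixture with a known ground-truth transform.

    The full (SfM-like) cloud lives in the tuber's canonical frame. The
    partial (RGB-D-like) cloud is rendered from a top-view camera aimed at
    the pin, mapped back to the canonical frame, then displaced by a random
    rigid transform (rotation ≤ ``transform_magnitude`` degrees); the
    inverse of that displacement is recorded as ``true_transform``. With
    magnitude 0 the true transform is the identity.
    """
    rng = np.random.default_rng(seed)
    if spec is None:
        spec = random_tuber_spec(rng)
    if camera is None:
        camera = default_camera()

    mesh = generate_tuber_mesh(spec)
    density = n_full / mesh.as_trimesh().area
    body = sample_full(mesh, n_points=n_full, seed=int(rng.integers(2 ** 31 - 1)))
    pin_pts, pin_cols = attach_pin(mesh, spec, density=density,
                                   rng=np.random.default_rng(spec.seed + 1))
    full = ColoredCloud(np.vstack([body.points, pin_pts]),
                        np.vstack([body.colors, pin_cols]))
    pin_idx_full = np.arange(len(body), len(full))

    # camera pose: pin normal toward the camera (-Z), random roll, tuber
    # centered at 420 mm working distance
    _, pin_normal = _pin_pose(mesh, spec)
    R_align = trimesh.geometry.align_vectors(pin_normal, [0.0, 0.0, -1.0])
    R_align = np.asarray(R_align)[:3, :3]
    roll = RigidTransform.about_axis([0, 0, 1],
                                     float(rng.uniform(0, 360))).rotation
    R_cam = roll @ R_align
    centroid = mesh.vertices.mean(axis=0)
    t_cam = np.array([0.0, 0.0, 420.0]) - R_cam @ centroid
    pose = RigidTransform.from_rotation_translation(R_cam, t_cam)

    frame, cloud_cam, pin_idx_partial = sample_partial_rgbd(
        mesh, camera, pose, depth_noise_sigma=depth_noise_sigma,
        seed=int(rng.integers(2 ** 31 - 1)), spec=spec)
    canonical = pose.inverse().apply(cloud_cam.points)

    displacement = _random_rigid(rng, transform_magnitude)
    partial = ColoredCloud(displacement.apply(canonical), cloud_cam.colors)

    return FixturePair(
        spec=spec,
        full_cloud=full,
        partial_cloud=partial,
        full_mesh=mesh,
        pin_indices_full=pin_idx_full,
        pin_indices_partial=pin_idx_partial,
        true_transform=displacement.inverse(),
        depth_noise_sigma=depth_noise_sigma,
        frame=frame,
        camera=camera,
        camera_pose=pose,
        pin_swatch=make_pin_swatch(spec.pin_hsv,
                                   rng=np.random.default_rng(spec.seed + 2)),
    )
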