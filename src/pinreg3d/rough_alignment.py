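"""Pin-frame initialization and stepwise cross-strip rough matching.

Aligning the two pin frames (center onto center, outward normal onto
outward normal) fixes all three translational degrees of freedom and two of
the three rotational ones. The residual unknown — rotation about the pin
normal N — is resolved by a grid search: the source (RGB-D) cloud is
rotated about N in 10° increments, and at each step two perpendicular 1 mm
"cross-strips" through the pin center are used to cheaply find the optimal
small tilts about the tangents u and v (5° grid). The total one-way Chamfer
RMSD over the 3 cm pin neighborhood, as a function of the N-rotation,
yields a profile whose *local minima* are the candidate alignments — the
global minimum is not always the correct match on near-symmetric tubers,
so candidates are ranked and the caller (or an operator re-running with a
different rank) makes the final choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import ColoredCloud, PinFrame, RigidTransform, rmsd_one_way

__all__ = [
    "CandidateAlignment",
    "RotationProfile",
    "init_by_pin",
    "crop_neighborhood",
    "extract_strip",
    "optimal_strip_rotation",
    "scan_N_rotations",
    "select_candidate",
    "circular_local_minima",
]


@dataclass
class CandidateAlignment:
    """One local minimum of the N-rotation RMSD profile."""

    theta_N: float  # degrees, on the 10° grid in [0, 360)
    theta_u: float  # degrees, on the 5° grid
    theta_v: float  # degrees, on the 5° grid
    rmsd: float     # mm, over the full pin neighborhood
    rank: int       # 1-based, ascending RMSD among local minima
    transform: RigidTransform  # full source→target transform (incl. init)


@dataclass
class RotationProfile:
    """Full scan output: 36 grid values plus the ranked candidates."""

    angles_N: np.ndarray          # the θ_N grid (deg)
    rmsd: np.ndarray              # profile values (mm)
    tilts: np.ndarray             # (36, 2) optimal (θ_u, θ_v) per step
    candidates: list[CandidateAlignment]
    rmsd_init: float              # neighborhood RMSD of the bare pin init


def init_by_pin(source_frame: PinFrame, target_frame: PinFrame) -> RigidTransform:
    """Rigid transform mapping the source pin frame onto the target's.

    Maps center→center and (u, v, N)→(u, v, N); with the deterministic
    tangent convention this leaves zero residual rotation about N relative
    to the frames' own u axes.
    """
    R = target_frame.basis @ source_frame.basis.T
    t = target_frame.center - R @ source_frame.center
    return RigidTransform.from_rotation_translation(R, t)


def crop_neighborhood(cloud: ColoredCloud, frame: PinFrame,
                      radius: float = 30.0) -> ColoredCloud:
    """Points within ``radius`` mm of the pin center (default 3 cm)."""
    d = np.linalg.norm(cloud.points - frame.center, axis=1)
    return cloud.select(d <= radius)


def _strip_mask(points: np.ndarray, frame: PinFrame, axis: str,
                width: float, radius: float) -> np.ndarray:
    local = frame.to_local(points)
    dist = np.linalg.norm(points - frame.center, axis=1)
    if axis == "u":       # strip extends along u: small |v| coordinate
        band = np.abs(local[:, 1]) <= width / 2.0
    elif axis == "v":     # strip extends along v: small |u| coordinate
        band = np.abs(local[:, 0]) <= width / 2.0
    else:
        raise ValueError("axis must be 'u' or 'v'")
    return band & (dist <= radius)


def extract_strip(cloud: ColoredCloud | np.ndarray, frame: PinFrame,
                  axis: str, width: float = 1.0,
                  radius: float = 30.0) -> np.ndarray:
    """Points of the 1 mm cross-strip along ``axis``, within the pin
    neighborhood, as an (M, 3) array (possibly empty)."""
    pts = cloud.points if isinstance(cloud, ColoredCloud) else np.asarray(cloud)
    return pts[_strip_mask(pts, frame, axis, width, radius)]


def optimal_strip_rotation(source_strip: np.ndarray,
                           target_strip: np.ndarray,
                           frame: PinFrame,
                           axis: str,
                           step: float = 5.0,
                           search_range: float = 45.0,
                           target_tree: cKDTree | None = None):
    """Grid-search the tilt that best overlays a source strip on a target strip.

    The strip that extends along ``u`` is tilted by rotating about ``v``
    (and vice versa) — the rotation axis is the tangent perpendicular to the
    strip's long direction, so the strip profile rocks against the
    reference. Returns ``(angle_deg, rmsd_mm)``; ties prefer the smaller
    |angle| (then the positive one).
    """
    source_strip = np.asarray(source_strip, dtype=np.float64).reshape(-1, 3)
    target_strip = np.asarray(target_strip, dtype=np.float64).reshape(-1, 3)
    if len(source_strip) == 0 or len(target_strip) == 0:
        raise ValueError("empty strip")
    rot_axis = frame.v if axis == "u" else frame.u
    if target_tree is None:
        target_tree = cKDTree(target_strip)
    n_steps = int(round(search_range / step))
    angles = step * np.arange(-n_steps, n_steps + 1)
    best = None
    for angle in sorted(angles, key=lambda a: (abs(a), -a)):
        T = RigidTransform.about_axis(rot_axis, angle, center=frame.center)
        rotated = T.apply(source_strip)
        r = rmsd_one_way(rotated, None, target_tree=target_tree)
        if best is None or r < best[1]:
            best = (float(angle), r)
    return best


def circular_local_minima(profile: np.ndarray) -> list[int]:
    """Indices of local minima on a circular profile.

    Strict inequality against the nearest *distinct* neighbor values on
    each side; a plateau of equal values counts once, at its leftmost
    index. A perfectly flat profile returns the single index 0.
    """
    profile = np.asarray(profile, dtype=np.float64)
    n = len(profile)
    minima = []
    for i in range(n):
        # left edge of a plateau only
        if profile[(i - 1) % n] == profile[i]:
            continue
        # previous distinct value
        j = (i - 1) % n
        while profile[j] == profile[i]:
            j = (j - 1) % n
        # next distinct value
        k = (i + 1) % n
        steps = 0
        while profile[k] == profile[i] and steps < n:
            k = (k + 1) % n
            steps += 1
        if steps >= n:  # flat profile
            return [0]
        if profile[j] > profile[i] and profile[k] > profile[i]:
            minima.append(i)
    if not minima:
        minima = [int(np.argmin(profile))]
    return minima


def scan_N_rotations(source_nbhd: ColoredCloud | np.ndarray,
                     target_nbhd: ColoredCloud | np.ndarray,
                     frame: PinFrame,
                     init: RigidTransform | None = None,
                     step_N: float = 10.0,
                     strip_width: float = 1.0,
                     strip_step: float = 5.0,
                     strip_range: float = 45.0,
                     radius: float = 30.0) -> RotationProfile:
    """Scan rotations about the pin normal and rank candidate alignments.

    ``source_nbhd`` must already be pin-initialized (i.e. expressed in the
    target's pin frame, cropped to the 3 cm neighborhood); ``frame`` is the
    target pin frame. ``init`` — the transform that produced that
    initialization — is composed into each candidate's transform so the
    candidates map *original* source coordinates onto the target.

    For each θ_N on the 10° grid: rotate the source about N, find the
    optimal tilts θ_u (about u, scored on the v-strip) and θ_v (about v,
    scored on the u-strip), apply θ_N then θ_u then θ_v about the fixed pin
    axes, and score the one-way RMSD over the whole neighborhood. Local
    minima of the resulting circular profile become ranked candidates.
    """
    src = (source_nbhd.points if isinstance(source_nbhd, ColoredCloud)
           else np.asarray(source_nbhd, dtype=np.float64))
    tgt = (target_nbhd.points if isinstance(target_nbhd, ColoredCloud)
           else np.asarray(target_nbhd, dtype=np.float64))
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("pin neighborhood too sparse: empty cloud")
    if init is None:
        init = RigidTransform.identity()

    tgt_tree = cKDTree(tgt)
    tgt_strip_u = extract_strip(tgt, frame, "u", strip_width, radius)
    tgt_strip_v = extract_strip(tgt, frame, "v", strip_width, radius)
    tree_u = cKDTree(tgt_strip_u) if len(tgt_strip_u) else None
    tree_v = cKDTree(tgt_strip_v) if len(tgt_strip_v) else None

    rmsd_init = rmsd_one_way(src, None, target_tree=tgt_tree)

    angles_N = np.arange(0.0, 360.0, step_N)
    profile = np.full(len(angles_N), np.inf)
    tilts = np.zeros((len(angles_N), 2))
    transforms: list[RigidTransform | None] = [None] * len(angles_N)
    any_strip = False
    for i, theta_N in enumerate(angles_N):
        T_N = RigidTransform.about_axis(frame.normal, theta_N,
                                        center=frame.center)
        rotated = T_N.apply(src)
        theta_u = theta_v = 0.0
        s_u = extract_strip(rotated, frame, "u", strip_width, radius)
        s_v = extract_strip(rotated, frame, "v", strip_width, radius)
        if len(s_v) and tree_v is not None and len(tgt_strip_v):
            theta_u, _ = optimal_strip_rotation(
                s_v, tgt_strip_v, frame, "v", strip_step, strip_range,
                target_tree=tree_v)
            any_strip = True
        if len(s_u) and tree_u is not None and len(tgt_strip_u):
            theta_v, _ = optimal_strip_rotation(
                s_u, tgt_strip_u, frame, "u", strip_step, strip_range,
                target_tree=tree_u)
            any_strip = True
        T_u = RigidTransform.about_axis(frame.u, theta_u, center=frame.center)
        T_v = RigidTransform.about_axis(frame.v, theta_v, center=frame.center)
        T_total = T_v @ T_u @ T_N
        profile[i] = rmsd_one_way(T_total.apply(src), None,
                                  target_tree=tgt_tree)
        tilts[i] = (theta_u, theta_v)
        transforms[i] = T_total
    if not any_strip:
        raise ValueError("pin neighborhood too sparse: all cross-strips empty")

    minima = circular_local_minima(profile)
    order = sorted(minima, key=lambda i: (profile[i], angles_N[i]))
    candidates = [
        CandidateAlignment(
            theta_N=float(angles_N[i]),
            theta_u=float(tilts[i, 0]),
            theta_v=float(tilts[i, 1]),
            rmsd=float(profile[i]),
            rank=rank,
            transform=transforms[i] @ init,
        )
        for rank, i in enumerate(order, start=1)
    ]
    return RotationProfile(angles_N, profile, tilts, candidates, rmsd_init)


def select_candidate(candidates: list[CandidateAlignment],
                     rank: int = 1) -> CandidateAlignment:
    """Return the rank-th candidate (1 = lowest RMSD local minimum)."""
    for c in candidates:
        if c.rank == rank:
            return c
    available = sorted(c.rank for c in candidates)
    raise ValueError(f"rank {rank} not available; candidate ranks: {available}")
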