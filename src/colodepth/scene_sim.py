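"""Procedural colon-scene simulator: paired RGB / metric-depth rendering.

A colon segment is modelled as a tube around a smooth centerline whose
radius is modulated by periodic haustral folds and local polyp bumps. The
surface is an implicit function (signed radial distance, negative inside
the lumen), rendered by per-pixel ray marching with bisection refinement,
so every rendered quantity has a closed-form oracle on simple geometry.

Rendering follows an endoscope model: a pinhole camera with two attached
spot light sources, inverse-square falloff, Lambertian diffuse shading plus
a Blinn-Phong specular lobe. Depth is the Euclidean distance from the
optical centre along the pixel ray, capped at ``d_max`` (default 20 cm);
rays that leave the open tube ends are reported at the cap with black RGB.

A "domain-shifted" render mode re-shades the same geometry with a disjoint
texture/lighting profile; it stands in for real colonoscopy frames when
exercising adversarial training on unlabeled images, with its ground-truth
depth retained for held-out scoring only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

D_MAX_DEFAULT = 20.0  # cm depth cap
_EXTENSION = 1000.0  # cm of straight virtual tube past each open end

__all__ = [
    "CameraModel",
    "MaterialSpec",
    "LightSpec",
    "SceneSpec",
    "CameraPose",
    "RenderedPair",
    "tube_surface_distance",
    "cast_ray",
    "render_pair",
    "render_domain_shifted",
    "sample_camera_path",
    "add_specular_artifacts",
    "generate_dataset",
    "quantize_depth",
    "default_scene",
    "default_camera",
    "material_grid",
    "light_grid",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics, zero skew; pixel centres at integer coordinates."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside image")

    def pixel_rays(self) -> np.ndarray:
        """Unit ray directions in the camera frame, shape (H, W, 3)."""
        u, v = np.meshgrid(np.arange(self.width), np.arange(self.height))
        d = np.stack(
            [(u - self.cx) / self.fx, (v - self.cy) / self.fy, np.ones_like(u, float)],
            axis=-1,
        )
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def project(self, pts_cam: np.ndarray) -> np.ndarray:
        """Project (N,3) camera-frame points to (N,2) pixel coordinates."""
        z = pts_cam[:, 2]
        return np.stack(
            [self.fx * pts_cam[:, 0] / z + self.cx, self.fy * pts_cam[:, 1] / z + self.cy],
            axis=-1,
        )


@dataclass(frozen=True)
class MaterialSpec:
    albedo: tuple = (0.75, 0.35, 0.30)  # RGB in [0,1]
    specular_coeff: float = 0.25
    shininess: float = 30.0
    texture_mode: str = "plain"  # plain | vessel | mottled

    def __post_init__(self):
        if not all(0.0 <= a <= 1.0 for a in self.albedo):
            raise ValueError("albedo channels must lie in [0,1]")
        if not 0.0 <= self.specular_coeff <= 1.0:
            raise ValueError("specular_coeff must lie in [0,1]")
        if self.shininess <= 0:
            raise ValueError("shininess must be positive")
        if self.texture_mode not in ("plain", "vessel", "mottled"):
            raise ValueError(f"unknown texture_mode {self.texture_mode!r}")


@dataclass(frozen=True)
class LightSpec:
    """Camera-attached spot light; zero contribution beyond ``range``."""

    offset: tuple = (0.3, 0.0, 0.0)  # cm, in the camera frame
    color: tuple = (1.0, 1.0, 1.0)
    intensity: float = 6.0  # radiant scale so walls at ~2 cm are mid-bright
    spot_angle: float = 1.2  # rad, half-angle of the cone
    range: float = 25.0  # cm

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not 0.0 < self.spot_angle <= np.pi:
            raise ValueError("spot_angle must lie in (0, pi]")


@dataclass(frozen=True)
class SceneSpec:
    """Tube geometry + material + lights; fully determines a render."""

    centerline: tuple = ((0.0, 0.0, 0.0), (0.0, 0.0, 30.0))
    base_radius: float = 1.5
    fold_amplitude: float = 0.25
    fold_frequency: float = 0.35  # fold cycles per cm along the axis
    polyps: tuple = ()  # (axial_pos cm, angle rad, bump_radius cm, bump_height cm)
    material: MaterialSpec = field(default_factory=MaterialSpec)
    lights: tuple = field(
        default_factory=lambda: (
            LightSpec(offset=(0.3, 0.0, 0.0)),
            LightSpec(offset=(-0.3, 0.0, 0.0)),
        )
    )
    seed: int = 0

    def __post_init__(self):
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.fold_amplitude >= self.base_radius:
            raise ValueError("fold_amplitude must be smaller than base_radius")
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 control points")

    def spec_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CameraPose:
    position: tuple  # cm
    orientation: tuple  # 3x3 proper rotation, rows as tuples

    def __post_init__(self):
        R = self.R
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("orientation must be a proper rotation matrix")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float)

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class RenderedPair:
    """An RGB image with its co-registered metric depth map (cm)."""

    rgb: np.ndarray  # H x W x 3 in [0,1]
    depth: np.ndarray  # H x W, cm in [0, d_max]
    d_max: float
    subset_id: tuple = (0, 0)  # (light_idx, material_idx)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Implicit tube geometry
# ---------------------------------------------------------------------------


class _Polyline:
    """Arc-length parametrized centerline with parallel-transport frames.

    The first and last segments are extended far past the control points so
    the tube has open ends: a ray fired down the axis never meets a wall and
    is later clamped to the depth cap.
    """

    def __init__(self, points):
        pts = np.asarray(points, dtype=float)
        d0 = pts[1] - pts[0]
        d0 /= np.linalg.norm(d0)
        dn = pts[-1] - pts[-2]
        dn /= np.linalg.norm(dn)
        pts = np.vstack([pts[0] - _EXTENSION * d0, pts, pts[-1] + _EXTENSION * dn])
        self.A = pts[:-1]
        seg = pts[1:] - pts[:-1]
        self.L = np.linalg.norm(seg, axis=1)
        self.D = seg / self.L[:, None]
        self.cum = np.concatenate([[0.0], np.cumsum(self.L)]) - _EXTENSION
        # parallel-transport normal frames per segment
        n = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(n, self.D[0])) > 0.9:
            n = np.array([0.0, 1.0, 0.0])
        n = n - np.dot(n, self.D[0]) * self.D[0]
        n /= np.linalg.norm(n)
        N1 = [n]
        for i in range(1, len(self.D)):
            a, b = self.D[i - 1], self.D[i]
            v = np.cross(a, b)
            c = np.dot(a, b)
            if np.linalg.norm(v) < 1e-12:
                N1.append(N1[-1])
            else:
                # Rodrigues rotation taking a onto b
                vx = np.array(
                    [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
                )
                Rm = np.eye(3) + vx + vx @ vx / (1.0 + c)
                N1.append(Rm @ N1[-1])
        self.N1 = np.asarray(N1)
        self.N2 = np.cross(self.D, self.N1)

    # softmin temperature (cm^2) for blending surface coordinates across
    # segments: the nearest-segment assignment switches discontinuously on
    # the concave side of a bend, which would make the fold phase (and hence
    # the implicit function) jump there; blending keeps it continuous.
    BLEND_TAU = 0.02

    def closest(self, P):
        """For (M,3) points return (s, radial_vec, rho, theta).

        rho is the exact distance to the polyline; the surface coordinates
        (s, theta) are softmin-blended over segments so they vary
        continuously across nearest-segment switches.
        """
        P = np.atleast_2d(P)
        t = np.einsum("msk,sk->ms", P[:, None, :] - self.A[None], self.D)
        t = np.clip(t, 0.0, self.L[None, :])
        C = self.A[None] + t[..., None] * self.D[None]
        d2 = np.sum((P[:, None, :] - C) ** 2, axis=-1)
        seg = np.argmin(d2, axis=1)
        m = np.arange(len(P))
        rho = np.sqrt(d2[m, seg])
        radial = P - C[m, seg]
        w = np.exp(-(d2 - d2[m, seg][:, None]) / self.BLEND_TAU)
        wsum = w.sum(axis=1)
        s_all = self.cum[None, :-1] + t
        s = np.einsum("ms,ms->m", w, s_all) / wsum
        rad_all = P[:, None, :] - C  # (M,S,3)
        e1 = np.einsum("msk,sk->ms", rad_all, self.N1)
        e2 = np.einsum("msk,sk->ms", rad_all, self.N2)
        theta = np.arctan2(
            np.einsum("ms,ms->m", w, e2), np.einsum("ms,ms->m", w, e1)
        )
        return s, radial, rho, theta

    def frame_at(self, s):
        """Point, tangent and normal frame at arc position s (scalar)."""
        idx = np.searchsorted(self.cum, s) - 1
        idx = int(np.clip(idx, 0, len(self.D) - 1))
        t_local = s - self.cum[idx]
        p = self.A[idx] + t_local * self.D[idx]
        return p, self.D[idx], self.N1[idx], self.N2[idx]

    @property
    def length(self):
        return self.cum[-1] - _EXTENSION


def _polyline(spec: SceneSpec) -> _Polyline:
    # tiny per-spec cache; SceneSpec is frozen so identity is fine
    key = id(spec)
    cached = _polyline._cache.get(key)
    if cached is None:
        cached = _Polyline(spec.centerline)
        if len(_polyline._cache) > 64:
            _polyline._cache.clear()
        _polyline._cache[key] = cached
    return cached


_polyline._cache = {}


def _wall_radius(spec: SceneSpec, s, theta):
    """Local tube radius at axial position s (cm) and angle theta (rad)."""
    r = spec.base_radius + spec.fold_amplitude * np.sin(
        2.0 * np.pi * spec.fold_frequency * s
    )
    for s0, th0, br, bh in spec.polyps:
        dth = np.arctan2(np.sin(theta - th0), np.cos(theta - th0))
        d = np.sqrt((s - s0) ** 2 + (spec.base_radius * dth) ** 2)
        prof = np.where(d < br, np.cos(0.5 * np.pi * d / br) ** 2, 0.0)
        r = r - bh * prof
    return r


def tube_surface_distance(point, spec: SceneSpec):
    """Signed radial distance (cm) to the tube wall; negative inside the lumen.

    Continuous in the point; includes the haustral-fold radial modulation and
    polyp bumps. Accepts a single 3-vector or an (M,3) array.
    """
    P = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite query point")
    single = P.ndim == 1
    pl = _polyline(spec)
    s, _, rho, theta = pl.closest(np.atleast_2d(P))
    f = rho - _wall_radius(spec, s, theta)
    return float(f[0]) if single else f


def _surface_normal(points, spec, h=1e-5):
    """Outward (away-from-lumen) unit normal by central differences."""
    P = np.atleast_2d(points)
    g = np.zeros_like(P)
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        g[:, k] = (tube_surface_distance(P + e, spec) - tube_surface_distance(P - e, spec)) / (2 * h)
    n = np.linalg.norm(g, axis=1, keepdims=True)
    return g / np.maximum(n, 1e-12)


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------


def _march_rays(origins, dirs, spec, d_max, step=0.05, bisect_iters=50):
    """Vectorized first-crossing search; returns (t, hit_mask).

    Marches in ``step`` cm increments until the signed distance changes sign,
    then bisects the bracketing interval. Rays with no crossing within
    ``d_max`` are misses.
    """
    M = len(origins)
    f0 = tube_surface_distance(origins, spec)
    if np.any(f0 >= 0):
        raise ValueError("ray origin outside the lumen")
    t_lo = np.zeros(M)
    t_hi = np.zeros(M)
    hit = np.zeros(M, dtype=bool)
    active = np.ones(M, dtype=bool)
    t = 0.0
    while t < d_max and active.any():
        t_next = min(t + step, d_max)
        idx = np.flatnonzero(active)
        f = tube_surface_distance(origins[idx] + t_next * dirs[idx], spec)
        crossed = f >= 0
        ci = idx[crossed]
        t_lo[ci] = t
        t_hi[ci] = t_next
        hit[ci] = True
        active[ci] = False
        t = t_next
    idx = np.flatnonzero(hit)
    lo = t_lo[idx]
    hi = t_hi[idx]
    for _ in range(bisect_iters):
        mid = 0.5 * (lo + hi)
        f = tube_surface_distance(origins[idx] + mid[:, None] * dirs[idx], spec)
        neg = f < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    tout = np.full(M, np.nan)
    tout[idx] = 0.5 * (lo + hi)
    return tout, hit


def cast_ray(origin, direction, spec: SceneSpec, d_max=D_MAX_DEFAULT, step=0.05):
    """First positive ray parameter where the wall is crossed, or None (miss).

    ``origin`` must lie strictly inside the lumen and ``direction`` must be a
    unit vector. The crossing is refined by bisection well below 1e-4 cm.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
        raise ValueError("direction must be a unit vector")
    t, hit = _march_rays(o[None], d[None], spec, d_max, step=step)
    return float(t[0]) if hit[0] else None


# ---------------------------------------------------------------------------
# Shading and rendering
# ---------------------------------------------------------------------------


def _texture_albedo(material: MaterialSpec, s, theta, seed):
    """Per-hit-point albedo (M,3) from the procedural texture mode."""
    base = np.asarray(material.albedo, dtype=float)
    M = len(s)
    if material.texture_mode == "plain":
        return np.broadcast_to(base, (M, 3)).copy()
    if material.texture_mode == "vessel":
        # branching dark streak pattern in surface coordinates
        w = (
            np.sin(7.0 * theta + 1.3 * np.sin(0.9 * s))
            + np.sin(3.0 * theta - 0.7 * s + seed)
        )
        mask = np.exp(-8.0 * np.abs(np.sin(0.5 * w * np.pi)))
        mod = 1.0 - 0.45 * mask
        alb = base[None, :] * mod[:, None]
        alb[:, 0] = np.minimum(1.0, alb[:, 0] * (1.0 + 0.25 * mask))
        return alb
    # mottled: smooth value noise from hashed lattice of (s, theta)
    gs = np.floor(s / 0.8).astype(np.int64)
    gt = np.floor((theta + np.pi) / 0.6).astype(np.int64)

    def lattice(i, j):
        h = (i * 73856093 ^ j * 19349663 ^ np.int64(seed) * 83492791) & 0x7FFFFFFF
        return (h % 10007) / 10007.0

    fs = s / 0.8 - gs
    ft = (theta + np.pi) / 0.6 - gt
    fs = fs * fs * (3 - 2 * fs)
    ft = ft * ft * (3 - 2 * ft)
    v = (
        lattice(gs, gt) * (1 - fs) * (1 - ft)
        + lattice(gs + 1, gt) * fs * (1 - ft)
        + lattice(gs, gt + 1) * (1 - fs) * ft
        + lattice(gs + 1, gt + 1) * fs * ft
    )
    mod = 0.75 + 0.5 * v
    return np.clip(base[None, :] * mod[:, None], 0.0, 1.0)


def _shade(points, normals, s, theta, spec, pose, clip=True):
    """Two-light spot + inverse-square Lambert/Blinn-Phong shading, (M,3)."""
    mat = spec.material
    cam_fwd = pose.R @ np.array([0.0, 0.0, 1.0])
    albedo = _texture_albedo(mat, s, theta, spec.seed)
    view = pose.p[None, :] - points
    view /= np.maximum(np.linalg.norm(view, axis=1, keepdims=True), 1e-12)
    # shading normal faces the camera side of the wall (into the lumen)
    n = -normals
    rgb = np.zeros((len(points), 3))
    for light in spec.lights:
        lpos = pose.p + pose.R @ np.asarray(light.offset, dtype=float)
        tol = points - lpos[None, :]
        dist = np.linalg.norm(tol, axis=1)
        ldir = tol / np.maximum(dist[:, None], 1e-12)
        cos_cone = np.einsum("mk,k->m", ldir, cam_fwd)
        cos_cut = np.cos(light.spot_angle)
        spot = np.clip((cos_cone - cos_cut) / max(1.0 - cos_cut, 1e-9), 0.0, 1.0)
        spot = np.where(dist <= light.range, spot, 0.0)
        atten = light.intensity / np.maximum(dist, 0.25) ** 2
        ndotl = np.maximum(np.einsum("mk,mk->m", n, -ldir), 0.0)
        half = -ldir + view
        half /= np.maximum(np.linalg.norm(half, axis=1, keepdims=True), 1e-12)
        ndoth = np.maximum(np.einsum("mk,mk->m", n, half), 0.0)
        specular = mat.specular_coeff * ndoth**mat.shininess
        w = (spot * atten)[:, None] * np.asarray(light.color)[None, :]
        rgb += w * (albedo * ndotl[:, None] + specular[:, None])
    return np.clip(rgb, 0.0, 1.0) if clip else rgb


def render_pair(
    spec: SceneSpec,
    camera: CameraModel,
    pose: CameraPose,
    d_max=D_MAX_DEFAULT,
    step=0.05,
    subset_id=(0, 0),
    _clip=True,
) -> RenderedPair:
    """Ray-cast one RGB/depth pair from ``pose``.

    depth[v,u] is the Euclidean length of the ray through pixel (u,v) to the
    wall, capped at ``d_max``; misses (rays leaving the open tube) get
    depth=d_max and black RGB.
    """
    if tube_surface_distance(pose.p, spec) >= 0:
        raise ValueError("camera pose outside the lumen")
    rays = camera.pixel_rays().reshape(-1, 3) @ pose.R.T
    origins = np.broadcast_to(pose.p, rays.shape).copy()
    t, hit = _march_rays(origins, rays, spec, d_max, step=step)
    depth = np.where(hit, np.minimum(t, d_max), d_max)
    rgb = np.zeros((len(rays), 3))
    if hit.any():
        hp = origins[hit] + t[hit, None] * rays[hit]
        nrm = _surface_normal(hp, spec)
        pl = _polyline(spec)
        s, _, _, theta = pl.closest(hp)
        rgb[hit] = _shade(hp, nrm, s, theta, spec, pose, clip=_clip)
    H, W = camera.height, camera.width
    meta = {
        "seed": spec.seed,
        "pose_position": list(map(float, pose.p)),
        "pose_orientation": [list(map(float, r)) for r in pose.R],
        "spec_hash": spec.spec_hash(),
        "depth_convention": "ray_length",
    }
    return RenderedPair(
        rgb=rgb.reshape(H, W, 3),
        depth=depth.reshape(H, W),
        d_max=d_max,
        subset_id=tuple(subset_id),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Camera path sampling
# ---------------------------------------------------------------------------


def _rotvec_to_matrix(rv):
    ang = np.linalg.norm(rv)
    if ang < 1e-12:
        return np.eye(3)
    k = rv / ang
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K


def sample_camera_path(
    spec: SceneSpec,
    n_poses: int,
    shift_sigma: float = 0.2,
    rot_sigma: float = 0.1,
    seed: int = 0,
    margin: float = 1.0,
) -> list[CameraPose]:
    """Poses along the centerline, randomly shifted and rotated.

    Base poses sit at evenly spaced arc positions looking along the tangent;
    each is perturbed by a zero-mean Gaussian position shift (per-axis sigma
    ``shift_sigma`` cm) and a zero-mean rotation (rotation-vector components
    of sigma ``rot_sigma`` rad). Positions landing outside the lumen are
    resampled, up to 100 times each. Deterministic given ``seed``.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    pl = _polyline(spec)
    length = pl.length
    ss = np.linspace(margin, max(length - margin, margin), n_poses)
    poses = []
    for s in ss:
        p0, tang, n1, n2 = pl.frame_at(s)
        R0 = np.column_stack([n1, n2, tang])
        for attempt in range(101):
            shift = rng.normal(0.0, shift_sigma, 3) if shift_sigma > 0 else np.zeros(3)
            pos = p0 + shift
            if tube_surface_distance(pos, spec) < -1e-6:
                break
        else:
            raise RuntimeError(
                "could not place camera inside the lumen after 100 resamples; "
                "shift_sigma too large for this tube"
            )
        rv = rng.normal(0.0, rot_sigma, 3) if rot_sigma > 0 else np.zeros(3)
        R = _rotvec_to_matrix(rv) @ R0
        poses.append(
            CameraPose(position=tuple(pos), orientation=tuple(map(tuple, R)))
        )
    return poses


# ---------------------------------------------------------------------------
# Specular augmentation
# ---------------------------------------------------------------------------


def add_specular_artifacts(
    rgb: np.ndarray,
    n_blobs: int,
    seed: int = 0,
    sigma_range=None,
    support_sigmas: float = 3.0,
) -> np.ndarray:
    """Superimpose random bright elliptical highlights on an RGB image.

    Each highlight is an elliptical Gaussian pushed toward white:
    ``out = rgb + (1 - rgb) * g`` with peak g=1 and support truncated at
    ``support_sigmas`` standard deviations, so blobs are disjoint connected
    regions. Blob size defaults to 1.5-4 % of the image side. The paired
    depth map is not an argument and is never touched: specularities are a
    texture nuisance the predictor must learn to ignore, not a geometric
    feature.
    """
    if n_blobs < 0:
        raise ValueError("n_blobs must be >= 0")
    img = np.asarray(rgb, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("rgb must lie in [0,1]")
    if n_blobs == 0:
        return img.copy()
    H, W = img.shape[:2]
    if sigma_range is None:
        side = min(H, W)
        sigma_range = (max(0.015 * side, 0.6), max(0.04 * side, 1.2))
    rng = np.random.default_rng(seed)
    placed = []  # (cy, cx, support_radius)
    for _ in range(n_blobs):
        for attempt in range(500):
            sa = rng.uniform(*sigma_range)
            sb = sa * rng.uniform(0.4, 1.0)
            rad = support_sigmas * sa
            cy = rng.uniform(rad + 1, H - rad - 1)
            cx = rng.uniform(rad + 1, W - rad - 1)
            phi = rng.uniform(0, np.pi)
            if all(
                np.hypot(cy - py, cx - px) > rad + pr + 1.5 for py, px, pr in placed
            ):
                placed.append((cy, cx, rad))
                break
        else:
            raise RuntimeError("could not place non-overlapping highlights")
        yy, xx = np.mgrid[0:H, 0:W]
        dy, dx = yy - cy, xx - cx
        ca, sn = np.cos(phi), np.sin(phi)
        a = (ca * dx + sn * dy) / sa
        b = (-sn * dx + ca * dy) / sb
        q = a * a + b * b
        g = np.where(q < support_sigmas**2, np.exp(-0.5 * q), 0.0)
        img = img + (1.0 - img) * g[..., None]
    return np.clip(img, 0.0, 1.0)


def quantize_depth(depth: np.ndarray, step_cm: float) -> np.ndarray:
    """Optional stair-step post-process mimicking CT-derived depth quantization."""
    if step_cm <= 0:
        raise ValueError("step must be positive")
    return np.round(np.asarray(depth, dtype=float) / step_cm) * step_cm


# ---------------------------------------------------------------------------
# Domain-shifted rendering
# ---------------------------------------------------------------------------

_SHIFT_MATRIX = np.array(
    [[0.95, 0.35, 0.05], [0.12, 0.70, 0.10], [0.06, 0.22, 0.60]]
)


def render_domain_shifted(
    spec: SceneSpec,
    camera: CameraModel,
    pose: CameraPose,
    shift_profile: str = "default",
    d_max=D_MAX_DEFAULT,
    step=0.05,
    subset_id=(0, 0),
) -> RenderedPair:
    """Render the same geometry with an out-of-distribution appearance.

    The shifted profile swaps in a vessel texture with stronger, tighter
    specular lobes, re-aims the lights and applies a gamma + channel-mixing
    color remap, giving an RGB distribution disjoint from the training grid
    while the depth map is pixel-identical to the unshifted render (the
    shift is shading-only). The retained depth is for held-out scoring; it
    must never feed a reconstruction loss.
    """
    if shift_profile == "identity":
        return render_pair(spec, camera, pose, d_max=d_max, step=step, subset_id=subset_id)
    if shift_profile != "default":
        raise ValueError(f"unknown shift_profile {shift_profile!r}")
    mat = MaterialSpec(
        albedo=(0.62, 0.28, 0.22),
        specular_coeff=0.9,
        shininess=150.0,
        texture_mode="vessel",
    )
    lights = tuple(
        LightSpec(
            offset=(l.offset[0] * 0.3, l.offset[1] + 0.25, l.offset[2]),
            color=(1.0, 0.88, 0.72),
            intensity=l.intensity * 2.5,
            spot_angle=max(0.5 * l.spot_angle, 0.3),
            range=l.range,
        )
        for l in spec.lights
    )
    shifted = dataclasses.replace(spec, material=mat, lights=lights)
    pair = render_pair(shifted, camera, pose, d_max=d_max, step=step, subset_id=subset_id)
    rgb = np.clip(pair.rgb, 0.0, 1.0) ** 0.6
    rgb = np.clip(rgb @ _SHIFT_MATRIX.T, 0.0, 1.0)
    # wet-tissue reflections and the vignette of a real endoscope tip
    n_blobs = max(1, min(4, min(camera.width, camera.height) // 16))
    rgb = add_specular_artifacts(rgb, n_blobs, seed=spec.seed + int(1e3 * pose.p[2]))
    yy, xx = np.mgrid[0 : camera.height, 0 : camera.width]
    r2 = ((yy - camera.cy) / camera.height) ** 2 + ((xx - camera.cx) / camera.width) ** 2
    rgb = rgb * (1.0 - 0.7 * r2)[..., None]
    pair.rgb = np.clip(rgb, 0.0, 1.0)
    pair.meta["domain"] = "shifted"
    return pair


# ---------------------------------------------------------------------------
# Dataset generation (the 3 lights x 3 materials grid)
# ---------------------------------------------------------------------------


def material_grid():
    """Three tissue materials varying in colour, reflectiveness, smoothness."""
    return (
        MaterialSpec(albedo=(0.75, 0.35, 0.30), specular_coeff=0.15, shininess=20.0, texture_mode="plain"),
        MaterialSpec(albedo=(0.80, 0.45, 0.35), specular_coeff=0.35, shininess=60.0, texture_mode="mottled"),
        MaterialSpec(albedo=(0.65, 0.30, 0.28), specular_coeff=0.55, shininess=90.0, texture_mode="plain"),
    )


def light_grid():
    """Three two-light rigs varying in spot angle, range, colour, intensity."""
    def rig(color, intensity, spot, rng_cm):
        return (
            LightSpec(offset=(0.3, 0.0, 0.0), color=color, intensity=intensity, spot_angle=spot, range=rng_cm),
            LightSpec(offset=(-0.3, 0.0, 0.0), color=color, intensity=intensity, spot_angle=spot, range=rng_cm),
        )

    return (
        rig((1.0, 1.0, 1.0), 6.0, 1.2, 25.0),
        rig((1.0, 0.95, 0.85), 9.0, 0.9, 20.0),
        rig((0.9, 0.9, 1.0), 4.0, 1.5, 25.0),
    )


def default_scene(seed=0):
    """A gently curved tube with folds and two polyps; the stock test scene."""
    centerline = (
        (0.0, 0.0, 0.0),
        (0.5, 0.2, 8.0),
        (-0.4, 0.5, 16.0),
        (0.3, -0.3, 24.0),
        (0.0, 0.0, 32.0),
    )
    return SceneSpec(
        centerline=centerline,
        base_radius=1.5,
        fold_amplitude=0.25,
        fold_frequency=0.35,
        polyps=((10.0, 0.8, 0.8, 0.45), (20.0, -1.9, 0.6, 0.35)),
        seed=seed,
    )


def default_camera(size=64):
    return CameraModel(
        fx=0.9 * size, fy=0.9 * size, cx=(size - 1) / 2, cy=(size - 1) / 2,
        width=size, height=size,
    )


def _write_pair(pair: RenderedPair, camera: CameraModel, stem: str):
    import imageio.v3 as iio

    rgb8 = np.round(pair.rgb * 255.0).astype(np.uint8)
    iio.imwrite(stem + "_rgb.png", rgb8)
    d16 = np.round(pair.depth / pair.d_max * 65535.0).astype(np.uint16)
    iio.imwrite(stem + "_depth.png", d16)
    sidecar = {
        "d_max": pair.d_max,
        "subset_id": list(pair.subset_id),
        "camera": dataclasses.asdict(camera),
        **pair.meta,
    }
    with open(stem + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_pair(path_rgb: str, path_depth: str) -> RenderedPair:
    """Read back a written pair (8-bit RGB PNG + 16-bit depth PNG + sidecar)."""
    import imageio.v3 as iio

    rgb = iio.imread(path_rgb).astype(float) / 255.0
    stem = path_depth[: -len("_depth.png")]
    with open(stem + ".json") as fh:
        sidecar = json.load(fh)
    d_max = float(sidecar["d_max"])
    depth = iio.imread(path_depth).astype(float) * d_max / 65535.0
    return RenderedPair(
        rgb=rgb, depth=depth, d_max=d_max,
        subset_id=tuple(sidecar.get("subset_id", (0, 0))), meta=sidecar,
    )


def generate_dataset(
    out_dir: str,
    n_per_subset: int,
    seed: int = 0,
    scene: SceneSpec | None = None,
    camera: CameraModel | None = None,
    d_max: float = D_MAX_DEFAULT,
    shift_sigma: float = 0.2,
    rot_sigma: float = 0.1,
    n_domain_shifted: int = 0,
    specular_blobs: int = 0,
    stairstep: float = 0.0,
    step: float = 0.05,
):
    """Render the 9-subset dataset (3 lights x 3 materials) plus a manifest.

    Writes ``n_per_subset`` RGB/depth pairs per subset under ``out_dir`` and a
    ``manifest.csv`` with columns path_rgb, path_depth, subset, split, domain.
    Optionally appends ``n_domain_shifted`` domain-shifted frames (domain
    column = "shifted"). Deterministic given ``seed``. Returns the manifest
    as a list of row dicts.
    """
    if n_per_subset < 1:
        raise ValueError("n_per_subset must be >= 1")
    scene = scene or default_scene(seed)
    camera = camera or default_camera()
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    mats = material_grid()
    rigs = light_grid()
    for li, rig_lights in enumerate(rigs):
        for mi, mat in enumerate(mats):
            sub_seed = (seed * 97 + li * 31 + mi * 7) % (2**31)
            spec = dataclasses.replace(scene, material=mat, lights=rig_lights, seed=sub_seed)
            poses = sample_camera_path(
                spec, n_per_subset, shift_sigma, rot_sigma, seed=sub_seed
            )
            for k, pose in enumerate(poses):
                pair = render_pair(
                    spec, camera, pose, d_max=d_max, step=step, subset_id=(li, mi)
                )
                if specular_blobs > 0:
                    pair.rgb = add_specular_artifacts(
                        pair.rgb, specular_blobs, seed=sub_seed + 7919 * k
                    )
                if stairstep > 0:
                    pair.depth = np.clip(quantize_depth(pair.depth, stairstep), 0, d_max)
                stem = os.path.join(out_dir, f"L{li}M{mi}_{k:04d}")
                _write_pair(pair, camera, stem)
                rows.append(
                    {
                        "path_rgb": stem + "_rgb.png",
                        "path_depth": stem + "_depth.png",
                        "subset": f"L{li}M{mi}",
                        "split": "",
                        "domain": "synthetic",
                    }
                )
    if n_domain_shifted > 0:
        spec = dataclasses.replace(scene, seed=(seed * 97 + 991) % (2**31))
        poses = sample_camera_path(
            spec, n_domain_shifted, shift_sigma, rot_sigma, seed=spec.seed
        )
        for k, pose in enumerate(poses):
            pair = render_domain_shifted(spec, camera, pose, d_max=d_max, step=step)
            stem = os.path.join(out_dir, f"real_{k:04d}")
            _write_pair(pair, camera, stem)
            rows.append(
                {
                    "path_rgb": stem + "_rgb.png",
                    "path_depth": stem + "_depth.png",
                    "subset": "shifted",
                    "split": "",
                    "domain": "shifted",
                }
            )
    manifest_path = os.path.join(out_dir, "manifest.csv")
    _write_manifest(rows, manifest_path)
    return rows


def _write_manifest(rows, path):
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["path_rgb", "path_depth", "subset", "split", "domain"]
        )
        w.writeheader()
        w.writerows(rows)


def read_manifest(path):
    import csv

    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
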