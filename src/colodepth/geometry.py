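"""Phantom ground-truth geometry: triangulation, Procrustes, back-projection.

The physical-phantom validation chain locates spherical markers in an
undistorted stereo view, triangulates their 3D world positions, and aligns
the world frame to the virtual (rendering) frame with a similarity
transform estimated by Procrustes/Umeyama analysis from a handful (4-7) of
correspondences. Depth maps are lifted to 3D point clouds through the
inverse pinhole projection under the ray-length depth convention.

Coordinates are right-handed, the camera looks down +z, the pixel origin is
the top-left corner and pixel centres sit at integer coordinates. All pixel
coordinates entering this module are assumed already undistorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene_sim import CameraModel

__all__ = [
    "StereoRig",
    "SimilarityTransform",
    "triangulate",
    "procrustes_similarity",
    "apply_transform",
    "backproject",
    "project_points",
    "save_ply",
    "read_marker_csv",
]


@dataclass(frozen=True)
class StereoRig:
    """Calibrated stereo pair; (R, t) map left-frame points into the right frame."""

    left: CameraModel
    right: CameraModel
    R: tuple  # 3x3 rotation, rows as tuples
    t: tuple  # cm

    def __post_init__(self):
        R = self.Rm
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("R must be a proper rotation")
        if np.linalg.norm(self.tv) == 0:
            raise ValueError("baseline translation must be nonzero")

    @property
    def Rm(self):
        return np.asarray(self.R, dtype=float)

    @property
    def tv(self):
        return np.asarray(self.t, dtype=float)


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> s * R @ x + t with s > 0 and det(R) = +1."""

    s: float
    R: tuple
    t: tuple

    def __post_init__(self):
        R = self.Rm
        if self.s <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("R must be a proper rotation")

    @property
    def Rm(self):
        return np.asarray(self.R, dtype=float)

    @property
    def tv(self):
        return np.asarray(self.t, dtype=float)

    def inverse(self) -> "SimilarityTransform":
        Ri = self.Rm.T
        si = 1.0 / self.s
        ti = -si * Ri @ self.tv
        return SimilarityTransform(s=si, R=tuple(map(tuple, Ri)), t=tuple(ti))


def _pixel_ray(cam: CameraModel, px):
    d = np.array([(px[0] - cam.cx) / cam.fx, (px[1] - cam.cy) / cam.fy, 1.0])
    return d / np.linalg.norm(d)


def triangulate(rig: StereoRig, left_px, right_px):
    """Midpoint triangulation of one marker; returns (xyz_cm, residual_px).

    Back-projects the two pixel rays (left camera frame), solves the 2x2
    least-squares system for the closest points on each ray and returns
    their midpoint; the residual is the mean reprojection error over both
    views. Near-parallel rays (angle < 1e-4 rad) are rejected.
    """
    o1 = np.zeros(3)
    d1 = _pixel_ray(rig.left, left_px)
    # right camera centre and ray expressed in the left frame
    o2 = -rig.Rm.T @ rig.tv
    d2 = rig.Rm.T @ _pixel_ray(rig.right, right_px)
    cross = np.cross(d1, d2)
    if np.linalg.norm(cross) < 1e-4:
        raise ValueError("rays nearly parallel; triangulation ill-posed")
    # [s, u] minimizing ||o1 + s d1 - (o2 + u d2)||
    A = np.array([[1.0, -d1 @ d2], [d1 @ d2, -1.0]])
    b = np.array([(o2 - o1) @ d1, (o2 - o1) @ d2])
    s, u = np.linalg.solve(A, b)
    p = 0.5 * (o1 + s * d1 + o2 + u * d2)
    lp = rig.left.project(p[None])[0]
    rp = rig.right.project((rig.Rm @ p + rig.tv)[None])[0]
    residual = 0.5 * (
        np.linalg.norm(lp - np.asarray(left_px, float))
        + np.linalg.norm(rp - np.asarray(right_px, float))
    )
    return p, float(residual)


def procrustes_similarity(src, dst, allow_scale=True):
    """Least-squares similarity transform aligning src onto dst (Umeyama).

    Minimizes sum_i ||s R src_i + t - dst_i||^2 over s>0, proper rotations R
    and translations t; the reflection branch is rejected by flipping the
    smallest singular vector. Returns (SimilarityTransform, rmse_cm).
    Requires N >= 3 non-collinear source points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (N,3) arrays")
    n = len(src)
    if n < 3:
        raise ValueError("need at least 3 correspondences")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = dc.T @ sc / n
    U, D, Vt = np.linalg.svd(cov)
    if D[1] < 1e-12 * max(D[0], 1.0):
        raise ValueError("source points are collinear or degenerate")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_s = float(np.mean(np.sum(sc**2, axis=1)))
    s = float(np.trace(np.diag(D) @ S) / var_s) if allow_scale else 1.0
    t = mu_d - s * R @ mu_s
    T = SimilarityTransform(s=s, R=tuple(map(tuple, R)), t=tuple(t))
    res = apply_transform(T, src) - dst
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return T, rms


def apply_transform(T: SimilarityTransform, points):
    """s * R @ p + t applied to a 3-vector or (N,3) array."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    out = T.s * np.atleast_2d(p) @ T.Rm.T + T.tv
    return out[0] if single else out


def backproject(depth, camera: CameraModel, drop_cap=False, d_max=None):
    """Lift a depth map to an (H*W, 3) camera-frame point cloud (cm).

    Each pixel maps to depth * unit_ray under the Euclidean ray-length depth
    convention. With ``drop_cap`` pixels at the cap (``d_max``, default the
    map maximum) are removed — they are misses, not surface points.
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    if d.shape != (camera.height, camera.width):
        raise ValueError("depth shape disagrees with camera model")
    rays = camera.pixel_rays().reshape(-1, 3)
    pts = d.reshape(-1, 1) * rays
    if drop_cap:
        cap = float(d.max()) if d_max is None else float(d_max)
        pts = pts[d.reshape(-1) < cap - 1e-9]
    return pts


def project_points(camera: CameraModel, points):
    """Pinhole projection of (N,3) camera-frame points to (N,2) pixels."""
    return camera.project(np.asarray(points, dtype=float))


def save_ply(path, points):
    """ASCII PLY point-cloud writer."""
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(pts)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_marker_csv(path):
    """Read a marker correspondence table.

    Two layouts are accepted: stereo observations with columns
    ``id,lx,ly,rx,ry`` (pixels) or 3D correspondences with columns
    ``id,wx,wy,wz,vx,vy,vz`` (world cm / virtual units). Returns a list of
    row dicts with float fields.
    """
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for r in rows:
        parsed = {"id": r["id"]}
        for k, v in r.items():
            if k != "id":
                parsed[k] = float(v)
        out.append(parsed)
    return out
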