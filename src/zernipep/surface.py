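"""Solvent-accessible surface point clouds and the patch → disk-image
pipeline feeding the 2D Zernike descriptors.

The surface is a discrete point cloud with outward unit normals, built by
deterministic spiral-lattice sampling of per-atom spheres inflated by the
water-probe radius, with points occluded by neighbouring atoms removed
(a DMS-equivalent construction).  A patch is the set of surface points
inside a Euclidean ball around a chosen surface point.  For descriptor
computation the patch is rigidly reoriented so its mean normal lies on the
z-axis, viewed from an on-axis apex point C chosen so the widest secant
angle is 45°, and binned onto a square grid over the unit disk where each
pixel holds the mean secant length r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ChainStructure
from .errors import (
    ConfigurationError,
    DegenerateOrientationError,
    EmptyInputError,
    EmptyPatchError,
    SolverError,
)

#: Fallback van der Waals radii (Å) by element when atoms carry no Rmin/2.
ELEMENT_RADII = {"H": 1.1, "C": 1.9, "N": 1.85, "O": 1.7, "S": 2.0}
DEFAULT_RADIUS = 1.8


@dataclass
class SurfacePointCloud:
    """Discretized solvent-accessible surface with outward unit normals."""

    points: np.ndarray          # (N, 3) Å
    normals: np.ndarray         # (N, 3) unit vectors
    atom_index: np.ndarray      # (N,) generating-atom index into structure.atoms()
    density: float              # requested points / Å^2
    probe_radius: float         # Å

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SurfacePatch:
    """Surface points within ``region_radius`` of ``center``."""

    points: np.ndarray
    normals: np.ndarray
    atom_index: np.ndarray
    center: np.ndarray
    region_radius: float

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class OrientedPatch:
    """Patch in the frame whose +z axis is the patch mean normal."""

    points: np.ndarray          # (N, 3), centroid at origin
    rotation: np.ndarray        # (3, 3) applied rigid rotation
    apex_height: float | None = None
    theta: float | None = None  # degrees


@dataclass
class DiskImage:
    """Square-grid image over the unit disk of mean secant lengths r."""

    grid: np.ndarray            # (G, G) float, 0 outside mask
    mask: np.ndarray            # (G, G) bool: pixels inside unit disk
    counts: np.ndarray          # (G, G) int: points binned per pixel
    grid_size: int

    @property
    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.grid_size
        c = (np.arange(g) + 0.5) * 2.0 / g - 1.0
        return np.meshgrid(c, c, indexing="xy")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice of n points."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i      # golden-angle increments
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def atom_radius(atom) -> float:
    if atom.lj_rmin_half is not None:
        return float(atom.lj_rmin_half)
    return ELEMENT_RADII.get(atom.element.upper(), DEFAULT_RADIUS)


def _canonical_frame(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic molecule-intrinsic frame (centroid, rotation columns).

    Principal axes of the atom-position covariance, ordered by decreasing
    eigenvalue, signs fixed by the third moment of the projections (falling
    back to the largest-magnitude coordinate when skewness vanishes), with
    a right-handed determinant.  Because the frame co-rotates with the
    structure, surfaces sampled in it are rigid-motion covariant.
    """
    c = centers.mean(axis=0)
    x = centers - c
    if len(centers) < 4:
        return c, np.eye(3)
    cov = x.T @ x / len(x)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending eigenvalue order
    for k in range(3):
        proj = x @ v[:, k]
        skew = np.mean(proj**3)
        if abs(skew) > 1e-9:
            if skew < 0:
                v[:, k] = -v[:, k]
        elif proj[np.argmax(np.abs(proj))] < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return c, v


def compute_sas_points(
    structure: ChainStructure,
    density: float = 5.0,
    probe_radius: float = 1.4,
) -> SurfacePointCloud:
    """Sample the solvent-accessible surface at the requested point density.

    Each atom sphere of radius (vdW + probe) is sampled on a deterministic
    spiral lattice; points falling inside any neighbouring atom's inflated
    sphere are discarded.  Normals point radially away from the generating
    atom center.  Sampling happens in a molecule-intrinsic principal-axes
    frame, so the resulting cloud co-rotates rigidly with the structure.
    """
    if density <= 0 or probe_radius < 0:
        raise ConfigurationError("density must be > 0 and probe_radius >= 0")
    atoms = structure.atoms()
    if not atoms:
        raise EmptyInputError("structure has no atoms")
    raw_centers = np.array([a.position for a in atoms])
    frame_origin, frame_rot = _canonical_frame(raw_centers)
    centers = (raw_centers - frame_origin) @ frame_rot
    radii = np.array([atom_radius(a) + probe_radius for a in atoms])
    tree = cKDTree(centers)
    max_r = radii.max()

    all_pts, all_nrm, all_idx = [], [], []
    for i, (c, r) in enumerate(zip(centers, radii)):
        n_pts = max(12, int(round(density * 4.0 * np.pi * r * r)))
        dirs = _fibonacci_sphere(n_pts)
        pts = c + r * dirs
        neighbours = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        keep = np.ones(n_pts, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            keep &= d2 >= (radii[j] - 1e-9) ** 2
        if keep.any():
            all_pts.append(pts[keep])
            all_nrm.append(dirs[keep])
            all_idx.append(np.full(int(keep.sum()), i))
    if not all_pts:
        # fully buried structure: no accessible surface
        return SurfacePointCloud(
            np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0, dtype=int),
            density, probe_radius,
        )
    pts = np.vstack(all_pts) @ frame_rot.T + frame_origin
    nrm = np.vstack(all_nrm) @ frame_rot.T
    return SurfacePointCloud(
        pts, nrm, np.concatenate(all_idx), density, probe_radius,
    )


def read_dms(text: str, density: float = 5.0, probe_radius: float = 1.4) -> SurfacePointCloud:
    """Read a DMS-style point file: x y z nx ny nz per line.

    Lets an externally computed molecular surface be substituted for the
    built-in sampler.
    """
    pts, nrms = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = [float(v) for v in line.split()[:6]]
        pts.append(vals[:3])
        nrms.append(vals[3:6])
    if not pts:
        raise EmptyInputError("no surface points in DMS input")
    normals = np.array(nrms)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfacePointCloud(
        np.array(pts), normals, np.full(len(pts), -1), density, probe_radius
    )


def extract_patch(
    cloud: SurfacePointCloud, center, region_radius: float
) -> SurfacePatch:
    """Points of the cloud within a Euclidean ball (boundary inclusive)."""
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(cloud.points - center, axis=1)
    keep = d <= region_radius + 1e-12
    if not keep.any():
        raise EmptyPatchError(
            f"no surface points within {region_radius} Å of {center}"
        )
    return SurfacePatch(
        cloud.points[keep], cloud.normals[keep], cloud.atom_index[keep],
        center, region_radius,
    )


def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rigid rotation taking unit vector u onto unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180° flip about any axis orthogonal to u
        a = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, a)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    k = axis / s
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    angle = np.arctan2(s, c)
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def reorient_patch(patch: SurfacePatch, flip: bool = False) -> OrientedPatch:
    """Rigidly rotate the patch so its mean normal is the +z axis.

    With ``flip=True`` the mean normal is aligned to −z instead — the
    convention used for the second surface of a complementarity pair, so
    that two interlocking patches are both viewed "from outside" and
    complementary shapes give similar disk images.
    """
    mean_n = patch.normals.mean(axis=0)
    norm = np.linalg.norm(mean_n)
    if norm < 1e-9:
        raise DegenerateOrientationError("patch mean normal is numerically zero")
    u = mean_n / norm
    target = np.array([0.0, 0.0, -1.0 if flip else 1.0])
    R = _rotation_aligning(u, target)
    pts = patch.points - patch.points.mean(axis=0)
    rotated = pts @ R.T
    if flip:
        # view the flipped patch from above: mirror z so the apex construction
        # is identical for both orientations
        rotated = rotated * np.array([1.0, 1.0, -1.0])
    # canonicalize the free azimuth: principal xy axis (skew-sign-fixed) -> +x,
    # so the oriented patch is independent of the input's global orientation
    xy = rotated[:, :2]
    if len(xy) > 3:
        cov = xy.T @ xy
        _, vecs = np.linalg.eigh(cov)
        axis = vecs[:, -1]
        proj = xy @ axis
        skew = np.mean(proj**3)
        if abs(skew) > 1e-9:
            if skew < 0:
                axis = -axis
        elif len(proj) and proj[np.argmax(np.abs(proj))] < 0:
            axis = -axis
        cos_a, sin_a = axis
        Rz = np.array(
            [[cos_a, sin_a, 0.0], [-sin_a, cos_a, 0.0], [0.0, 0.0, 1.0]]
        )
        rotated = rotated @ Rz.T
    return OrientedPatch(points=rotated, rotation=R)


def fit_apex_point(
    patch: OrientedPatch, theta_target: float = 45.0, tol: float = 1e-6
) -> float:
    """Height h of the on-axis apex C = (0,0,h) from which the widest secant
    angle to the patch equals ``theta_target`` degrees.

    The maximum secant angle decreases strictly with h (for C above every
    point), so bisection converges; h is returned in Å.
    """
    pts = patch.points
    if len(pts) == 0:
        raise EmptyPatchError("cannot fit apex of an empty patch")
    target = np.deg2rad(theta_target)
    zmax = pts[:, 2].max()
    rho = np.linalg.norm(pts[:, :2], axis=1)

    def max_angle(h: float) -> float:
        dz = h - pts[:, 2]
        return float(np.max(np.arctan2(rho, dz)))

    lo = zmax + 1e-9
    hi = max(zmax + 1.0, 2.0 * (np.abs(pts).max() + 1.0))
    for _ in range(200):
        if max_angle(hi) < target:
            break
        hi *= 2.0
    else:
        raise SolverError("could not bracket apex height from above")
    if max_angle(lo) < target:
        raise SolverError(
            f"no apex height reaches theta = {theta_target}° (patch too steep/flat)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if max_angle(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, abs(hi)):
            break
    h = 0.5 * (lo + hi)
    patch.apex_height = h
    patch.theta = theta_target
    return h


def project_to_disk(
    patch: OrientedPatch,
    apex_height: float,
    grid_size: int = 64,
    theta_max: float = 45.0,
    fill: bool = True,
) -> DiskImage:
    """Bin patch points into a square grid over the unit disk.

    Each point's secant from C = (0,0,apex_height) is mapped to unit-disk
    coordinates (sin α / sin θ_max)·(cos ϕ, sin ϕ), with α the secant's
    angle to the z-axis and ϕ its azimuth; the pixel value is the mean
    secant length r of the points it receives.  Interior pixels left empty
    are filled once from their valid 8-neighbourhood (else the patch mean),
    so the expansion integrand is defined on the whole disk.
    """
    if grid_size < 8:
        raise ConfigurationError("grid_size must be >= 8")
    pts = patch.points
    C = np.array([0.0, 0.0, apex_height])
    v = pts - C
    dz = -v[:, 2]
    if np.any(dz <= 0):
        raise SolverError("apex must lie strictly above all patch points")
    r = np.linalg.norm(v, axis=1)
    alpha = np.arctan2(np.linalg.norm(v[:, :2], axis=1), dz)
    phi = np.arctan2(v[:, 1], v[:, 0])
    s = np.sin(alpha) / np.sin(np.deg2rad(theta_max))
    x = s * np.cos(phi)
    y = s * np.sin(phi)

    g = grid_size
    ix = np.clip(((x + 1.0) * 0.5 * g).astype(int), 0, g - 1)
    iy = np.clip(((y + 1.0) * 0.5 * g).astype(int), 0, g - 1)
    counts = np.zeros((g, g), dtype=int)
    sums = np.zeros((g, g))
    np.add.at(counts, (iy, ix), 1)
    np.add.at(sums, (iy, ix), r)

    cx, cy = np.meshgrid(
        (np.arange(g) + 0.5) * 2.0 / g - 1.0,
        (np.arange(g) + 0.5) * 2.0 / g - 1.0,
        indexing="xy",
    )
    in_disk = cx * cx + cy * cy <= 1.0
    grid = np.zeros((g, g))
    occupied = counts > 0
    grid[occupied] = sums[occupied] / counts[occupied]

    if fill:
        empty = in_disk & ~occupied
        if empty.any() and occupied.any():
            filled = grid.copy()
            occ = occupied.copy()
            ys, xs = np.nonzero(empty)
            patch_mean = grid[occupied].mean()
            for yy, xx in zip(ys, xs):
                y0, y1 = max(0, yy - 1), min(g, yy + 2)
                x0, x1 = max(0, xx - 1), min(g, xx + 2)
                nb_occ = occ[y0:y1, x0:x1]
                if nb_occ.any():
                    filled[yy, xx] = grid[y0:y1, x0:x1][nb_occ].mean()
                else:
                    filled[yy, xx] = patch_mean
            grid = filled
    grid[~in_disk] = 0.0
    return DiskImage(grid=grid, mask=in_disk, counts=counts, grid_size=g)


def normalize_disk_image(image: DiskImage) -> DiskImage:
    """Shift/scale masked values to zero mean and unit max-abs.

    Makes descriptor distances comparable across patches of different
    absolute size; flat images (zero spread) map to all-zero.
    """
    vals = image.grid[image.mask]
    out = image.grid.copy()
    if len(vals):
        shifted = vals - vals.mean()
        m = np.abs(shifted).max()
        out[image.mask] = shifted / m if m > 0 else 0.0
    out[~image.mask] = 0.0
    return DiskImage(out, image.mask, image.counts, image.grid_size)


def patch_disk_image(
    patch: SurfacePatch,
    grid_size: int = 64,
    theta: float = 45.0,
    flip: bool = False,
    normalize: bool = True,
) -> DiskImage:
    """Full patch → oriented → apex → disk-image pipeline."""
    oriented = reorient_patch(patch, flip=flip)
    h = fit_apex_point(oriented, theta_target=theta)
    img = project_to_disk(oriented, h, grid_size=grid_size, theta_max=theta)
    return normalize_disk_image(img) if normalize else img
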