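"""2D Zernike expansion of disk images and rotation-invariant descriptors.

A real function f(r, ϕ) on the unit disk is expanded in the complex
Zernike basis Z_nm = R_nm(r)·e^{imϕ} with coefficients

    c_nm = (n+1)/π · ⟨Z_nm | f⟩,

where the inner product is approximated by a midpoint Riemann sum over the
square pixels of the disk image clipped to the unit disk.  Only m ≥ 0 with
(n − m) even is stored: for real images the moduli of ±m coefficients
coincide, and this convention yields 121 coefficients at maximum order
N = 20.  The moduli z_nm = |c_nm| are invariant under rotations of the
image about the disk center and serve as compact shape descriptors; two
patches are compared by the Euclidean distance between their invariant
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np

from .errors import EmptyInputError
from .surface import DiskImage


def index_pairs(order: int) -> list[tuple[int, int]]:
    """(n, m) pairs with 0 ≤ m ≤ n ≤ order and n − m even, lexicographic."""
    if order < 0:
        raise ValueError("order must be >= 0")
    return [(n, m) for n in range(order + 1) for m in range(n + 1) if (n - m) % 2 == 0]


def coefficient_count(order: int) -> int:
    """Number of stored coefficients up to the given maximum order."""
    return len(index_pairs(order))


def radial_polynomial(n: int, m: int, r) -> np.ndarray:
    """Radial Zernike polynomial R_nm evaluated at r (scalar or array).

    R_nm(r) = Σ_k (−1)^k (n−k)! / [k! ((n+m)/2−k)! ((n−m)/2−k)!] · r^{n−2k}
    for 0 ≤ m ≤ n with n − m even.
    """
    if not (0 <= m <= n):
        raise ValueError(f"need 0 <= m <= n, got (n, m) = ({n}, {m})")
    if (n - m) % 2:
        raise ValueError(f"(n - m) must be even, got (n, m) = ({n}, {m})")
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for k in range((n - m) // 2 + 1):
        coef = ((-1) ** k * factorial(n - k)) / (
            factorial(k)
            * factorial((n + m) // 2 - k)
            * factorial((n - m) // 2 - k)
        )
        out = out + coef * r ** (n - 2 * k)
    return out


@dataclass
class ZernikeExpansion:
    """Complex coefficients c_nm of a disk image up to maximum order N."""

    order: int
    coefficients: dict[tuple[int, int], complex]
    grid_size: int

    def vector(self) -> np.ndarray:
        return np.array([self.coefficients[p] for p in index_pairs(self.order)])


@dataclass
class InvariantVector:
    """Rotation-invariant moduli z_nm = |c_nm| in lexicographic (n,m) order."""

    values: np.ndarray
    order: int

    def __len__(self) -> int:
        return len(self.values)


@lru_cache(maxsize=8)
def _disk_pixels(grid_size: int):
    """Pixel-center polar coordinates and in-disk mask for a G×G grid."""
    g = grid_size
    c = (np.arange(g) + 0.5) * 2.0 / g - 1.0
    x, y = np.meshgrid(c, c, indexing="xy")
    r = np.sqrt(x * x + y * y)
    mask = r <= 1.0
    phi = np.arctan2(y, x)
    return r, phi, mask


@lru_cache(maxsize=8)
def _real_design_matrix(order: int, grid_size: int) -> np.ndarray:
    """Real design matrix of the truncated series at in-disk pixel centers.

    A real image is modelled as Re Σ ε_m c_nm Z_nm with ε_0 = 1, ε_m = 2
    (negative-m terms are conjugates of positive-m ones).  Per (n, m) pair
    the matrix holds one column R_n0 for m = 0 and two columns
    (2·R_nm·cos mϕ, −2·R_nm·sin mϕ) for m > 0, multiplying Re c and Im c.
    """
    r, phi, mask = _disk_pixels(grid_size)
    rm, phim = r[mask], phi[mask]
    cols = []
    for n, m in index_pairs(order):
        rad = radial_polynomial(n, m, np.clip(rm, 0.0, 1.0))
        if m == 0:
            cols.append(rad)
        else:
            cols.append(2.0 * rad * np.cos(m * phim))
            cols.append(-2.0 * rad * np.sin(m * phim))
    return np.column_stack(cols)


@lru_cache(maxsize=8)
def _projection_matrix(order: int, grid_size: int) -> np.ndarray:
    """Pseudo-inverse of the design matrix: pixels -> real/imag coefficients.

    Least-squares projection onto the sampled basis; because the sampled
    Zernike functions are near-orthogonal, this agrees with the (n+1)/π
    quadrature of the analytic inner product up to grid resolution, while
    representing band-limited images exactly.
    """
    return np.linalg.pinv(_real_design_matrix(order, grid_size))


def expand(image: DiskImage, order: int = 20) -> ZernikeExpansion:
    """Zernike coefficients c_nm of a disk image.

    Coefficients are the least-squares projection of the pixel values onto
    the sampled basis (equivalent to the (n+1)/π inner-product quadrature
    in the continuum limit).  Masked-out pixels contribute zero.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    _, _, disk = _disk_pixels(image.grid_size)
    if not (image.mask & disk).any():
        raise EmptyInputError("disk image has no valid pixels")
    f = np.where(image.mask, image.grid, 0.0)[disk]
    raw = _projection_matrix(order, image.grid_size) @ f
    coeffs: dict[tuple[int, int], complex] = {}
    i = 0
    for n, m in index_pairs(order):
        if m == 0:
            coeffs[(n, m)] = complex(raw[i], 0.0)
            i += 1
        else:
            coeffs[(n, m)] = complex(raw[i], raw[i + 1])
            i += 2
    return ZernikeExpansion(order, coeffs, image.grid_size)


def reconstruct(expansion: ZernikeExpansion, grid_size: int | None = None) -> DiskImage:
    """Real part of the truncated Zernike series sampled on a square grid.

    For a real image the negative-m terms are conjugates of the stored
    positive-m ones, so the m > 0 contributions enter with weight 2.
    """
    g = grid_size or expansion.grid_size
    r, phi, mask = _disk_pixels(g)
    rm, phim = r[mask], phi[mask]
    total = np.zeros(len(rm), dtype=complex)
    for (n, m), c in expansion.coefficients.items():
        zb = radial_polynomial(n, m, rm) * np.exp(1j * m * phim)
        total += (2.0 if m else 1.0) * c * zb
    grid = np.zeros((g, g))
    grid[mask] = np.real(total)
    counts = np.zeros((g, g), dtype=int)
    return DiskImage(grid=grid, mask=mask, counts=counts, grid_size=g)


def invariants(expansion: ZernikeExpansion) -> InvariantVector:
    """Rotation-invariant descriptor vector z_nm = |c_nm|."""
    vals = np.abs(expansion.vector())
    return InvariantVector(vals, expansion.order)


def descriptor_distance(a: InvariantVector, b: InvariantVector) -> float:
    """Euclidean distance between two invariant vectors of equal order."""
    if a.order != b.order or len(a) != len(b):
        raise ValueError(
            f"descriptor orders differ: {a.order} (len {len(a)}) vs "
            f"{b.order} (len {len(b)})"
        )
    return float(np.linalg.norm(a.values - b.values))


def basis_inner_products(order: int, grid_size: int = 256, sub: int = 5) -> np.ndarray:
    """Gram matrix ⟨Z_nm|Z_n'm'⟩ by subdivided pixel quadrature.

    Each pixel of the G×G grid is integrated with a sub×sub midpoint rule
    clipped to the unit disk.  Analytically the Gram matrix is
    π/(n+1)·δ_nn'·δ_mm'; comparing against that verifies the quadrature.
    """
    gs = grid_size * sub
    c = (np.arange(gs) + 0.5) * 2.0 / gs - 1.0
    x, y = np.meshgrid(c, c, indexing="xy")
    r = np.sqrt(x * x + y * y)
    inside = r <= 1.0
    rm, phim = r[inside], np.arctan2(y, x)[inside]
    rows = np.array(
        [
            radial_polynomial(n, m, rm) * np.exp(-1j * m * phim)
            for n, m in index_pairs(order)
        ]
    )
    return rows @ rows.conj().T * (2.0 / gs) ** 2
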