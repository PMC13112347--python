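"""Deterministic generators for every input class the toolkit consumes.

These fixtures are geometric, not biological: toy two-chain complexes with
ideal extended backbones, synthetic trajectories with prescribed
per-residue contact occupancy, analytic disk images exercising the
Zernike machinery, and single-atom structures for surface tests.  All
generators are deterministic under their seed — that is the package's
reproducibility contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomRecord, ChainStructure, ResidueRecord, Trajectory
from .errors import ConfigurationError
from .surface import DiskImage
from .zernike import index_pairs, radial_polynomial

_CA_SPACING = 3.8  # Å between consecutive Cα along an extended chain


@dataclass
class ToyDimerSpec:
    """Parameters of a synthetic two-chain complex."""

    n_residues: int = 8
    separation: float = 6.0       # Å between facing Cα rows
    geometry: str = "extended"    # extended | helical
    seed: int = 0
    residue_type: str = "ALA"
    chain_ids: tuple[str, str] = ("A", "B")
    n_residues_b: int | None = None

    def __post_init__(self):
        if self.n_residues < 2:
            raise ConfigurationError("n_residues must be >= 2")
        if self.separation <= 0:
            raise ConfigurationError("separation must be > 0")


@dataclass
class ContactSchedule:
    """Per-residue target contact occupancy over a synthetic trajectory."""

    occupancies: np.ndarray
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self):
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if np.any((self.occupancies < 0) | (self.occupancies > 1)):
            raise ConfigurationError("occupancies must lie in [0, 1]")


def _chain_residues(
    chain_id: str,
    n_res: int,
    origin: np.ndarray,
    side_sign: float,
    geometry: str,
    residue_type: str,
    rng: np.random.Generator,
) -> list[ResidueRecord]:
    residues = []
    for i in range(n_res):
        if geometry == "extended":
            ca = origin + np.array([_CA_SPACING * i, 0.0, 0.0])
        elif geometry == "helical":
            ang = np.deg2rad(100.0 * i)
            ca = origin + np.array(
                [1.5 * i, 2.3 * np.cos(ang), 2.3 * np.sin(ang)]
            )
        else:
            raise ConfigurationError(f"unknown geometry {geometry!r}")
        jitter = rng.normal(0.0, 0.01, size=(5, 3))
        atoms = [
            AtomRecord("N", "N", ca + np.array([-1.2, 0.5 * side_sign, 0.0]) + jitter[0]),
            AtomRecord("CA", "C", ca + jitter[1]),
            AtomRecord("C", "C", ca + np.array([1.2, 0.5 * side_sign, 0.0]) + jitter[2]),
            AtomRecord("O", "O", ca + np.array([1.4, 1.6 * side_sign, 0.0]) + jitter[3]),
        ]
        if residue_type != "GLY":
            atoms.append(
                AtomRecord(
                    "CB", "C",
                    ca + np.array([0.0, 1.3 * side_sign, 0.9]) + jitter[4],
                )
            )
        residues.append(ResidueRecord(chain_id, i + 1, residue_type, atoms))
    return residues


def make_toy_dimer(spec: ToyDimerSpec) -> ChainStructure:
    """Two facing poly-peptide chains at the prescribed Cα separation.

    Chain A lies along +x with side chains pointing toward chain B, which
    runs parallel at y = separation with side chains pointing back.  A
    0.01 Å seeded jitter breaks exact symmetry while keeping coordinates
    bit-identical for equal seeds.
    """
    if spec.separation < 2.0:
        raise ConfigurationError(
            f"separation {spec.separation} Å would clash (< 2 Å)"
        )
    rng = np.random.default_rng(spec.seed)
    cid_a, cid_b = spec.chain_ids
    n_b = spec.n_residues_b or spec.n_residues
    res_a = _chain_residues(
        cid_a, spec.n_residues, np.zeros(3), +1.0, spec.geometry,
        spec.residue_type, rng,
    )
    offset_b = np.array(
        [(spec.n_residues - n_b) * _CA_SPACING / 2.0, spec.separation, 0.0]
    )
    res_b = _chain_residues(
        cid_b, n_b, offset_b, -1.0, spec.geometry, spec.residue_type, rng,
    )
    return ChainStructure({cid_a: res_a, cid_b: res_b})


def make_synthetic_trajectory(
    dimer: ChainStructure,
    schedule: ContactSchedule,
    chain_id: str = "A",
    displacement: float = 50.0,
) -> Trajectory:
    """Trajectory whose chain-A residues realize prescribed contact
    occupancies.

    For each residue the number of in-contact frames is
    round(occupancy·n_frames); a seeded permutation decides which frames.
    Out-of-contact frames displace the residue's atoms by ``displacement``
    Å along +z, far beyond any contact cutoff.
    """
    residues = dimer.residues(chain_id)
    if len(schedule.occupancies) != len(residues):
        raise ConfigurationError(
            f"schedule length {len(schedule.occupancies)} != chain "
            f"{chain_id} length {len(residues)}"
        )
    rng = np.random.default_rng(schedule.seed)
    n = schedule.n_frames
    in_contact = np.zeros((len(residues), n), dtype=bool)
    for i, occ in enumerate(schedule.occupancies):
        k = int(round(occ * n))
        frames = rng.permutation(n)[:k]
        in_contact[i, frames] = True
    shift = np.array([0.0, 0.0, displacement])
    frames = []
    for f in range(n):
        frame = dimer.copy()
        for i, res in enumerate(frame.residues(chain_id)):
            if not in_contact[i, f]:
                for a in res.atoms:
                    a.position = a.position + shift
        frame.model_id = f + 1
        frames.append(frame)
    return Trajectory(frames)


def make_sphere_structure(
    position=(0.0, 0.0, 0.0),
    rmin_half: float = 1.9,
    epsilon: float = 0.1,
    charge: float = 0.0,
    atom_name: str = "CA",
    chain_id: str = "A",
) -> ChainStructure:
    """Single parameterized atom, for spherical-surface tests."""
    atom = AtomRecord(
        atom_name, "C", np.asarray(position, dtype=float),
        partial_charge=charge, lj_epsilon=epsilon, lj_rmin_half=rmin_half,
    )
    res = ResidueRecord(chain_id, 1, "ALA", [atom])
    return ChainStructure({chain_id: [res]})


# ---------------------------------------------------------------------------
# Analytic disk images
# ---------------------------------------------------------------------------

def _grid_polar(grid_size: int):
    c = (np.arange(grid_size) + 0.5) * 2.0 / grid_size - 1.0
    x, y = np.meshgrid(c, c, indexing="xy")
    r = np.sqrt(x * x + y * y)
    return r, np.arctan2(y, x), r <= 1.0


def _as_image(fn, grid_size: int) -> DiskImage:
    r, phi, mask = _grid_polar(grid_size)
    grid = np.where(mask, fn(np.clip(r, 0.0, 1.0), phi), 0.0)
    return DiskImage(
        grid=grid, mask=mask, counts=np.zeros_like(grid, dtype=int),
        grid_size=grid_size,
    )


def make_analytic_disk_image(
    kind: str,
    grid_size: int = 64,
    n: int | None = None,
    m: int | None = None,
    rotation: float = 0.0,
    center=(0.3, 0.0),
    width: float = 0.3,
) -> DiskImage:
    """Exact function values of a known shape sampled on the pixel grid.

    Kinds: ``constant`` (f ≡ 1), ``zernike_mode`` (Re Z_nm, needs n, m),
    ``gaussian_bump`` (off-center bump of the given width).  ``rotation``
    (radians) evaluates the function at ϕ − rotation, i.e. rotates the
    image about the disk center without any resampling error.
    """
    if kind == "constant":
        return _as_image(lambda r, p: np.ones_like(r), grid_size)
    if kind == "zernike_mode":
        if n is None or m is None or not (0 <= m <= n) or (n - m) % 2:
            raise ConfigurationError(f"invalid zernike mode (n={n}, m={m})")
        return _as_image(
            lambda r, p: radial_polynomial(n, m, r) * np.cos(m * (p - rotation)),
            grid_size,
        )
    if kind == "gaussian_bump":
        cx, cy = center
        c = complex(cx, cy) * np.exp(1j * rotation)
        return _as_image(
            lambda r, p: np.exp(
                -((r * np.cos(p) - c.real) ** 2 + (r * np.sin(p) - c.imag) ** 2)
                / width**2
            ),
            grid_size,
        )
    raise ConfigurationError(f"unknown disk-image kind {kind!r}")


def make_random_disk_image(
    seed: int, grid_size: int = 64, order: int = 8, rotation: float = 0.0
) -> DiskImage:
    """Random band-limited image: a seeded real Zernike series of the given
    order, optionally rotated analytically (no resampling error)."""
    rng = np.random.default_rng(seed)
    terms = []
    for n, m in index_pairs(order):
        re, im = rng.normal(size=2) / (n + 1)
        terms.append((n, m, re, im))

    def fn(r, p):
        total = np.zeros_like(r)
        for n, m, re, im in terms:
            rad = radial_polynomial(n, m, r)
            if m == 0:
                total += re * rad
            else:
                ang = m * (p - rotation)
                total += 2.0 * rad * (re * np.cos(ang) - im * np.sin(ang))
        return total

    return _as_image(fn, grid_size)
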