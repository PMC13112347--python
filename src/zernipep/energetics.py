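"""Nonbonded interface energetics and surface hydropathy.

Three ingredients of interface scoring live here:

* residue-pair 12–6 Lennard-Jones energies between chains, using per-atom
  CHARMM-style well depths ε (kcal/mol) and Rmin/2 (Å) with the standard
  combination rules ε_lm = √(ε_l·ε_m), R_lm = Rmin/2_l + Rmin/2_m;
* a Coulomb energy between two 2-bead coarse-grained models,
  E = k_e/ε_r · Σ q_a q_b / r_ab with k_e = 332.0636 kcal·Å/(mol·e²);
* surface-patch hydropathy: each surface point is attributed to its
  nearest heavy atom's residue, point counts are weighted by a per-residue
  hydropathy index, and the patch value is the point-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import CGModel, ChainStructure, ResidueRecord
from .errors import (
    AssignmentError,
    ParameterLookupError,
    SingularityError,
)
from .surface import SurfacePatch

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)


@dataclass
class EnergyMatrix:
    """Inter-chain residue-pair LJ energies for one frame (kcal/mol)."""

    row_residues: list[tuple[str, int]]   # (chain_id, seq_index) of chain A
    col_residues: list[tuple[str, int]]
    values: np.ndarray                    # (len(rows), len(cols))
    frame_id: int = 0

    def total(self) -> float:
        return float(self.values.sum())

    def row_index(self, seq_index: int) -> int:
        for i, (_, si) in enumerate(self.row_residues):
            if si == seq_index:
                return i
        raise KeyError(f"residue {seq_index} not in matrix rows")

    def to_tsv(self) -> str:
        header = "\t".join(
            ["residue"] + [f"{c}{s}" for c, s in self.col_residues]
        )
        lines = [header]
        for (c, s), row in zip(self.row_residues, self.values):
            lines.append("\t".join([f"{c}{s}"] + [f"{v:.6g}" for v in row]))
        return "\n".join(lines) + "\n"


@dataclass
class PatchHydropathy:
    """Point-weighted mean hydropathy of a surface patch."""

    value: float
    n_surface_points: int
    contributing_residues: list[tuple[str, int]]


def _require_params(atoms, what: str):
    missing = [a.name for a in atoms if a.lj_epsilon is None or a.lj_rmin_half is None]
    if missing:
        raise ParameterLookupError([(what, n) for n in missing])


def lj_pair_energy(
    atom_l, atom_m, r_lm: float, strict_literal: bool = False
) -> float:
    """12–6 Lennard-Jones energy of one atom pair at separation r_lm (Å).

    Default combination rules are CHARMM's: ε_lm = √(ε_l ε_m) and
    R_lm = Rmin/2_l + Rmin/2_m (each atom stores Rmin/2, so the sum is the
    pair's minimum-energy distance).  ``strict_literal=True`` instead uses
    the plain products ε_l·ε_m and the sum of full Rmin values.
    """
    if r_lm <= 0:
        raise SingularityError(f"atom pair at zero separation ({atom_l.name}, {atom_m.name})")
    _require_params([atom_l, atom_m], "pair")
    if strict_literal:
        eps = atom_l.lj_epsilon * atom_m.lj_epsilon
        rmin = 2.0 * (atom_l.lj_rmin_half + atom_m.lj_rmin_half)
    else:
        eps = np.sqrt(atom_l.lj_epsilon * atom_m.lj_epsilon)
        rmin = atom_l.lj_rmin_half + atom_m.lj_rmin_half
    q = (rmin / r_lm) ** 6
    return float(eps * (q * q - 2.0 * q))


def residue_pair_lj(
    res_i: ResidueRecord,
    res_j: ResidueRecord,
    strict_literal: bool = False,
    cutoff: float | None = None,
) -> float:
    """Sum of LJ energies over all atom pairs of two residues (Eq-style
    double sum), vectorized over the pair grid."""
    _require_params(res_i.atoms, f"{res_i.residue_type}{res_i.seq_index}")
    _require_params(res_j.atoms, f"{res_j.residue_type}{res_j.seq_index}")
    pi = np.array([a.position for a in res_i.atoms])
    pj = np.array([a.position for a in res_j.atoms])
    ei = np.array([a.lj_epsilon for a in res_i.atoms])
    ej = np.array([a.lj_epsilon for a in res_j.atoms])
    ri = np.array([a.lj_rmin_half for a in res_i.atoms])
    rj = np.array([a.lj_rmin_half for a in res_j.atoms])
    d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
    if np.any(d <= 0):
        raise SingularityError(
            f"coincident atoms between residues {res_i.seq_index} and {res_j.seq_index}"
        )
    if strict_literal:
        eps = ei[:, None] * ej[None, :]
        rmin = 2.0 * (ri[:, None] + rj[None, :])
    else:
        eps = np.sqrt(ei[:, None] * ej[None, :])
        rmin = ri[:, None] + rj[None, :]
    q = (rmin / d) ** 6
    e = eps * (q * q - 2.0 * q)
    if cutoff is not None:
        e = np.where(d <= cutoff, e, 0.0)
    return float(e.sum())


def interface_lj_matrix(
    frame: ChainStructure,
    chain_a: str,
    chain_b: str,
    strict_literal: bool = False,
    cutoff: float | None = None,
    frame_id: int = 0,
) -> EnergyMatrix:
    """Residue-pair LJ energy matrix between two chains (no intra-chain
    terms)."""
    rows = frame.residues(chain_a)
    cols = frame.residues(chain_b)
    values = np.array(
        [
            [residue_pair_lj(ri, rj, strict_literal, cutoff) for rj in cols]
            for ri in rows
        ]
    )
    return EnergyMatrix(
        [(r.chain_id, r.seq_index) for r in rows],
        [(c.chain_id, c.seq_index) for c in cols],
        values,
        frame_id,
    )


def coulomb_energy_cg(
    cg_a: CGModel, cg_b: CGModel, dielectric: float = 1.0
) -> float:
    """Coulomb energy between the beads of two coarse-grained models.

    E = k_e/ε_r · Σ_ab q_a q_b / r_ab over inter-model bead pairs only.
    """
    if dielectric <= 0:
        raise ValueError("dielectric must be > 0")
    qa, qb = cg_a.charges(), cg_b.charges()
    if len(qa) == 0 or len(qb) == 0:
        return 0.0
    pa, pb = cg_a.positions(), cg_b.positions()
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    if np.any(d <= 1e-12):
        i, j = np.argwhere(d <= 1e-12)[0]
        raise SingularityError(f"coincident beads (a[{i}], b[{j}])")
    return float(COULOMB_CONSTANT / dielectric * np.sum(np.outer(qa, qb) / d))


def assign_points_to_residues(
    patch: SurfacePatch, structure: ChainStructure, max_distance: float = 5.0
) -> list[ResidueRecord]:
    """Nearest-heavy-atom attribution of each patch point to a residue."""
    atom_res = []
    positions = []
    for res in structure.residues():
        for a in res.atoms:
            if a.element.upper() != "H":
                positions.append(a.position)
                atom_res.append(res)
    tree = cKDTree(np.array(positions))
    dist, idx = tree.query(patch.points)
    if np.any(dist > max_distance):
        worst = float(dist.max())
        raise AssignmentError(
            f"surface point {worst:.2f} Å from nearest heavy atom "
            f"(limit {max_distance} Å)"
        )
    return [atom_res[i] for i in idx]


def patch_hydropathy(
    patch: SurfacePatch,
    structure: ChainStructure,
    scale: dict | None = None,
    max_distance: float = 5.0,
) -> PatchHydropathy:
    """Point-weighted mean hydropathy of the residues exposed in a patch.

    Each surface point contributes the hydropathy index of the residue of
    its nearest heavy atom; the patch value is the sum over points divided
    by the number of points.
    """
    if scale is None:
        from .params import default_hydropathy_scale
        scale = default_hydropathy_scale()
    residues = assign_points_to_residues(patch, structure, max_distance)
    total = 0.0
    seen: list[tuple[str, int]] = []
    for res in residues:
        total += scale[res.residue_type]
        key = (res.chain_id, res.seq_index)
        if key not in seen:
            seen.append(key)
    n = len(patch)
    return PatchHydropathy(total / n, n, seen)


def hydropathy_difference(fixed_side: PatchHydropathy, mut_side: PatchHydropathy) -> float:
    """H_d = H_fixed − H_mut, the signed hydropathy mismatch of the two
    facing patches."""
    return fixed_side.value - mut_side.value
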