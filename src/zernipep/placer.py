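"""Side-chain placement for point mutations.

The built-in placer is deliberately naive: backbone atoms are left
untouched, CB is kept (or built with ideal tetrahedral geometry from N,
CA, C), and the remaining side-chain heavy atoms are placed from a fixed
per-residue template expressed in a local frame anchored at CB and
oriented along the CA→CB direction.  There is no rotamer search and no
relaxation — the coarse-grained electrostatics downstream is specifically
tolerant of unrelaxed side chains.  An external placer (e.g. Scwrl4) can
be substituted through the same callable interface.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import numpy as np

from .core import (
    AtomRecord,
    ChainStructure,
    ONE_TO_THREE,
    ResidueRecord,
)
from .errors import AdapterError, MalformedResidueError

#: Side-chain heavy atoms beyond CB, as (name, element, local offset from CB).
#: Local frame: e1 along CA→CB, e2 ⟂ in the N–CA–CB plane, e3 = e1×e2.
SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [],
    "VAL": [("CG1", "C", (1.2, 0.9, 0.0)), ("CG2", "C", (1.2, -0.9, 0.0))],
    "LEU": [("CG", "C", (1.3, 0.0, 0.0)), ("CD1", "C", (2.3, 0.9, 0.0)),
            ("CD2", "C", (2.3, -0.9, 0.0))],
    "ILE": [("CG1", "C", (1.2, 0.9, 0.0)), ("CG2", "C", (1.2, -0.9, 0.0)),
            ("CD1", "C", (2.4, 1.2, 0.0))],
    "MET": [("CG", "C", (1.3, 0.0, 0.0)), ("SD", "S", (2.6, 0.4, 0.0)),
            ("CE", "C", (3.9, 0.1, 0.0))],
    "PHE": [("CG", "C", (1.3, 0.0, 0.0)), ("CD1", "C", (2.0, 1.1, 0.0)),
            ("CD2", "C", (2.0, -1.1, 0.0)), ("CE1", "C", (3.3, 1.2, 0.0)),
            ("CE2", "C", (3.3, -1.2, 0.0)), ("CZ", "C", (4.0, 0.0, 0.0))],
    "TRP": [("CG", "C", (1.3, 0.0, 0.0)), ("CD1", "C", (2.0, 1.1, 0.0)),
            ("CD2", "C", (2.2, -0.9, 0.0)), ("NE1", "N", (3.3, 1.0, 0.0)),
            ("CE2", "C", (3.5, -0.2, 0.0)), ("CE3", "C", (2.5, -2.2, 0.0)),
            ("CZ2", "C", (4.7, -0.8, 0.0)), ("CZ3", "C", (3.8, -2.8, 0.0)),
            ("CH2", "C", (4.9, -2.1, 0.0))],
    "SER": [("OG", "O", (1.4, 0.0, 0.0))],
    "THR": [("OG1", "O", (1.2, 0.9, 0.0)), ("CG2", "C", (1.2, -0.9, 0.0))],
    "CYS": [("SG", "S", (1.8, 0.0, 0.0))],
    "TYR": [("CG", "C", (1.3, 0.0, 0.0)), ("CD1", "C", (2.0, 1.1, 0.0)),
            ("CD2", "C", (2.0, -1.1, 0.0)), ("CE1", "C", (3.3, 1.2, 0.0)),
            ("CE2", "C", (3.3, -1.2, 0.0)), ("CZ", "C", (4.0, 0.0, 0.0)),
            ("OH", "O", (5.4, 0.0, 0.0))],
    "ASN": [("CG", "C", (1.3, 0.0, 0.0)), ("OD1", "O", (2.1, 1.0, 0.0)),
            ("ND2", "N", (2.1, -1.0, 0.0))],
    "ASP": [("CG", "C", (1.3, 0.0, 0.0)), ("OD1", "O", (2.1, 1.0, 0.0)),
            ("OD2", "O", (2.1, -1.0, 0.0))],
    "GLN": [("CG", "C", (1.3, 0.0, 0.0)), ("CD", "C", (2.6, 0.0, 0.0)),
            ("OE1", "O", (3.3, 1.0, 0.0)), ("NE2", "N", (3.3, -1.0, 0.0))],
    "GLU": [("CG", "C", (1.3, 0.0, 0.0)), ("CD", "C", (2.6, 0.0, 0.0)),
            ("OE1", "O", (3.3, 1.0, 0.0)), ("OE2", "O", (3.3, -1.0, 0.0))],
    "LYS": [("CG", "C", (1.3, 0.0, 0.0)), ("CD", "C", (2.6, 0.0, 0.0)),
            ("CE", "C", (3.9, 0.0, 0.0)), ("NZ", "N", (5.0, 0.0, 0.0))],
    "ARG": [("CG", "C", (1.3, 0.0, 0.0)), ("CD", "C", (2.6, 0.0, 0.0)),
            ("NE", "N", (3.9, 0.0, 0.0)), ("CZ", "C", (5.0, 0.0, 0.0)),
            ("NH1", "N", (5.7, 0.9, 0.0)), ("NH2", "N", (5.7, -0.9, 0.0))],
    "HIS": [("CG", "C", (1.3, 0.0, 0.0)), ("ND1", "N", (2.0, 1.0, 0.0)),
            ("CD2", "C", (2.0, -1.0, 0.0)), ("CE1", "C", (3.2, 0.9, 0.0)),
            ("NE2", "N", (3.2, -0.9, 0.0))],
    "PRO": [("CG", "C", (1.2, 0.8, 0.0)), ("CD", "C", (0.7, 1.9, 0.0))],
}


def _ideal_cb(res: ResidueRecord) -> np.ndarray:
    """Tetrahedral CB position from backbone N, CA, C."""
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        raise MalformedResidueError(
            f"residue {res.chain_id}{res.seq_index} lacks backbone for CB build"
        )
    u = n.position - ca.position
    v = c.position - ca.position
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bis = -(u + v)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp)
    direction = bis * np.cos(np.deg2rad(54.0)) + perp * np.sin(np.deg2rad(54.0))
    return ca.position + 1.53 * direction / np.linalg.norm(direction)


def naive_placer(
    structure: ChainStructure, chain_id: str, seq_index: int, new_residue: str
) -> ChainStructure:
    """Replace one residue's side chain with the ideal-geometry template.

    Backbone atoms are copied unchanged; CB is retained when present.
    Returns a new structure (parameters are not re-assigned here).
    """
    new3 = ONE_TO_THREE.get(new_residue, new_residue)
    if new3 not in SIDECHAIN_TEMPLATES:
        raise MalformedResidueError(f"unknown residue type {new_residue!r}")
    out = structure.copy()
    target = None
    for res in out.residues(chain_id):
        if res.seq_index == seq_index:
            target = res
            break
    if target is None:
        raise MalformedResidueError(f"no residue {seq_index} in chain {chain_id}")
    backbone = [a for a in target.atoms if a.is_backbone]
    if not any(a.name == "CA" for a in backbone):
        raise MalformedResidueError(
            f"residue {chain_id}{seq_index} has no CA; cannot mutate"
        )
    atoms = list(backbone)
    if new3 != "GLY":
        cb_old = target.atom("CB")
        cb_pos = cb_old.position.copy() if cb_old is not None else _ideal_cb(target)
        atoms.append(AtomRecord("CB", "C", cb_pos))
        ca = target.atom("CA").position
        n = target.atom("N")
        e1 = cb_pos - ca
        e1 = e1 / np.linalg.norm(e1)
        ref = (n.position - ca) if n is not None else np.array([1.0, 0.0, 0.0])
        e2 = ref - np.dot(ref, e1) * e1
        nrm = np.linalg.norm(e2)
        if nrm < 1e-6:
            ref = np.array([0.0, 0.0, 1.0])
            e2 = ref - np.dot(ref, e1) * e1
            nrm = np.linalg.norm(e2)
        e2 /= nrm
        e3 = np.cross(e1, e2)
        for name, element, (a1, a2, a3) in SIDECHAIN_TEMPLATES[new3]:
            pos = cb_pos + a1 * e1 + a2 * e2 + a3 * e3
            atoms.append(AtomRecord(name, element, pos))
    target.residue_type = new3
    target.atoms = atoms
    return out


class Scwrl4Placer:
    """Adapter calling an external Scwrl4 binary, when installed.

    Runs Scwrl4 on the mutated sequence and reads back the predicted
    structure; any failure is wrapped in :class:`AdapterError` with the
    captured diagnostics.
    """

    def __init__(self, executable: str = "Scwrl4"):
        self.executable = executable

    def __call__(self, structure, chain_id, seq_index, new_residue):
        from .core import read_structure, write_pdb

        mutated = naive_placer(structure, chain_id, seq_index, new_residue)
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "in.pdb"
            outp = Path(tmp) / "out.pdb"
            inp.write_text(write_pdb(mutated))
            proc = subprocess.run(
                [self.executable, "-i", str(inp), "-o", str(outp)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0 or not outp.exists():
                raise AdapterError(
                    f"{self.executable} failed (rc={proc.returncode}): "
                    f"{proc.stderr.strip()[:500]}"
                )
            return read_structure(outp.read_text())
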