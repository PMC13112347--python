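"""Structure/trajectory data model, PDB/PQR I/O, force-field parameter
assignment, and the 2-bead coarse-graining transform.

The data model is deliberately small: atoms carry Cartesian coordinates in
Å together with the per-atom nonbonded parameters needed by the energy
terms (partial charge *q* in units of the elementary charge, Lennard-Jones
well depth ε in kcal/mol and Rmin/2 in Å).  Residue and chain identity
follow the author numbering of the input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptyInputError,
    MalformedResidueError,
    ParameterLookupError,
    PDBParseError,
    TopologyError,
)

#: Atom names treated as backbone; everything else is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class AtomRecord:
    """One atom: name, element, position (Å) and nonbonded parameters."""

    name: str
    element: str
    position: np.ndarray
    serial: int = 0
    partial_charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.name}: lj_epsilon must be >= 0")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


@dataclass
class ResidueRecord:
    """One residue: chain id, author sequence index, type, ordered atoms."""

    chain_id: str
    seq_index: int
    residue_type: str  # 3-letter code
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord:
        a = self.atom("CA")
        if a is None:
            raise MalformedResidueError(
                f"residue {self.residue_type} {self.chain_id}{self.seq_index} has no CA"
            )
        return a

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.residue_type, "X")

    def net_charge(self) -> float:
        return sum(a.partial_charge or 0.0 for a in self.atoms)

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            self.chain_id, self.seq_index, self.residue_type,
            [a.copy() for a in self.atoms], self.insertion_code,
        )


@dataclass
class ChainStructure:
    """A single model: mapping chain id -> ordered residues."""

    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    model_id: int = 1

    def residues(self, chain_id: str | None = None):
        if chain_id is not None:
            if chain_id not in self.chains:
                raise KeyError(f"no chain {chain_id!r} in structure")
            return list(self.chains[chain_id])
        return [r for rs in self.chains.values() for r in rs]

    def atoms(self, chain_id: str | None = None):
        return [a for r in self.residues(chain_id) for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms())

    def coordinates(self, chain_id: str | None = None) -> np.ndarray:
        ats = self.atoms(chain_id)
        if not ats:
            return np.zeros((0, 3))
        return np.array([a.position for a in ats])

    def translated(self, t) -> "ChainStructure":
        t = np.asarray(t, dtype=float)
        out = self.copy()
        for a in out.atoms():
            a.position = a.position + t
        return out

    def rotated(self, R, about=None) -> "ChainStructure":
        R = np.asarray(R, dtype=float)
        c = np.zeros(3) if about is None else np.asarray(about, dtype=float)
        out = self.copy()
        for a in out.atoms():
            a.position = R @ (a.position - c) + c
        return out

    def copy(self) -> "ChainStructure":
        return ChainStructure(
            {cid: [r.copy() for r in rs] for cid, rs in self.chains.items()},
            self.model_id,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; spacing is metadata only."""

    frames: list[ChainStructure]
    frame_spacing_ns: float = 1.0

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# PDB / PQR I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int, pqr: bool = False):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = "".join(c for c in name if c.isalpha())[:1]
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    charge = None
    if pqr:
        fields = line.split()
        try:
            charge = float(fields[-2])
        except (ValueError, IndexError) as exc:
            raise PDBParseError(
                f"malformed PQR charge field at line {lineno}"
            ) from exc
    return serial, name, resname, chain, resseq, icode, (x, y, z), element, charge


def _build_model(records, model_id: int) -> ChainStructure:
    chains: dict[str, list[ResidueRecord]] = {}
    current: ResidueRecord | None = None
    for serial, name, resname, chain, resseq, icode, xyz, element, charge in records:
        if (
            current is None
            or current.chain_id != chain
            or current.seq_index != resseq
            or current.insertion_code != icode
            or current.residue_type != resname
        ):
            current = ResidueRecord(chain, resseq, resname, [], icode)
            chains.setdefault(chain, []).append(current)
        current.atoms.append(
            AtomRecord(name, element, np.array(xyz), serial, partial_charge=charge)
        )
    return ChainStructure(chains, model_id)


def read_structure(pdb_text: str) -> ChainStructure:
    """Parse the first (or only) model of PDB text into a ChainStructure.

    Only ATOM records are kept; HETATM (waters, ligands) are ignored by the
    protein-centric pipeline.  Raises :class:`EmptyInputError` if no ATOM
    record is present and :class:`PDBParseError` (naming the line number)
    on malformed records.
    """
    records = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith("ENDMDL") and records:
            break
        if line.startswith("ATOM"):
            records.append(_parse_atom_line(line, lineno))
    if not records:
        raise EmptyInputError("no ATOM records found in PDB input")
    return _build_model(records, model_id=1)


def read_trajectory(multi_model_pdb: str) -> Trajectory:
    """Parse a multi-model PDB into a Trajectory of identical-topology frames."""
    frames: list[ChainStructure] = []
    records: list = []
    model_id = 1
    seen_model_card = False
    for lineno, line in enumerate(multi_model_pdb.splitlines(), start=1):
        if line.startswith("MODEL"):
            seen_model_card = True
            try:
                model_id = int(line.split()[1])
            except (IndexError, ValueError):
                model_id = len(frames) + 1
            records = []
        elif line.startswith("ATOM"):
            records.append(_parse_atom_line(line, lineno))
        elif line.startswith("ENDMDL"):
            if records:
                frames.append(_build_model(records, model_id))
            records = []
    if records and (not seen_model_card or not frames):
        frames.append(_build_model(records, model_id))
    elif records:
        frames.append(_build_model(records, model_id))
    if not frames:
        raise EmptyInputError("no ATOM records found in trajectory input")
    ref_sig = _topology_signature(frames[0])
    for i, fr in enumerate(frames[1:], start=2):
        if _topology_signature(fr) != ref_sig:
            raise TopologyError(
                f"model {i} differs in topology from model 1 "
                f"(atom/residue composition mismatch)"
            )
    return Trajectory(frames)


def _topology_signature(structure: ChainStructure):
    return tuple(
        (r.chain_id, r.seq_index, r.residue_type, tuple(a.name for a in r.atoms))
        for r in structure.residues()
    )


def write_pdb(structure: ChainStructure | Trajectory) -> str:
    """Serialize to PDB text with standard 8.3 coordinate fields."""
    if isinstance(structure, Trajectory):
        chunks = []
        for i, frame in enumerate(structure.frames, start=1):
            chunks.append(f"MODEL     {i:4d}\n")
            chunks.append(_write_model(frame))
            chunks.append("ENDMDL\n")
        return "".join(chunks) + "END\n"
    return _write_model(structure) + "END\n"


def _write_model(structure: ChainStructure) -> str:
    lines = []
    serial = 0
    for res in structure.residues():
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {res.residue_type:<3.3s} "
                f"{res.chain_id:1.1s}{res.seq_index:4d}{res.insertion_code:1.1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2.2s}\n"
            )
    return "".join(lines)


def read_pqr(pqr_text: str) -> dict:
    """Read a PQR file into a map (chain, resseq, atom name) -> charge (e).

    PQR is whitespace-delimited; the charge is the second-to-last field and
    the radius the last.  Used to override table charges in
    :func:`assign_parameters`.
    """
    charges: dict[tuple[str, int, str], float] = {}
    for lineno, line in enumerate(pqr_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parsed = _parse_atom_line(line, lineno, pqr=True)
        serial, name, resname, chain, resseq, icode, xyz, element, charge = parsed
        charges[(chain, resseq, name)] = charge
    if not charges:
        raise EmptyInputError("no ATOM records found in PQR input")
    return charges


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def assign_parameters(
    structure: ChainStructure,
    table: dict | None = None,
    pqr_charges: dict | None = None,
) -> ChainStructure:
    """Attach per-atom ε, Rmin/2 and partial charge from a parameter table.

    ``table`` maps (residue_type, atom_name) -> (epsilon, rmin_half, charge).
    When ``pqr_charges`` is given, its charges take precedence over the
    table's.  All unresolved atoms are collected and reported together in a
    single :class:`ParameterLookupError`.
    """
    if table is None:
        from .params import default_parameter_table
        table = default_parameter_table()
    out = structure.copy()
    unresolved = []
    for res in out.residues():
        for a in res.atoms:
            key = (res.residue_type, a.name)
            entry = table.get(key)
            if entry is None:
                unresolved.append(key)
                continue
            eps, rmin_half, q = entry
            a.lj_epsilon = eps
            a.lj_rmin_half = rmin_half
            if pqr_charges is not None:
                q = pqr_charges.get((res.chain_id, res.seq_index, a.name), q)
            a.partial_charge = q
    if unresolved:
        raise ParameterLookupError(sorted(set(unresolved)))
    return out


# ---------------------------------------------------------------------------
# 2-bead coarse graining
# ---------------------------------------------------------------------------

@dataclass
class CGBead:
    """One coarse-grained bead: mean position of its atoms, summed charge."""

    role: str  # "backbone" | "sidechain"
    position: np.ndarray
    charge: float
    parent_residue: ResidueRecord


@dataclass
class CGModel:
    """2-bead-per-residue model used by the Coulomb term."""

    beads: list[CGBead]
    source: ChainStructure

    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads])

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    def total_charge(self) -> float:
        return float(sum(b.charge for b in self.beads))


def coarse_grain(structure: ChainStructure, chain_id: str | None = None) -> CGModel:
    """Reduce each residue to a backbone bead and a side-chain bead.

    Bead positions are unweighted means of the constituent atom positions;
    bead charges are sums of the constituent partial charges, so total
    charge is conserved exactly.  Glycine has no side-chain heavy atoms and
    yields a single backbone bead carrying the full residue charge.
    """
    beads: list[CGBead] = []
    for res in structure.residues(chain_id):
        bb = [a for a in res.atoms if a.is_backbone]
        sc = [a for a in res.atoms if not a.is_backbone]
        if not bb:
            raise MalformedResidueError(
                f"residue {res.residue_type} {res.chain_id}{res.seq_index} "
                f"has no backbone atoms"
            )
        bb_pos = np.mean([a.position for a in bb], axis=0)
        bb_q = sum(a.partial_charge or 0.0 for a in bb)
        if sc:
            sc_pos = np.mean([a.position for a in sc], axis=0)
            sc_q = sum(a.partial_charge or 0.0 for a in sc)
            beads.append(CGBead("backbone", bb_pos, bb_q, res))
            beads.append(CGBead("sidechain", sc_pos, sc_q, res))
        else:
            # glycine (or stripped residue): backbone bead absorbs everything
            beads.append(CGBead("backbone", bb_pos, bb_q, res))
    return CGModel(beads, structure)
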