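"""Trajectory-level interface statistics, peptide-template selection, and
MSA position frequencies.

The contact criterion follows the Cα rule: two residues of opposite
chains are in contact in a frame when their Cα–Cα distance is strictly
below the cutoff (8 Å by default).  Contact occurrence is the fraction of
frames in which a residue has at least one such partner; the peptide
template is the longest contiguous run of residues whose occurrence
exceeds a threshold (25% by default).  A minimum-interatomic-distance
variant of the residue-pair distance is also exposed for energy-context
queries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ChainStructure, Trajectory
from .errors import (
    CorrespondenceError,
    EmptyInputError,
    MalformedResidueError,
    NoSegmentError,
    UndefinedFractionError,
)
from .energetics import EnergyMatrix


@dataclass
class ContactProfile:
    """Per-residue fraction of frames spent at the interface."""

    residue_ids: list[int]
    occurrence: np.ndarray
    n_frames: int
    chain_id: str = ""

    def to_tsv(self) -> str:
        lines = ["residue\toccurrence"]
        for rid, occ in zip(self.residue_ids, self.occurrence):
            lines.append(f"{rid}\t{occ:.6g}")
        return "\n".join(lines) + "\n"


@dataclass
class SegmentSelection:
    """A contiguous run of residues chosen as the peptide template."""

    start: int
    end: int
    member_occurrences: np.ndarray

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def mean_occurrence(self) -> float:
        return float(np.mean(self.member_occurrences))

    def residue_ids(self) -> list[int]:
        return list(range(self.start, self.end + 1))


@dataclass
class ExtensionInterval:
    """Mean ± k·sd band of an edge-to-edge distance series."""

    mean: float
    sd: float
    low: float
    high: float
    occupancy: float


def _ca_positions(frame: ChainStructure, chain_id: str):
    ids, pos = [], []
    for res in frame.residues(chain_id):
        ca = res.atom("CA")
        if ca is None:
            raise MalformedResidueError(
                f"residue {res.residue_type} {chain_id}{res.seq_index} has no CA"
            )
        ids.append(res.seq_index)
        pos.append(ca.position)
    return ids, np.array(pos)


def interface_residues(
    frame: ChainStructure, chain_a: str, chain_b: str, cutoff: float = 8.0
) -> tuple[set[int], set[int]]:
    """Residues of each chain with a partner-chain Cα strictly within
    ``cutoff`` Å; returns (set for chain_a, set for chain_b)."""
    ids_a, pos_a = _ca_positions(frame, chain_a)
    ids_b, pos_b = _ca_positions(frame, chain_b)
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    close = d < cutoff
    set_a = {ids_a[i] for i in np.nonzero(close.any(axis=1))[0]}
    set_b = {ids_b[j] for j in np.nonzero(close.any(axis=0))[0]}
    return set_a, set_b


def min_interatomic_distance(res_i, res_j) -> float:
    """Minimum distance between any atoms of two residues (Å)."""
    pi = np.array([a.position for a in res_i.atoms])
    pj = np.array([a.position for a in res_j.atoms])
    return float(np.min(np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)))


def contact_occurrence(
    traj: Trajectory, chain_a: str, chain_b: str, cutoff: float = 8.0
) -> ContactProfile:
    """Fraction of frames in which each residue of chain_a touches chain_b."""
    if len(traj) == 0:
        raise EmptyInputError("trajectory has no frames")
    ids, _ = _ca_positions(traj.frames[0], chain_a)
    counts = dict.fromkeys(ids, 0)
    for frame in traj:
        at_interface, _ = interface_residues(frame, chain_a, chain_b, cutoff)
        for rid in at_interface:
            counts[rid] += 1
    occ = np.array([counts[rid] / len(traj) for rid in ids])
    return ContactProfile(ids, occ, len(traj), chain_a)


def select_peptide_segment(
    profile: ContactProfile, threshold: float = 0.25, max_gaps: int = 0
) -> SegmentSelection:
    """Longest contiguous run of residues with occurrence > threshold.

    Ties on length break toward higher mean occurrence, then smaller start
    id.  ``max_gaps`` > 0 tolerates that many below-threshold members
    inside a run.
    """
    ids = profile.residue_ids
    occ = profile.occurrence
    above = occ > threshold
    runs: list[tuple[int, int]] = []  # index ranges [i, j]
    i = 0
    n = len(ids)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        gaps = 0
        best_j = i
        while j + 1 < n and ids[j + 1] == ids[j] + 1:
            if above[j + 1]:
                best_j = j + 1
            else:
                gaps += 1
                if gaps > max_gaps:
                    break
            j += 1
        runs.append((i, best_j))
        i = best_j + 1
    if not runs:
        raise NoSegmentError(
            f"no residue exceeds occurrence threshold {threshold}"
        )
    def key(run):
        i, j = run
        return (j - i + 1, float(np.mean(occ[i : j + 1])), -ids[i])
    i, j = max(runs, key=key)
    return SegmentSelection(ids[i], ids[j], occ[i : j + 1].copy())


def segment_vdw_fraction(matrix: EnergyMatrix, segment: SegmentSelection) -> float:
    """Fraction of the inter-chain LJ energy carried by the segment's rows
    (signed sums)."""
    total = matrix.values.sum()
    if total == 0:
        raise UndefinedFractionError("total interface energy is zero")
    seg_ids = set(segment.residue_ids())
    mask = np.array([si in seg_ids for _, si in matrix.row_residues])
    return float(matrix.values[mask].sum() / total)


def per_residue_vdw_share(matrix: EnergyMatrix, seq_index: int) -> float:
    """One residue's row sum over the whole matrix total (signed sums)."""
    total = matrix.values.sum()
    if total == 0:
        raise UndefinedFractionError("total interface energy is zero")
    return float(matrix.values[matrix.row_index(seq_index)].sum() / total)


def _matched_coordinates(frame, reference, selection):
    def keyed(structure):
        out = {}
        for res in structure.residues():
            for a in res.atoms:
                if selection is None or selection(res, a):
                    out[(res.chain_id, res.seq_index, a.name)] = a.position
        return out
    fa, ra = keyed(frame), keyed(reference)
    if set(fa) != set(ra):
        raise CorrespondenceError(
            f"atom selections differ: {len(fa)} vs {len(ra)} atoms "
            f"({len(set(fa) ^ set(ra))} unmatched)"
        )
    keys = sorted(fa)
    return np.array([fa[k] for k in keys]), np.array([ra[k] for k in keys])


def rmsd(
    frame: ChainStructure,
    reference: ChainStructure,
    selection=None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation over matched atoms (Å).

    ``selection`` is an optional predicate (residue, atom) -> bool; atom
    correspondence is by (chain, residue index, atom name).  With
    ``superpose`` a least-squares rigid fit (Kabsch) is applied first.
    """
    x, y = _matched_coordinates(frame, reference, selection)
    if superpose:
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        # Kabsch rotation minimizing |R xc - yc|
        H = xc.T @ yc
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
        x = xc @ R.T
        y = yc
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def edge_to_edge(frame: ChainStructure, segment: SegmentSelection, chain_id: str | None = None) -> float:
    """Cα–Cα distance between the first and last residues of the segment."""
    residues = {r.seq_index: r for r in frame.residues(chain_id)}
    try:
        first, last = residues[segment.start], residues[segment.end]
    except KeyError as exc:
        raise MalformedResidueError(f"segment residue missing: {exc}") from exc
    return float(np.linalg.norm(first.ca.position - last.ca.position))


def extension_interval(
    distances, k_sigma: float = 2.0, interval: tuple[float, float] | None = None
) -> ExtensionInterval:
    """Mean ± k·sd band of a distance series and its frame occupancy.

    The standard deviation is the population sd (frames are the full
    analysed sample).  If ``interval`` is given, occupancy is measured for
    that externally supplied band instead — the cross-trajectory
    comparison used when referring one simulation's band to another's.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < 2:
        raise EmptyInputError("need at least two frames for an interval")
    mean = float(d.mean())
    sd = float(d.std())
    low, high = (mean - k_sigma * sd, mean + k_sigma * sd)
    if interval is not None:
        low, high = float(interval[0]), float(interval[1])
    occupancy = float(np.mean((d >= low) & (d <= high)))
    return ExtensionInterval(mean, sd, low, high, occupancy)


# ---------------------------------------------------------------------------
# MSA position frequencies
# ---------------------------------------------------------------------------

def msa_position_frequencies(
    alignment_fasta: str, positions: list[int], reference_id: str
) -> dict[int, dict[str, float]]:
    """Residue frequencies at alignment columns matching reference positions.

    ``positions`` are 1-based indices into the *ungapped* reference
    sequence; each is mapped through the alignment to its column, and the
    per-column frequency of each residue among non-gap symbols is
    returned as {position: {residue: frequency}}.
    """
    import io

    from Bio import AlignIO

    aln = AlignIO.read(io.StringIO(alignment_fasta), "fasta")
    ref = None
    for rec in aln:
        if rec.id == reference_id:
            ref = str(rec.seq)
            break
    if ref is None:
        raise KeyError(f"reference sequence {reference_id!r} not in alignment")
    # map ungapped reference position (1-based) -> alignment column
    col_of_pos = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch != "-":
            pos += 1
            col_of_pos[pos] = col
    out: dict[int, dict[str, float]] = {}
    for p in positions:
        if p not in col_of_pos:
            raise IndexError(
                f"position {p} outside ungapped reference length {pos}"
            )
        col = col_of_pos[p]
        column = [str(rec.seq[col]) for rec in aln if str(rec.seq[col]) != "-"]
        n = len(column)
        freqs: dict[str, float] = {}
        for ch in column:
            freqs[ch] = freqs.get(ch, 0.0) + 1.0 / n
        out[p] = freqs
    return out
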