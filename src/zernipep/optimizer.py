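"""Metropolis Monte Carlo mutagenesis of an interface peptide.

Each step proposes a single random point mutation of the peptide, rebuilds
the mutated side chain, re-scores the peptide–target interface with three
physicochemical descriptors — 2D Zernike shape-complementarity distance
Z_d, coarse-grained Coulomb energy E_c (kcal/mol), and hydropathy
mismatch H_d — and accepts or rejects by the Metropolis rule on the cost
change

    ΔC_f = A·ΔZ + B·ΔE_c + C·ΔH + D·(M_new − M_old)·M_new²

with M the mutation count relative to the original sequence (an
alternative literal cubic penalty D·(M_new − M_old)³ is selectable).
Default weights A = 10, B = 0.04, C = 32.1, D = 0.5 put the four terms on
a comparable scale.  Accepted sequences from all runs are pooled,
restricted to at most ``max_mutations`` mutations, deduplicated and
ranked by the physicochemical part of the cost alone.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import ChainStructure, assign_parameters, coarse_grain
from .energetics import coulomb_energy_cg, patch_hydropathy
from .errors import ConfigurationError
from .placer import naive_placer
from .surface import compute_sas_points, extract_patch, patch_disk_image
from .zernike import descriptor_distance, expand, invariants

#: 19-letter default mutation alphabet (cysteine excluded: disulfide risk).
DEFAULT_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass
class Metrics:
    """The three physicochemical descriptors of a posed peptide."""

    z_d: float
    e_c: float
    h_d: float


@dataclass
class CostWeights:
    """Coefficients of the composite cost and the inverse temperature."""

    weight_a: float = 10.0
    weight_b: float = 0.04
    weight_c: float = 32.1
    weight_d: float = 0.5
    beta: float = 1.0

    def __post_init__(self):
        for name in ("weight_a", "weight_b", "weight_c", "weight_d", "beta"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.beta <= 0:
            raise ConfigurationError("beta must be > 0")

    def physicochemical_cost(self, m: Metrics) -> float:
        return self.weight_a * m.z_d + self.weight_b * m.e_c + self.weight_c * m.h_d


@dataclass
class PeptideState:
    """Current peptide sequence, structure and metrics inside a chain."""

    sequence: str
    original_sequence: str
    structure: ChainStructure | None
    metrics: Metrics

    @property
    def mutation_count(self) -> int:
        return hamming(self.sequence, self.original_sequence)


@dataclass
class MCStepRecord:
    """Full bookkeeping of one proposal."""

    step: int
    position: int
    proposed_residue: str
    delta_z: float
    delta_ec: float
    delta_h: float
    mutation_term: float
    delta_cost: float
    accepted: bool
    rng_draw: float | None
    sequence: str
    metrics: Metrics
    mutation_count: int


@dataclass
class MCRunRecord:
    """One Monte Carlo chain: every proposal plus the accepted states."""

    run_id: int
    seed: int
    steps: list[MCStepRecord] = field(default_factory=list)
    accepted: list[MCStepRecord] = field(default_factory=list)
    initial_sequence: str = ""
    initial_metrics: Metrics | None = None

    @property
    def acceptance_rate(self) -> float:
        return len(self.accepted) / len(self.steps) if self.steps else 0.0


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def propose_mutation(sequence: str, rng: np.random.Generator, alphabet: str = DEFAULT_ALPHABET):
    """Uniform position, uniform replacement residue ≠ current one."""
    pos = int(rng.integers(len(sequence)))
    choices = [c for c in alphabet if c != sequence[pos]]
    if not choices:
        raise ConfigurationError(
            f"alphabet {alphabet!r} offers no replacement at position {pos}"
        )
    return pos, choices[int(rng.integers(len(choices)))]


def mutation_penalty(
    m_old: int, m_new: int, weight_d: float, variant: str = "signed_quadratic"
) -> float:
    """Cost-term penalizing mutational drift from the original sequence.

    ``signed_quadratic`` (default): D·(M_new − M_old)·M_new², growing
    quadratically with total mutational load; ``literal_cubic``:
    D·(M_new − M_old)³.
    """
    if variant == "signed_quadratic":
        return weight_d * (m_new - m_old) * m_new**2
    if variant == "literal_cubic":
        return weight_d * (m_new - m_old) ** 3
    raise ConfigurationError(f"unknown mutation-penalty variant {variant!r}")


def cost_delta(
    old: Metrics,
    new: Metrics,
    m_old: int,
    m_new: int,
    weights: CostWeights,
    penalty_variant: str = "signed_quadratic",
) -> float:
    """ΔC_f between two evaluated states."""
    return (
        weights.weight_a * (new.z_d - old.z_d)
        + weights.weight_b * (new.e_c - old.e_c)
        + weights.weight_c * (new.h_d - old.h_d)
        + mutation_penalty(m_old, m_new, weights.weight_d, penalty_variant)
    )


def metropolis_accept(delta: float, beta: float, rng: np.random.Generator):
    """Metropolis rule: always accept downhill, else with prob e^{−βΔ}.

    Returns (accepted, draw) where draw is the uniform variate consumed
    for an uphill proposal (None for downhill ones).
    """
    if beta <= 0:
        raise ConfigurationError("beta must be > 0")
    if delta < 0:
        return True, None
    draw = float(rng.random())
    return draw <= math.exp(-beta * delta), draw


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

class StubScorer:
    """Deterministic sequence-only metric provider for driver testing.

    Metrics are stable hashes of the sequence (no structural computation),
    so chains are fully reproducible and fast.
    """

    def __init__(self, z_scale: float = 1.0, e_scale: float = 50.0, h_scale: float = 1.0):
        self.z_scale, self.e_scale, self.h_scale = z_scale, e_scale, h_scale

    @staticmethod
    def _unit(tag: bytes, seq: str) -> float:
        return zlib.crc32(tag + seq.encode()) / 0xFFFFFFFF

    def evaluate(self, sequence: str, structure=None) -> Metrics:
        return Metrics(
            z_d=self.z_scale * self._unit(b"Z", sequence),
            e_c=self.e_scale * (2.0 * self._unit(b"E", sequence) - 1.0),
            h_d=self.h_scale * (2.0 * self._unit(b"H", sequence) - 1.0),
        )

    #: no structural mutation needed
    needs_structure = False


class ComplexScorer:
    """Real physicochemical scorer for a peptide posed on a target chain.

    The target-side patch descriptors and hydropathy are computed once;
    each evaluation recomputes only the peptide-side surface, disk image,
    coarse-grained model and hydropathy.  The peptide patch is projected
    with its mean normal flipped to −z so that complementary (interlocking)
    shapes yield small descriptor distances.
    """

    needs_structure = True

    def __init__(
        self,
        target: ChainStructure,
        target_chain: str,
        peptide_chain: str,
        patch_radius: float = 9.0,
        grid_size: int = 64,
        order: int = 20,
        density: float = 5.0,
        probe_radius: float = 1.4,
        dielectric: float = 1.0,
        contact_cutoff: float = 8.0,
        hydropathy_scale: dict | None = None,
    ):
        from .params import default_hydropathy_scale

        self.target_chain = target_chain
        self.peptide_chain = peptide_chain
        self.patch_radius = patch_radius
        self.grid_size = grid_size
        self.order = order
        self.density = density
        self.probe_radius = probe_radius
        self.dielectric = dielectric
        self.contact_cutoff = contact_cutoff
        self.scale = hydropathy_scale or default_hydropathy_scale()

        self.target_only = ChainStructure(
            {target_chain: [r.copy() for r in target.residues(target_chain)]}
        )
        peptide_centroid = target.coordinates(peptide_chain).mean(axis=0)
        cloud = compute_sas_points(self.target_only, density, probe_radius)
        center = cloud.points[
            np.argmin(np.linalg.norm(cloud.points - peptide_centroid, axis=1))
        ]
        patch = extract_patch(cloud, center, patch_radius)
        image = patch_disk_image(patch, grid_size=grid_size, flip=False)
        self.target_invariants = invariants(expand(image, order))
        self.target_hydropathy = patch_hydropathy(patch, self.target_only, self.scale)
        # only beads of target residues near the peptide enter the Coulomb term
        from .analysis import interface_residues

        iface_a, _ = interface_residues(
            target, target_chain, peptide_chain, contact_cutoff
        )
        iface = ChainStructure(
            {
                target_chain: [
                    r.copy()
                    for r in target.residues(target_chain)
                    if r.seq_index in iface_a
                ]
            }
        )
        if not iface.residues():
            iface = self.target_only
        self.target_cg = coarse_grain(iface)
        self.target_centroid = self.target_only.coordinates().mean(axis=0)

    def evaluate(self, sequence: str, structure: ChainStructure) -> Metrics:
        peptide = ChainStructure(
            {
                self.peptide_chain: [
                    r.copy() for r in structure.residues(self.peptide_chain)
                ]
            }
        )
        cloud = compute_sas_points(peptide, self.density, self.probe_radius)
        center = cloud.points[
            np.argmin(np.linalg.norm(cloud.points - self.target_centroid, axis=1))
        ]
        patch = extract_patch(cloud, center, self.patch_radius)
        image = patch_disk_image(patch, grid_size=self.grid_size, flip=True)
        z_d = descriptor_distance(
            self.target_invariants, invariants(expand(image, self.order))
        )
        pep_cg = coarse_grain(peptide)
        e_c = coulomb_energy_cg(self.target_cg, pep_cg, self.dielectric)
        h_mut = patch_hydropathy(patch, peptide, self.scale)
        h_d = self.target_hydropathy.value - h_mut.value
        return Metrics(z_d=z_d, e_c=e_c, h_d=h_d)


def evaluate_state(
    sequence: str, structure: ChainStructure | None, scorer
) -> Metrics:
    """Score a peptide state with whichever scorer is configured."""
    return scorer.evaluate(sequence, structure)


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

def run_chain(
    initial_sequence: str,
    scorer,
    weights: CostWeights | None = None,
    n_steps: int = 6000,
    seed: int = 0,
    structure: ChainStructure | None = None,
    peptide_chain: str = "B",
    alphabet: str = DEFAULT_ALPHABET,
    penalty_variant: str = "signed_quadratic",
    placer=naive_placer,
    run_id: int = 0,
    parameter_table: dict | None = None,
) -> MCRunRecord:
    """Run one Metropolis chain of ``n_steps`` single-mutation proposals.

    Fully reproducible under (seed, configuration): the only randomness is
    the numpy Generator seeded here.  ``structure`` is the peptide posed on
    the target (required by structure-based scorers); sequence indices map
    onto the peptide chain's residues in order.
    """
    weights = weights or CostWeights()
    rng = np.random.default_rng(seed)
    metrics = scorer.evaluate(initial_sequence, structure)
    state = PeptideState(initial_sequence, initial_sequence, structure, metrics)
    record = MCRunRecord(
        run_id, seed, initial_sequence=initial_sequence, initial_metrics=metrics
    )
    if scorer.needs_structure:
        residues = structure.residues(peptide_chain)
        if len(residues) != len(initial_sequence):
            raise ConfigurationError(
                f"peptide chain {peptide_chain} has {len(residues)} residues "
                f"but sequence has length {len(initial_sequence)}"
            )
        seq_indices = [r.seq_index for r in residues]
    for step in range(n_steps):
        pos, new_res = propose_mutation(state.sequence, rng, alphabet)
        new_seq = state.sequence[:pos] + new_res + state.sequence[pos + 1 :]
        if scorer.needs_structure:
            mutated = placer(
                state.structure, peptide_chain, seq_indices[pos], new_res
            )
            mutated = assign_parameters(mutated, parameter_table)
            new_metrics = scorer.evaluate(new_seq, mutated)
        else:
            mutated = state.structure
            new_metrics = scorer.evaluate(new_seq)
        m_old = state.mutation_count
        m_new = hamming(new_seq, state.original_sequence)
        delta = cost_delta(
            state.metrics, new_metrics, m_old, m_new, weights, penalty_variant
        )
        accepted, draw = metropolis_accept(delta, weights.beta, rng)
        rec = MCStepRecord(
            step=step,
            position=pos,
            proposed_residue=new_res,
            delta_z=new_metrics.z_d - state.metrics.z_d,
            delta_ec=new_metrics.e_c - state.metrics.e_c,
            delta_h=new_metrics.h_d - state.metrics.h_d,
            mutation_term=mutation_penalty(
                m_old, m_new, weights.weight_d, penalty_variant
            ),
            delta_cost=delta,
            accepted=accepted,
            rng_draw=draw,
            sequence=new_seq,
            metrics=new_metrics,
            mutation_count=m_new,
        )
        record.steps.append(rec)
        if accepted:
            record.accepted.append(rec)
            state = PeptideState(
                new_seq, state.original_sequence, mutated, new_metrics
            )
    return record


@dataclass
class Candidate:
    """One ranked optimized sequence."""

    sequence: str
    mutation_count: int
    metrics: Metrics
    cost: float  # physicochemical part only


def filter_candidates(
    runs: list[MCRunRecord],
    max_mutations: int = 5,
    top_k: int = 100,
    weights: CostWeights | None = None,
) -> list[Candidate]:
    """Pool accepted sequences, cap mutations, rank by physicochemical cost.

    Duplicates across runs keep their best cost; ties break by sequence
    lexicographic order.  An empty result is returned (not raised) when no
    accepted state survives the mutation cap.
    """
    weights = weights or CostWeights()
    best: dict[str, Candidate] = {}
    for run in runs:
        for rec in run.accepted:
            if rec.mutation_count > max_mutations:
                continue
            cost = weights.physicochemical_cost(rec.metrics)
            cur = best.get(rec.sequence)
            if cur is None or cost < cur.cost:
                best[rec.sequence] = Candidate(
                    rec.sequence, rec.mutation_count, rec.metrics, cost
                )
    ranked = sorted(best.values(), key=lambda c: (c.cost, c.sequence))
    return ranked[:top_k]


def mutability_profile(candidates: list[Candidate], original: str):
    """Per-position mutation counts and residue frequencies over candidates."""
    length = len(original)
    counts = np.zeros(length, dtype=int)
    freqs: list[dict[str, float]] = [dict() for _ in range(length)]
    n = len(candidates)
    for cand in candidates:
        if len(cand.sequence) != length:
            raise ValueError(
                f"candidate length {len(cand.sequence)} != original {length}"
            )
        for i, (a, b) in enumerate(zip(original, cand.sequence)):
            if a != b:
                counts[i] += 1
            freqs[i][b] = freqs[i].get(b, 0.0) + (1.0 / n if n else 0.0)
    return counts, freqs


def candidates_tsv(candidates: list[Candidate]) -> str:
    lines = ["sequence\tmutations\tz_d\te_c\th_d\tcost"]
    for c in candidates:
        m = c.metrics
        lines.append(
            f"{c.sequence}\t{c.mutation_count}\t{m.z_d:.6g}\t{m.e_c:.6g}"
            f"\t{m.h_d:.6g}\t{c.cost:.6g}"
        )
    return "\n".join(lines) + "\n"
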