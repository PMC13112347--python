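"""Monte Carlo driver: proposals, acceptance, cost, filtering, placer."""

import math

import numpy as np
import pytest
from scipy import stats

import zernipep as zp
from zernipep.errors import ConfigurationError
from zernipep.fixtures import ToyDimerSpec, make_toy_dimer
from zernipep.optimizer import (
    DEFAULT_ALPHABET,
    Metrics,
    hamming,
    mutation_penalty,
)
from zernipep.placer import SIDECHAIN_TEMPLATES, naive_placer


class TestProposeMutation:
    def test_positions_uniform(self):
        rng = np.random.default_rng(0)
        seq = "A" * 16
        counts = np.zeros(16)
        n = 20_000
        for _ in range(n):
            pos, _ = zp.propose_mutation(seq, rng)
            counts[pos] += 1
        chi2 = ((counts - n / 16) ** 2 / (n / 16)).sum()
        assert stats.chi2.sf(chi2, df=15) > 0.01

    def test_never_proposes_current_residue(self):
        rng = np.random.default_rng(1)
        seq = "ADEFGHIKLMNPQRSTVWY"[:8]
        for _ in range(2000):
            pos, res = zp.propose_mutation(seq, rng)
            assert res != seq[pos]
            assert res in DEFAULT_ALPHABET

    def test_fixed_seed_reproducible(self):
        draws1 = [
            zp.propose_mutation("AAAA", np.random.default_rng(42))
            for _ in range(1)
        ]
        stream1 = []
        stream2 = []
        for rng in (np.random.default_rng(7), np.random.default_rng(7)):
            s = [zp.propose_mutation("AAAAAA", rng) for _ in range(50)]
            (stream1 if not stream1 else stream2).extend(s)
        assert stream1 == stream2

    def test_degenerate_alphabet_rejected(self):
        with pytest.raises(ConfigurationError):
            zp.propose_mutation("A", np.random.default_rng(0), alphabet="A")


class TestCostDelta:
    W = zp.CostWeights(10.0, 0.04, 32.1, 0.5)

    def test_worked_arithmetic(self):
        old = Metrics(z_d=1.0, e_c=20.0, h_d=0.10)
        new = Metrics(z_d=1.2, e_c=10.0, h_d=0.15)
        delta = zp.cost_delta(old, new, m_old=2, m_new=2, weights=self.W)
        assert delta == pytest.approx(10 * 0.2 + 0.04 * (-10) + 32.1 * 0.05)
        assert delta == pytest.approx(3.205)

    def test_identical_states(self):
        m = Metrics(0.5, -3.0, 0.2)
        assert zp.cost_delta(m, m, 1, 1, self.W) == 0.0

    def test_all_improving_terms_negative(self):
        old = Metrics(1.0, 0.0, 0.5)
        new = Metrics(0.8, -5.0, 0.4)
        assert zp.cost_delta(old, new, 3, 3, self.W) < 0

    def test_penalty_variants(self):
        assert mutation_penalty(2, 3, 0.5) == pytest.approx(0.5 * 1 * 9)
        assert mutation_penalty(3, 2, 0.5) == pytest.approx(-0.5 * 4)
        assert mutation_penalty(2, 3, 0.5, "literal_cubic") == pytest.approx(0.5)
        assert mutation_penalty(3, 1, 0.5, "literal_cubic") == pytest.approx(-4.0)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(
            zp.metropolis_accept(-1.0, beta, rng)[0] for beta in (0.1, 1.0, 100.0)
        )

    def test_zero_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        accepted = [zp.metropolis_accept(0.0, 1.0, rng)[0] for _ in range(200)]
        assert all(accepted)

    def test_ln2_half_acceptance(self):
        rng = np.random.default_rng(123)
        n = 100_000
        acc = sum(zp.metropolis_accept(math.log(2), 1.0, rng)[0] for _ in range(n))
        # 99% binomial CI around 0.5
        half_width = 2.576 * math.sqrt(0.25 / n)
        assert abs(acc / n - 0.5) < half_width + 0.001

    def test_accepted_uphill_has_valid_draw(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            delta = 0.7
            ok, draw = zp.metropolis_accept(delta, 1.0, rng)
            if ok:
                assert draw <= math.exp(-delta)


class WorseningScorer:
    """Every new sequence costs +10 more than the current one (via z_d)."""

    needs_structure = False

    def __init__(self):
        self.calls = 0

    def evaluate(self, sequence, structure=None):
        self.calls += 1
        return Metrics(z_d=float(self.calls), e_c=0.0, h_d=0.0)


class TestRunChain:
    def test_step_count_and_records(self):
        rec = zp.run_chain("AAAAAA", zp.StubScorer(), n_steps=100, seed=0)
        assert len(rec.steps) == 100
        assert all(s.step == i for i, s in enumerate(rec.steps))

    def test_always_worse_beta_large_rejects_all(self):
        w = zp.CostWeights(beta=100.0)
        rec = zp.run_chain("AAAAAA", WorseningScorer(), weights=w, n_steps=200, seed=1)
        assert len(rec.accepted) == 0

    def test_same_seed_identical_accepted_sequences(self):
        r1 = zp.run_chain("APKLMIYD", zp.StubScorer(), n_steps=300, seed=9)
        r2 = zp.run_chain("APKLMIYD", zp.StubScorer(), n_steps=300, seed=9)
        assert [s.sequence for s in r1.accepted] == [s.sequence for s in r2.accepted]

    def test_acceptance_invariant_on_every_step(self):
        w = zp.CostWeights()
        rec = zp.run_chain("APKLMIYD", zp.StubScorer(), w, n_steps=500, seed=3)
        for s in rec.steps:
            if s.accepted:
                assert s.delta_cost < 0 or s.rng_draw <= math.exp(
                    -w.beta * s.delta_cost
                )

    def test_mutation_count_is_recomputed_hamming(self):
        rec = zp.run_chain("APKLMIYD", zp.StubScorer(), n_steps=400, seed=2)
        seq = "APKLMIYD"
        current = seq
        for s in rec.steps:
            if s.accepted:
                current = s.sequence
            assert s.mutation_count == hamming(s.sequence, seq)
        # final state's M consistent with the last accepted sequence
        assert hamming(current, seq) <= len(seq)

    def test_greedy_limit_no_uphill_acceptance(self):
        w = zp.CostWeights(beta=1e6)
        rec = zp.run_chain("APKLMIYD", zp.StubScorer(), w, n_steps=2000, seed=4)
        assert all(s.delta_cost < 0 for s in rec.accepted)

    def test_detailed_balance_two_state(self):
        # two-state landscape: cost gap dC; occupancy ratio must approach
        # the Boltzmann factor e^{-beta dC}
        beta, d_cost = 1.0, 1.0
        rng = np.random.default_rng(11)
        state = 0
        visits = np.zeros(2)
        n = 200_000
        for _ in range(n):
            delta = d_cost if state == 0 else -d_cost
            accepted, _ = zp.metropolis_accept(delta, beta, rng)
            if accepted:
                state = 1 - state
            visits[state] += 1
        ratio = visits[1] / visits[0]
        expected = math.exp(-beta * d_cost)
        # 3 sigma on the occupancy fraction
        p = expected / (1 + expected)
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(visits[1] / n - p) < 3 * sigma + 0.01
        assert ratio == pytest.approx(expected, rel=0.1)


class TestFilterCandidates:
    def _run_with(self, entries):
        rec = zp.MCRunRecord(0, 0)
        for i, (seq, m, z, e, h) in enumerate(entries):
            step = zp.MCStepRecord(
                step=i, position=0, proposed_residue=seq[0], delta_z=0,
                delta_ec=0, delta_h=0, mutation_term=0, delta_cost=-1,
                accepted=True, rng_draw=None, sequence=seq,
                metrics=Metrics(z, e, h), mutation_count=m,
            )
            rec.steps.append(step)
            rec.accepted.append(step)
        return rec

    def test_ranking_matches_brute_force_sort(self):
        rng = np.random.default_rng(0)
        entries = [
            ("SEQ%02d" % i, int(rng.integers(0, 6)), rng.random(),
             rng.normal() * 10, rng.normal())
            for i in range(50)
        ]
        w = zp.CostWeights()
        cands = zp.filter_candidates([self._run_with(entries)], 5, 10, w)
        brute = sorted(
            (
                (w.weight_a * z + w.weight_b * e + w.weight_c * h, seq)
                for seq, m, z, e, h in entries if m <= 5
            ),
        )[:10]
        assert [c.sequence for c in cands] == [b[1] for b in brute]
        assert [c.cost for c in cands] == pytest.approx([b[0] for b in brute])

    def test_six_mutations_excluded(self):
        entries = [("AAAAAA", 6, 0.0, -100.0, -1.0), ("CCCCCC", 5, 1.0, 0.0, 0.0)]
        cands = zp.filter_candidates([self._run_with(entries)], 5, 100)
        assert [c.sequence for c in cands] == ["CCCCCC"]

    def test_duplicates_keep_best_cost(self):
        entries = [("AAAA", 1, 1.0, 0.0, 0.0), ("AAAA", 1, 0.2, 0.0, 0.0)]
        cands = zp.filter_candidates([self._run_with(entries)], 5, 100)
        assert len(cands) == 1
        assert cands[0].cost == pytest.approx(2.0)  # 10 * 0.2

    def test_empty_pool_returns_empty_list(self):
        assert zp.filter_candidates([zp.MCRunRecord(0, 0)]) == []


class TestMutabilityProfile:
    def _cand(self, seq, m=1):
        return zp.Candidate(seq, m, Metrics(0, 0, 0), 0.0)

    def test_no_mutations(self):
        counts, _ = zp.mutability_profile(
            [self._cand("AAAA", 0)] * 5, "AAAA"
        )
        assert np.all(counts == 0)

    def test_counts_match_brute_force_tallies(self):
        rng = np.random.default_rng(0)
        original = "APKLMIYDVDNRPSGV"
        cands = []
        for _ in range(100):
            seq = list(original)
            for pos in rng.choice(16, size=rng.integers(0, 4), replace=False):
                seq[pos] = "W"
            cands.append(self._cand("".join(seq)))
        counts, freqs = zp.mutability_profile(cands, original)
        brute = [
            sum(c.sequence[i] != original[i] for c in cands) for i in range(16)
        ]
        assert list(counts) == brute
        for i in range(16):
            assert sum(freqs[i].values()) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            zp.mutability_profile([self._cand("AAA")], "AAAA")


@pytest.fixture(scope="module")
def complex_():
    return zp.assign_parameters(
        make_toy_dimer(ToyDimerSpec(n_residues=6, separation=6.0))
    )


class TestPlacer:

    def test_mutation_to_gly_strips_side_chain(self, complex_):
        out = naive_placer(complex_, "B", 2, "G")
        res = [r for r in out.residues("B") if r.seq_index == 2][0]
        assert res.residue_type == "GLY"
        assert all(a.is_backbone for a in res.atoms)

    def test_backbone_untouched(self, complex_):
        out = naive_placer(complex_, "B", 3, "W")
        before = {a.name: a.position for a in complex_.residues("B")[2].atoms
                  if a.is_backbone}
        res = [r for r in out.residues("B") if r.seq_index == 3][0]
        for a in res.atoms:
            if a.is_backbone:
                assert np.max(np.abs(a.position - before[a.name])) < 1e-6

    def test_ala_to_val_near_cb(self, complex_):
        out = naive_placer(complex_, "B", 1, "V")
        res = [r for r in out.residues("B") if r.seq_index == 1][0]
        cb = res.atom("CB").position
        for name in ("CG1", "CG2"):
            d = np.linalg.norm(res.atom(name).position - cb)
            assert d < 2.0

    def test_idempotent_heavy_atom_set(self, complex_):
        out1 = naive_placer(complex_, "B", 1, "L")
        out2 = naive_placer(out1, "B", 1, "L")
        res1 = [r for r in out1.residues("B") if r.seq_index == 1][0]
        res2 = [r for r in out2.residues("B") if r.seq_index == 1][0]
        assert [a.name for a in res1.atoms] == [a.name for a in res2.atoms]

    def test_templates_cover_all_standard_residues(self):
        from zernipep.core import THREE_TO_ONE

        assert set(SIDECHAIN_TEMPLATES) == set(THREE_TO_ONE)

    def test_template_atoms_parameterizable(self, complex_):
        # every mutated residue must resolve against the shipped table
        for letter in DEFAULT_ALPHABET + "C":
            out = naive_placer(complex_, "B", 2, letter)
            zp.assign_parameters(out)


class TestComplexScorer:
    def test_metrics_rigid_motion_invariant(self, small_complex):
        sc = zp.ComplexScorer(small_complex, "A", "B", grid_size=48, order=12)
        m0 = sc.evaluate("AAAAAA", small_complex)
        ang = 0.8
        R = np.array([
            [np.cos(ang), -np.sin(ang), 0],
            [np.sin(ang), np.cos(ang), 0],
            [0, 0, 1],
        ])
        moved = small_complex.rotated(R).translated((7.0, -3.0, 11.0))
        sc2 = zp.ComplexScorer(moved, "A", "B", grid_size=48, order=12)
        m1 = sc2.evaluate("AAAAAA", moved)
        assert m1.z_d == pytest.approx(m0.z_d, abs=2e-3)
        assert m1.e_c == pytest.approx(m0.e_c, abs=1e-3)
        assert m1.h_d == pytest.approx(m0.h_d, abs=1e-3)

    def test_neutralized_charges_zero_coulomb(self, small_complex):
        neutral = small_complex.copy()
        for a in neutral.atoms():
            a.partial_charge = 0.0
        sc = zp.ComplexScorer(neutral, "A", "B", grid_size=48, order=8)
        assert sc.evaluate("AAAAAA", neutral).e_c == 0.0

    def test_native_baseline_finite(self, small_complex):
        sc = zp.ComplexScorer(small_complex, "A", "B", grid_size=48, order=12)
        m = sc.evaluate("AAAAAA", small_complex)
        assert np.isfinite([m.z_d, m.e_c, m.h_d]).all()
        assert m.z_d >= 0
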