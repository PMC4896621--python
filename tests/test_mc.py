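"""Metropolis moves: locality, constraint preservation, equilibrium, codes."""

import itertools

import numpy as np
import pytest

from nucmux.constraints import initial_state
from nucmux.genetic_code import (
    CODON_STRINGS,
    aa_of_codon,
    codon_code,
    codon_string,
    synonymous_tables,
    translate,
)
from nucmux.mc import (
    MCConfig,
    ROOM_T,
    metropolis_accept,
    mutation_move,
    run_mmc,
    run_smmc,
    spatial_move,
    synonymous_move,
    _unconstrained_state,
)
from nucmux.mechanics import chain_energy

from conftest import random_seq


class TestMetropolisAccept:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(dE, 100.0, rng) for dE in (-5.0, -1e-9, 0.0))

    def test_infinite_temperature_accepts_everything(self, rng):
        assert all(metropolis_accept(50.0, 1e12, rng) for _ in range(100))

    def test_half_acceptance_at_ln2_barrier(self):
        """dE = (T/300) ln 2 has acceptance probability exactly 1/2."""
        rng = np.random.default_rng(0)
        T = 137.0
        dE = (T / ROOM_T) * np.log(2.0)
        acc = sum(metropolis_accept(dE, T, rng) for _ in range(100_000)) / 100_000
        assert acc == pytest.approx(0.5, abs=0.01)

    def test_nonfinite_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(np.nan, 100.0, rng)


class TestSingleMoves:
    def test_spatial_move_is_local(self, params, nuc_constraints, rng):
        state = initial_state(random_seq(147, seed=1), nuc_constraints, params)
        before = state.steps.copy()
        cfg = MCConfig(temperature_K=1e9, n_sweeps=1, sigma_trans=0.1, sigma_rot=1.0)
        for _ in range(20):
            _, dE, accepted = spatial_move(state, params, cfg, rng)
            assert accepted  # effectively infinite temperature
            changed = np.flatnonzero(np.abs(state.steps - before).max(axis=1) > 0)
            assert len(changed) <= 3
            if len(changed) > 1:
                assert changed.max() - changed.min() <= 2
            before = state.steps.copy()

    def test_constrained_pair_move_preserves_midframe(self, params, nuc_constraints, rng):
        state = initial_state(random_seq(147, seed=1), nuc_constraints, params)
        cfg = MCConfig(temperature_K=1e9, n_sweeps=1, sigma_trans=0.2, sigma_rot=2.0)
        for _ in range(200):
            spatial_move(state, params, cfg, rng)
        pos_err, rot_err = state.constraint_residuals()
        assert pos_err < 1e-10
        assert rot_err < 1e-10

    def test_zero_width_proposal_is_identity(self, params, nuc_constraints, rng):
        state = initial_state(random_seq(147, seed=1), nuc_constraints, params)
        before = state.steps.copy()
        cfg = MCConfig(temperature_K=50.0, n_sweeps=1, sigma_trans=0.0, sigma_rot=0.0)
        _, dE, accepted = spatial_move(state, params, cfg, rng)
        assert accepted
        assert dE == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(state.steps, before, atol=1e-12)

    def test_terminal_mutation_touches_one_step(self, params):
        state = _unconstrained_state("ACGTA", params)
        cfg = MCConfig(temperature_K=300.0, n_sweeps=1)

        class FixedRng:
            def __init__(self, choices):
                self.choices = iter(choices)

            def integers(self, n):
                return next(self.choices)

            def random(self):
                return 0.0

        e_before = [chain_energy(state.seq, state.steps, params)]
        _, dE, accepted = mutation_move(state, params, cfg, FixedRng([0, 0]))
        local = (
            chain_energy(state.seq, state.steps, params) - e_before[0]
            if accepted else 0.0
        )
        assert dE == pytest.approx(local, abs=1e-10)

    def test_mutation_never_proposes_same_base(self, params, rng):
        state = _unconstrained_state("AAAAA", params)
        cfg = MCConfig(temperature_K=1e9, n_sweeps=1)
        for _ in range(50):
            mutation_move(state, params, cfg, rng)
            # at infinite temperature every proposal is accepted, so the
            # sequence must change every time a position is hit twice
        assert set(state.seq) != {"A"}


class TestGeneticCodeTables:
    def test_met_and_trp_have_no_alternatives(self):
        syn_n, _ = synonymous_tables()
        assert syn_n[codon_code("ATG")] == 0
        assert syn_n[codon_code("TGG")] == 0
        assert sum(syn_n > 0) == 59  # 61 sense codons minus ATG and TGG

    def test_threonine_proposals_stay_in_the_box(self):
        syn_n, syn_codons = synonymous_tables()
        c = codon_code("ACA")
        alts = {codon_string(int(a)) for a in syn_codons[c, : syn_n[c]]}
        assert alts == {"ACT", "ACC", "ACG"}

    def test_stop_codons_never_proposed(self):
        syn_n, syn_codons = synonymous_tables()
        stops = {"TAA", "TAG", "TGA"}
        for c in range(64):
            alts = {codon_string(int(a)) for a in syn_codons[c, : syn_n[c]]}
            assert not (alts & stops)

    def test_glu_thr_junction_steps_are_AA_or_GA(self):
        """Across all synonymous choices of a Glu|Thr codon pair, the junction
        dinucleotide can only be AA or GA."""
        glu = [c for c in CODON_STRINGS if aa_of_codon(c) == "E"]
        thr = [c for c in CODON_STRINGS if aa_of_codon(c) == "T"]
        junctions = {g[-1] + t[0] for g in glu for t in thr}
        assert junctions == {"AA", "GA"}


class TestSynonymousMoves:
    def test_all_met_gene_never_changes(self, params, nuc_constraints):
        gene = "ATG" * 49
        cfg = MCConfig(temperature_K=100.0, n_sweeps=300, seed=3, record_every=5)
        ens = run_smmc(gene, 0, nuc_constraints, cfg, params)
        assert set(ens.sequences()) == {gene[:147]}

    def test_protein_invariant_along_run(self, params, nuc_constraints):
        from nucmux.synth import random_coding_sequence

        gene = random_coding_sequence(60, seed=8)
        cfg = MCConfig(temperature_K=100.0, n_sweeps=800, seed=4, record_every=2)
        ens = run_smmc(gene, 9, nuc_constraints, cfg, params)
        assert len(ens) > 100
        proteins = {translate(s[: 49 * 3]) for s in ens.sequences()}
        assert len(proteins) == 1
        assert proteins == {ens.meta["protein"]}

    def test_stop_codon_in_window_rejected(self, params, nuc_constraints):
        gene = "ATG" + "TAA" + "ATG" * 60
        with pytest.raises(ValueError, match="stop"):
            run_smmc(gene, 0, nuc_constraints, MCConfig(n_sweeps=10), params)

    def test_single_synonymous_move_preserves_protein(self, params, rng):
        from nucmux.synth import random_coding_sequence

        state = _unconstrained_state(random_coding_sequence(49, seed=1), params)
        cfg = MCConfig(temperature_K=1e9, n_sweeps=1)
        before = translate(state.seq)
        for _ in range(100):
            synonymous_move(state, 0, params, cfg, rng)
        assert translate(state.seq) == before
        with pytest.raises(ValueError, match="reading_frame"):
            synonymous_move(state, 5, params, cfg, rng)


class TestEnsembleRuns:
    def test_seed_reproducibility(self, params, nuc_constraints):
        cfg = MCConfig(temperature_K=100.0, n_sweeps=400, seed=11, record_every=2)
        seq0 = random_seq(147, seed=5)
        e1 = run_mmc(seq0, nuc_constraints, cfg, params)
        e2 = run_mmc(seq0, nuc_constraints, cfg, params)
        assert np.array_equal(e1.seqs, e2.seqs)
        assert np.array_equal(e1.energies, e2.energies)
        e3 = run_mmc(seq0, nuc_constraints,
                     MCConfig(temperature_K=100.0, n_sweeps=400, seed=12,
                              record_every=2), params)
        assert not np.array_equal(e1.seqs, e3.seqs)

    def test_infinite_temperature_dinucleotide_frequencies(self, params):
        """Unconstrained chain at 1e6 K: all 16 steps equally likely."""
        cfg = MCConfig(temperature_K=1e6, n_sweeps=4000, seed=2, record_every=2,
                       burn_in_fraction=0.1)
        ens = run_mmc(random_seq(40, seed=1), None, cfg, params)
        codes = 4 * ens.seqs[:, :-1].astype(int) + ens.seqs[:, 1:]
        freq = np.bincount(codes.ravel(), minlength=16) / codes.size
        assert np.abs(freq - 1 / 16).max() < 0.01

    def test_lower_temperature_gives_lower_energy(self, params, nuc_constraints):
        seq0 = random_seq(147, seed=5)
        means = {}
        for T in (100.0, 600.0):
            cfg = MCConfig(temperature_K=T, n_sweeps=4000, seed=21, record_every=2,
                           burn_in_fraction=0.25)
            ens = run_mmc(seq0, nuc_constraints, cfg, params)
            means[T] = ens.energies.mean()
        assert means[100.0] < means[600.0]

    def test_constraints_preserved_during_sampling(self, params, nuc_constraints):
        from nucmux.mc import _run

        state = initial_state(random_seq(147, seed=3), nuc_constraints, params)
        cfg = MCConfig(temperature_K=300.0, n_sweeps=300, seed=7, record_every=50)
        _, final, _ = _run(state, params, cfg)
        pos_err, rot_err = final.constraint_residuals()
        assert pos_err < 1e-6
        assert rot_err < 1e-8

    def test_fasta_roundtrip(self, params, nuc_constraints, tmp_path):
        from nucmux.mc import SequenceEnsemble

        cfg = MCConfig(temperature_K=100.0, n_sweeps=200, seed=1, record_every=5)
        ens = run_mmc(random_seq(147, seed=5), nuc_constraints, cfg, params)
        path = tmp_path / "ens.fasta"
        ens.to_fasta(path)
        back = SequenceEnsemble.from_fasta(path)
        assert np.array_equal(back.seqs, ens.seqs)
        assert np.allclose(back.energies, ens.energies, atol=1e-6)


class TestBoltzmannEquilibrium:
    def test_mutation_only_matches_exact_enumeration(self, params):
        """Mutation-only sampling on a 3-bp chain with frozen configuration
        reproduces the exact 64-state Boltzmann distribution."""
        n = 3
        T = 300.0
        steps = np.tile(params.mean_intrinsic(), (n - 1, 1))
        seqs = ["".join(s) for s in itertools.product("ACGT", repeat=n)]
        E = np.array([chain_energy(s, steps, params) for s in seqs])
        boltz = np.exp(-(E - E.min()) * ROOM_T / T)
        boltz /= boltz.sum()
        cfg = MCConfig(temperature_K=T, n_sweeps=70_000, seed=17,
                       move_mix=(0.0, 1.0), record_every=1, burn_in_fraction=0.05)
        ens = run_mmc("A" * n, None, cfg, params)
        idx = {s: i for i, s in enumerate(seqs)}
        counts = np.zeros(64)
        for s in ens.sequences():
            counts[idx[s]] += 1
        emp = counts / counts.sum()
        tv = 0.5 * np.abs(emp - boltz).sum()
        assert tv < 0.03
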