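"""Metropolis sampler in joint conformation/sequence space.

Two move families are mixed at a single effective temperature:

* *spatial moves* perturb the DNA conformation without violating the fixed
  midframes — either a rigid-body Gaussian displacement of one unconstrained
  base pair, or an internal perturbation of a constrained pair that keeps
  its midframe exactly invariant;
* *mutation moves* change the sequence while keeping the configuration
  fixed — a uniform single-base substitution (MMC) or a synonymous codon
  replacement (sMMC), which leaves the encoded protein untouched.

The effective temperature T is simulation-technical: the parametrization's
energies are in units of kT at room temperature, so Metropolis uses
``beta_eff = 300 / T_K``; lowering T below 300 K sharpens the sequence
ensemble towards high-affinity sequences.  It is not a physiological
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .constraints import ConstraintSet, NucleosomeState, initial_state
from .genetic_code import synonymous_tables, translate
from .mechanics import (
    Frame,
    StepParamSet,
    compose_frames,
    decode_sequence,
    encode_sequence,
    frames_from_midstep,
    frames_to_step,
    step_energy,
    validate_sequence,
)

__all__ = [
    "MCConfig",
    "SequenceEnsemble",
    "metropolis_accept",
    "mutation_move",
    "run_mmc",
    "run_smmc",
    "spatial_move",
    "synonymous_move",
]

ROOM_T = 300.0

_SYN_N, _SYN_CODONS = synonymous_tables()
_NO_SYN = (np.zeros(64, dtype=np.int64), np.full((64, 6), -1, dtype=np.int64))


@dataclass
class MCConfig:
    """Sampler configuration.

    ``move_mix`` is the (spatial, mutation) proposal fraction and must sum
    to 1.  Proposal widths are the Gaussian sigmas for translations
    [Angstrom] and rotations [degrees]; with ``autotune`` they are adjusted
    during burn-in towards a 40-60% spatial acceptance rate.  One sweep
    proposes as many moves as there are base pairs.
    """

    temperature_K: float = 100.0
    n_sweeps: int = 1000
    seed: int = 0
    move_mix: tuple[float, float] = (0.5, 0.5)
    sigma_trans: float = 0.12
    sigma_rot: float = 2.0
    record_every: int = 1
    burn_in_fraction: float = 0.1
    autotune: bool = True

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if abs(sum(self.move_mix) - 1.0) > 1e-9:
            raise ValueError("move_mix fractions must sum to 1")

    @property
    def beta(self) -> float:
        return ROOM_T / self.temperature_K


@dataclass
class SequenceEnsemble:
    """Recorded (sequence, energy) samples with run provenance."""

    seqs: np.ndarray        # (n, L) int8 base codes
    energies: np.ndarray    # (n,) kT
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def sequences(self) -> list[str]:
        return [decode_sequence(row) for row in self.seqs]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for k, row in enumerate(self.seqs):
                fh.write(f">sample_{k} energy_kT={self.energies[k]:.6f}\n")
                fh.write(decode_sequence(row) + "\n")

    @classmethod
    def from_fasta(cls, path) -> "SequenceEnsemble":
        seqs, energies = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    energies.append(float(line.split("energy_kT=")[1]))
                elif line:
                    seqs.append(encode_sequence(line))
        return cls(np.array(seqs, dtype=np.int8), np.array(energies))


def metropolis_accept(dE: float, temperature_K: float, rng) -> bool:
    """Accept with probability min(1, exp(-dE * 300/T))."""
    if not np.isfinite(dE):
        raise ValueError("dE must be finite")
    if dE <= 0:
        return True
    return bool(rng.random() < np.exp(-dE * ROOM_T / temperature_K))


# ---------------------------------------------------------------------------
# Kernel plumbing
# ---------------------------------------------------------------------------

def _constraint_arrays(constraints: ConstraintSet | None, n_bp: int):
    n_steps = n_bp - 1
    cons_id = np.full(n_steps, -1, dtype=np.int64)
    if constraints is None:
        midR = np.zeros((1, 3, 3))
        mido = np.zeros((1, 3))
        cons_steps = np.empty(0, dtype=np.int64)
    else:
        cons_steps = constraints.step_indices.astype(np.int64)
        midR = np.stack([f.R for f in constraints.frames])
        mido = np.stack([f.origin for f in constraints.frames])
        cons_id[cons_steps] = np.arange(len(cons_steps))
    blocked = np.zeros(n_bp, dtype=bool)
    for s in cons_steps:
        blocked[s] = blocked[s + 1] = True
    free_bp = np.flatnonzero(~blocked).astype(np.int64)
    return cons_id, midR, mido, free_bp, cons_steps


def _state_arrays(state: NucleosomeState, params: StepParamSet):
    seq = encode_sequence(state.seq)
    R = np.ascontiguousarray(state.frames_R, dtype=np.float64)
    o = np.ascontiguousarray(state.frames_o, dtype=np.float64)
    stepq = np.ascontiguousarray(state.steps, dtype=np.float64)
    E = np.empty(len(seq) - 1)
    _kernels.refresh_energies(seq, stepq, E, params.q0, params.Q)
    return seq, R, o, stepq, E


def _unconstrained_state(seq: str, params: StepParamSet,
                         steps: np.ndarray | None = None) -> NucleosomeState:
    """A straight (or user-supplied) chain with no constraints."""
    s = validate_sequence(seq)
    n = len(s)
    if steps is None:
        steps = np.tile(params.mean_intrinsic(), (n - 1, 1))
    steps = np.asarray(steps, dtype=float).reshape(n - 1, 6)
    frames = [Frame.identity()]
    for i in range(n - 1):
        frames.append(compose_frames(frames[-1], steps[i]))
    return NucleosomeState(
        s, np.stack([f.R for f in frames]), np.stack([f.origin for f in frames]),
        steps, None,
    )


def _run(state: NucleosomeState, params: StepParamSet, cfg: MCConfig,
         syn_mode: int = 0,
         mut_positions: np.ndarray | None = None,
         codon_starts: np.ndarray | None = None,
         rec_window: tuple[int, int] | None = None):
    """Drive the kernel: burn-in (with optional width autotuning) + sampling.

    Returns (ensemble, final-state, info-dict).
    """
    seq, R, o, stepq, E = _state_arrays(state, params)
    n_bp = len(seq)
    cons_id, midR, mido, free_bp, cons_steps = _constraint_arrays(state.constraints, n_bp)
    if mut_positions is None:
        mut_positions = np.arange(n_bp, dtype=np.int64)
    if codon_starts is None:
        codon_starts = np.empty(0, dtype=np.int64)
    syn_n, syn_codons = (_SYN_N, _SYN_CODONS) if syn_mode else _NO_SYN
    rec_lo, rec_hi = rec_window if rec_window is not None else (0, n_bp - 2)

    rng = np.random.default_rng(cfg.seed)
    moves_per_sweep = n_bp
    p_spatial = cfg.move_mix[0]
    sig_t, sig_r = cfg.sigma_trans, cfg.sigma_rot

    empty_seq = np.empty((0, n_bp), dtype=np.int8)
    empty_E = np.empty(0)

    n_burn = int(round(cfg.burn_in_fraction * cfg.n_sweeps))
    if n_burn > 0 and p_spatial > 0:
        n_tune = 8 if cfg.autotune else 1
        per = max(1, n_burn // n_tune)
        done = 0
        while done < n_burn:
            sweeps = min(per, n_burn - done)
            res = _kernels.mc_chunk(
                seq, R, o, stepq, E, params.q0, params.Q,
                cons_id, midR, mido, free_bp, cons_steps,
                cfg.beta, sig_t, sig_r, p_spatial,
                mut_positions, syn_mode, codon_starts, syn_n, syn_codons,
                sweeps * moves_per_sweep, 0, empty_seq, empty_E,
                rec_lo, rec_hi, int(rng.integers(2**31)),
            )
            _, sp_prop, sp_acc, _, _ = res
            if cfg.autotune and sp_prop > 0:
                acc = sp_acc / sp_prop
                if acc < 0.40:
                    sig_t *= 0.8
                    sig_r *= 0.8
                elif acc > 0.60:
                    sig_t *= 1.25
                    sig_r *= 1.25
            done += sweeps
    elif n_burn > 0:
        _kernels.mc_chunk(
            seq, R, o, stepq, E, params.q0, params.Q,
            cons_id, midR, mido, free_bp, cons_steps,
            cfg.beta, sig_t, sig_r, p_spatial,
            mut_positions, syn_mode, codon_starts, syn_n, syn_codons,
            n_burn * moves_per_sweep, 0, empty_seq, empty_E,
            rec_lo, rec_hi, int(rng.integers(2**31)),
        )

    n_sample = cfg.n_sweeps - n_burn
    record_interval = cfg.record_every * moves_per_sweep
    n_rec_max = (n_sample * moves_per_sweep) // record_interval if n_sample > 0 else 0
    rec_seq = np.empty((n_rec_max, n_bp), dtype=np.int8)
    rec_E = np.empty(n_rec_max)
    n_rec, sp_prop, sp_acc, mu_prop, mu_acc = _kernels.mc_chunk(
        seq, R, o, stepq, E, params.q0, params.Q,
        cons_id, midR, mido, free_bp, cons_steps,
        cfg.beta, sig_t, sig_r, p_spatial,
        mut_positions, syn_mode, codon_starts, syn_n, syn_codons,
        n_sample * moves_per_sweep, record_interval, rec_seq, rec_E,
        rec_lo, rec_hi, int(rng.integers(2**31)),
    )

    final = NucleosomeState(decode_sequence(seq), R, o, stepq, state.constraints)
    info = {
        "sigma_trans": sig_t, "sigma_rot": sig_r,
        "spatial_acceptance": sp_acc / sp_prop if sp_prop else np.nan,
        "mutation_acceptance": mu_acc / mu_prop if mu_prop else np.nan,
    }
    ens = SequenceEnsemble(
        rec_seq[:n_rec], rec_E[:n_rec],
        meta={"config": cfg, "constraints": getattr(state.constraints, "chain_length", None),
              **info},
    )
    return ens, final, info


def run_mmc(seq0: str, constraints: ConstraintSet | None, cfg: MCConfig,
            params: StepParamSet) -> SequenceEnsemble:
    """Mutation Monte Carlo: joint spatial + single-base mutation sampling.

    With ``constraints=None`` the chain is unconstrained (straight start).
    Reproducible: a given (seed, config) yields a bit-identical ensemble.
    """
    if constraints is not None:
        state = initial_state(seq0, constraints, params)
    else:
        state = _unconstrained_state(seq0, params)
    ens, _, _ = _run(state, params, cfg, syn_mode=0)
    return ens


def run_smmc(gene_seq: str, codon_offset: int, constraints: ConstraintSet | None,
             cfg: MCConfig, params: StepParamSet) -> SequenceEnsemble:
    """Synonymous MMC on a nucleosome wrapped at ``codon_offset`` on a gene.

    ``codon_offset`` is the 0-based start of the wrapped window within the
    gene; it sets both the nucleosome position and the reading frame
    (``codon_offset % 3``).  Only codons fully contained in the window are
    mutable, so every recorded sequence translates to the same protein.
    """
    gene = validate_sequence(gene_seq)
    n_bp = constraints.chain_length if constraints is not None else 147
    if codon_offset < 0 or len(gene) < codon_offset + n_bp:
        raise ValueError("gene too short for the requested nucleosome position")
    window = gene[codon_offset : codon_offset + n_bp]
    frame = (-codon_offset) % 3
    codon_starts = np.arange(frame, n_bp - 2, 3, dtype=np.int64)
    wrapped_codons = "".join(window[i : i + 3] for i in codon_starts)
    protein = translate(wrapped_codons)
    if "*" in protein:
        raise ValueError("wrapped segment contains an in-frame stop codon")
    if constraints is not None:
        state = initial_state(window, constraints, params)
    else:
        state = _unconstrained_state(window, params)
    ens, _, _ = _run(state, params, cfg, syn_mode=1, codon_starts=codon_starts)
    ens.meta["protein"] = protein
    ens.meta["reading_frame"] = frame
    return ens


# ---------------------------------------------------------------------------
# Single-move reference implementations (python/scipy route)
# ---------------------------------------------------------------------------

def _affected_energy(state: NucleosomeState, params: StepParamSet,
                     step_ids, steps=None, seq=None) -> float:
    steps = state.steps if steps is None else steps
    seq = state.seq if seq is None else seq
    return sum(
        step_energy(steps[s], seq[s : s + 2], params) for s in step_ids
    )


def spatial_move(state: NucleosomeState, params: StepParamSet, cfg: MCConfig,
                 rng) -> tuple[NucleosomeState, float, bool]:
    """One spatial Metropolis move, performed in place.

    Proposes either a rigid-body perturbation of an unconstrained base pair
    or an internal perturbation of a constrained pair (midframe invariant),
    chosen uniformly; returns (state, dE, accepted).
    """
    n_bp = len(state.seq)
    cons_id, midR, mido, free_bp, cons_steps = _constraint_arrays(state.constraints, n_bp)
    t = int(rng.integers(len(free_bp) + len(cons_steps)))
    if t < len(free_bp):
        b = int(free_bp[t])
        dphi = np.deg2rad(cfg.sigma_rot) * rng.standard_normal(3)
        dt = cfg.sigma_trans * rng.standard_normal(3)
        from scipy.spatial.transform import Rotation

        Rn = state.frames_R[b] @ Rotation.from_rotvec(dphi).as_matrix()
        on = state.frames_o[b] + state.frames_R[b] @ dt
        touched = [s for s in (b - 1, b) if 0 <= s <= n_bp - 2]
        new_steps = {}
        for s in touched:
            fi = Frame(on, Rn) if s == b else Frame(state.frames_o[s], state.frames_R[s])
            fj = Frame(on, Rn) if s + 1 == b else Frame(state.frames_o[s + 1], state.frames_R[s + 1])
            new_steps[s] = frames_to_step(fi, fj)
        e_old = _affected_energy(state, params, touched)
        trial = state.steps.copy()
        for s, q in new_steps.items():
            trial[s] = q
        e_new = _affected_energy(state, params, touched, steps=trial)
        dE = e_new - e_old
        accepted = metropolis_accept(dE, cfg.temperature_K, rng)
        if accepted:
            state.frames_R[b] = Rn
            state.frames_o[b] = on
            state.steps = trial
        return state, dE, accepted

    s = int(cons_steps[t - len(free_bp)])
    target = state.constraints.frames[int(np.flatnonzero(state.constraints.step_indices == s)[0])]
    dq = np.concatenate([
        cfg.sigma_trans * rng.standard_normal(3),
        cfg.sigma_rot * rng.standard_normal(3),
    ])
    qnew = state.steps[s] + dq
    fi, fj = frames_from_midstep(target, qnew)
    touched = [x for x in (s - 1, s, s + 1) if 0 <= x <= n_bp - 2]
    trial = state.steps.copy()
    trial[s] = qnew
    if s - 1 >= 0:
        trial[s - 1] = frames_to_step(Frame(state.frames_o[s - 1], state.frames_R[s - 1]), fi)
    if s + 2 <= n_bp - 1:
        trial[s + 1] = frames_to_step(fj, Frame(state.frames_o[s + 2], state.frames_R[s + 2]))
    dE = (_affected_energy(state, params, touched, steps=trial)
          - _affected_energy(state, params, touched))
    accepted = metropolis_accept(dE, cfg.temperature_K, rng)
    if accepted:
        state.frames_R[s], state.frames_o[s] = fi.R, fi.origin
        state.frames_R[s + 1], state.frames_o[s + 1] = fj.R, fj.origin
        state.steps = trial
    return state, dE, accepted


def mutation_move(state: NucleosomeState, params: StepParamSet, cfg: MCConfig,
                  rng) -> tuple[NucleosomeState, float, bool]:
    """One single-base mutation move (configuration fixed), in place."""
    n_bp = len(state.seq)
    p = int(rng.integers(n_bp))
    old = state.seq[p]
    alternatives = [b for b in "ACGT" if b != old]
    new = alternatives[int(rng.integers(3))]
    trial_seq = state.seq[:p] + new + state.seq[p + 1 :]
    touched = [s for s in (p - 1, p) if 0 <= s <= n_bp - 2]
    dE = (_affected_energy(state, params, touched, seq=trial_seq)
          - _affected_energy(state, params, touched))
    accepted = metropolis_accept(dE, cfg.temperature_K, rng)
    if accepted:
        state.seq = trial_seq
    return state, dE, accepted


def synonymous_move(state: NucleosomeState, reading_frame: int,
                    params: StepParamSet, cfg: MCConfig,
                    rng) -> tuple[NucleosomeState, float, bool]:
    """One synonymous codon replacement move, in place.

    Codons with no synonymous alternative (Met, Trp) are a no-op counted as
    rejected.  The encoded protein is invariant by construction.
    """
    if reading_frame not in (0, 1, 2):
        raise ValueError("reading_frame must be 0, 1 or 2")
    n_bp = len(state.seq)
    codon_starts = np.arange(reading_frame, n_bp - 2, 3)
    cstart = int(codon_starts[int(rng.integers(len(codon_starts)))])
    codon = state.seq[cstart : cstart + 3]
    from .genetic_code import codon_code, codon_string

    c = codon_code(codon)
    nalt = int(_SYN_N[c])
    if nalt == 0:
        return state, 0.0, False
    alt = codon_string(int(_SYN_CODONS[c, int(rng.integers(nalt))]))
    trial_seq = state.seq[:cstart] + alt + state.seq[cstart + 3 :]
    touched = [s for s in range(cstart - 1, cstart + 3) if 0 <= s <= n_bp - 2]
    dE = (_affected_energy(state, params, touched, seq=trial_seq)
          - _affected_energy(state, params, touched))
    accepted = metropolis_accept(dE, cfg.temperature_K, rng)
    if accepted:
        state.seq = trial_seq
    return state, dE, accepted
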