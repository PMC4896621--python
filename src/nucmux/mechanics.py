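"""Rigid base-pair DNA geometry and sequence-dependent elastic energy.

The double helix is coarse-grained to one rigid body per base pair.  The
relative placement of two consecutive base pairs (a *step*) is described by
six step parameters, ordered package-wide as

    q = (shift, slide, rise, tilt, roll, twist)

with translations in Angstrom along the mid-step frame's x, y, z axes and
rotations in degrees about the same axes (rotation-vector parametrization,
half-rotation "mid-step" convention).  The elastic energy of a step of
dinucleotide type ``s`` is the quadratic form

    E(q) = 1/2 (q - q0_s)^T  Q_s  (q - q0_s)

in units of kT at room temperature, with intrinsic values ``q0_s`` and a
symmetric positive-definite 6x6 stiffness matrix ``Q_s`` per dinucleotide.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "BASES",
    "COMPONENT_NAMES",
    "DINUCLEOTIDES",
    "Frame",
    "StepParamSet",
    "chain_energy",
    "compose_frames",
    "frames_to_step",
    "load_step_params",
    "midframe",
    "reverse_complement",
    "sequence_steps",
    "step_energy",
    "validate_sequence",
]

BASES = "ACGT"
COMPONENT_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Signature of the strand-inversion (reverse-complement) transformation on
#: step parameters: shift and tilt change sign, the other four are invariant.
INVERSION_SIGNS = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])


def validate_sequence(seq: str) -> str:
    """Upper-case ``seq`` and check it is over the {A,C,G,T} alphabet."""
    s = seq.upper()
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sequence_steps(seq: str) -> list[str]:
    """The N-1 dinucleotide step types of an N-base sequence."""
    s = validate_sequence(seq)
    return [s[i : i + 2] for i in range(len(s) - 1)]


def encode_sequence(seq: str) -> np.ndarray:
    """Sequence string -> int8 codes (A=0, C=1, G=2, T=3)."""
    s = validate_sequence(seq)
    lut = np.full(128, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(s.encode(), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """Position and orientation of a base pair (or mid-step frame) in the lab.

    ``R`` holds the frame axes as columns; x points towards the major groove,
    y along the long base-pair axis, z along the local helix axis.
    """

    origin: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(self.origin)) or not np.all(np.isfinite(self.R)):
            raise ValueError("Frame entries must be finite")
        err = np.abs(self.R @ self.R.T - np.eye(3)).max()
        if err > 1e-9 or not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError(
                f"Frame orientation is not a proper rotation (orthonormality "
                f"error {err:.2e}, det {np.linalg.det(self.R):.6f})"
            )

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.zeros(3), np.eye(3))

    def copy(self) -> "Frame":
        return Frame(self.origin.copy(), self.R.copy())


def _split_q(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q = np.asarray(q, dtype=float).reshape(6)
    return q[:3], np.deg2rad(q[3:])


def compose_frames(frame_i: Frame, q: np.ndarray) -> Frame:
    """Frame of base pair i+1 given the frame of i and step parameters ``q``.

    Mid-step convention: the rotation vector (tilt, roll, twist) and the
    translation (shift, slide, rise) are expressed in the mid-step frame,
    which is frame i rotated by half the relative rotation.
    """
    t, phi = _split_q(q)
    R_half = Rotation.from_rotvec(phi / 2.0).as_matrix()
    R_mid = frame_i.R @ R_half
    return Frame(frame_i.origin + R_mid @ t, R_mid @ R_half)


def frames_to_step(frame_i: Frame, frame_j: Frame) -> np.ndarray:
    """Step parameters between two frames; exact inverse of compose_frames."""
    M = frame_i.R.T @ frame_j.R
    rv = Rotation.from_matrix(M).as_rotvec()
    angle = np.linalg.norm(rv)
    if angle > np.pi - 1e-6:
        raise ValueError(
            f"relative rotation of {np.rad2deg(angle):.1f} degrees is too close "
            "to 180 degrees for the rotation-vector parametrization"
        )
    R_mid = frame_i.R @ Rotation.from_rotvec(rv / 2.0).as_matrix()
    t = R_mid.T @ (frame_j.origin - frame_i.origin)
    return np.concatenate([t, np.rad2deg(rv)])


def midframe(frame_i: Frame, frame_j: Frame) -> Frame:
    """Frame exactly in between two base-pair frames.

    Origin is the midpoint of the origins; orientation is frame i rotated by
    half of the relative rotation vector.
    """
    M = frame_i.R.T @ frame_j.R
    rv = Rotation.from_matrix(M).as_rotvec()
    if np.linalg.norm(rv) > np.pi - 1e-6:
        raise ValueError("relative rotation too close to 180 degrees")
    R_mid = frame_i.R @ Rotation.from_rotvec(rv / 2.0).as_matrix()
    return Frame((frame_i.origin + frame_j.origin) / 2.0, R_mid)


def frames_from_midstep(mid: Frame, q: np.ndarray) -> tuple[Frame, Frame]:
    """The two base-pair frames whose mid-step frame is ``mid`` with step ``q``.

    Inverse bookkeeping used by the constrained-pair Monte Carlo move: the
    midframe is held fixed while the internal step parameters vary.
    """
    t, phi = _split_q(q)
    R_half = Rotation.from_rotvec(phi / 2.0).as_matrix()
    f_i = Frame(mid.origin - mid.R @ t / 2.0, mid.R @ R_half.T)
    f_j = Frame(mid.origin + mid.R @ t / 2.0, mid.R @ R_half)
    return f_i, f_j


# ---------------------------------------------------------------------------
# Step parameter set
# ---------------------------------------------------------------------------

@dataclass
class StepParamSet:
    """Intrinsic values and stiffness matrices for the 16 dinucleotide steps.

    Only 10 steps are independent; the reverse-complement partners follow by
    the inversion transformation (sign flip of intrinsic shift and tilt, and
    of the stiffness cross-couplings between the {shift, tilt} block and the
    {slide, rise, roll, twist} block).
    """

    q0: np.ndarray  # (16, 6)
    Q: np.ndarray   # (16, 6, 6)
    source: str = "unknown"
    #: strict sets require positive-definite stiffnesses (always the case for
    #: physical tables); non-strict permits semidefinite degenerate sets such
    #: as an all-zero-stiffness limit used in flat-landscape checks
    strict: bool = True
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.q0 = np.asarray(self.q0, dtype=float).reshape(16, 6)
        self.Q = np.asarray(self.Q, dtype=float).reshape(16, 6, 6)
        self._index = {d: i for i, d in enumerate(DINUCLEOTIDES)}
        self.validate()

    def step_index(self, step_type: str) -> int:
        try:
            return self._index[step_type.upper()]
        except KeyError:
            raise KeyError(f"unknown dinucleotide step type: {step_type!r}") from None

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.q0)) and np.all(np.isfinite(self.Q))):
            raise ValueError("step parameters must be finite")
        E = INVERSION_SIGNS
        for i, d in enumerate(DINUCLEOTIDES):
            Qi = self.Q[i]
            if np.abs(Qi - Qi.T).max() > 1e-9:
                raise ValueError(f"stiffness matrix of {d} is not symmetric")
            lam = np.linalg.eigvalsh(Qi).min()
            if lam <= 0 and (self.strict or lam < 0):
                raise ValueError(f"stiffness matrix of {d} is not positive definite")
            j = self._index[reverse_complement(d)]
            if np.abs(self.q0[j] - E * self.q0[i]).max() > 1e-8:
                raise ValueError(f"intrinsic values of {d} violate inversion symmetry")
            if np.abs(self.Q[j] - (E[:, None] * Qi * E[None, :])).max() > 1e-8:
                raise ValueError(f"stiffness of {d} violates inversion symmetry")

    def mean_intrinsic(self) -> np.ndarray:
        """Average intrinsic step; a convenient 'generic B-DNA' step."""
        return self.q0.mean(axis=0)


def _expand_inversion(q0_10: dict, Q_10: dict) -> tuple[np.ndarray, np.ndarray]:
    E = INVERSION_SIGNS
    q0 = np.zeros((16, 6))
    Q = np.zeros((16, 6, 6))
    seen = set()
    for d, block in q0_10.items():
        i = DINUCLEOTIDES.index(d)
        q0[i] = block
        Q[i] = Q_10[d]
        seen.add(d)
    for d in DINUCLEOTIDES:
        rc = reverse_complement(d)
        if d not in seen:
            i, j = DINUCLEOTIDES.index(d), DINUCLEOTIDES.index(rc)
            q0[i] = E * q0[j]
            Q[i] = E[:, None] * Q[j] * E[None, :]
    return q0, Q


def load_step_params(path=None) -> StepParamSet:
    """Load a step-parameter table.

    The table is a long-format TSV with one ``q0`` row and six ``Q0..Q5``
    rows per dinucleotide block for the 10 distinct steps; the remaining six
    steps are generated by the inversion transformation on load (which the
    constructor then re-verifies).
    """
    if path is None:
        ref = importlib.resources.files("nucmux.data") / "step_params.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_step_params(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"step", "row", *COMPONENT_NAMES}
    if set(df.columns) != expected:
        raise ValueError(f"parameter table must have columns {sorted(expected)}")
    q0_10, Q_10 = {}, {}
    for step, block in df.groupby("step"):
        block = block.set_index("row")
        q0_10[step] = block.loc["q0", list(COMPONENT_NAMES)].to_numpy(dtype=float)
        Q_10[step] = np.stack(
            [block.loc[f"Q{k}", list(COMPONENT_NAMES)].to_numpy(dtype=float) for k in range(6)]
        )
    if len(q0_10) != 10:
        raise ValueError(f"expected 10 distinct steps in table, got {len(q0_10)}")
    q0, Q = _expand_inversion(q0_10, Q_10)
    return StepParamSet(q0, Q, source=str(path))


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------

def step_energy(q: np.ndarray, step_type: str, params: StepParamSet) -> float:
    """Elastic energy (kT) of one step deformed to ``q``."""
    i = params.step_index(step_type)
    dq = np.asarray(q, dtype=float).reshape(6) - params.q0[i]
    return 0.5 * float(dq @ params.Q[i] @ dq)


def chain_energy(seq: str, steps: np.ndarray, params: StepParamSet) -> float:
    """Total elastic energy of a chain: sum of step energies.

    ``steps`` is an (N-1, 6) array of step parameters for an N-base sequence.
    The energy is local: base i only enters steps i-1 and i.
    """
    s = validate_sequence(seq)
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    if steps.shape != (len(s) - 1, 6):
        raise ValueError(
            f"need {len(s) - 1} steps of 6 parameters for a {len(s)}-base "
            f"sequence, got array of shape {steps.shape}"
        )
    idx = np.array([params.step_index(s[i : i + 2]) for i in range(len(s) - 1)])
    dq = steps - params.q0[idx]
    return 0.5 * float(np.einsum("ij,ijk,ik->", dq, params.Q[idx], dq))
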