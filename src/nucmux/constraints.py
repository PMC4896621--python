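"""Nucleosome constraints: 28 fixed mid-step frames forming 14 binding sites.

The 147-bp nucleosomal DNA is forced onto a left-handed superhelix by rigidly
fixing the mid-step frames of selected base-pair steps.  Each binding site
consists of two fixed midframes a few steps apart, one on either side of the
minor groove, mimicking the pair of octamer-bound phosphates; the minor
groove faces the histone core at the site centres.

Coordinates are dyad-centred: base pair 0 sits at the dyad, bp indices run
0..146 along the chain and dyad offsets -73..+73.  Step ``i`` connects bp
``i`` and ``i+1``; its mid-step frame sits at dyad offset ``i - 72.5`` for
the canonical 147-bp chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .mechanics import (
    Frame,
    StepParamSet,
    frames_from_midstep,
    frames_to_step,
    validate_sequence,
)

__all__ = [
    "ConstraintSet",
    "NucleosomeState",
    "default_constraints",
    "ideal_superhelix_constraints",
    "initial_state",
    "load_constraints",
    "save_constraints",
]

#: Nucleosome superhelix defaults (Angstrom): radius and pitch of the
#: left-handed path, 1.75 turns, 14 two-phosphate binding sites spaced by
#: one helical repeat.
SUPERHELIX_RADIUS = 41.9
SUPERHELIX_PITCH = 25.4
HELICAL_REPEAT = 10.3


class ConstraintValidationError(ValueError):
    pass


@dataclass
class ConstraintSet:
    """Fixed mid-step frames grouped into binding sites (two frames each)."""

    step_indices: np.ndarray      # (n,) 0-based step indices, strictly increasing
    frames: list                  # n target Frames
    site_ids: np.ndarray          # (n,) site assignment, 0-based
    chain_length: int = 147

    def __post_init__(self) -> None:
        self.step_indices = np.asarray(self.step_indices, dtype=int)
        self.site_ids = np.asarray(self.site_ids, dtype=int)
        self.validate()

    def validate(self) -> None:
        n = len(self.step_indices)
        if not (len(self.frames) == n and len(self.site_ids) == n):
            raise ConstraintValidationError("step_indices, frames, site_ids length mismatch")
        if n == 0:
            raise ConstraintValidationError("constraint set is empty")
        if np.any(np.diff(self.step_indices) <= 0):
            raise ConstraintValidationError("constraint step indices must be strictly increasing")
        if self.step_indices[0] < 0 or self.step_indices[-1] > self.chain_length - 2:
            raise ConstraintValidationError(
                f"constraint step indices must lie in [0, {self.chain_length - 2}]"
            )
        sites, counts = np.unique(self.site_ids, return_counts=True)
        if np.any(counts != 2):
            raise ConstraintValidationError(
                "every binding site must contain exactly two constrained midframes"
            )
        for f in self.frames:
            if not isinstance(f, Frame):
                raise ConstraintValidationError("constraint targets must be Frames")

    @property
    def n_sites(self) -> int:
        return len(np.unique(self.site_ids))

    def validate_nucleosome(self) -> None:
        """Enforce the canonical 28-constraint / 14-site nucleosome structure."""
        if self.chain_length != 147:
            raise ConstraintValidationError("nucleosome constraint set must span 147 bp")
        if len(self.step_indices) != 28 or self.n_sites != 14:
            raise ConstraintValidationError(
                f"nucleosome constraint set needs 28 constraints in 14 sites, "
                f"got {len(self.step_indices)} in {self.n_sites}"
            )

    def step_offsets(self) -> np.ndarray:
        """Dyad offsets of the constrained mid-step frames."""
        return self.step_indices - (self.chain_length - 2) / 2.0

    def site_centers(self) -> np.ndarray:
        """Per-site mean dyad offset of its two constrained steps.

        These are the positions where the minor groove faces the histone
        core (the bound-phosphate pairs straddle the inward-facing minor
        groove), i.e. where AA/TT/TA steps are expected to peak.
        """
        off = self.step_offsets()
        return np.array(
            [off[self.site_ids == s].mean() for s in np.unique(self.site_ids)]
        )

    # alias with the domain name used by the positioning-rule analyses
    minor_groove_inward_offsets = site_centers


# ---------------------------------------------------------------------------
# Ideal superhelix generator
# ---------------------------------------------------------------------------

def _superhelix_frame(m, span_steps, turns, radius, pitch, phase_anchor,
                      helical_repeat) -> Frame:
    """Frame at fractional step offset ``m`` on the ideal left-handed path."""
    theta = 2.0 * np.pi * turns * m / span_steps
    dtheta = 2.0 * np.pi * turns / span_steps
    origin = np.array(
        [radius * np.cos(theta), -radius * np.sin(theta), pitch * theta / (2 * np.pi)]
    )
    tangent = np.array(
        [-radius * np.sin(theta) * dtheta,
         -radius * np.cos(theta) * dtheta,
         pitch * dtheta / (2 * np.pi)]
    )
    e3 = tangent / np.linalg.norm(tangent)
    radial = np.array([np.cos(theta), -np.sin(theta), 0.0])
    a = radial - (radial @ e3) * e3
    a /= np.linalg.norm(a)
    b = np.cross(e3, a)
    phi = 2.0 * np.pi * (m - phase_anchor) / helical_repeat
    x = np.cos(phi) * a + np.sin(phi) * b
    y = np.cross(e3, x)
    return Frame(origin, np.column_stack([x, y, e3]))


def ideal_superhelix_constraints(
    radius: float = SUPERHELIX_RADIUS,
    pitch: float = SUPERHELIX_PITCH,
    turns: float = 1.75,
    n_sites: int = 14,
    chain_length: int = 147,
    helical_repeat: float = HELICAL_REPEAT,
) -> ConstraintSet:
    """Constraint set on an ideal left-handed superhelix.

    ``n_sites`` binding sites are spaced one helical repeat apart, centred on
    the dyad; each contributes two fixed midframes three steps apart,
    straddling the inward-facing minor groove.  The path winds ``turns``
    superhelical turns between the outermost constrained steps, and the local
    twist phase is anchored so that the base-pair x-axis (major-groove
    direction) points radially outward at every site centre, i.e. the minor
    groove faces the superhelix axis there.
    """
    if turns <= 0:
        raise ValueError("turns must be positive")
    if n_sites < 2:
        raise ValueError("need at least 2 binding sites")
    if radius <= 0 or pitch < 0:
        raise ValueError("non-physical superhelix dimensions")
    centers = (np.arange(n_sites) - (n_sites - 1) / 2.0) * helical_repeat
    half = (chain_length - 2) / 2.0
    step_indices, site_ids = [], []
    for j, c in enumerate(centers):
        for d in (-1.5, 1.5):
            i = int(round(c + d + half))
            if not (0 <= i <= chain_length - 2):
                raise ValueError(
                    f"binding site at offset {c:+.2f} falls outside a "
                    f"{chain_length}-bp chain"
                )
            step_indices.append(i)
            site_ids.append(j)
    step_indices = np.array(step_indices)
    site_ids = np.array(site_ids)
    order = np.argsort(step_indices)
    step_indices, site_ids = step_indices[order], site_ids[order]
    offsets = step_indices - half
    span = offsets[-1] - offsets[0]
    frames = [
        _superhelix_frame(m, span, turns, radius, pitch, centers[0], helical_repeat)
        for m in offsets
    ]
    return ConstraintSet(step_indices, frames, site_ids, chain_length)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_FRAME_COLS = ["ox", "oy", "oz"] + [f"r{i}{j}" for i in range(3) for j in range(3)]


def save_constraints(cset: ConstraintSet, path) -> None:
    rows = []
    for i, f, s in zip(cset.step_indices, cset.frames, cset.site_ids):
        rows.append(
            {"step_index": i, "site_id": s,
             **dict(zip(_FRAME_COLS, np.concatenate([f.origin, f.R.ravel()])))}
        )
    with open(path, "w") as fh:
        fh.write(f"# nucmux constraint set, chain_length={cset.chain_length}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def load_constraints(path, require_nucleosome: bool = True) -> ConstraintSet:
    """Load and validate a constraint-set TSV.

    With ``require_nucleosome`` (default) the canonical 28-constraint /
    14-site structure is enforced in addition to the generic schema.
    """
    chain_length = 147
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "chain_length=" in first:
        chain_length = int(first.strip().split("chain_length=")[1])
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise ConstraintValidationError(f"constraint file {path} is empty") from None
    missing = {"step_index", "site_id", *_FRAME_COLS} - set(df.columns)
    if missing:
        raise ConstraintValidationError(f"constraint file missing columns {sorted(missing)}")
    if df.empty:
        raise ConstraintValidationError(f"constraint file {path} has no records")
    frames = []
    for _, row in df.iterrows():
        vals = row[_FRAME_COLS].to_numpy(dtype=float)
        try:
            frames.append(Frame(vals[:3], vals[3:].reshape(3, 3)))
        except ValueError as e:
            raise ConstraintValidationError(
                f"malformed frame at step_index {int(row['step_index'])}: {e}"
            ) from None
    cset = ConstraintSet(
        df["step_index"].to_numpy(dtype=int), frames,
        df["site_id"].to_numpy(dtype=int), chain_length,
    )
    if require_nucleosome:
        cset.validate_nucleosome()
    return cset


def default_constraints() -> ConstraintSet:
    """The packaged nucleosome constraint fixture (28 midframes, 14 sites).

    A synthetic stand-in on an ideal left-handed superhelix with the
    nucleosome's dimensions; see the packaged TSV header for provenance.
    """
    import importlib.resources

    ref = importlib.resources.files("nucmux.data") / "nucleosome_constraints_synthetic.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_constraints(p)


# ---------------------------------------------------------------------------
# Initial state
# ---------------------------------------------------------------------------

@dataclass
class NucleosomeState:
    """A sequence threaded onto the constrained superhelix.

    ``frames_R``/``frames_o`` hold the lab orientation and origin of every
    base pair; ``steps`` caches the 146 step-parameter vectors.  All
    constrained midframes coincide with their targets (hard constraints).
    """

    seq: str
    frames_R: np.ndarray   # (N, 3, 3)
    frames_o: np.ndarray   # (N, 3)
    steps: np.ndarray      # (N-1, 6)
    constraints: ConstraintSet

    def energy(self, params: StepParamSet) -> float:
        from .mechanics import chain_energy

        return chain_energy(self.seq, self.steps, params)

    def constraint_residuals(self) -> tuple[float, float]:
        """(max position error [A], max orientation error [Frobenius])."""
        pos_err = rot_err = 0.0
        from .mechanics import midframe as _midframe

        for i, target in zip(self.constraints.step_indices, self.constraints.frames):
            mid = _midframe(
                Frame(self.frames_o[i], self.frames_R[i]),
                Frame(self.frames_o[i + 1], self.frames_R[i + 1]),
            )
            pos_err = max(pos_err, float(np.abs(mid.origin - target.origin).max()))
            rot_err = max(rot_err, float(np.abs(mid.R - target.R).max()))
        return pos_err, rot_err


def _step_transform(q: np.ndarray) -> np.ndarray:
    """Homogeneous 4x4 transform of one step in the mid-step convention."""
    t, phi = q[:3], np.deg2rad(q[3:])
    T = np.eye(4)
    T[:3, :3] = Rotation.from_rotvec(phi).as_matrix()
    T[:3, 3] = Rotation.from_rotvec(phi / 2.0).as_matrix() @ t
    return T


def _hom(frame: Frame) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = frame.R
    T[:3, 3] = frame.origin
    return T


def initial_state(seq: str, constraints: ConstraintSet,
                  params: StepParamSet | None = None) -> NucleosomeState:
    """Thread a sequence onto the constraints with a smooth starting geometry.

    Base pairs flanking each constrained step are placed symmetrically about
    the target midframe with a nominal B-DNA internal step; the gaps between
    consecutive anchors are filled by geodesic interpolation of the
    twist-detrended frames, and the ends are extended with nominal steps.
    The constrained midframes are satisfied exactly by construction.
    """
    s = validate_sequence(seq)
    N = constraints.chain_length
    if len(s) != N:
        raise ValueError(f"sequence length {len(s)} != constrained chain length {N}")
    if params is not None:
        q_nom = params.mean_intrinsic()
    else:
        q_nom = np.array([0.0, 0.0, 3.35, 0.0, 1.5, 34.0])
    S = _step_transform(q_nom)
    S_inv = np.linalg.inv(S)

    known: dict[int, np.ndarray] = {}
    for i, target in zip(constraints.step_indices, constraints.frames):
        f_i, f_j = frames_from_midstep(target, q_nom)
        known[i] = _hom(f_i)
        known[i + 1] = _hom(f_j)

    # powers of the nominal step for detrending
    pow_S = [np.eye(4)]
    for _ in range(N):
        pow_S.append(pow_S[-1] @ S)

    frames = [None] * N
    for p, T in known.items():
        frames[p] = T
    anchor_ps = sorted(known)
    for pa, pb in zip(anchor_ps[:-1], anchor_ps[1:]):
        if pb - pa <= 1:
            continue
        Ha = known[pa] @ np.linalg.matrix_power(S_inv, pa)
        Hb = known[pb] @ np.linalg.matrix_power(S_inv, pb)
        Rrel = Rotation.from_matrix(Ha[:3, :3].T @ Hb[:3, :3])
        rv = Rrel.as_rotvec()
        for p in range(pa + 1, pb):
            f = (p - pa) / (pb - pa)
            H = np.eye(4)
            H[:3, :3] = Ha[:3, :3] @ Rotation.from_rotvec(f * rv).as_matrix()
            H[:3, 3] = (1 - f) * Ha[:3, 3] + f * Hb[:3, 3]
            frames[p] = H @ pow_S[p]
    for p in range(anchor_ps[0] - 1, -1, -1):
        frames[p] = frames[p + 1] @ S_inv
    for p in range(anchor_ps[-1] + 1, N):
        frames[p] = frames[p - 1] @ S

    frames_R = np.stack([T[:3, :3] for T in frames])
    frames_o = np.stack([T[:3, 3] for T in frames])
    steps = np.empty((N - 1, 6))
    for i in range(N - 1):
        try:
            steps[i] = frames_to_step(
                Frame(frames_o[i], frames_R[i]), Frame(frames_o[i + 1], frames_R[i + 1])
            )
        except ValueError as e:
            raise ValueError(
                f"constraints unsatisfiable: interpolation produced a degenerate "
                f"step at index {i} ({e})"
            ) from None
    return NucleosomeState(s, frames_R, frames_o, steps, constraints)
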