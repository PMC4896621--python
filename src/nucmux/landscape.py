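"""Elastic energy landscapes along long sequences and excluded volume.

The elastic landscape is the mean low-temperature nucleosome energy as a
function of dyad position along a sequence (spatial moves only; the sequence
is fixed at each position).  The excluded-volume analysis places hard rods
of one nucleosome footprint on that landscape at a chemical potential mu and
computes the exact equilibrium occupancy by the two-pass transfer (Tonks
gas / Vanderlick) recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constraints import ConstraintSet, initial_state
from .mc import MCConfig, _run
from .mechanics import StepParamSet, validate_sequence

__all__ = [
    "EnergyLandscape",
    "OccupancyResult",
    "effective_landscape",
    "elastic_landscape",
    "find_local_minima",
    "formation_energy_delta",
    "map_distance_histogram",
    "tonks_density",
]

FOOTPRINT = 147


@dataclass
class EnergyLandscape:
    """Mean elastic energy (kT) per dyad position (1-based along the input)."""

    positions: np.ndarray
    E: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.E = np.asarray(self.E, dtype=float)
        if not np.all(np.isfinite(self.E)):
            raise ValueError("landscape energies must be finite")


@dataclass
class OccupancyResult:
    """Occupancy (dyad-start probability) and effective energy per position."""

    positions: np.ndarray
    mu: float
    occupancy: np.ndarray
    effective_energy: np.ndarray


def _position_energy(window_seq: str, constraints: ConstraintSet,
                     params: StepParamSet, T_low_K: float, sweeps: int,
                     seed: int, anneal_from_K: float = 300.0,
                     rec_window=None) -> float:
    """Mean energy over the second half of a spatial-only run at T_low_K.

    Burn-in anneals the temperature from ``anneal_from_K`` down to the
    target in a few stages to avoid trapping in the stiff constrained chain.
    """
    state = initial_state(window_seq, constraints, params)
    rng = np.random.default_rng(seed)
    n_anneal = max(1, sweeps // 4)
    temps = np.geomspace(anneal_from_K, T_low_K, 4)
    sig_t, sig_r = 0.12, 2.0
    for T in temps:
        cfg = MCConfig(temperature_K=float(T), n_sweeps=n_anneal // 2 or 1,
                       seed=int(rng.integers(2**31)), move_mix=(1.0, 0.0),
                       sigma_trans=sig_t, sigma_rot=sig_r,
                       record_every=10**9, burn_in_fraction=1.0)
        _, state, info = _run(state, params, cfg)
        sig_t, sig_r = info["sigma_trans"], info["sigma_rot"]
    cfg = MCConfig(temperature_K=T_low_K, n_sweeps=sweeps,
                   seed=int(rng.integers(2**31)), move_mix=(1.0, 0.0),
                   sigma_trans=sig_t, sigma_rot=sig_r,
                   record_every=1, burn_in_fraction=0.5, autotune=False)
    ens, state, _ = _run(state, params, cfg, rec_window=rec_window)
    return float(ens.energies.mean())


def elastic_landscape(long_seq: str, constraints: ConstraintSet,
                      params: StepParamSet, T_low_K: float = 50.0,
                      sweeps: int = 2000, seed: int = 0,
                      positions=None) -> EnergyLandscape:
    """Elastic energy vs dyad position (1-based) along ``long_seq``.

    Valid dyad positions are 74..L-73; ``positions`` restricts the scan.
    Positions are sampled independently with per-position seeds derived from
    (seed, position).
    """
    s = validate_sequence(long_seq)
    L = len(s)
    if L < FOOTPRINT:
        raise ValueError(f"sequence of length {L} is shorter than one footprint")
    half = FOOTPRINT // 2
    valid = np.arange(half + 1, L - half + 1)
    if positions is None:
        positions = valid
    else:
        positions = np.asarray(positions, dtype=int)
        if np.any(positions < valid[0]) or np.any(positions > valid[-1]):
            raise ValueError(f"dyad positions must lie in [{valid[0]}, {valid[-1]}]")
    E = np.empty(len(positions))
    for k, pos in enumerate(positions):
        window = s[pos - half - 1 : pos + half]
        sub_seed = int(np.random.SeedSequence((seed, int(pos))).generate_state(1)[0] % 2**31)
        E[k] = _position_energy(window, constraints, params, T_low_K, sweeps, sub_seed)
    return EnergyLandscape(positions, E,
                           meta={"T": T_low_K, "sweeps": sweeps, "seed": seed})


def find_local_minima(landscape) -> np.ndarray:
    """Interior local minima positions; plateaus report their leftmost point."""
    if isinstance(landscape, EnergyLandscape):
        pos, E = landscape.positions, landscape.E
    else:
        E = np.asarray(landscape, dtype=float)
        pos = np.arange(len(E))
    if len(E) < 3:
        raise ValueError("landscape must have at least 3 positions")
    minima = []
    i = 1
    while i < len(E) - 1:
        if E[i] < E[i - 1]:
            j = i
            while j + 1 < len(E) and E[j + 1] == E[i]:
                j += 1
            if j < len(E) - 1 and E[j + 1] > E[i]:
                minima.append(pos[i])
            i = j + 1
        else:
            i += 1
    return np.asarray(minima, dtype=int)


# ---------------------------------------------------------------------------
# Excluded volume (hard rods on the landscape)
# ---------------------------------------------------------------------------

def effective_landscape(landscape, mu: float, footprint: int = FOOTPRINT) -> OccupancyResult:
    """Exact hard-rod occupancy on an energy landscape at chemical potential mu.

    Rods of length ``footprint`` occupy ``footprint`` consecutive dyad-lattice
    sites; a rod sitting at position ``s`` has statistical weight
    ``exp(mu - E(s))`` (energies and mu in kT).  The two-pass transfer
    recursion gives the exact equilibrium probability n(s) that a rod sits at
    s.  The effective energy is ``-ln n(s) + const`` with the constant fixed
    so its global minimum coincides with the elastic landscape's.
    """
    if isinstance(landscape, EnergyLandscape):
        pos, E = landscape.positions, landscape.E
    else:
        E = np.asarray(landscape, dtype=float)
        pos = np.arange(1, len(E) + 1)
    if not np.all(np.isfinite(E)) or not np.isfinite(mu):
        raise ValueError("landscape energies and mu must be finite")
    M = len(E)
    a = int(footprint)
    logw = mu - E
    # forward: Zf[p] over configurations of rods starting in 1..p
    # backward: Zb[p] over rods starting in p..M  (log space)
    logZf = np.zeros(M + 1)
    for p in range(1, M + 1):
        prev = logZf[max(p - a, 0)]
        logZf[p] = np.logaddexp(logZf[p - 1], logw[p - 1] + prev)
    logZb = np.zeros(M + 2)
    for p in range(M, 0, -1):
        nxt = logZb[min(p + a, M + 1)]
        logZb[p] = np.logaddexp(logZb[p + 1], logw[p - 1] + nxt)
    logZ = logZf[M]
    logn = logw + logZf[np.maximum(np.arange(M) + 1 - a, 0)] \
        + logZb[np.minimum(np.arange(M) + 1 + a, M + 1)] - logZ
    n = np.exp(logn)
    with np.errstate(divide="ignore"):
        eff = -logn
    shift = E.min() - eff.min()
    return OccupancyResult(pos, mu, n, eff + shift)


def tonks_density(mu: float, footprint: int = FOOTPRINT) -> float:
    """Bulk rod-start density of the lattice Tonks gas at chemical potential mu.

    Closed form via the exact free energy of hard ``a``-mers on an infinite
    1D lattice: mu = ln[ rho (1-(a-1)rho)^(a-1) / (1-a rho)^a ].
    """
    a = int(footprint)

    def f(rho):
        return (np.log(rho) + (a - 1) * np.log1p(-(a - 1) * rho)
                - a * np.log1p(-a * rho) - mu)

    eps = 1e-15
    return float(brentq(f, eps, 1.0 / a - eps, xtol=1e-15, rtol=8.9e-16))


def map_distance_histogram(minima, dyad_positions, max_dist: int = 20):
    """Distance from each mapped dyad to the nearest landscape minimum.

    Returns (distances clipped at ``max_dist``, histogram over 0..max_dist,
    fraction within +-1 bp).
    """
    minima = np.asarray(minima, dtype=int)
    dyads = np.asarray(dyad_positions, dtype=int)
    if minima.size == 0 or dyads.size == 0:
        raise ValueError("minima and dyad map must be nonempty")
    d = np.min(np.abs(dyads[:, None] - minima[None, :]), axis=1)
    d = np.minimum(d, max_dist)
    hist = np.bincount(d, minlength=max_dist + 1)
    frac_1bp = float(np.mean(d <= 1))
    return d, hist, frac_1bp


def formation_energy_delta(seqA: str, seqB: str, constraints: ConstraintSet,
                           params: StepParamSet, T_low_K: float = 50.0,
                           sweeps: int = 2000, seed: int = 0,
                           site_subset=None) -> float:
    """Difference of mean low-temperature energies of two 147-bp sequences.

    ``site_subset`` (an iterable of site ids) restricts the energy sum to
    the steps spanned by a contiguous subset of binding sites, a proxy for
    sub-nucleosomal (e.g. tetramer-bound) formation energies.
    """
    rec_window = None
    if site_subset is not None:
        ids = np.asarray(sorted(site_subset))
        if np.any(np.diff(ids) != 1):
            raise ValueError("site_subset must be contiguous")
        sel = np.isin(constraints.site_ids, ids)
        steps = constraints.step_indices[sel]
        rec_window = (int(steps.min()), int(steps.max()))
    out = []
    for which, seq in enumerate((seqA, seqB)):
        s = validate_sequence(seq)
        if len(s) != constraints.chain_length:
            raise ValueError(
                f"sequence {'AB'[which]} has length {len(s)}, "
                f"expected {constraints.chain_length}"
            )
        sub_seed = int(np.random.SeedSequence((seed, which)).generate_state(1)[0] % 2**31)
        out.append(_position_energy(s, constraints, params, T_low_K, sweeps,
                                    sub_seed, rec_window=rec_window))
    return out[0] - out[1]
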