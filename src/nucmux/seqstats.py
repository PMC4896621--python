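"""Position-resolved dinucleotide statistics over sequence ensembles.

Profiles are indexed by the step's left base pair in dyad coordinates
(-73..+72 for the 147-bp nucleosome), so groove-bending site positions can
be compared directly with the constraint geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .mechanics import DINUCLEOTIDES

__all__ = [
    "MOTIF_GROUPS",
    "OccurrenceProfile",
    "dinucleotide_profile",
    "periodicity_summary",
    "plot_profiles",
    "profile_peaks",
    "tetranucleotide_profile",
]

#: Named motif groups used in the positioning-rule readouts.
MOTIF_GROUPS = {
    "GC": {"GC"},
    "AA/TT/TA": {"AA", "TT", "TA"},
    "AA/AT/TA/TT": {"AA", "AT", "TA", "TT"},
    "CC/CG/GC/GG": {"CC", "CG", "GC", "GG"},
}


@dataclass
class OccurrenceProfile:
    """Per-position frequency of a motif class along the nucleosome frame."""

    motifs: frozenset
    positions: np.ndarray   # dyad coordinate of the step's left bp
    freq: np.ndarray        # in [0, 1]
    n_samples: int
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.freq = np.asarray(self.freq, dtype=float)
        if np.any(self.freq < -1e-12) or np.any(self.freq > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")


def _step_codes(seqs: np.ndarray) -> np.ndarray:
    return 4 * seqs[:, :-1].astype(np.int64) + seqs[:, 1:]


def dinucleotide_profile(ensemble, motifs) -> OccurrenceProfile:
    """Fraction of ensemble sequences whose step at each position is in
    ``motifs``; a group's frequency is the sum of its members'."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    motifs = frozenset(m.upper() for m in motifs)
    unknown = motifs - set(DINUCLEOTIDES)
    if unknown:
        raise ValueError(f"unknown dinucleotides: {sorted(unknown)}")
    codes = _step_codes(ensemble.seqs)
    wanted = np.zeros(16, dtype=bool)
    for m in motifs:
        wanted[DINUCLEOTIDES.index(m)] = True
    freq = wanted[codes].mean(axis=0)
    n_steps = codes.shape[1]
    positions = np.arange(n_steps) - n_steps // 2
    return OccurrenceProfile(motifs, positions, freq, len(ensemble),
                             label="/".join(sorted(motifs)))


def tetranucleotide_profile(ensemble, tetramer: str) -> OccurrenceProfile:
    """Per-position occurrence frequency of one 4-mer (e.g. TTAA, AGCT)."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    t = tetramer.upper()
    if len(t) != 4:
        raise ValueError("tetramer must have length 4")
    from .mechanics import encode_sequence

    target = encode_sequence(t)
    seqs = ensemble.seqs
    n_pos = seqs.shape[1] - 3
    hits = np.ones((seqs.shape[0], n_pos), dtype=bool)
    for k in range(4):
        hits &= seqs[:, k : k + n_pos] == target[k]
    freq = hits.mean(axis=0)
    positions = np.arange(n_pos) - seqs.shape[1] // 2
    return OccurrenceProfile(frozenset([t]), positions, freq, len(ensemble), label=t)


def _amplitude_at(x: np.ndarray, pos: np.ndarray, period: float) -> complex:
    """Complex amplitude of the mean-subtracted profile at a trial period,
    phase referenced to the dyad (position 0)."""
    y = x - x.mean()
    return 2.0 / len(y) * np.sum(y * np.exp(-2j * np.pi * pos / period))


def periodicity_summary(profile: OccurrenceProfile) -> tuple[float, float, float]:
    """(dominant_period, amplitude, phase) of a profile.

    The dominant DFT bin (excluding the mean) seeds a continuous-period
    refinement; the returned amplitude is that of the best-fit cosine
    ``a * cos(2*pi*s/p - phase)`` with ``s`` the dyad coordinate, so the
    phase is relative to the dyad.  A constant profile returns amplitude 0.
    """
    y = profile.freq - profile.freq.mean()
    n = len(y)
    if n < 20:
        raise ValueError("profile too short for a periodicity summary")
    if np.allclose(y, 0):
        return np.inf, 0.0, 0.0
    spec = np.abs(np.fft.rfft(y))
    k = int(np.argmax(spec[1:]) + 1)
    lo = n / min(k + 1.5, n // 2)
    hi = n / max(k - 1.5, 0.5)
    res = minimize_scalar(
        lambda p: -np.abs(_amplitude_at(profile.freq, profile.positions, p)),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    period = float(res.x)
    amp_c = _amplitude_at(profile.freq, profile.positions, period)
    # c = a * exp(-i*phase) for x = a cos(2 pi s / p - phase)
    return period, float(np.abs(amp_c)), float(-np.angle(amp_c))


def plot_profiles(profiles, site_offsets=None, ax=None):
    """Plot occurrence profiles along the nucleosome with groove-site guides.

    ``site_offsets`` (e.g. ``ConstraintSet.site_centers()``) are drawn as
    solid vertical lines (minor-groove-inward sites); midpoints between them
    as dashed lines (major-groove sites).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for prof in profiles:
        ax.plot(prof.positions, prof.freq, label=prof.label)
    if site_offsets is not None:
        site_offsets = np.asarray(site_offsets, dtype=float)
        for s in site_offsets:
            ax.axvline(s, color="0.6", lw=0.6)
        for m in (site_offsets[:-1] + site_offsets[1:]) / 2:
            ax.axvline(m, color="0.8", lw=0.6, ls="--")
    ax.set_xlabel("position relative to dyad (bp)")
    ax.set_ylabel("fraction")
    ax.legend(frameon=False)
    return ax


def profile_peaks(profile: OccurrenceProfile, smooth: int = 1) -> np.ndarray:
    """Dyad coordinates of local maxima of a (lightly smoothed) profile."""
    y = profile.freq
    if smooth > 0:
        kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
        y = np.convolve(y, kernel, mode="same")
    idx = [
        i for i in range(1, len(y) - 1)
        if y[i] > y[i - 1] and y[i] >= y[i + 1]
    ]
    return profile.positions[idx]
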