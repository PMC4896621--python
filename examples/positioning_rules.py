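"""Recover the nucleosome positioning rules by Mutation Monte Carlo.

Samples high-affinity 147-bp sequences on the constrained superhelix at an
effective temperature of 100 K and reads off the dinucleotide occurrence
profiles: AA/TT/TA steps should peak where the minor groove faces the
histone core (the binding-site centres), GC in anti-phase, both with the
~10-bp helical repeat.
"""

import numpy as np

from nucmux import (
    MCConfig, default_constraints, dinucleotide_profile, load_step_params,
    periodicity_summary, profile_peaks, run_mmc,
)

params = load_step_params()
constraints = default_constraints()

rng = np.random.default_rng(0)
seq0 = "".join("ACGT"[i] for i in rng.integers(0, 4, 147))
cfg = MCConfig(temperature_K=100.0, n_sweeps=30_000, seed=1, record_every=1,
               burn_in_fraction=0.15)
ensemble = run_mmc(seq0, constraints, cfg, params)
print(f"recorded {len(ensemble)} sequences, mean energy "
      f"{ensemble.energies.mean():.1f} kT")

for motifs in ({"AA", "TT", "TA"}, {"GC"}):
    prof = dinucleotide_profile(ensemble, motifs)
    period, amp, phase = periodicity_summary(prof)
    print(f"{prof.label:>9s}: period {period:.2f} bp, amplitude {amp:.3f}, "
          f"crest at {phase * period / (2 * np.pi):+.1f} bp from the dyad")

aa_peaks = profile_peaks(dinucleotide_profile(ensemble, {"AA", "TT", "TA"}))
centers = constraints.site_centers()
print("minor-groove-inward site centres:", centers)
print("AA/TT/TA peak positions:         ", aa_peaks)
# Each site centre should have an AA/TT/TA peak within ~1 bp: the sequence
# ensemble has learned where the superhelix bends into the minor groove.
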