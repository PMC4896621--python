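"""Positioning signals on top of genes: synonymous Mutation Monte Carlo.

Runs sMMC (mutation moves restricted to synonymous codon swaps, so the
encoded protein never changes) on many random coding sequences and compares
the averaged AA/TT/TA profile with the unconstrained MMC one: the same
periodic signal appears, but with a smaller amplitude — the genetic code
only leaves part of the sequence freedom to the mechanical signal.
"""

import numpy as np

from nucmux import (
    MCConfig, SequenceEnsemble, default_constraints, dinucleotide_profile,
    load_step_params, periodicity_summary, random_coding_sequence, run_mmc,
    run_smmc,
)

params = load_step_params()
constraints = default_constraints()
motifs = {"AA", "TT", "TA"}

cfg = MCConfig(temperature_K=100.0, n_sweeps=20_000, seed=1, record_every=1,
               burn_in_fraction=0.15)
rng = np.random.default_rng(0)
seq0 = "".join("ACGT"[i] for i in rng.integers(0, 4, 147))
mmc_prof = dinucleotide_profile(run_mmc(seq0, constraints, cfg, params), motifs)

n_genes = 30
chunks = []
for g in range(n_genes):
    gene = random_coding_sequence(49, seed=1000 + g)
    cfg_g = MCConfig(temperature_K=100.0, n_sweeps=2_000, seed=g,
                     record_every=2, burn_in_fraction=0.2)
    chunks.append(run_smmc(gene, 0, constraints, cfg_g, params).seqs)
smmc_ens = SequenceEnsemble(np.concatenate(chunks), np.zeros(sum(map(len, chunks))))
smmc_prof = dinucleotide_profile(smmc_ens, motifs)

for name, prof in (("MMC", mmc_prof), ("sMMC", smmc_prof)):
    period, amp, phase = periodicity_summary(prof)
    print(f"{name:>5s}: period {period:.2f} bp, 10-bp amplitude {amp:.3f}")
# The sMMC amplitude is strictly smaller: synonymous freedom suffices to
# write the rotational signal, but with reduced contrast.
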