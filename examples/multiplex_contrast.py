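"""The multiplexing signature on a synthetic genome.

Builds a toy genome whose intergenic background carries a 10-bp periodic
base composition, plants rotationally phased nucleosome dyads outside genes
(and phase-free ones inside), then runs the nucleosome/amino-acid
correlation analysis: per amino acid, the normalized 10-bp Fourier
amplitude of its positional distribution inside vs outside genes.  Points
below the diagonal (coding < non-coding) are the multiplexing hallmark.
"""

from nucmux import (
    ToyGenomeSpec, coding_noncoding_contrast, filter_map, planted_phased_map,
    toy_genome,
)

spec = ToyGenomeSpec(n_chrom=2, chrom_length=60_000,
                     intergenic_phase_strength=0.6, seed=42)
genome, genes = toy_genome(spec)
print(f"toy genome: {sum(map(len, genome.values()))} bp, {len(genes)} genes")

dyad_map = planted_phased_map(genome, genes, phased_regions="noncoding",
                              frac_subthreshold=0.4, seed=7)
kept = filter_map(dyad_map, min_snr=1.5)
print(f"dyad map: {len(dyad_map)} records, {len(kept)} pass the 1.5 SNR filter")

result = coding_noncoding_contrast(genome, genes, kept)
print(result.table.round(3))
print(f"{result.n_below_diagonal}/20 amino acids below the diagonal")
# With phasing planted only outside genes, nearly all amino acids show a
# weaker 10-bp amplitude inside genes — the planted ground truth recovered.
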