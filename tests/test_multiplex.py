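"""Codon/trinucleotide positioning along nucleosomes and the A10 contrast."""

import numpy as np
import pandas as pd
import pytest

from nucmux.genetic_code import AMINO_ACIDS, aa_of_codon, codon_code
from nucmux.io import DyadMap, Gene, filter_map
from nucmux.mechanics import reverse_complement
from nucmux.multiplex import (
    A10_INDEX,
    coding_noncoding_contrast,
    codon_position_profile,
    fourier_amplitudes,
    lump_synonymous,
    trim_profile,
)
from nucmux.synth import ToyGenomeSpec, planted_phased_map, toy_genome


def make_map(records):
    return DyadMap(pd.DataFrame(records, columns=["chrom", "pos", "score", "noise"]))


class TestFilterMap:
    def test_threshold_is_strict(self):
        m = make_map([("c", 100, 1.4, 1.0), ("c", 200, 1.6, 1.0)])
        out = filter_map(m, 1.5)
        assert out.df["pos"].tolist() == [200]

    def test_identity_when_all_pass(self):
        m = make_map([("c", 100, 3.0, 1.0), ("c", 200, 2.0, 1.0)])
        assert len(filter_map(m, 1.5)) == 2

    def test_zero_noise_dropped_with_warning(self):
        m = make_map([("c", 100, 3.0, 0.0), ("c", 200, 2.0, 1.0)])
        with pytest.warns(UserWarning, match="noise"):
            out = filter_map(m, 1.5)
        assert len(out) == 1

    def test_planted_subthreshold_counts(self):
        recs = [("c", 100 + i, 1.0, 1.0 if i < 40 else 0.2) for i in range(100)]
        out = filter_map(make_map(recs), 1.5)
        assert len(out) == 60


class TestCountMatrix:
    def test_hand_enumerated_toy_placement(self):
        """One gene fully covered by one nucleosome: counts match a direct
        per-codon enumeration."""
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        # plant a clean ORF at 31..75 (1-based), 15 codons
        orf = "ATG" + "GCTACAGAAATT" * 3 + "TAA"
        seq = seq[:30] + orf + seq[30 + len(orf):]
        gene = Gene("g1", "chr1", "+", [(31, 30 + len(orf))])
        genome = {"chr1": seq}
        dmap = make_map([("chr1", 80, 3.0, 1.0)])
        counts = codon_position_profile(genome, [gene], dmap, coding=True)
        expected = np.zeros((64, 147), dtype=int)
        for k in range(len(orf) // 3):
            g5 = 31 + 3 * k  # 1-based genomic coord of codon first base
            off = g5 - (80 - 73)
            if 0 <= off <= 146:
                expected[codon_code(orf[3 * k : 3 * k + 3]), off] += 1
        assert np.array_equal(counts, expected)
        assert counts.sum() == len(orf) // 3

    def test_nucleosome_off_gene_contributes_nothing(self):
        seq = "ACGT" * 200
        gene = Gene("g1", "chr1", "+", [(1, 30)])
        dmap = make_map([("chr1", 500, 3.0, 1.0)])
        counts = codon_position_profile({"chr1": seq}, [gene], dmap, coding=True)
        assert counts.sum() == 0

    def test_window_edge_first_base_rule(self):
        """A codon is counted iff its first base is inside the window, even
        when the rest sticks out."""
        seq = "A" * 300
        gene = Gene("g1", "chr1", "+", [(1, 300)])
        # codon starting at genomic 220 sits at window offset 146 (the last
        # position) of the dyad-147 window; its other two bases stick out
        dmap = make_map([("chr1", 147, 3.0, 1.0)])
        counts = codon_position_profile({"chr1": seq}, [gene], dmap, coding=True)
        starts = np.flatnonzero(counts[codon_code("AAA")])
        assert starts[-1] == 146
        assert counts[codon_code("AAA"), 146] == 1

    def test_unknown_chromosomes_rejected(self):
        gene = Gene("g1", "chrX", "+", [(1, 30)])
        dmap = make_map([("chr1", 100, 3.0, 1.0)])
        with pytest.raises(ValueError, match="chrX"):
            codon_position_profile({"chr1": "A" * 300}, [gene], dmap, coding=True)

    def test_split_codon_skipped(self):
        """A codon split across an intron is not counted."""
        seq = "ATGAAATTTGGGCCCTAAA" + "A" * 281
        # CDS in two segments splitting the third spliced codon: 1..7 + 9..19
        gene = Gene("g1", "chr1", "+", [(1, 7), (9, 19)])
        dmap = make_map([("chr1", 74, 3.0, 1.0)])  # window covers bases 1..147
        counts = codon_position_profile({"chr1": seq}, [gene], dmap, coding=True)
        assert counts.sum() == 5  # 6 spliced codons, one split and skipped

    def test_strand_mirroring_leaves_profiles_unchanged(self):
        """Reverse-complementing the genome (and flipping genes and dyads)
        must not change coding profiles, nor non-coding profiles counted on
        both strands."""
        spec = ToyGenomeSpec(n_chrom=1, chrom_length=12_000, seed=5,
                             intergenic_phase_strength=0.5)
        genome, genes = toy_genome(spec)
        dmap = planted_phased_map(genome, genes, phased_regions="none", seed=3)
        L = len(genome["chr1"])
        genome_m = {"chr1": reverse_complement(genome["chr1"])}
        genes_m = [
            Gene(g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                 [(L + 1 - b, L + 1 - a) for a, b in g.cds])
            for g in genes
        ]
        dmap_m = make_map([
            ("chr1", L + 1 - int(p), 3.0, 1.0) for p in dmap.df["pos"]
        ])
        for coding, both in ((True, False), (False, True)):
            c1 = codon_position_profile(genome, genes, dmap, coding=coding,
                                        both_strands=both)
            c2 = codon_position_profile(genome_m, genes_m, dmap_m, coding=coding,
                                        both_strands=both)
            assert np.array_equal(c1, c2)


class TestLumping:
    def test_single_codon_maps_to_its_amino_acid(self):
        counts = np.zeros((64, 147), dtype=int)
        counts[codon_code("ACA")] = 2
        lumped = lump_synonymous(counts)
        assert np.array_equal(lumped.loc["T"].to_numpy(), counts[codon_code("ACA")])
        assert lumped.drop(index="T").to_numpy().sum() == 0

    def test_leucine_sums_six_codons(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 5, (64, 147))
        lumped = lump_synonymous(counts)
        leu_rows = [c for c in range(64)
                    if aa_of_codon("ACGT"[c // 16] + "ACGT"[(c // 4) % 4] + "ACGT"[c % 4]) == "L"]
        assert len(leu_rows) == 6
        assert np.array_equal(lumped.loc["L"].to_numpy(), counts[leu_rows].sum(axis=0))

    def test_total_counts_conserved_with_stop_row(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, (64, 147))
        lumped = lump_synonymous(counts)
        assert lumped.to_numpy().sum() == counts.sum()
        assert lumped.shape == (21, 147)
        assert "*" in lumped.index


class TestTrim:
    def test_all_ones_trims_to_130_ones(self):
        out = trim_profile(np.ones(147))
        assert out.shape == (130,)
        assert np.all(out == 1)

    def test_retained_indices(self):
        out = trim_profile(np.arange(147))
        expected = np.concatenate([np.arange(3, 68), np.arange(78, 143)])
        assert np.array_equal(out, expected)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            trim_profile(np.ones(140))


class TestFourier:
    def test_constant_profile_all_zero(self):
        amps = fourier_amplitudes(np.full(130, 2.5))
        assert np.abs(amps.to_numpy()).max() < 1e-12

    def test_pure_period_10_cosine_hits_index_13(self):
        x = 1.0 + 0.3 * np.cos(2 * np.pi * np.arange(130) / 10.0)
        amps = fourier_amplitudes(x)
        assert amps.idxmax() == A10_INDEX
        others = amps.drop(index=A10_INDEX)
        assert others.abs().max() < 1e-12

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 1.5, 130)
        amps = fourier_amplitudes(x)
        xn = x / x.mean()
        # one-sided amplitudes: double all but the Nyquist bin
        ss = 2 * (amps.to_numpy()[:-1] ** 2).sum() + amps.to_numpy()[-1] ** 2
        assert ss == pytest.approx(130 * xn.var(), rel=1e-10)

    def test_zero_sum_profile_rejected(self):
        with pytest.raises(ValueError):
            fourier_amplitudes(np.zeros(130))


@pytest.fixture(scope="module")
def phased_genome():
    spec = ToyGenomeSpec(n_chrom=2, chrom_length=40_000, seed=9,
                         intergenic_phase_strength=0.6)
    return toy_genome(spec)


class TestContrast:

    def test_symmetric_phasing_sits_near_the_diagonal(self, phased_genome):
        genome, genes = phased_genome
        dmap = planted_phased_map(genome, genes, phased_regions="none", seed=1)
        res = coding_noncoding_contrast(genome, genes, dmap)
        # no planted asymmetry: below-diagonal count is binomial-like
        assert 3 <= res.n_below_diagonal <= 17

    def test_planted_phasing_recovered_above_shuffled_null(self, phased_genome):
        """Planted rotational phasing lifts A10 above the 95th percentile of a
        position-shuffled null; an unphased map does not."""
        genome, genes = phased_genome
        rng = np.random.default_rng(4)

        def a10_stats(dmap):
            counts = codon_position_profile(genome, genes, dmap, coding=False)
            lumped = trim_profile(lump_synonymous(counts)).to_numpy()[:20]
            obs, null95 = [], []
            for row in lumped:
                obs.append(fourier_amplitudes(row).loc[A10_INDEX])
                null = [
                    fourier_amplitudes(rng.permutation(row)).loc[A10_INDEX]
                    for _ in range(40)
                ]
                null95.append(np.quantile(null, 0.95))
            return np.array(obs), np.array(null95)

        phased = planted_phased_map(genome, genes, phased_regions="noncoding", seed=2)
        obs, null95 = a10_stats(phased)
        assert (obs > null95).sum() >= 18
        unphased = planted_phased_map(genome, genes, phased_regions="none", seed=2)
        obs_u, null95_u = a10_stats(unphased)
        assert (obs_u > null95_u).sum() <= 6

    def test_no_nucleosomes_over_genes_names_the_failing_mode(self, phased_genome):
        genome, genes = phased_genome
        # dyads only far inside one intergenic region
        dmap = make_map([("chr1", genes[0].start - 400, 3.0, 1.0)])
        with pytest.raises(ValueError, match="coding"):
            coding_noncoding_contrast(genome, genes, dmap)

    def test_end_to_end_count_conservation(self, phased_genome):
        genome, genes = phased_genome
        dmap = planted_phased_map(genome, genes, phased_regions="none", seed=6)
        counts = codon_position_profile(genome, genes, dmap, coding=True)
        assert lump_synonymous(counts).to_numpy().sum() == counts.sum()
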