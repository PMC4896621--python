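"""Nucleosome-amino-acid correlation analysis (the multiplexing test).

Codons (in genes) or trinucleotides (outside genes) are located within every
mapped 147-bp nucleosome window, giving 64 occurrence profiles along the
nucleosome frame.  Synonymous codons are lumped into amino-acid classes
("virtual" amino acids for non-coding trinucleotides), the profiles are
trimmed to the 130 bp that are free of mapping artifacts and divisible by
the helical repeat, and the normalized Fourier amplitude of the 10-bp
periodicity (frequency index 13 of 130) is compared between coding and
non-coding nucleosomes.  Weaker 10-bp amplitudes inside genes — points below
the diagonal — are the multiplexing signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import AMINO_ACIDS, CODON_AA_INDEX
from .io import DyadMap, Gene, filter_map, read_dyad_map, read_fasta, read_gtf
from .mechanics import encode_sequence

__all__ = [
    "A10_INDEX",
    "coding_noncoding_contrast",
    "codon_position_profile",
    "filter_map",
    "fourier_amplitudes",
    "lump_synonymous",
    "trim_profile",
]

WINDOW = 147
HALF = 73
TRIMMED = 130
#: DFT frequency index of the 10-bp periodicity in a 130-bp profile
A10_INDEX = 13

#: 0-based indices retained by the trim: 3 bp off the left terminus, 4 bp off
#: the right, and the central 10 bp (spanning the dyad) removed.
_KEEP = np.concatenate([np.arange(3, 68), np.arange(78, 143)])


def _as_genome(genome) -> dict[str, str]:
    return genome if isinstance(genome, dict) else read_fasta(genome)


def _as_genes(genes) -> list[Gene]:
    return genes if isinstance(genes, list) else read_gtf(genes)


def _as_map(dmap) -> DyadMap:
    return dmap if isinstance(dmap, DyadMap) else read_dyad_map(dmap)


def _coding_code_arrays(chrom_seq: str, chrom_genes: list[Gene],
                        genome: dict[str, str]):
    """Per-position codon codes: plus[g] / minus[g] hold the 64-code of the
    codon whose 5' base sits at genomic position g (0-based), else -1."""
    L = len(chrom_seq)
    plus = np.full(L, -1, dtype=np.int16)
    minus = np.full(L, -1, dtype=np.int16)
    n_split = 0
    for gene in chrom_genes:
        if gene.cds_length() % 3:
            raise ValueError(f"gene {gene.gene_id}: CDS length not a multiple of 3")
        spliced = encode_sequence(gene.spliced_sequence(genome))
        gpos = gene.spliced_positions() - 1  # 0-based genomic coords, 5'->3'
        step = 1 if gene.strand == "+" else -1
        for k in range(0, len(spliced) - 2, 3):
            g0, g1, g2 = gpos[k], gpos[k + 1], gpos[k + 2]
            if g1 != g0 + step or g2 != g1 + step:
                n_split += 1  # codon split across an intron: skipped
                continue
            code = 16 * spliced[k] + 4 * spliced[k + 1] + spliced[k + 2]
            (plus if gene.strand == "+" else minus)[g0] = code
    return plus, minus, n_split


def _noncoding_code_arrays(chrom_seq: str, chrom_genes: list[Gene],
                           both_strands: bool):
    """Trinucleotide codes in intergenic regions (complement of gene spans).

    ``plus[g]`` holds the forward-strand trinucleotide starting at g;
    ``minus[g]`` (only with ``both_strands``) the reverse-strand
    trinucleotide whose 5' base is at g, i.e. the reverse complement of the
    forward trinucleotide ending at g.  A trinucleotide counts only if fully
    intergenic.
    """
    L = len(chrom_seq)
    genic = np.zeros(L, dtype=bool)
    for gene in chrom_genes:
        genic[gene.start - 1 : gene.end] = True
    codes = encode_sequence(chrom_seq)
    plus = np.full(L, -1, dtype=np.int16)
    minus = np.full(L, -1, dtype=np.int16)
    if L >= 3:
        tri = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
        ok = ~(genic[:-2] | genic[1:-1] | genic[2:])
        plus[: L - 2][ok] = tri[ok]
        if both_strands:
            # reverse complement: code of revcomp(b0 b1 b2) = 16*(3-b2)+4*(3-b1)+(3-b0)
            rc = 16 * (3 - codes[2:]) + 4 * (3 - codes[1:-1]) + (3 - codes[:-2])
            minus[2:][ok] = rc[ok]
    return plus, minus


def codon_position_profile(genome, genes, dmap, coding: bool,
                           both_strands: bool = False) -> np.ndarray:
    """Raw 64 x 147 count matrix of codon/trinucleotide first-base offsets
    within all mapped nucleosome windows (dyad +- 73).

    Coding mode counts in-frame codons of annotated CDS; non-coding mode
    counts trinucleotides of fully intergenic positions (forward strand by
    default).  Offsets are measured 5'->3' along the counted strand; a motif
    straddling the window edge is counted iff its first (5') base lies
    inside.
    """
    genome = _as_genome(genome)
    genes = _as_genes(genes)
    dmap = _as_map(dmap)
    bad = sorted({g.chrom for g in genes} - set(genome))
    if bad:
        raise ValueError(f"genes reference unknown chromosomes: {bad}")
    dmap.validate_against(genome)

    counts = np.zeros((64, WINDOW), dtype=np.int64)
    for chrom, seq in genome.items():
        chrom_genes = [g for g in genes if g.chrom == chrom]
        if coding:
            plus, minus, _ = _coding_code_arrays(seq, chrom_genes, genome)
        else:
            plus, minus = _noncoding_code_arrays(seq, chrom_genes, both_strands)
        L = len(seq)
        for d in dmap.positions(chrom):
            lo = max(d - 1 - HALF, 0)
            hi = min(d - 1 + HALF, L - 1)
            g = np.arange(lo, hi + 1)
            pc = plus[lo : hi + 1]
            sel = pc >= 0
            if sel.any():
                np.add.at(counts, (pc[sel], g[sel] - (d - 1 - HALF)), 1)
            mc = minus[lo : hi + 1]
            sel = mc >= 0
            if sel.any():
                np.add.at(counts, (mc[sel], (d - 1 + HALF) - g[sel]), 1)
    return counts


def lump_synonymous(counts: np.ndarray) -> pd.DataFrame:
    """Sum the 64 codon rows into 20 amino-acid classes plus a stop row '*'.

    The stop row is kept separately and excluded from the 20-amino-acid
    analyses; total counts are conserved.
    """
    counts = np.asarray(counts)
    if counts.shape[0] != 64:
        raise ValueError("expected a 64-row codon count matrix")
    out = np.zeros((21, counts.shape[1]), dtype=counts.dtype)
    for c in range(64):
        k = CODON_AA_INDEX[c]
        out[k if k >= 0 else 20] += counts[c]
    return pd.DataFrame(out, index=list(AMINO_ACIDS) + ["*"])


def trim_profile(profile):
    """Trim a length-147 profile to 130 positions.

    Removes 3 bp from the left terminus, 4 bp from the right, and the
    central 10 bp spanning the dyad (1-based window positions 69..78); the
    two retained flanks are concatenated.  Works on vectors or on the rows
    of a matrix/DataFrame.
    """
    if isinstance(profile, pd.DataFrame):
        if profile.shape[1] != WINDOW:
            raise ValueError(f"expected {WINDOW} columns, got {profile.shape[1]}")
        return profile.iloc[:, _KEEP].set_axis(range(TRIMMED), axis=1)
    arr = np.asarray(profile)
    if arr.shape[-1] != WINDOW:
        raise ValueError(f"expected length-{WINDOW} profile, got {arr.shape[-1]}")
    return arr[..., _KEEP]


def fourier_amplitudes(profile) -> pd.Series:
    """Normalized DFT amplitudes of a length-130 profile, index k = 1..65.

    The profile is divided by its mean, and amplitude k is |DFT_k|/sqrt(130)
    so that the sum of squared amplitudes over all non-zero frequencies
    equals length x variance (Parseval).  Index k corresponds to spatial
    period 130/k; the 10-bp signal is k = 13.
    """
    x = np.asarray(profile, dtype=float)
    if x.shape[-1] != TRIMMED:
        raise ValueError(f"expected length-{TRIMMED} profile, got {x.shape[-1]}")
    m = x.mean()
    if m == 0:
        raise ValueError("cannot normalize a zero-sum profile")
    xn = x / m
    F = np.fft.rfft(xn)
    amps = np.abs(F[1 : TRIMMED // 2 + 1]) / np.sqrt(TRIMMED)
    return pd.Series(amps, index=np.arange(1, TRIMMED // 2 + 1), name="amplitude")


@dataclass
class ContrastResult:
    """Per-amino-acid 10-bp amplitudes inside vs outside genes."""

    table: pd.DataFrame  # index: amino acid; columns A10_coding, A10_noncoding
    n_below_diagonal: int

    def spectra(self):
        return self.table


def coding_noncoding_contrast(genome, genes, dmap, min_snr: float | None = None,
                              both_strands: bool = False) -> ContrastResult:
    """The multiplexing contrast: per-amino-acid 10-bp amplitude inside genes
    (codons) vs outside genes (trinucleotides lumped the same way).

    Returns the 20 amplitude pairs and the number of amino acids whose
    coding amplitude is below the non-coding one (points below the
    diagonal).
    """
    genome = _as_genome(genome)
    genes = _as_genes(genes)
    dmap = _as_map(dmap)
    if min_snr is not None:
        dmap = filter_map(dmap, min_snr)
    a10 = {}
    for label, coding in (("coding", True), ("noncoding", False)):
        counts = codon_position_profile(genome, genes, dmap, coding=coding,
                                        both_strands=both_strands)
        lumped = trim_profile(lump_synonymous(counts))
        amps = np.empty(20)
        for i, aa in enumerate(AMINO_ACIDS):
            row = lumped.loc[aa].to_numpy()
            if row.sum() == 0:
                raise ValueError(
                    f"no {label} counts for amino acid {aa}; the {label} "
                    "profiles are empty or too sparse"
                )
            amps[i] = fourier_amplitudes(row).loc[A10_INDEX]
        a10[label] = amps
    table = pd.DataFrame(
        {"A10_coding": a10["coding"], "A10_noncoding": a10["noncoding"]},
        index=list(AMINO_ACIDS),
    )
    below = int((table["A10_coding"] < table["A10_noncoding"]).sum())
    return ContrastResult(table, below)
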