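"""Synthetic genomes, coding sequences and dyad maps with planted structure.

These generators make every analysis stage testable without downloads: toy
genomes with annotated genes on both strands, random coding sequences for
the synonymous-sampler averages, and nucleosome dyad maps in which a 10-bp
rotational phasing is planted in chosen regions (the ground truth for the
multiplexing-recovery analyses).

Each generator consumes a single seeded RNG stream, so outputs are
reproducible from (spec, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import CODON_STRINGS, STOP_CODON_CODES, codon_string
from .io import DyadMap, Gene
from .mechanics import BASES

__all__ = [
    "ToyGenomeSpec",
    "planted_phased_map",
    "random_coding_sequence",
    "toy_genome",
]

_SENSE = np.array([c for c in range(64) if c not in STOP_CODON_CODES])


def random_coding_sequence(n_codons: int, usage=None, seed: int = 0) -> str:
    """A random in-frame coding sequence of ``n_codons`` sense codons.

    ``usage`` is a probability distribution over the 61 sense codons
    (dict codon->weight or array over the 64 codes with zero weight on
    stops); by default uniform.  No in-frame stop codons ever occur.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    if usage is None:
        p = np.full(len(_SENSE), 1.0 / len(_SENSE))
    else:
        w = np.zeros(64)
        if isinstance(usage, dict):
            for codon, weight in usage.items():
                w[CODON_STRINGS.index(codon.upper())] = weight
        else:
            w = np.asarray(usage, dtype=float).copy()
        if any(w[c] > 0 for c in STOP_CODON_CODES):
            raise ValueError("codon usage must put zero weight on stop codons")
        w = w[_SENSE]
        if w.sum() <= 0:
            raise ValueError("codon usage must have positive total weight")
        p = w / w.sum()
    draws = rng.choice(_SENSE, size=n_codons, p=p)
    return "".join(codon_string(int(c)) for c in draws)


@dataclass
class ToyGenomeSpec:
    """Parameters of the toy genome generator.

    ``intergenic_phase_strength`` > 0 gives the intergenic background a
    10-bp periodic base composition (A/T-enriched at phase 0, G/C at the
    opposite phase, anchored to absolute genomic coordinates), which is the
    substrate for planting rotational phasing.
    """

    n_chrom: int = 2
    chrom_length: int = 60_000
    gene_fraction: float = 0.45
    gene_length_range: tuple[int, int] = (300, 1800)
    codon_usage: dict | None = None
    intergenic_period: int = 10
    intergenic_phase_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.chrom_length < 1000:
            raise ValueError("need at least one chromosome of >= 1000 bp")
        if not 0 < self.gene_fraction < 1:
            raise ValueError("gene_fraction must be in (0, 1)")
        lo, hi = self.gene_length_range
        if lo < 60 or hi < lo:
            raise ValueError("gene lengths must be >= 60 with lo <= hi")


def _intergenic_bases(start: int, length: int, spec: ToyGenomeSpec, rng) -> str:
    """Background sequence for genomic positions start..start+length-1 (0-based)."""
    if length <= 0:
        return ""
    g = np.arange(start, start + length)
    s = spec.intergenic_phase_strength
    if s <= 0:
        return "".join(BASES[i] for i in rng.integers(0, 4, length))
    c = np.cos(2 * np.pi * g / spec.intergenic_period)
    w = np.empty((length, 4))
    w[:, 0] = 1 + s * c  # A
    w[:, 3] = 1 + s * c  # T
    w[:, 1] = 1 - s * c  # C
    w[:, 2] = 1 - s * c  # G
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(length)
    cum = np.cumsum(w, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(BASES[i] for i in idx)


def toy_genome(spec: ToyGenomeSpec) -> tuple[dict[str, str], list[Gene]]:
    """Generate a toy genome and its gene models.

    Genes are non-overlapping, single-CDS, on both strands, each a complete
    ORF (ATG ... stop); intergenic gaps are sized to match the requested
    gene fraction and are long enough to host nucleosomes.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    mean_gene = (lo + hi) / 2
    mean_gap = max(250.0, mean_gene * (1 - spec.gene_fraction) / spec.gene_fraction)
    genome: dict[str, str] = {}
    genes: list[Gene] = []
    for ci in range(spec.n_chrom):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        pos = 0  # 0-based next free position
        gi = 0
        while True:
            gap = int(rng.uniform(0.6, 1.4) * mean_gap)
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            gene_len = 3 * n_codons + 6  # ATG + body + stop
            if pos + gap + gene_len + 250 > spec.chrom_length:
                parts.append(_intergenic_bases(pos, spec.chrom_length - pos, spec, rng))
                break
            parts.append(_intergenic_bases(pos, gap, spec, rng))
            pos += gap
            body = random_coding_sequence(
                n_codons, spec.codon_usage, seed=int(rng.integers(2**31))
            )
            stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
            orf = "ATG" + body + stop
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                from .mechanics import reverse_complement

                parts.append(reverse_complement(orf))
            else:
                parts.append(orf)
            genes.append(
                Gene(f"{chrom}_g{gi}", chrom, strand, [(pos + 1, pos + gene_len)])
            )
            gi += 1
            pos += gene_len
        genome[chrom] = "".join(parts)
        assert len(genome[chrom]) == spec.chrom_length
    return genome, genes


def _intervals(genome, genes, chrom: str, genic: bool) -> list[tuple[int, int]]:
    """1-based inclusive genic or intergenic intervals of a chromosome."""
    L = len(genome[chrom])
    spans = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
    if genic:
        return spans
    out = []
    prev = 1
    for a, b in spans:
        if a > prev:
            out.append((prev, a - 1))
        prev = max(prev, b + 1)
    if prev <= L:
        out.append((prev, L))
    return out


def planted_phased_map(genome, genes, period: int = 10, jitter: float = 0.0,
                       spacing: int = 180, phased_regions: str = "noncoding",
                       frac_subthreshold: float = 0.0,
                       snr_above: float = 3.0, snr_below: float = 1.0,
                       seed: int = 0) -> DyadMap:
    """A synthetic dyad map with rotational phasing planted in chosen regions.

    Dyads are placed every ``spacing`` bp in both genic and intergenic
    intervals; in ``phased_regions`` ("coding", "noncoding", "both" or
    "none") they snap to absolute genomic multiples of ``period`` (plus
    Gaussian ``jitter``), locking their rotational phase to any ``period``-
    periodic feature of the underlying sequence; elsewhere the offset is
    uniform random, a phase-free control.  A fraction ``frac_subthreshold``
    of records receives score/noise = ``snr_below`` (failing the usual 1.5
    SNR filter), the rest ``snr_above``.
    """
    if phased_regions not in ("coding", "noncoding", "both", "none"):
        raise ValueError("phased_regions must be coding|noncoding|both|none")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in genome:
        L = len(genome[chrom])
        for genic in (True, False):
            phased = phased_regions == "both" or (
                phased_regions == ("coding" if genic else "noncoding")
            )
            for a, b in _intervals(genome, genes, chrom, genic):
                if b - a + 1 < WINDOW_MARGIN:
                    continue
                d = a + 73
                while d <= b - 73:
                    if phased:
                        pos = int(round(d / period)) * period
                        if jitter > 0:
                            pos += int(round(rng.normal(0, jitter)))
                    else:
                        pos = d + int(rng.integers(0, period))
                    if a + 73 <= pos <= b - 73 and 74 <= pos <= L - 73:
                        rows.append((chrom, pos))
                    d += spacing
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    n = len(df)
    sub = rng.random(n) < frac_subthreshold
    df["score"] = 1.0
    df["noise"] = np.where(sub, 1.0 / snr_below, 1.0 / snr_above)
    return DyadMap(df)


WINDOW_MARGIN = 160
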