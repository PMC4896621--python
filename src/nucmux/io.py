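"""Readers, writers and run configuration.

Coordinates are 1-based inclusive internally (GTF-native).  Dyad maps are
BED-like tab-separated tables with columns chrom, pos, score, noise (one
nucleosome dyad call per row, strand-agnostic).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mechanics import validate_sequence

__all__ = [
    "DyadMap",
    "Gene",
    "RunConfig",
    "read_dyad_map",
    "read_fasta",
    "read_gtf",
    "write_dyad_map",
    "write_fasta",
    "write_gtf",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA -> {name: sequence}, validated over the ACGT alphabet."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = validate_sequence(str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        str(path), "fasta",
    )


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    """A protein-coding gene: CDS segments in genomic order, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    cds: list  # [(start, end), ...] sorted by start

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for a, b in self.cds:
            if a > b or a < 1:
                raise ValueError(f"gene {self.gene_id}: bad CDS segment ({a}, {b})")

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def spliced_positions(self) -> np.ndarray:
        """Genomic coordinate of each spliced-CDS base, 5'->3' in gene order."""
        pos = np.concatenate([np.arange(a, b + 1) for a, b in self.cds])
        return pos[::-1] if self.strand == "-" else pos

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        from .mechanics import reverse_complement

        chrom = genome[self.chrom]
        s = "".join(chrom[a - 1 : b] for a, b in self.cds)
        return reverse_complement(s) if self.strand == "-" else s


def read_gtf(path) -> list[Gene]:
    """Parse a GTF into Gene models (CDS features grouped by gene_id)."""
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as e:
        raise ValueError(f"malformed GTF {path}: {e}") from None
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        entry = by_gene.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand, "cds": []}
        )
        if entry["chrom"] != feat.seqid or entry["strand"] != feat.strand:
            raise ValueError(f"gene {gid}: CDS features disagree on chrom/strand")
        entry["cds"].append((feat.start, feat.end))
    if not by_gene:
        raise ValueError(f"no CDS features found in {path}")
    return [Gene(gid, d["chrom"], d["strand"], d["cds"])
            for gid, d in sorted(by_gene.items())]


def write_gtf(genes: list[Gene], path, source: str = "nucmux") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            segs = g.cds if g.strand == "+" else g.cds[::-1]
            frame = 0
            for a, b in segs:
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{a}\t{b}\t.\t{g.strand}\t{frame}\t{attrs}\n"
                )
                frame = (3 - ((b - a + 1 - frame) % 3)) % 3
            fh.write(
                f"{g.chrom}\t{source}\texon\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Dyad maps
# ---------------------------------------------------------------------------

@dataclass
class DyadMap:
    """Nucleosome dyad records: chrom, pos (1-based), score, noise."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "score", "noise"]
        missing = set(required) - set(self.df.columns)
        if missing:
            raise ValueError(f"dyad map missing columns {sorted(missing)}")
        self.df = self.df[required].reset_index(drop=True)
        if (self.df["score"] < 0).any() or (self.df["noise"] < 0).any():
            raise ValueError("dyad map scores and noises must be non-negative")

    def __len__(self) -> int:
        return len(self.df)

    def positions(self, chrom: str) -> np.ndarray:
        return np.sort(self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy())

    def validate_against(self, genome: dict[str, str]) -> None:
        bad_chrom = sorted(set(self.df["chrom"]) - set(genome))
        if bad_chrom:
            raise ValueError(f"dyad map references unknown chromosomes: {bad_chrom}")
        for chrom, grp in self.df.groupby("chrom"):
            L = len(genome[chrom])
            out = grp[(grp["pos"] < 1) | (grp["pos"] > L)]
            if not out.empty:
                raise ValueError(
                    f"dyad positions outside {chrom} (length {L}): "
                    f"{out['pos'].tolist()[:5]}..."
                )


def read_dyad_map(path) -> DyadMap:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as e:
        raise ValueError(f"malformed dyad map {path}: {e}") from None
    try:
        df["pos"] = df["pos"].astype(int)
        df["score"] = df["score"].astype(float)
        df["noise"] = df["noise"].astype(float)
    except (KeyError, ValueError) as e:
        raise ValueError(f"malformed dyad map {path}: {e}") from None
    return DyadMap(df)


def write_dyad_map(dmap: DyadMap, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        dmap.df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level run configuration; serializes losslessly to YAML."""

    seed: int = 0
    out_dir: str = "."
    params_path: str | None = None
    constraints_path: str | None = None
    options: dict = field(default_factory=dict)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        import os

        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls(**data)


def filter_map(dmap: DyadMap, min_snr: float = 1.5) -> DyadMap:
    """Retain dyad records with score/noise strictly above ``min_snr``.

    Records with zero noise are rejected with a warning (their ratio is
    undefined).
    """
    df = dmap.df
    zero = df["noise"] <= 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} dyad records with non-positive noise",
            stacklevel=2,
        )
        df = df[~zero]
    keep = df["score"] / df["noise"] > min_snr
    return DyadMap(df[keep].reset_index(drop=True))
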