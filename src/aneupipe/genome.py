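"""Genome annotation container and plain-text genome IO.

Coordinates are 0-based half-open internally; VCF-style positions used
elsewhere in the package are 1-based and converted at the boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, gene (CDS) intervals and optional sequence.

    Parameters
    ----------
    chrom_lengths
        Ordered mapping chromosome name -> length in bp.
    genes
        DataFrame with columns ``gene_id, chrom, start, end, strand``;
        each gene is a single CDS interval (0-based, half-open).
    seqs
        Optional mapping chromosome -> sequence string (upper-case ACGT).
    gc_fraction
        Genomic G+C fraction used for composition normalization when no
        sequence is attached.
    repeat_loci
        Chromosome -> sorted positions of repeat elements; structural
        breakpoints are constrained to these loci by the simulator.
    masked_regions
        ``(chrom, start, end)`` intervals excluded from copy-number
        calling (rDNA-like arrays).
    """

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    seqs: dict[str, str] | None = None
    gc_fraction: float = 0.38
    repeat_loci: dict[str, list[int]] = field(default_factory=dict)
    masked_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome required")
        for c, n in self.chrom_lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {c} has nonpositive length")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        self.genes = pd.DataFrame(self.genes, columns=GENE_COLUMNS)
        if len(self.genes) and (self.genes["end"] <= self.genes["start"]).any():
            raise ValueError("gene intervals must be non-empty")

    # -- derived quantities -------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def coding_fraction(self) -> float:
        if not len(self.genes):
            return 0.0
        return float((self.genes["end"] - self.genes["start"]).sum()) / self.genome_length

    @property
    def f_gc(self) -> float:
        return self.gc_fraction

    @property
    def f_at(self) -> float:
        return 1.0 - self.gc_fraction

    def tss(self) -> pd.Series:
        """Transcription start site per gene (0-based position)."""
        plus = self.genes["strand"] == "+"
        return self.genes["start"].where(plus, self.genes["end"] - 1)

    def gene_at(self, chrom: str, pos0: int) -> str | None:
        """Gene id containing 0-based position ``pos0``, or None."""
        g = self.genes
        hit = g[(g["chrom"] == chrom) & (g["start"] <= pos0) & (pos0 < g["end"])]
        if len(hit) == 0:
            return None
        return str(hit.iloc[0]["gene_id"])

    def base_at(self, chrom: str, pos0: int) -> str:
        if self.seqs is None:
            raise ValueError("no sequence attached to annotation")
        return self.seqs[chrom][pos0]

    # -- IO -----------------------------------------------------------------

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for c, n in self.chrom_lengths.items():
                fh.write(f"{c}\t{n}\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c, n in self.chrom_lengths.items():
                fh.write(f"##sequence-region {c} 1 {n}\n")
            for _, g in self.genes.iterrows():
                attrs = f"ID={g.gene_id}"
                # GFF is 1-based inclusive
                fh.write(
                    f"{g.chrom}\taneupipe\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
                )

    def write_fasta(self, path, width: int = 80) -> None:
        if self.seqs is None:
            raise ValueError("no sequence attached to annotation")
        with open(path, "w") as fh:
            for c, seq in self.seqs.items():
                fh.write(f">{c}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, n = line.split("\t")[:2]
            sizes[name] = int(n)
    return sizes


def read_gff3(path, chrom_lengths: dict[str, int] | None = None,
              gc_fraction: float = 0.38) -> GenomeAnnotation:
    """Load a minimal single-interval-per-gene GFF3 written by this package."""
    rows = []
    seen_regions: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, name, _start, end = line.split()
                seen_regions[name] = int(end)
                continue
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, _type, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            m = re.search(r"ID=([^;]+)", attrs)
            gene_id = m.group(1) if m else f"{chrom}:{start}-{end}"
            rows.append((gene_id, chrom, int(start) - 1, int(end), strand))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    lengths = chrom_lengths or seen_regions
    if not lengths:
        raise ValueError("no chromosome lengths available (need ##sequence-region)")
    return GenomeAnnotation(chrom_lengths=lengths, genes=genes, gc_fraction=gc_fraction)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def random_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(["A", "C", "G", "T"])[idx])
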