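"""Genome annotation containers and strand-aware coordinate arithmetic.

All intervals are 0-based, half-open ``[start, end)``.  Offsets are
TSS-relative and strand-aware: offset 0 is the first transcribed base,
positive offsets run in the direction of transcription.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class Gene:
    """A gene model with a single (first) TSS per gene id."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int   # txStart
    end: int     # txEnd
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(f"empty gene interval for {self.gene_id}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon outside gene body in {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


def genomic_to_offset(tss: int, strand: str, pos: int) -> int:
    """TSS-relative, strand-aware offset of genomic position ``pos``."""
    return pos - tss if strand == "+" else tss - pos


def offset_window_to_genomic(tss: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Map the offset window ``[a, b)`` to a genomic half-open interval."""
    if a >= b:
        raise ValueError("empty offset window")
    if strand == "+":
        return tss + a, tss + b
    return tss - b + 1, tss - a + 1


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or touching intervals merge."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GenomeAnnotation:
    """Chromosomes, gene models, CpG islands, enhancers and tiled regions."""

    chromosomes: dict[str, int]
    genes: list[Gene]
    cgis: list[tuple[str, int, int]] = field(default_factory=list)
    enhancers: list[tuple[str, int, int]] = field(default_factory=list)
    tiled_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > self.chromosomes[g.chrom]:
                raise ValueError(f"gene {g.gene_id} beyond chromosome end")
        for name, ivs in (("cgis", self.cgis), ("enhancers", self.enhancers),
                          ("tiled_regions", self.tiled_regions)):
            for chrom, s, e in ivs:
                if chrom not in self.chromosomes:
                    raise ValueError(f"{name} interval on unknown chromosome {chrom}")
                if not 0 <= s < e:
                    raise ValueError(f"bad {name} interval ({chrom}, {s}, {e})")

    def gene(self, gene_id: str) -> Gene:
        try:
            return next(g for g in self.genes if g.gene_id == gene_id)
        except StopIteration:
            raise KeyError(gene_id) from None

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
            out.setdefault(g.chrom, []).append(g)
        return out

    # ------------------------------------------------------------------ I/O

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for chrom, length in self.chromosomes.items():
            lines.append(f"##sequence-region {chrom} 1 {length}")
        for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
            lines.append("\t".join([
                g.chrom, "hydroxyscan", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]))
            for i, (s, e) in enumerate(g.exons, 1):
                lines.append("\t".join([
                    g.chrom, "hydroxyscan", "exon", str(s + 1), str(e),
                    ".", g.strand, ".", f"ID={g.gene_id}.e{i};Parent={g.gene_id}",
                ]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GenomeAnnotation":
        chromosomes: dict[str, int] = {}
        genes: dict[str, dict] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("##sequence-region"):
                _, chrom, _one, length = line.split()
                chromosomes[chrom] = int(length)
                continue
            if not line or line.startswith("#"):
                continue
            chrom, _src, kind, start, end, _sc, strand, _fr, attrs = line.split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";"))
            if kind == "gene":
                genes[fields["ID"]] = dict(
                    chrom=chrom, strand=strand, start=int(start) - 1, end=int(end))
            elif kind == "exon":
                exons.setdefault(fields["Parent"], []).append((int(start) - 1, int(end)))
        gene_objs = [
            Gene(gene_id=gid, exons=tuple(sorted(exons.get(gid, []))), **spec)
            for gid, spec in genes.items()
        ]
        return cls(chromosomes=chromosomes, genes=gene_objs)

    def write_bed_tracks(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for name, ivs in (("cgis", self.cgis), ("enhancers", self.enhancers),
                          ("tiled_regions", self.tiled_regions)):
            write_bed(outdir / f"{name}.bed",
                      [(c, s, e, f"{name[:-1] if name.endswith('s') else name}_{i}")
                       for i, (c, s, e) in enumerate(ivs)])


def write_bed(path: str | Path, records: Sequence[tuple]) -> None:
    """Write BED records ``(chrom, start, end[, name[, score[, strand]]])``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into columns chrom/start/end(/name/score/strand)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def ledger_to_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=str))
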