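"""Reading and writing the standard text formats.

Conventions: BED / bedGraph / narrowPeak are 0-based half-open; GFF3 is
1-based closed.  Coverage is written sparsely as bedGraph runs; masked
(NaN) positions are encoded by omission of the interval, the standard
sparse convention, and come back as NaN on read when a genome sizes
mapping is supplied.
"""

from __future__ import annotations

from math import ceil
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import AnnotatedGene, GenomicInterval
from .tracks import CoverageTrack


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------- bedGraph

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length encode each chromosome vector; NaN runs are omitted."""
    res = track.resolution
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            # boundaries where the value changes (NaN == NaN for this purpose)
            same = (vec[1:] == vec[:-1]) | (np.isnan(vec[1:]) & np.isnan(vec[:-1]))
            starts = np.r_[0, np.nonzero(~same)[0] + 1]
            ends = np.r_[starts[1:], len(vec)]
            for s, e in zip(starts, ends):
                val = vec[s]
                if np.isnan(val):
                    continue
                fh.write(f"{chrom}\t{s * res}\t{e * res}\t{val:g}\n")


def read_bedgraph(
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    scale: str = "raw_counts",
    resolution: int = 1,
) -> CoverageTrack:
    """Read a bedGraph into a dense track.

    Positions not covered by any interval become NaN when
    ``chrom_lengths`` is given (mask-by-omission); without it the track
    spans up to the last covered base per chromosome.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    data: dict[str, np.ndarray] = {}
    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            data[chrom] = np.full(ceil(length / resolution), np.nan)
    for chrom, sub in df.groupby("chrom", sort=True):
        if chrom not in data:
            data[chrom] = np.full(ceil(sub["end"].max() / resolution), np.nan)
        vec = data[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            vec[s // resolution : ceil(e / resolution)] = v
    return CoverageTrack(data, scale=scale, resolution=resolution)


# ------------------------------------------------------------ BED flavours

def write_bed3(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bed6(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    ivs = list(intervals)
    names = names if names is not None else [f"region_{i}" for i in range(len(ivs))]
    scores = scores if scores is not None else [0.0] * len(ivs)
    with open(path, "w") as fh:
        for iv, name, score in zip(ivs, names, scores):
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return out


def write_narrowpeak(peaks, path: str | Path) -> None:
    """BED6+4: signalValue, pValue (-log10), qValue (-log10), summit offset."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{min(1000, int(round(pk.score)))}\t.\t"
                f"{pk.score:.4f}\t{-np.log10(pk.p_value):.4f}\t{-np.log10(pk.q_value):.4f}\t"
                f"{pk.summit - iv.start}\n"
            )


# --------------------------------------------------------------- GFF3

def write_gff3(
    genes: Iterable[AnnotatedGene], path: str | Path, source: str = "rubychip"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            iv = gene.interval
            attrs = f"ID={gene.name};biotype={gene.biotype}"
            for key, val in sorted(gene.attributes.items()):
                attrs += f";{key}={val}"
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[AnnotatedGene]:
    genes: list[AnnotatedGene] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, _src, _type, start1, end1, _score, strand, _phase, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            biotype = attr.pop("biotype", "ncRNA")
            name = attr.pop("ID", "")
            genes.append(
                AnnotatedGene(
                    GenomicInterval(chrom, int(start1) - 1, int(end1), strand),
                    biotype=biotype,
                    name=name,
                    attributes=attr,
                )
            )
    return genes
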