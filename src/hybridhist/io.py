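"""Readers and writers for BED, BedGraph, GFF3 and TSV tables.

GFF3 uses 1-based closed coordinates; they are converted to the internal
0-based half-open convention on read and back on write, so round-trips are
lossless. Files ending in ``.gz`` are read and written gzip-compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, GenomicInterval


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3..BED6; strand defaults to '.' when absent."""
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BED line") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, scores=None) -> None:
    ivs = list(intervals)
    with _open(path, "wt") as fh:
        for i, iv in enumerate(ivs):
            score = "0" if scores is None else f"{scores[i]:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a BedGraph into dense per-base float tracks."""
    tracks = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            try:
                chrom, start, end, value = line.split("\t")
                start, end, value = int(start), int(end), float(value)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BedGraph line") from exc
            if chrom in tracks:
                tracks[chrom][start:end] = value
    return tracks


def write_bedgraph(tracks: dict[str, np.ndarray], path) -> None:
    """Write dense tracks run-length encoded; zero runs are omitted."""
    with _open(path, "wt") as fh:
        for chrom in sorted(tracks):
            t = np.asarray(tracks[chrom], dtype=float)
            if t.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(t)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [t.size]])
            for s, e in zip(starts, ends):
                v = t[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


_GFF_CLASS = {
    "gene": "protein_coding",
    "transposable_element": "TE",
    "transposable_element_gene": "TE_gene",
}
_GFF_TYPE = {v: k for k, v in _GFF_CLASS.items()}


def read_gff3(path) -> list[GeneAnnotation]:
    """Read gene/TE records from GFF3 (1-based closed -> 0-based half-open)."""
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in _GFF_CLASS:
                continue
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            gene_id = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            out.append(
                GeneAnnotation(
                    GenomicInterval(chrom, start - 1, end, strand, gene_id),
                    gene_id=gene_id,
                    feature_class=_GFF_CLASS[ftype],
                )
            )
    return out


def write_gff3(genes: Iterable[GeneAnnotation], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\thybridhist\t{_GFF_TYPE[g.feature_class]}\t"
                f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.gene_id}\n"
            )


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_snp_table(path) -> pd.DataFrame:
    """SNP table columns: chrom, pos (0-based), allele_P1, allele_P2."""
    df = read_tsv(path)
    required = {"chrom", "pos", "allele_P1", "allele_P2"}
    if not required.issubset(df.columns):
        raise ValueError(f"SNP table must have columns {sorted(required)}")
    return df


def genes_to_bed(genes: Sequence[GeneAnnotation], path) -> None:
    write_bed([g.interval for g in genes], path)
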