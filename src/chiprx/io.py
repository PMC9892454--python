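"""Readers and writers for the pipeline's plain-text formats.

Formats: BED (tags, 0-based half-open, 3-6 columns), TSV with a header row
for gene annotations and count tables, a chromosome-sizes TSV, and a flat
``key=value`` configuration file.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    DEFAULT_SPIKE_PREFIX,
    AlignedTag,
    CountTable,
    GeneAnnotation,
    GenomicInterval,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record in an input file (message carries the line number)."""


def read_bed(path, spike_prefix: str = DEFAULT_SPIKE_PREFIX) -> list[AlignedTag]:
    """Read aligned tags from a 3-6 column BED file.

    Record order is preserved.  ``is_spike`` is set from the chromosome-name
    prefix.  A missing or '.' strand is treated as '+' (logged once).
    """
    tags: list[AlignedTag] = []
    n_defaulted = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end} "
                    "(require 0 <= start < end)"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            if strand == ".":
                strand = "+"
                n_defaulted += 1
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            tags.append(
                AlignedTag(
                    interval=GenomicInterval(chrom, start, end),
                    strand=strand,
                    is_spike=chrom.startswith(spike_prefix),
                )
            )
    if n_defaulted:
        logger.warning("%s: %d records without strand, defaulted to '+'", path, n_defaulted)
    return tags


def write_bed(tags: Iterable[AlignedTag], path) -> None:
    """Write tags as 6-column BED (name=t<i>, score=0)."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags):
            iv = tag.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tt{i}\t0\t{tag.strand}\n")


_GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand")


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read gene annotations from a TSV with header.

    Required columns: gene_id, chrom, tss, strand; optional
    baseline_expression.  Unknown extra columns are ignored.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "chrom": str},
        float_precision="round_trip",
    )
    for col in _GENE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicated gene_id {dup!r}")
    has_base = "baseline_expression" in df.columns
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneAnnotation(
                gene_id=row.gene_id,
                chrom=row.chrom,
                tss=int(row.tss),
                strand=row.strand,
                baseline_expression=float(row.baseline_expression) if has_base else 1.0,
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "baseline_expression": [g.baseline_expression for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> CountTable:
    """Read a count table from a TSV: first column row ids, header = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated row ids")
    return CountTable(df)


def write_counts(table: CountTable, path) -> None:
    table.data.to_csv(path, sep="\t")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (no header): chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_config(path) -> dict[str, str]:
    """Flat ``key=value`` configuration file; '#' starts a comment line."""
    config: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}: line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            config[key.strip()] = value.strip()
    return config


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set id, description, member genes)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            sets[fields[0]] = set(fields[2:])
    return sets
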