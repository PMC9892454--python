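"""Shared genomic data model: intervals, aligned tags, annotations, count tables.

All coordinates are 0-based and half-open ``[start, end)``.  Every interval
consumer in the package goes through the single overlap predicate defined
here: two intervals overlap iff ``a.start < b.end and b.start < a.end``
(at least one shared base pair; a larger minimum overlap can be requested).

Spike-in (exogenous species) chromosomes are distinguished from endogenous
ones purely by a reserved chromosome-name prefix, mirroring a combined
two-species alignment index.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Default chromosome-name prefix marking spike-in (exogenous) chromosomes.
DEFAULT_SPIKE_PREFIX = "spk"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (0-based, half-open)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        """True iff the two intervals share at least ``min_overlap`` bp."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """Shared overlap predicate (see module docstring)."""
    return a.overlaps(b, min_overlap=min_overlap)


@dataclass(frozen=True)
class AlignedTag:
    """One mapped read/fragment endpoint.

    The interval records the 5' base of the sequenced tag (length-1 record in
    BED output); ``strand`` orients the fragment, ``is_spike`` flags tags
    mapped to the exogenous spike-in genome.
    """

    interval: GenomicInterval
    strand: str
    is_spike: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def position5p(self) -> int:
        """0-based position of the 5' end of the tag."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to the features the pipeline needs: TSS and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    baseline_expression: float = 1.0

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.baseline_expression <= 0:
            raise ValueError(f"gene {self.gene_id}: baseline_expression must be > 0")


@dataclass(frozen=True)
class EnhancerAnnotation:
    """A distal regulatory element assigned to a single target gene.

    ``baseline_enrichment`` is the tag-density fold over genomic background
    emitted at this element in an unperturbed sample (must exceed 1).
    """

    enhancer_id: str
    interval: GenomicInterval
    target_gene_id: str
    baseline_enrichment: float

    def __post_init__(self) -> None:
        if self.baseline_enrichment <= 1:
            raise ValueError(
                f"enhancer {self.enhancer_id}: baseline_enrichment must be > 1"
            )


@dataclass
class CountTable:
    """Non-negative integer counts, rows (genes or cells) by samples.

    Thin validated wrapper over a pandas DataFrame; ``data.index`` holds the
    row ids and ``data.columns`` the sample ids, both unique and ordered.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate row ids in count table")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count table must be numeric")
        if (values < 0).any():
            raise ValueError("count table contains negative entries")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)


def tag_arrays(tags: Sequence[AlignedTag]):
    """Decompose a tag list into parallel numpy arrays (chrom, start, end,
    strand, is_spike) for vectorised processing."""
    n = len(tags)
    chroms = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    strands = np.empty(n, dtype="U1")
    spike = np.empty(n, dtype=bool)
    for i, t in enumerate(tags):
        chroms[i] = t.interval.chrom
        starts[i] = t.interval.start
        ends[i] = t.interval.end
        strands[i] = t.strand
        spike[i] = t.is_spike
    return chroms, starts, ends, strands, spike


def shifted_positions(tags: Sequence[AlignedTag], fragment_shift: int) -> tuple[np.ndarray, np.ndarray]:
    """5'-end positions shifted ``fragment_shift`` bp toward the 3' end,
    strand-aware.  Returns (chroms, positions); positions may fall outside
    chromosome bounds and are clamped by callers that know the bounds."""
    chroms, starts, ends, strands, _ = tag_arrays(tags)
    pos = np.where(strands == "+", starts + fragment_shift, ends - 1 - fragment_shift)
    return chroms, pos
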