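"""Enhancer-gene expression integration.

Pipeline: classify H3K4me1 islands into promoter vs enhancer class by
TSS proximity, link each enhancer-class island to its nearest TSS within a
distance cap, compute CPM expression fold changes, apply the dual
fold-change filter (both the enhancer signal and the linked gene's
expression reduced by at least the threshold, default 1.6-fold), and score
what fraction of the passing genes' enhancers carry binding of the
methyltransferase (overlap with its islands).

The report always carries the three study-level summary numbers - n_pass,
n_pass_bound and bound_fraction - so a run on real data drops into the
same slot as a synthetic run.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CountTable, GeneAnnotation, GenomicInterval
from .islands import (
    Island,
    IslandCallParams,
    KMT2D_PARAMS,
    call_significant_islands,
    differential_island_fc,
)
from .spikenorm import ScaleFactorSet, compute_scale_factors, partition_tags

logger = logging.getLogger(__name__)


@dataclass
class EnhancerGeneLink:
    """An enhancer-class island assigned to its nearest gene (by TSS)."""

    island: Island
    gene_id: str
    distance_bp: int


@dataclass
class DifferentialGeneRecord:
    """Per-gene joint evidence: expression fc, linked-enhancer fc, binding."""

    gene_id: str
    expr_fc_wt_over_ko: float
    enhancer_fc_wt_over_ko: float
    enhancer_interval: GenomicInterval
    kmt2d_bound: bool = False
    passes_dual: bool = False


@dataclass
class IntegrationResult:
    records: list[DifferentialGeneRecord]
    n_pass: int
    n_pass_bound: int
    bound_fraction: float

    def summary(self) -> dict:
        return {
            "n_pass": self.n_pass,
            "n_pass_bound": self.n_pass_bound,
            "bound_fraction": self.bound_fraction,
        }


def classify_islands(
    islands: Sequence[Island],
    genes: Sequence[GeneAnnotation],
    promoter_halfwidth: int = 2000,
) -> tuple[list[Island], list[Island]]:
    """Split islands into (promoter-class, enhancer-class).

    An island is promoter-class iff it overlaps any TSS +/- halfwidth
    window under the shared half-open overlap predicate; the partition is
    exhaustive and exclusive.
    """
    if promoter_halfwidth <= 0:
        raise ValueError("promoter_halfwidth must be > 0")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[attr-defined]
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    promoters, enhancers = [], []
    for isl in islands:
        tss = tss_by_chrom.get(isl.chrom)
        if tss is None:
            enhancers.append(isl)
            continue
        # Promoter window [tss - hw, tss + hw + 1) overlaps the island iff
        # tss falls in [start - hw, end + hw).
        lo = np.searchsorted(tss, isl.start - promoter_halfwidth, side="left")
        hi = np.searchsorted(tss, isl.end + promoter_halfwidth, side="left")
        (promoters if hi > lo else enhancers).append(isl)
    return promoters, enhancers


def _edge_distance(island: Island, tss: np.ndarray) -> np.ndarray:
    """Distance from a TSS to the nearest island edge (0 inside)."""
    d = np.zeros(tss.size, dtype=np.int64)
    left = tss < island.start
    right = tss >= island.end
    d[left] = island.start - tss[left]
    d[right] = tss[right] - island.end + 1
    return d


def link_to_gene(
    enhancer_islands: Sequence[Island],
    genes: Sequence[GeneAnnotation],
    max_link_distance: int = 100_000,
) -> list[EnhancerGeneLink]:
    """Link each enhancer island to the gene with minimum edge-to-TSS
    distance within ``max_link_distance`` (ties: lexicographically smallest
    gene_id).  Unlinked enhancers are dropped with a logged count."""
    if max_link_distance <= 0:
        raise ValueError("max_link_distance must be > 0")
    if not genes:
        raise ValueError("empty gene list")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = sorted((g.tss, g.gene_id) for g in genes if g.chrom == chrom)
        by_chrom[chrom] = (np.array([t for t, _ in sub]), [gid for _, gid in sub])
    links, n_dropped = [], 0
    for isl in enhancer_islands:
        entry = by_chrom.get(isl.chrom)
        if entry is None:
            n_dropped += 1
            continue
        tss, gene_ids = entry
        d = _edge_distance(isl, tss)
        dmin = int(d.min())
        if dmin > max_link_distance:
            n_dropped += 1
            continue
        candidates = [gene_ids[i] for i in np.flatnonzero(d == dmin)]
        links.append(EnhancerGeneLink(island=isl, gene_id=min(candidates), distance_bp=dmin))
    if n_dropped:
        logger.info("%d enhancer islands had no gene within %d bp", n_dropped, max_link_distance)
    return links


def compute_cpm(table: CountTable) -> pd.DataFrame:
    """Counts per million: count / library size x 1e6 (columns sum to 1e6)."""
    libs = table.library_sizes
    if (libs <= 0).any():
        zero = libs.index[libs <= 0][0]
        raise ValueError(f"sample {zero!r} has zero library size")
    return table.data / libs * 1e6


def expression_fc(
    cpm: pd.DataFrame,
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene fc = (mean WT CPM + eps) / (mean KO CPM + eps), eps = 0.5."""
    if not wt_samples or not ko_samples:
        raise ValueError("need at least one sample per genotype")
    overlap = set(wt_samples) & set(ko_samples)
    if overlap:
        raise ValueError(f"samples assigned to both genotypes: {sorted(overlap)}")
    wt_mean = cpm[list(wt_samples)].mean(axis=1)
    ko_mean = cpm[list(ko_samples)].mean(axis=1)
    return (wt_mean + pseudocount) / (ko_mean + pseudocount)


def dual_threshold_filter(
    expr_fc: Mapping[str, float] | pd.Series,
    links: Sequence[EnhancerGeneLink],
    threshold: float = 1.6,
    combine: str = "max",
    direction: str = "reduced",
) -> list[DifferentialGeneRecord]:
    """Apply the dual fold-change filter.

    A gene passes iff its expression fc >= threshold AND its linked
    enhancer fc >= threshold ("at least" - inclusive boundaries).  Genes
    with several linked enhancers use the maximum enhancer fc (the
    most-changed enhancer evidences the gene; ``combine="mean"`` averages
    instead).  ``direction="increased"`` inverts both ratios so KO gains
    are filtered instead of losses.  Output is sorted by gene_id.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    if combine not in ("max", "mean"):
        raise ValueError("combine must be 'max' or 'mean'")
    if direction not in ("reduced", "increased"):
        raise ValueError("direction must be 'reduced' or 'increased'")
    expr = pd.Series(expr_fc, dtype=float)
    by_gene: dict[str, list[EnhancerGeneLink]] = {}
    for link in links:
        if link.island.fold_change is None:
            raise ValueError("islands must carry fold changes (differential_island_fc)")
        by_gene.setdefault(link.gene_id, []).append(link)
    n_unlinked = sum(1 for g in expr.index if g not in by_gene)
    if n_unlinked:
        logger.info("%d genes with expression but no linked enhancer excluded", n_unlinked)

    def oriented(fc: float) -> float:
        return fc if direction == "reduced" else 1.0 / fc

    records = []
    for gene_id in sorted(by_gene):
        if gene_id not in expr.index:
            continue
        gene_links = by_gene[gene_id]
        fcs = [oriented(l.island.fold_change) for l in gene_links]
        best = int(np.argmax(fcs))
        enh_fc = fcs[best] if combine == "max" else float(np.mean(fcs))
        e_fc = oriented(expr.loc[gene_id])
        records.append(
            DifferentialGeneRecord(
                gene_id=gene_id,
                expr_fc_wt_over_ko=float(expr.loc[gene_id]),
                enhancer_fc_wt_over_ko=float(
                    enh_fc if direction == "reduced" else 1.0 / enh_fc
                ),
                enhancer_interval=gene_links[best].island.interval,
                passes_dual=bool(e_fc >= threshold and enh_fc >= threshold),
            )
        )
    return records


def kmt2d_overlap(
    records: Sequence[DifferentialGeneRecord],
    kmt2d_islands: Sequence[Island],
) -> IntegrationResult:
    """Flag genes whose linked enhancer overlaps (>= 1 bp) any binding
    island of the methyltransferase, and summarise the passing set.

    With zero passing genes, bound_fraction is reported as 0.0 alongside
    n_pass = 0 (the degenerate flag).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {i.chrom for i in kmt2d_islands}:
        sub = [i for i in kmt2d_islands if i.chrom == chrom]
        by_chrom[chrom] = (
            np.array([i.start for i in sub]),
            np.array([i.end for i in sub]),
        )
    for rec in records:
        entry = by_chrom.get(rec.enhancer_interval.chrom)
        if entry is None:
            rec.kmt2d_bound = False
            continue
        starts, ends = entry
        rec.kmt2d_bound = bool(
            ((starts < rec.enhancer_interval.end) & (ends > rec.enhancer_interval.start)).any()
        )
    n_pass = sum(1 for r in records if r.passes_dual)
    n_pass_bound = sum(1 for r in records if r.passes_dual and r.kmt2d_bound)
    return IntegrationResult(
        records=list(records),
        n_pass=n_pass,
        n_pass_bound=n_pass_bound,
        bound_fraction=(n_pass_bound / n_pass) if n_pass else 0.0,
    )


@dataclass
class StudyIntegration:
    """Full pipeline output with the intermediates useful for reporting."""

    result: IntegrationResult
    scale_factors: ScaleFactorSet
    islands: list[Island]
    enhancer_islands: list[Island]
    links: list[EnhancerGeneLink]
    expr_fc: pd.Series
    kmt2d_islands: list[Island]


def integrate_study(
    genome,
    wt_h3k4me1_tags,
    ko_h3k4me1_tags,
    rna_counts: CountTable,
    kmt2d_tags=None,
    *,
    wt_samples: Optional[Sequence[str]] = None,
    ko_samples: Optional[Sequence[str]] = None,
    h3k4me1_params: Optional[IslandCallParams] = None,
    kmt2d_params: Optional[IslandCallParams] = None,
    threshold: float = 1.6,
    promoter_halfwidth: int = 2000,
    max_link_distance: int = 100_000,
) -> StudyIntegration:
    """Run the whole differential pipeline on simulated (or real) inputs.

    Islands are called on the WT histone-mark sample (control-free,
    E-value mode), fold changes use spike-scaled WT/KO counts inside each
    island, and binding islands come from a WT sample of the enzyme mark.
    RNA sample groups default to column names starting with WT_/KO_.
    """
    if h3k4me1_params is None:
        h3k4me1_params = IslandCallParams()
    if kmt2d_params is None:
        kmt2d_params = IslandCallParams(**KMT2D_PARAMS)
    chrom_lengths = genome.endog_chrom_lengths

    wt_part = partition_tags(wt_h3k4me1_tags)
    ko_part = partition_tags(ko_h3k4me1_tags)
    factors = compute_scale_factors(
        {"WT": wt_part.n_spike, "KO": ko_part.n_spike}, reference="auto"
    )

    islands = call_significant_islands(
        wt_h3k4me1_tags, None, h3k4me1_params, chrom_lengths=chrom_lengths
    )
    differential_island_fc(
        islands,
        {"WT": wt_h3k4me1_tags, "KO": ko_h3k4me1_tags},
        factors,
        "WT",
        "KO",
        fragment_shift=h3k4me1_params.fragment_shift,
    )
    _, enhancer_islands = classify_islands(
        islands, genome.gene_annotations, promoter_halfwidth
    )
    links = link_to_gene(enhancer_islands, genome.gene_annotations, max_link_distance)

    if wt_samples is None:
        wt_samples = [s for s in rna_counts.sample_ids if s.startswith("WT")]
    if ko_samples is None:
        ko_samples = [s for s in rna_counts.sample_ids if s.startswith("KO")]
    fc = expression_fc(compute_cpm(rna_counts), wt_samples, ko_samples)
    records = dual_threshold_filter(fc, links, threshold=threshold)

    kmt2d_islands: list[Island] = []
    if kmt2d_tags is not None:
        kmt2d_islands = call_significant_islands(
            kmt2d_tags, None, kmt2d_params, chrom_lengths=chrom_lengths
        )
    result = kmt2d_overlap(records, kmt2d_islands)
    return StudyIntegration(
        result=result,
        scale_factors=factors,
        islands=islands,
        enhancer_islands=enhancer_islands,
        links=links,
        expr_fc=fc,
        kmt2d_islands=kmt2d_islands,
    )
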