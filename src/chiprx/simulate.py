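"""Synthetic two-genotype study generator with planted, recoverable effects.

The generator emulates the design of a knockout study of an H3K4me1
methyltransferase in T cells: wild-type (WT) and knockout (KO) samples are
profiled by ChIP-seq for the histone mark H3K4me1 and for the enzyme itself
(here called the Kmt2d mark), with a fixed fraction of exogenous spike-in
chromatin added to every ChIP so that global signal shifts remain
detectable after sequencing.  Matched bulk RNA-seq counts and a two-cluster
(resting / stimulated) single-cell matrix carry planted expression effects.

Emission model
--------------
ChIP tags are emitted from a mixture of a uniform genome-wide background
and per-feature enrichment components (gene promoters and distal
enhancers).  Tag yield is proportional to the amount of immunoprecipitated
material: the expected number of spike-in tags is ``depth x spike_fraction``
for every sample, while the expected endogenous yield scales with the
sample's total emission weight relative to the unperturbed (WT) weight.
Consequently a global KO depletion reduces endogenous tag counts uniformly
without touching the spike-in expectation - exactly the situation spike-in
normalization is designed to detect, and one that plain per-library CPM
scaling hides completely.

For KO H3K4me1 samples the entire endogenous emission is multiplied by
``TruthTable.global_depletion``; enhancers listed in ``affected_enhancers``
are additionally depleted by their per-enhancer factor (applied to the
enrichment component).  KO samples of the Kmt2d mark emit background only:
the protein is absent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SPIKE_PREFIX,
    AlignedTag,
    CountTable,
    EnhancerAnnotation,
    GeneAnnotation,
    GenomicInterval,
)

logger = logging.getLogger(__name__)

#: Enrichment fold applied to every gene promoter for the H3K4me1 mark, so
#: that promoter/enhancer classification is exercised downstream.
PROMOTER_FOLD = 3.0
#: Half-width (bp) of the promoter emission window around each TSS.
PROMOTER_HALFWIDTH = 2000
#: Minimum TSS-to-TSS spacing enforced at genome construction.
MIN_GENE_SPACING = 10_000
#: Enhancer placement bounds relative to the target TSS (genuinely distal).
MIN_ENHANCER_OFFSET = 5_000
MAX_ENHANCER_OFFSET = 100_000

GENOTYPES = ("WT", "KO")
MARKS = ("H3K4me1", "Kmt2d")

SC_CLUSTERS = ("resting", "stimulated")


@dataclass
class GenomeModel:
    """A small synthetic genome: chromosomes, genes and distal enhancers."""

    endogenous_chroms: list[tuple[str, int]]
    spike_chroms: list[tuple[str, int]]
    gene_annotations: list[GeneAnnotation]
    enhancer_annotations: list[EnhancerAnnotation]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.endogenous_chroms] + [n for n, _ in self.spike_chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        lengths = dict(self.endogenous_chroms) | dict(self.spike_chroms)
        for g in self.gene_annotations:
            if g.tss >= lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id}: tss beyond chromosome end")
        gene_ids = {g.gene_id for g in self.gene_annotations}
        for e in self.enhancer_annotations:
            if e.target_gene_id not in gene_ids:
                raise ValueError(f"enhancer {e.enhancer_id}: unknown target gene")
            if e.interval.end > lengths[e.interval.chrom]:
                raise ValueError(f"enhancer {e.enhancer_id}: beyond chromosome end")

    @property
    def endog_chrom_lengths(self) -> dict[str, int]:
        return dict(self.endogenous_chroms)

    @property
    def spike_chrom_lengths(self) -> dict[str, int]:
        return dict(self.spike_chroms)

    @property
    def all_chrom_lengths(self) -> dict[str, int]:
        return self.endog_chrom_lengths | self.spike_chrom_lengths

    @property
    def endog_length(self) -> int:
        return sum(l for _, l in self.endogenous_chroms)

    @property
    def genes_by_id(self) -> dict[str, GeneAnnotation]:
        return {g.gene_id: g for g in self.gene_annotations}

    @property
    def enhancers_by_id(self) -> dict[str, EnhancerAnnotation]:
        return {e.enhancer_id: e for e in self.enhancer_annotations}

    def enhancers_of_gene(self, gene_id: str) -> list[EnhancerAnnotation]:
        return [e for e in self.enhancer_annotations if e.target_gene_id == gene_id]


@dataclass
class TruthTable:
    """Planted simulation effects, the ground truth for recovery scoring.

    ``global_depletion`` multiplies all KO H3K4me1 signal; per-enhancer
    factors in ``affected_enhancers`` multiply the enrichment component of
    individual enhancers on top of it.  ``affected_genes`` holds KO
    expression fold factors; ``sc_cluster2_signature`` holds fold factors
    applied to the stimulated single-cell cluster.
    """

    global_depletion: float = 1.0
    affected_enhancers: dict[str, float] = field(default_factory=dict)
    affected_genes: dict[str, float] = field(default_factory=dict)
    kmt2d_bound_enhancers: set[str] = field(default_factory=set)
    sc_cluster2_signature: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.global_depletion <= 1:
            raise ValueError("global_depletion must be in (0, 1]")
        for d in (self.affected_enhancers, self.affected_genes, self.sc_cluster2_signature):
            for key, factor in d.items():
                if factor <= 0:
                    raise ValueError(f"factor for {key!r} must be strictly positive")

    def net_enhancer_factor(self, enhancer_id: str) -> float:
        """KO depletion of an enhancer's enrichment, including the global term."""
        return self.global_depletion * self.affected_enhancers.get(enhancer_id, 1.0)

    def dual_effect_genes(self, genome: GenomeModel, threshold: float = 1.6) -> list[str]:
        """Genes planted to satisfy the dual >= ``threshold``-fold reduction:
        expression factor <= 1/threshold AND some linked enhancer's net
        factor <= 1/threshold.  This list is the recovery target for the
        integration pipeline."""
        cut = 1.0 / threshold
        by_gene: dict[str, list[str]] = {}
        for e in genome.enhancer_annotations:
            by_gene.setdefault(e.target_gene_id, []).append(e.enhancer_id)
        out = []
        for gene_id, expr_factor in self.affected_genes.items():
            if expr_factor > cut:
                continue
            if any(self.net_enhancer_factor(eid) <= cut for eid in by_gene.get(gene_id, [])):
                out.append(gene_id)
        return sorted(out)


def build_genome(
    n_endog_chroms: int,
    chrom_length: int,
    n_genes: int,
    n_enhancers: int,
    n_spike_chroms: int = 1,
    seed: int = 0,
    *,
    enhancer_width: int = 1000,
    enhancer_enrichment: float = 30.0,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
) -> GenomeModel:
    """Place genes and distal enhancers on a synthetic genome.

    Genes are laid out on a regular grid with at least 10 kb TSS spacing
    (an error names the constraint when they do not fit).  Each enhancer is
    assigned a distinct target gene and placed 5-100 kb downstream of its
    TSS, bounded so that its own target remains its nearest TSS and so that
    it never overlaps the target's promoter window.  Deterministic for a
    fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_enhancers > n_genes:
        raise ValueError("n_enhancers must be <= n_genes (distinct targets)")
    if n_endog_chroms < 1 or n_spike_chroms < 1:
        raise ValueError("need at least one endogenous and one spike chromosome")
    chrom_length = int(chrom_length)
    rng = np.random.default_rng(seed)

    endog = [(f"chr{i + 1}", chrom_length) for i in range(n_endog_chroms)]
    spike = [(f"{spike_prefix}{i + 1}", chrom_length) for i in range(n_spike_chroms)]

    # Distribute genes across chromosomes as evenly as possible.
    per_chrom = [n_genes // n_endog_chroms] * n_endog_chroms
    for i in range(n_genes % n_endog_chroms):
        per_chrom[i] += 1

    genes: list[GeneAnnotation] = []
    spacing_by_chrom: dict[str, int] = {}
    idx = 0
    for (chrom, length), n_here in zip(endog, per_chrom):
        if n_here == 0:
            continue
        spacing = length // (n_here + 1)
        if spacing < MIN_GENE_SPACING:
            raise ValueError(
                f"cannot place {n_here} genes on a {length} bp chromosome with "
                f">= {MIN_GENE_SPACING} bp TSS spacing (got {spacing} bp); "
                "increase chrom_length or reduce n_genes"
            )
        spacing_by_chrom[chrom] = spacing
        for j in range(n_here):
            idx += 1
            genes.append(
                GeneAnnotation(
                    gene_id=f"g{idx:04d}",
                    chrom=chrom,
                    tss=spacing * (j + 1),
                    strand=str(rng.choice(["+", "-"])),
                    baseline_expression=float(rng.lognormal(np.log(100.0), 0.5)),
                )
            )

    targets = sorted(rng.choice(n_genes, size=n_enhancers, replace=False).tolist())
    enhancers: list[EnhancerAnnotation] = []
    for k, gi in enumerate(targets):
        gene = genes[gi]
        spacing = spacing_by_chrom[gene.chrom]
        chrom_len = dict(endog)[gene.chrom]
        # Keep the enhancer nearer its own target than any neighbouring TSS
        # and clear of the target's promoter window.
        d_max = min(
            MAX_ENHANCER_OFFSET,
            (spacing - enhancer_width) // 2 - 1,
            chrom_len - gene.tss - enhancer_width - 1,
        )
        if d_max < MIN_ENHANCER_OFFSET:
            raise ValueError(
                f"cannot place a distal enhancer for gene {gene.gene_id}: "
                f"usable offset range [{MIN_ENHANCER_OFFSET}, {d_max}] bp is empty; "
                "TSS spacing too tight for distal placement"
            )
        d = int(rng.integers(MIN_ENHANCER_OFFSET, d_max + 1))
        start = gene.tss + d
        enhancers.append(
            EnhancerAnnotation(
                enhancer_id=f"e{k + 1:04d}",
                interval=GenomicInterval(gene.chrom, start, start + enhancer_width),
                target_gene_id=gene.gene_id,
                baseline_enrichment=enhancer_enrichment,
            )
        )
    return GenomeModel(endog, spike, genes, enhancers)


def _emission_components(
    genome: GenomeModel, truth: TruthTable, genotype: str, mark: str
) -> tuple[float, list[tuple[str, GenomicInterval, float]]]:
    """Background weight and per-feature (key, interval, weight) emission
    components for one sample.  Weights are in units of bp x fold-over-
    background, so the uniform background has weight = genome length."""
    ko = genotype == "KO"
    comps: list[tuple[str, GenomicInterval, float]] = []
    if mark == "H3K4me1":
        g = truth.global_depletion if ko else 1.0
        bg = genome.endog_length * g
        lengths = genome.endog_chrom_lengths
        for gene in genome.gene_annotations:
            lo = max(0, gene.tss - PROMOTER_HALFWIDTH)
            hi = min(lengths[gene.chrom], gene.tss + PROMOTER_HALFWIDTH)
            iv = GenomicInterval(gene.chrom, lo, hi)
            comps.append((f"promoter:{gene.gene_id}", iv, (PROMOTER_FOLD - 1.0) * iv.length * g))
        for enh in genome.enhancer_annotations:
            w = (enh.baseline_enrichment - 1.0) * enh.interval.length * g
            if ko:
                w *= truth.affected_enhancers.get(enh.enhancer_id, 1.0)
            comps.append((enh.enhancer_id, enh.interval, w))
    elif mark == "Kmt2d":
        bg = float(genome.endog_length)
        if not ko:  # protein absent in KO: background only
            for enh in genome.enhancer_annotations:
                if enh.enhancer_id in truth.kmt2d_bound_enhancers:
                    w = (enh.baseline_enrichment - 1.0) * enh.interval.length
                    comps.append((enh.enhancer_id, enh.interval, w))
    else:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    return bg, comps


def expected_tag_rates(
    genome: GenomeModel,
    truth: TruthTable,
    genotype: str,
    mark: str,
    depth: int,
    spike_fraction: float,
) -> dict[str, float]:
    """Closed-form expected tag counts per emission component.

    Keys: 'spike', 'background', every 'promoter:<gene>' and enhancer id.
    The expected count of feature *i* is ``depth * (1 - s) * w_i / W_WT``
    where ``W_WT`` is the unperturbed total emission weight, so the spike
    expectation is genotype-independent while endogenous expectations scale
    with the planted depletions.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    bg_wt, comps_wt = _emission_components(genome, truth, "WT", mark)
    w_wt_total = bg_wt + sum(w for _, _, w in comps_wt)
    bg_s, comps_s = _emission_components(genome, truth, genotype, mark)
    scale = depth * (1.0 - spike_fraction) / w_wt_total
    rates = {"spike": depth * spike_fraction, "background": bg_s * scale}
    for key, _, w in comps_s:
        rates[key] = w * scale
    return rates


def simulate_chip_sample(
    genome: GenomeModel,
    truth: TruthTable,
    genotype: str,
    mark: str,
    depth: int = 200_000,
    spike_fraction: float = 0.10,
    fragment_len: int = 150,
    seed: int = 0,
) -> list[AlignedTag]:
    """Simulate one ChIP sample as a list of aligned tags.

    ``depth`` is the nominal tag yield of an unperturbed sample; realized
    spike and endogenous counts are binomial draws against it (see the
    module docstring for the emission model).  Fragment length is fixed per
    sample; each tag records its 5' end and strand, with the fragment
    midpoint drawn from the emission mixture.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 < spike_fraction < 1:
        raise ValueError("spike_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    shift = fragment_len // 2

    bg_wt, comps_wt = _emission_components(genome, truth, "WT", mark)
    bg_s, comps_s = _emission_components(genome, truth, genotype, mark)
    w_wt_total = bg_wt + sum(w for _, _, w in comps_wt)
    w_s_total = bg_s + sum(w for _, _, w in comps_s)
    g_eff = w_s_total / w_wt_total

    n_spike = int(rng.binomial(int(depth), spike_fraction))
    n_endog = int(rng.binomial(int(depth), (1.0 - spike_fraction) * g_eff))

    # Spike-in tags: uniform over spike chromosomes (only their total count
    # is used downstream).
    sp_names = [n for n, _ in genome.spike_chroms]
    sp_lens = np.array([l for _, l in genome.spike_chroms], dtype=float)
    sp_choice = rng.choice(len(sp_names), size=n_spike, p=sp_lens / sp_lens.sum())
    spike_chroms = np.array(sp_names, dtype=object)[sp_choice]
    spike_pos = np.floor(rng.random(n_spike) * sp_lens[sp_choice]).astype(np.int64)

    # Endogenous tags: background vs feature mixture.
    weights = np.array([bg_s] + [w for _, _, w in comps_s], dtype=float)
    comp = rng.choice(len(weights), size=n_endog, p=weights / weights.sum())
    en_names = [n for n, _ in genome.endogenous_chroms]
    en_lens = np.array([l for _, l in genome.endogenous_chroms], dtype=float)
    endog_chroms = np.empty(n_endog, dtype=object)
    endog_pos = np.empty(n_endog, dtype=np.int64)
    bg_mask = comp == 0
    n_bg = int(bg_mask.sum())
    bg_choice = rng.choice(len(en_names), size=n_bg, p=en_lens / en_lens.sum())
    endog_chroms[bg_mask] = np.array(en_names, dtype=object)[bg_choice]
    endog_pos[bg_mask] = np.floor(rng.random(n_bg) * en_lens[bg_choice]).astype(np.int64)
    if comps_s:
        f_idx = comp[~bg_mask] - 1
        starts = np.array([c[1].start for c in comps_s], dtype=np.int64)
        lens = np.array([c[1].length for c in comps_s], dtype=np.int64)
        f_chroms = np.array([c[1].chrom for c in comps_s], dtype=object)
        endog_chroms[~bg_mask] = f_chroms[f_idx]
        endog_pos[~bg_mask] = starts[f_idx] + np.floor(
            rng.random(f_idx.size) * lens[f_idx]
        ).astype(np.int64)

    chroms = np.concatenate([spike_chroms, endog_chroms])
    centers = np.concatenate([spike_pos, endog_pos])
    is_spike = np.concatenate(
        [np.ones(n_spike, dtype=bool), np.zeros(n_endog, dtype=bool)]
    )
    strands = rng.integers(0, 2, size=chroms.size)  # 0 -> '+', 1 -> '-'
    p5 = np.where(strands == 0, centers - shift, centers + shift)
    lengths_map = genome.all_chrom_lengths
    chrom_len = np.fromiter((lengths_map[c] for c in chroms), dtype=np.int64, count=chroms.size)
    p5 = np.clip(p5, 0, chrom_len - 1)

    return [
        AlignedTag(
            interval=GenomicInterval(str(c), int(p), int(p) + 1),
            strand="+" if s == 0 else "-",
            is_spike=bool(sp),
        )
        for c, p, s, sp in zip(chroms, p5, strands, is_spike)
    ]


def simulate_rna_counts(
    genome: GenomeModel,
    truth: TruthTable,
    n_reps: int = 3,
    dispersion: float = 0.05,
    lib_size: int = 5_000_000,
    seed: int = 0,
) -> CountTable:
    """Bulk RNA-seq counts: negative binomial per gene, genes x samples.

    WT mean of gene *g* is ``baseline_g / sum(baselines) * lib_size``; the
    KO mean multiplies in the planted expression factor, so the expected
    KO/WT mean ratio equals the factor exactly.  ``dispersion`` is the NB
    alpha (variance = mu + alpha mu^2); 0 degenerates to Poisson.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = genome.gene_annotations
    base = np.array([g.baseline_expression for g in genes], dtype=float)
    mu_wt = base / base.sum() * lib_size
    factors = np.array([truth.affected_genes.get(g.gene_id, 1.0) for g in genes])
    mu_ko = mu_wt * factors

    def draw(mu: np.ndarray, n: int) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu[:, None], size=(mu.size, n))
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(mu.size, n))

    data = np.hstack([draw(mu_wt, n_reps), draw(mu_ko, n_reps)])
    samples = [f"WT_{i + 1}" for i in range(n_reps)] + [f"KO_{i + 1}" for i in range(n_reps)]
    df = pd.DataFrame(data, index=[g.gene_id for g in genes], columns=samples)
    return CountTable(df)


def simulate_sc_counts(
    genome: GenomeModel,
    truth: TruthTable,
    n_cells_per_cluster: int = 200,
    dropout: float = 0.0,
    seed: int = 0,
    cell_depth: int = 2000,
) -> tuple[CountTable, pd.Series]:
    """Two-cluster single-cell counts (cells x genes) plus cluster labels.

    Cluster 2 ("stimulated") cells have the planted signature fold factors
    applied to their per-gene Poisson means; every entry is then zeroed
    independently with probability ``dropout``.
    """
    if n_cells_per_cluster < 3:
        raise ValueError("n_cells_per_cluster must be >= 3 (t-test needs >= 2 per group)")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = genome.gene_annotations
    base = np.array([g.baseline_expression for g in genes], dtype=float)
    mu1 = base / base.sum() * cell_depth
    sig = np.array([truth.sc_cluster2_signature.get(g.gene_id, 1.0) for g in genes])
    mu2 = mu1 * sig

    n = n_cells_per_cluster
    counts = np.vstack(
        [
            rng.poisson(mu1[None, :], size=(n, mu1.size)),
            rng.poisson(mu2[None, :], size=(n, mu2.size)),
        ]
    )
    if dropout > 0:
        keep = rng.random(counts.shape) >= dropout
        counts = counts * keep
    cells = [f"{SC_CLUSTERS[0]}_{i + 1:04d}" for i in range(n)] + [
        f"{SC_CLUSTERS[1]}_{i + 1:04d}" for i in range(n)
    ]
    labels = pd.Series([SC_CLUSTERS[0]] * n + [SC_CLUSTERS[1]] * n, index=cells, name="label")
    df = pd.DataFrame(counts, index=cells, columns=[g.gene_id for g in genes])
    return CountTable(df), labels


def default_scenario(
    seed: int,
    *,
    n_endog_chroms: int = 2,
    chrom_length: int = 10_000_000,
    n_genes: int = 1000,
    n_enhancers: int = 1000,
    n_affected: int = 100,
    effect: float = 0.4,
    global_depletion: float = 1.0,
    kmt2d_bound_frac: float = 0.6,
    n_sc_signature: int = 50,
    sc_fold: float = 3.0,
) -> tuple[GenomeModel, TruthTable]:
    """The package's reference study scenario.

    1000 genes, one distal enhancer each, on a 20 Mb two-chromosome genome
    with a 10 Mb spike genome; 100 planted dual-effect genes whose enhancer
    and expression are both depleted to 0.4 (a 2.5-fold reduction); 60% of
    both affected and unaffected enhancers bound by Kmt2d (stratified, so
    the bound fraction among affected enhancers is exact); a 50-gene fold-3
    single-cell signature in the stimulated cluster.
    """
    genome = build_genome(
        n_endog_chroms, chrom_length, n_genes, n_enhancers, n_spike_chroms=1, seed=seed
    )
    rng = np.random.default_rng(seed + 1_000_003)
    enh_ids = [e.enhancer_id for e in genome.enhancer_annotations]
    affected = sorted(rng.choice(len(enh_ids), size=n_affected, replace=False).tolist())
    affected_ids = [enh_ids[i] for i in affected]
    rest_ids = [eid for eid in enh_ids if eid not in set(affected_ids)]
    by_id = genome.enhancers_by_id
    affected_enhancers = {eid: effect for eid in affected_ids}
    affected_genes = {by_id[eid].target_gene_id: effect for eid in affected_ids}

    n_bound_aff = int(round(kmt2d_bound_frac * len(affected_ids)))
    n_bound_rest = int(round(kmt2d_bound_frac * len(rest_ids)))
    bound = set(
        np.array(affected_ids, dtype=object)[
            rng.choice(len(affected_ids), size=n_bound_aff, replace=False)
        ].tolist()
    )
    if rest_ids:
        bound |= set(
            np.array(rest_ids, dtype=object)[
                rng.choice(len(rest_ids), size=n_bound_rest, replace=False)
            ].tolist()
        )
    gene_ids = [g.gene_id for g in genome.gene_annotations]
    sig_idx = rng.choice(len(gene_ids), size=n_sc_signature, replace=False)
    signature = {gene_ids[i]: sc_fold for i in sorted(sig_idx.tolist())}

    truth = TruthTable(
        global_depletion=global_depletion,
        affected_enhancers=affected_enhancers,
        affected_genes=affected_genes,
        kmt2d_bound_enhancers=bound,
        sc_cluster2_signature=signature,
    )
    return genome, truth


def truth_to_frame(truth: TruthTable) -> pd.DataFrame:
    """Serialize a truth table to a tidy (kind, id, value) frame."""
    rows = [("global_depletion", "", truth.global_depletion)]
    rows += [("enhancer_factor", k, v) for k, v in sorted(truth.affected_enhancers.items())]
    rows += [("gene_factor", k, v) for k, v in sorted(truth.affected_genes.items())]
    rows += [("kmt2d_bound", k, 1.0) for k in sorted(truth.kmt2d_bound_enhancers)]
    rows += [("sc_signature", k, v) for k, v in sorted(truth.sc_cluster2_signature.items())]
    return pd.DataFrame(rows, columns=["kind", "id", "value"])


def truth_from_frame(df: pd.DataFrame) -> TruthTable:
    truth = TruthTable()
    for row in df.itertuples(index=False):
        if row.kind == "global_depletion":
            truth.global_depletion = float(row.value)
        elif row.kind == "enhancer_factor":
            truth.affected_enhancers[row.id] = float(row.value)
        elif row.kind == "gene_factor":
            truth.affected_genes[row.id] = float(row.value)
        elif row.kind == "kmt2d_bound":
            truth.kmt2d_bound_enhancers.add(row.id)
        elif row.kind == "sc_signature":
            truth.sc_cluster2_signature[row.id] = float(row.value)
        else:
            raise ValueError(f"unknown truth-table kind {row.kind!r}")
    return truth
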