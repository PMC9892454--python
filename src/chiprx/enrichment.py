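"""Downstream enrichment statistics: GSEA and the single-cell DE filter.

GSEA uses the classic weighted Kolmogorov-Smirnov running sum over a
ranked gene list; hits add ``|metric|^p`` (normalized over hits), misses
subtract ``1/(N - N_hits)``, and the enrichment score (ES) is the running
sum's signed maximum deviation from zero.  The normalized score (NES)
divides the ES by the mean magnitude of same-sign null scores from random
same-size gene sets (gene-tag permutation), with a one-sided empirical
p-value (+1 smoothing) and Benjamini-Hochberg q across sets.  A set is
reported significant when NES >= 1.5 and q < 0.10 (configurable).

The single-cell filter flags a gene as differentially expressed in a
cluster when it is expressed in at least 30% of that cluster's cells, its
mean fold change is at least 1.2, and the Benjamini-Hochberg FDR of a
two-sample Student's t-test (equal variance) on log-normalized expression
is at most 5% - all three boundaries inclusive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by a signed metric, descending; ties broken by id."""

    gene_ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.metric):
            raise ValueError("gene_ids and metric must have equal length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        self.metric = np.asarray(self.metric, dtype=float)
        order = sorted(range(len(self.gene_ids)), key=lambda i: (-self.metric[i], self.gene_ids[i]))
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.metric = self.metric[order]

    @classmethod
    def from_mapping(cls, scores: Mapping[str, float] | pd.Series) -> "RankedList":
        s = pd.Series(scores, dtype=float)
        return cls(list(s.index), s.to_numpy())

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list[str]
    significant: bool = False


def _running_sum(metric: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> np.ndarray:
    n = metric.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hits == n:
        raise ValueError("gene set equals the universe (miss denominator zero)")
    w = np.abs(metric) ** weight_p
    w_hits = np.where(hit_mask, w, 0.0)
    total = w_hits.sum()
    if total == 0:
        # All hit metrics are exactly zero: fall back to unweighted hits.
        w_hits = hit_mask.astype(float)
        total = w_hits.sum()
    steps = w_hits / total - (~hit_mask) / (n - n_hits)
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, running-sum profile, and leading-edge genes for one set.

    ES is the running sum's value at its first maximum absolute deviation;
    the leading edge holds the hit genes up to (resp. from) the extremum
    for positive (negative) ES.
    """
    hit_mask = np.array([g in gene_set.members for g in ranked.gene_ids])
    running = _running_sum(ranked.metric, hit_mask, weight_p)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.gene_ids) if hit_mask[i] and i <= peak]
    else:
        leading = [g for i, g in enumerate(ranked.gene_ids) if hit_mask[i] and i >= peak]
    return es, running, leading


def permutation_nes(
    ranked: RankedList,
    sets: Sequence[GeneSet],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    nes_threshold: float = 1.5,
    q_threshold: float = 0.10,
) -> list[EnrichmentResult]:
    """Permutation-normalized enrichment across gene sets.

    The null for each set is the ES of ``n_perm`` random same-size gene
    sets drawn from the ranked universe (gene-tag permutation; phenotype
    permutation is degenerate at the replicate counts this pipeline sees).
    Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    universe = set(ranked.gene_ids)
    null_cache: dict[int, np.ndarray] = {}

    results: list[EnrichmentResult] = []
    for gs in sets:
        members = frozenset(gs.members & universe)
        if len(members) < len(gs.members):
            logger.info(
                "set %s trimmed to %d/%d genes in the universe",
                gs.set_id, len(members), len(gs.members),
            )
        if not members:
            raise ValueError(f"gene set {gs.set_id!r} does not intersect the universe")
        k = len(members)
        if k > n // 2:
            logger.warning("set %s covers more than half the universe; null unstable", gs.set_id)
        es, _, leading = enrichment_score(ranked, GeneSet(gs.set_id, members), weight_p)
        if k not in null_cache:
            null = np.empty(n_perm)
            mask = np.zeros(n, dtype=bool)
            for b in range(n_perm):
                mask[:] = False
                mask[rng.choice(n, size=k, replace=False)] = True
                running = _running_sum(ranked.metric, mask, weight_p)
                null[b] = running[np.argmax(np.abs(running))]
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes, p = 0.0, 1.0
        else:
            nes = float(es / np.abs(same_sign).mean())
            p = float((1 + (np.abs(same_sign) >= abs(es)).sum()) / (1 + same_sign.size))
        results.append(EnrichmentResult(gs.set_id, es, nes, p, 1.0, leading))
    qvals = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.q = float(q)
        r.significant = bool(r.nes >= nes_threshold and r.q < q_threshold)
    return results


def sc_de_filter(
    counts,
    labels: Mapping[str, str] | pd.Series,
    target_cluster: str,
    min_pct: float = 0.30,
    min_fc: float = 1.2,
    fdr: float = 0.05,
    equal_var: bool = True,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Cluster DE filter on a cell-by-gene count matrix.

    Counts are normalized per cell to ``target_sum`` and log1p-transformed;
    the t-test (Student's equal-variance by default, Welch behind the flag)
    compares the target cluster against all remaining cells on the
    log-normalized scale.  Fold change is the ratio of mean normalized
    expression with a pseudo-count of 1 (the same offset log1p implies).

    Returns a frame indexed by gene: pct_target, pct_rest, fold_change,
    t, p, q, is_de.
    """
    data = counts.data if hasattr(counts, "data") else pd.DataFrame(counts)
    labels = pd.Series(labels)
    labels = labels.reindex(data.index)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    if target_cluster not in set(labels):
        raise ValueError(f"cluster label {target_cluster!r} absent from labels")
    in_mask = (labels == target_cluster).to_numpy()
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError("need at least 2 cells per group")

    raw = data.to_numpy(dtype=float)
    cell_tot = raw.sum(axis=1, keepdims=True)
    cell_tot[cell_tot == 0] = 1.0
    norm = raw / cell_tot * target_sum
    logn = np.log1p(norm)

    pct_target = (raw[in_mask] > 0).mean(axis=0)
    pct_rest = (raw[~in_mask] > 0).mean(axis=0)
    fold = (norm[in_mask].mean(axis=0) + 1.0) / (norm[~in_mask].mean(axis=0) + 1.0)
    t, p = stats.ttest_ind(logn[in_mask], logn[~in_mask], axis=0, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    is_de = (pct_target >= min_pct) & (fold >= min_fc) & (q <= fdr)
    return pd.DataFrame(
        {
            "pct_target": pct_target,
            "pct_rest": pct_rest,
            "fold_change": fold,
            "t": np.where(np.isnan(t), 0.0, t),
            "p": p,
            "q": q,
            "is_de": is_de,
        },
        index=data.columns,
    )
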