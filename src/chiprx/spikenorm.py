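"""Spike-in (ChIP-Rx) normalization.

Exogenous chromatin is added to every ChIP at a fixed fraction of total
material, so the exogenous tag COUNT is the per-sample yardstick: scale
factors are ratios of spike counts, invariant to endogenous read content.
This makes global endogenous shifts visible that per-library CPM scaling
would silently renormalize away.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import AlignedTag

logger = logging.getLogger(__name__)


@dataclass
class SpikePartition:
    """Tags split by species, order preserved within each part."""

    endogenous: list[AlignedTag]
    spike: list[AlignedTag]

    @property
    def n_endog(self) -> int:
        return len(self.endogenous)

    @property
    def n_spike(self) -> int:
        return len(self.spike)


@dataclass
class ScaleFactorSet:
    """Per-sample spike-derived multipliers; the reference sample has scale 1."""

    scales: dict[str, float]
    reference_sample: str

    def __post_init__(self) -> None:
        if self.reference_sample not in self.scales:
            raise ValueError("reference sample missing from scales")
        if abs(self.scales[self.reference_sample] - 1.0) > 1e-12:
            raise ValueError("reference sample must have scale 1")
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("all scale factors must be > 0")

    def scale(self, sample_id: str) -> float:
        if sample_id not in self.scales:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.scales[sample_id]


def partition_tags(tags: Sequence[AlignedTag]) -> SpikePartition:
    """Partition tags by their ``is_spike`` flag.  Counts are conserved.

    A partition with zero spike tags is returned with a warning; it becomes
    fatal only when scale factors are requested.
    """
    if not tags:
        raise ValueError("cannot partition an empty tag list")
    endog = [t for t in tags if not t.is_spike]
    spike = [t for t in tags if t.is_spike]
    if not spike:
        logger.warning("no spike-in tags found; spike normalization will be impossible")
    return SpikePartition(endogenous=endog, spike=spike)


def compute_scale_factors(
    spike_counts: Mapping[str, int], reference: str = "auto"
) -> ScaleFactorSet:
    """Scale factor of sample s = n_spike(reference) / n_spike(s).

    ``reference="auto"`` picks the sample with the smallest spike count, so
    every scale is <= 1 and scaling only down-weights (never inflates a
    sparse sample).
    """
    if not spike_counts:
        raise ValueError("no samples given")
    for sid, n in spike_counts.items():
        if n <= 0:
            raise ValueError(
                f"sample {sid!r} has {n} spike-in tags: spike normalization is "
                "impossible without exogenous reads in every sample"
            )
    if reference == "auto":
        reference = min(spike_counts, key=lambda s: (spike_counts[s], s))
    elif reference not in spike_counts:
        raise KeyError(f"reference sample {reference!r} not among samples")
    ref_count = spike_counts[reference]
    scales = {sid: ref_count / n for sid, n in spike_counts.items()}
    return ScaleFactorSet(scales=scales, reference_sample=reference)


def scaled_signal(counts, sample_id: str, factors: ScaleFactorSet) -> np.ndarray:
    """Multiply raw per-region counts of one sample by its spike scale.

    Linear by construction: scaled(a + b) = scaled(a) + scaled(b).
    """
    return np.asarray(counts, dtype=float) * factors.scale(sample_id)
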