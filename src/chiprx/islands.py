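"""Broad-domain island calling for histone marks, SICER-style.

The genome is tiled with fixed non-overlapping windows; a window is
*eligible* when its tag count reaches the smallest count whose upper-tail
Poisson probability under the genome-wide background rate falls below the
eligibility p-value.  Islands are maximal clusters of eligible windows in
which consecutive eligible windows are separated by at most ``gap_size`` bp
of ineligible windows.  An island's score is the sum over its eligible
windows of -ln Poisson(count; background rate).

Significance is assessed either against a control sample (per-island
upper-tail Poisson p with a library-size-scaled control expectation,
Benjamini-Hochberg across islands) or, without a control, by a score
threshold calibrated so that the expected number of background islands
does not exceed a configured E-value.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AlignedTag, GenomicInterval, shifted_positions
from .spikenorm import ScaleFactorSet

logger = logging.getLogger(__name__)

#: Fixed seed for the Monte-Carlo background-score calibration, so that
#: repeated calls (and repeated pipeline runs) are byte-reproducible.
_CALIBRATION_SEED = 20_200_615


@dataclass
class IslandCallParams:
    """Tunable island-calling parameters.

    window_size/gap_size in bp (gap must be a multiple of the window);
    eligibility_p is the per-window Poisson p-value cut; fragment_shift
    moves each tag's 5' end toward the fragment midpoint; fdr applies to
    control-based calls, evalue to control-free calls.
    """

    window_size: int = 200
    gap_size: int = 200
    eligibility_p: float = 0.2
    fragment_shift: int = 75
    fdr: float = 0.05
    evalue: float = 100.0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        if self.gap_size < 0 or self.gap_size % self.window_size != 0:
            raise ValueError("gap_size must be >= 0 and a multiple of window_size")
        if not 0 < self.eligibility_p <= 1:
            raise ValueError("eligibility_p must be in (0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")


#: Parameters used for the enzyme (Kmt2d) mark: 50 bp windows and gaps.
KMT2D_PARAMS = dict(window_size=50, gap_size=50)


@dataclass
class WindowTrack:
    """Per-chromosome fixed-window tag counts."""

    chrom: str
    window_size: int
    counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.counts.size)


@dataclass
class Island:
    """A maximal cluster of eligible windows (grid-aligned interval)."""

    interval: GenomicInterval
    n_eligible_windows: int
    tag_count: int
    score: float = 0.0
    control_count: Optional[int] = None
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    fold_change: Optional[float] = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def deduplicate_tags(tags: Sequence[AlignedTag], max_per_position: int = 1) -> list[AlignedTag]:
    """Keep at most ``max_per_position`` tags per exact (chrom, 5' position,
    strand), preserving order - a minimal PCR-duplicate filter."""
    seen: dict[tuple, int] = {}
    out = []
    for t in tags:
        key = (t.interval.chrom, t.position5p, t.strand)
        c = seen.get(key, 0)
        if c < max_per_position:
            out.append(t)
            seen[key] = c + 1
    return out


def count_windows(
    tags: Sequence[AlignedTag],
    chrom_lengths: Mapping[str, int],
    params: IslandCallParams,
) -> dict[str, WindowTrack]:
    """Assign each tag to a fixed window on its chromosome.

    Tag position = 5' end shifted ``fragment_shift`` bp toward the 3' end
    (strand-aware); window ordinal = floor(position / window_size).
    Positions shifted beyond the chromosome are clamped to the last base
    (counted and logged).  Every known chromosome gets a track, so tag
    conservation holds: sum of all window counts = number of tags.
    """
    w = params.window_size
    tracks = {
        chrom: WindowTrack(chrom, w, np.zeros((length + w - 1) // w, dtype=np.int64))
        for chrom, length in chrom_lengths.items()
    }
    if not tags:
        return tracks
    chroms, pos = shifted_positions(tags, params.fragment_shift)
    n_clamped = 0
    for chrom in np.unique(chroms):
        if chrom not in chrom_lengths:
            raise ValueError(f"tags on unknown chromosome {chrom!r}")
        p = pos[chroms == chrom]
        length = chrom_lengths[chrom]
        n_clamped += int(((p < 0) | (p >= length)).sum())
        p = np.clip(p, 0, length - 1)
        idx = p // w
        tracks[chrom].counts += np.bincount(idx, minlength=tracks[chrom].n_windows)
    if n_clamped:
        logger.warning("%d shifted tag positions clamped to chromosome bounds", n_clamped)
    return tracks


def eligibility_threshold(lambda_bg: float, p0: float) -> int:
    """Smallest integer c with upper-tail Poisson P(X >= c; lambda) <= p0."""
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be > 0")
    if not 0 < p0 <= 1:
        raise ValueError("p0 must be in (0, 1]")
    c = 0
    # sf(c-1) = P(X >= c); the loop terminates because the tail -> 0.
    while stats.poisson.sf(c - 1, lambda_bg) > p0:
        c += 1
        if c > 10_000_000:  # pragma: no cover - defensive
            raise RuntimeError("eligibility threshold search did not converge")
    return c


def find_islands(
    track: WindowTrack, threshold: int, params: IslandCallParams
) -> list[Island]:
    """Cluster eligible windows into gap-tolerant islands (unscored).

    The island interval spans the first to the last eligible window;
    ``tag_count`` sums ALL windows inside the interval, gap windows
    included.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    w = params.window_size
    max_gap_windows = params.gap_size // w
    eligible = np.flatnonzero(track.counts >= threshold)
    if eligible.size == 0:
        return []
    # Split where more than max_gap_windows ineligible windows intervene.
    breaks = np.flatnonzero(np.diff(eligible) > max_gap_windows + 1)
    groups = np.split(eligible, breaks + 1)
    islands = []
    for grp in groups:
        first, last = int(grp[0]), int(grp[-1])
        islands.append(
            Island(
                interval=GenomicInterval(track.chrom, first * w, (last + 1) * w),
                n_eligible_windows=int(grp.size),
                tag_count=int(track.counts[first : last + 1].sum()),
            )
        )
    return islands


def score_island(
    island: Island, track: WindowTrack, lambda_bg: float, threshold: int
) -> float:
    """Island score: sum over eligible windows of -ln Poisson(count; lambda).

    Additive over windows and non-negative whenever each pmf term <= 1.
    """
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be > 0")
    w = track.window_size
    counts = track.counts[island.start // w : island.end // w]
    counts = counts[counts >= threshold]
    return float(-stats.poisson.logpmf(counts, lambda_bg).sum())


def background_score_threshold(
    lambda_bg: float,
    threshold: int,
    params: IslandCallParams,
    n_windows_real: int,
    n_sim: int = 500_000,
) -> float:
    """Monte-Carlo score cut so that the expected number of pure-background
    islands reaching it in ``n_windows_real`` windows is <= params.evalue.

    A fixed internal seed keeps the calibration deterministic across runs.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    sim = WindowTrack("_sim", params.window_size, rng.poisson(lambda_bg, size=n_sim))
    islands = find_islands(sim, threshold, params)
    scores = np.sort(
        np.array([score_island(i, sim, lambda_bg, threshold) for i in islands])
    )[::-1]
    k = int(params.evalue * n_sim / max(n_windows_real, 1))
    if k >= scores.size:
        return 0.0
    if k == 0:
        return float(scores[0]) + 1e-6 if scores.size else 0.0
    return float(scores[k - 1])


def _poisson_sf(count: int, lam: float) -> float:
    return float(stats.poisson.sf(count - 1, lam))


def call_islands_from_tracks(
    chip_tracks: Mapping[str, WindowTrack],
    control_tracks: Optional[Mapping[str, WindowTrack]],
    chip_lib: int,
    control_lib: int,
    lambda_bg: float,
    params: IslandCallParams,
) -> list[Island]:
    """Core island call on precomputed window tracks (see module docstring).

    With control tracks: per-island p = upper-tail Poisson with expectation
    control-count-in-island x (chip_lib / control_lib), a zero control
    count replaced by a pseudo-count of 1; q by Benjamini-Hochberg across
    all islands; keep q <= params.fdr.  Without control: keep islands whose
    score reaches the E-value-calibrated background threshold.
    """
    threshold = eligibility_threshold(lambda_bg, params.eligibility_p)
    islands: list[Island] = []
    for chrom in sorted(chip_tracks):
        track = chip_tracks[chrom]
        for isl in find_islands(track, threshold, params):
            isl.score = score_island(isl, track, lambda_bg, threshold)
            islands.append(isl)
    if not islands:
        return []
    if control_tracks is not None:
        ratio = chip_lib / control_lib
        w = params.window_size
        for isl in islands:
            ctrack = control_tracks[isl.chrom]
            ctrl = int(ctrack.counts[isl.start // w : isl.end // w].sum())
            isl.control_count = ctrl
            lam = max(ctrl, 1) * ratio
            isl.p_value = _poisson_sf(isl.tag_count, lam)
        pvals = np.array([isl.p_value for isl in islands])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for isl, q in zip(islands, qvals):
            isl.q_value = float(q)
        kept = [isl for isl in islands if isl.q_value <= params.fdr]
    else:
        n_windows = sum(t.n_windows for t in chip_tracks.values())
        cut = background_score_threshold(lambda_bg, threshold, params, n_windows)
        kept = [isl for isl in islands if isl.score >= cut]
    kept.sort(key=lambda i: (i.chrom, i.start))
    return kept


def call_significant_islands(
    chip_tags: Sequence[AlignedTag],
    control_tags: Optional[Sequence[AlignedTag]] = None,
    params: Optional[IslandCallParams] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    effective_genome_length: Optional[int] = None,
    deduplicate: bool = True,
) -> list[Island]:
    """End-to-end island call from aligned tags.

    Spike-in tags are excluded up front; redundant tags (same chromosome,
    5' position and strand) are collapsed to one unless ``deduplicate`` is
    False.  The background rate is estimated as endogenous tag count x
    window_size / effective genome length (total endogenous length by
    default).
    """
    if params is None:
        params = IslandCallParams()
    if chrom_lengths is None:
        raise ValueError("chrom_lengths is required (endogenous chromosomes)")
    chip = [t for t in chip_tags if not t.is_spike]
    if deduplicate:
        chip = deduplicate_tags(chip)
    if not chip:
        raise ValueError("no endogenous ChIP tags")
    effective = effective_genome_length or sum(chrom_lengths.values())
    lambda_bg = len(chip) * params.window_size / effective
    chip_tracks = count_windows(chip, chrom_lengths, params)
    control_tracks = None
    control_lib = 0
    if control_tags is not None:
        control = [t for t in control_tags if not t.is_spike]
        if deduplicate:
            control = deduplicate_tags(control)
        if not control:
            raise ValueError("control sample provided but contains no endogenous tags")
        control_tracks = count_windows(control, chrom_lengths, params)
        control_lib = len(control)
    return call_islands_from_tracks(
        chip_tracks, control_tracks, len(chip), control_lib, lambda_bg, params
    )


def count_tags_in_intervals(
    tags: Sequence[AlignedTag],
    intervals: Sequence[GenomicInterval],
    fragment_shift: int = 75,
) -> np.ndarray:
    """Number of (shifted) tag positions falling in each interval."""
    chroms, pos = shifted_positions(tags, fragment_shift)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms):
        by_chrom[chrom] = np.sort(pos[chroms == chrom])
    out = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        p = by_chrom.get(iv.chrom)
        if p is None:
            continue
        out[i] = np.searchsorted(p, iv.end, side="left") - np.searchsorted(
            p, iv.start, side="left"
        )
    return out


def differential_island_fc(
    islands: Sequence[Island],
    tags_by_sample: Mapping[str, Sequence[AlignedTag]],
    factors: ScaleFactorSet,
    wt_sample: str,
    ko_sample: str,
    fragment_shift: int = 75,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Spike-scaled WT/KO fold change per island (attached to each island).

    fc = (scaled WT count + eps) / (scaled KO count + eps), eps = 0.5, so a
    reduction in the KO gives fc > 1.
    """
    sample_chroms = set()
    for sid in (wt_sample, ko_sample):
        for t in tags_by_sample[sid]:
            sample_chroms.add(t.interval.chrom)
    for isl in islands:
        if isl.chrom not in sample_chroms:
            raise ValueError(
                f"island on {isl.chrom!r} lies outside both samples' chromosomes"
            )
    ivs = [isl.interval for isl in islands]
    wt_endog = [t for t in tags_by_sample[wt_sample] if not t.is_spike]
    ko_endog = [t for t in tags_by_sample[ko_sample] if not t.is_spike]
    wt = count_tags_in_intervals(wt_endog, ivs, fragment_shift) * factors.scale(wt_sample)
    ko = count_tags_in_intervals(ko_endog, ivs, fragment_shift) * factors.scale(ko_sample)
    fc = (wt + pseudocount) / (ko + pseudocount)
    for isl, f in zip(islands, fc):
        isl.fold_change = float(f)
    return fc
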