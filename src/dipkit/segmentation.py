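"""Sliding-window segmentation of DIP-Seq tag enrichment.

Enriched regions are found by counting tags in fixed-width sliding
windows (default 1000 bp, stepped by half a window), building an
empirical null distribution of window counts by Monte-Carlo permutation
of tag positions (uniform redraw within each chromosome, preserving the
per-chromosome tag count), and merging windows whose empirical tail
probability falls below ``alpha``.

The permutation null is pooled over all windows and permutations;
empirical tail probabilities use the standard ``(1 + #null >= c) /
(1 + N)`` convention so they are always in (0, 1].  Trailing partial
windows are kept: their counts are rescaled to full-window equivalents
before any tail lookup, identically for observed and permuted data.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np

from .genomic_io import GenomicInterval, TagSet


@dataclasses.dataclass
class WindowCounts:
    """Tag counts in sliding windows tiling one genome.

    Per chromosome: window start/end arrays and the tag count of each
    window (a tag at position p contributes to every window containing
    p).  ``partial`` flags windows truncated at the chromosome end.
    """

    window_bp: int
    step_bp: int
    genome: dict[str, int]
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    partial: dict[str, np.ndarray]

    @property
    def n_windows(self) -> int:
        return sum(arr.size for arr in self.counts.values())

    def all_counts(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.genome]) if self.genome else np.empty(0)

    def scaled_counts(self, chrom: str) -> np.ndarray:
        """Counts rescaled to full-window equivalents for partial windows."""
        c = self.counts[chrom].astype(float)
        width = self.ends[chrom] - self.starts[chrom]
        return np.where(
            self.partial[chrom], np.round(c * self.window_bp / width), c
        )


def _window_grid(chrom_len: int, window_bp: int, step_bp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if window_bp >= chrom_len:
        warnings.warn(
            f"window ({window_bp} bp) >= chromosome length ({chrom_len} bp); "
            "using a single whole-chromosome window"
        )
        starts = np.array([0], dtype=np.int64)
        ends = np.array([chrom_len], dtype=np.int64)
        return starts, ends, np.array([window_bp > chrom_len])
    starts = np.arange(0, chrom_len, step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, chrom_len)
    partial = ends - starts < window_bp
    return starts, ends, partial


def _count_grid(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    return (hi - lo).astype(np.int64)


def count_windows(tags: TagSet, window_bp: int = 1000, step_bp: int = 500) -> WindowCounts:
    """Count tags in sliding windows over every chromosome of ``tags``.

    Requires ``window_bp >= step_bp >= 1`` so that windows tile the
    chromosome without gaps.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("require window_bp >= step_bp >= 1")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    partial: dict[str, np.ndarray] = {}
    for chrom, length in tags.genome.items():
        s, e, part = _window_grid(length, window_bp, step_bp)
        starts[chrom], ends[chrom], partial[chrom] = s, e, part
        counts[chrom] = _count_grid(tags.positions(chrom), s, e)
    return WindowCounts(window_bp, step_bp, dict(tags.genome), starts, ends, counts, partial)


class MonteCarloNull:
    """Pooled empirical null distribution of window counts.

    ``tail_counts[c]`` holds the number of null windows with (scaled)
    count >= c; tail probabilities use the +1 permutation convention.
    """

    def __init__(self, count_histogram: np.ndarray, window_bp: int, step_bp: int,
                 n_permutations: int) -> None:
        self.histogram = count_histogram.astype(np.int64)
        self.n_null = int(self.histogram.sum())
        # tail_counts[c] = # null windows with count >= c
        self.tail_counts = self.histogram[::-1].cumsum()[::-1]
        self.window_bp = window_bp
        self.step_bp = step_bp
        self.n_permutations = n_permutations

    def tail_prob(self, counts: np.ndarray | int) -> np.ndarray:
        """Empirical P(null count >= c) with the (1+k)/(1+N) convention."""
        c = np.atleast_1d(np.asarray(counts, dtype=np.int64))
        c = np.clip(c, 0, None)
        k = np.where(c < self.tail_counts.size, self.tail_counts[np.minimum(c, self.tail_counts.size - 1)], 0)
        return (1.0 + k) / (1.0 + self.n_null)

    def quantile_table(self) -> dict[int, float]:
        """Per-count upper-tail probabilities (for reporting/serialization)."""
        return {int(c): float(self.tail_prob(c)[0]) for c in range(self.tail_counts.size)}


def monte_carlo_null(
    tags: TagSet,
    window_bp: int = 1000,
    step_bp: int = 500,
    n_permutations: int = 100,
    seed: int = 0,
) -> MonteCarloNull:
    """Build the permutation null of window counts for one tag library.

    Each permutation redraws every tag position uniformly within its
    chromosome (per-chromosome tag counts preserved), recounts all
    windows, and pools the counts into one empirical distribution.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if tags.n_tags == 0:
        raise ValueError("cannot build a permutation null from zero tags")
    rng = np.random.default_rng(seed)
    hist = np.zeros(1, dtype=np.int64)
    grids = {
        chrom: _window_grid(length, window_bp, step_bp)
        for chrom, length in tags.genome.items()
    }
    for _ in range(n_permutations):
        for chrom, length in tags.genome.items():
            n = tags.positions(chrom).size
            s, e, part = grids[chrom]
            if n == 0:
                cnt = np.zeros(s.size, dtype=np.int64)
            else:
                pos = np.sort(rng.integers(0, length, size=n))
                cnt = _count_grid(pos, s, e)
            if part.any():
                width = e - s
                cnt = np.where(part, np.round(cnt * window_bp / width).astype(np.int64), cnt)
            h = np.bincount(cnt)
            if h.size > hist.size:
                h[: hist.size] += hist
                hist = h
            else:
                hist[: h.size] += h
    return MonteCarloNull(hist, window_bp, step_bp, n_permutations)


@dataclasses.dataclass
class EnrichedRegion:
    interval: GenomicInterval
    max_window_count: int
    empirical_p: float


@dataclasses.dataclass
class EnrichedRegionSet:
    """Non-overlapping enriched regions for one library and mark."""

    regions: list[EnrichedRegion]
    mark: str
    library_id: str
    null_quantiles: dict[int, float]

    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def window_pvalues(obs: WindowCounts, null: MonteCarloNull) -> dict[str, np.ndarray]:
    """Empirical tail probability of each observed window count."""
    if (obs.window_bp, obs.step_bp) != (null.window_bp, null.step_bp):
        raise ValueError("null was built with different window/step settings")
    return {
        chrom: null.tail_prob(obs.scaled_counts(chrom).astype(np.int64))
        for chrom in obs.genome
    }


def segment_enriched_regions(
    obs: WindowCounts,
    null: MonteCarloNull,
    alpha: float = 0.001,
    merge_gap_bp: int | None = None,
    mark: str = "5mC",
    library_id: str = "",
) -> EnrichedRegionSet:
    """Call windows with empirical p <= alpha and merge them into regions.

    Retained windows whose intervals overlap or lie within
    ``merge_gap_bp`` (default: one window width) of each other are merged
    into a single region spanning their union; the region's p is the
    minimum window p and its count the maximum window count.
    """
    if merge_gap_bp is None:
        merge_gap_bp = obs.window_bp
    pvals = window_pvalues(obs, null)
    regions: list[EnrichedRegion] = []
    for chrom in obs.genome:
        p = pvals[chrom]
        keep = np.flatnonzero(p <= alpha)
        if keep.size == 0:
            continue
        s = obs.starts[chrom][keep]
        e = obs.ends[chrom][keep]
        c = obs.counts[chrom][keep]
        pv = p[keep]
        cur_s, cur_e, cur_c, cur_p = s[0], e[0], c[0], pv[0]
        for i in range(1, keep.size):
            if s[i] <= cur_e + merge_gap_bp:
                cur_e = max(cur_e, e[i])
                cur_c = max(cur_c, c[i])
                cur_p = min(cur_p, pv[i])
            else:
                regions.append(
                    EnrichedRegion(GenomicInterval(chrom, int(cur_s), int(cur_e)), int(cur_c), float(cur_p))
                )
                cur_s, cur_e, cur_c, cur_p = s[i], e[i], c[i], pv[i]
        regions.append(
            EnrichedRegion(GenomicInterval(chrom, int(cur_s), int(cur_e)), int(cur_c), float(cur_p))
        )
    return EnrichedRegionSet(regions, mark, library_id, null.quantile_table())


def segment_tagset(
    tags: TagSet,
    window_bp: int = 1000,
    step_bp: int = 500,
    n_permutations: int = 100,
    alpha: float = 0.001,
    merge_gap_bp: int | None = None,
    seed: int = 0,
) -> EnrichedRegionSet:
    """Convenience wrapper: count, permute, and segment one library."""
    obs = count_windows(tags, window_bp, step_bp)
    null = monte_carlo_null(tags, window_bp, step_bp, n_permutations, seed)
    return segment_enriched_regions(
        obs, null, alpha, merge_gap_bp, mark=tags.mark, library_id=tags.library_id
    )
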