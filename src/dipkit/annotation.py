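"""Region-to-gene annotation and genomic-context classification.

Differential regions are linked to the gene whose TSS is nearest to the
region midpoint within a 50 kb window (one gene per region), classified
relative to gene boundaries with a fixed precedence (TSS-proximal at
25 kb > intragenic > boundary > intergenic), and optionally tested for
enrichment in labeled annotation classes (e.g. repeat families) against
a uniform re-placement null.

Tie-breaks everywhere are by ascending (chrom, start, gene_id) so the
annotation is deterministic.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np

from .differential import DifferentialRegion
from .genomic_io import GeneModel, GenomicInterval

CONTEXTS = ("tss_proximal", "intragenic", "boundary", "intergenic")


@dataclasses.dataclass
class GeneRegionAnnotation:
    """A region linked to (at most) one gene.

    ``distance_to_tss`` is signed along the gene strand: negative means
    the region midpoint lies upstream of the TSS.  ``context_flags``
    records every class the region belongs to; ``context`` is the single
    exclusive label under the documented precedence.
    """

    region: DifferentialRegion
    gene_id: str | None
    distance_to_tss: int | None
    context: str
    context_flags: dict[str, bool] = dataclasses.field(default_factory=dict)


def _tss_index(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, list[GeneModel]]]:
    """Per chromosome: TSS positions sorted by (tss, start, gene_id)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.interval.start, g.gene_id))
        out[chrom] = (np.array([g.tss for g in gs], dtype=np.int64), gs)
    return out


def _nearest_tss(index, chrom: str, point: int) -> tuple[GeneModel | None, int]:
    """Nearest-TSS gene to a point; ties broken by ascending
    (chrom, start, gene_id).  Returns (gene, unsigned distance)."""
    if chrom not in index:
        return None, -1
    tss, gs = index[chrom]
    i = int(np.searchsorted(tss, point))
    best: GeneModel | None = None
    best_d = -1
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(gs):
            d = abs(int(tss[j]) - point)
            g = gs[j]
            if (
                best is None
                or d < best_d
                or (d == best_d and (g.interval.start, g.gene_id) < (best.interval.start, best.gene_id))
            ):
                best, best_d = g, d
    return best, best_d


def classify_context(
    region: GenomicInterval | DifferentialRegion,
    genes: Sequence[GeneModel],
    proximity_bp: int = 25_000,
) -> str:
    """Exclusive context label of one region (precedence:
    tss_proximal > intragenic > boundary > intergenic)."""
    return _classify(region, _tss_index(genes), proximity_bp)[0]


def context_flags(
    region: GenomicInterval | DifferentialRegion,
    genes: Sequence[GeneModel],
    proximity_bp: int = 25_000,
) -> dict[str, bool]:
    """Non-exclusive membership flags for every context class."""
    return _classify(region, _tss_index(genes), proximity_bp)[1]


def _classify(region, index, proximity_bp: int) -> tuple[str, dict[str, bool]]:
    iv = region.interval if isinstance(region, DifferentialRegion) else region
    mid = iv.midpoint
    gene, d = _nearest_tss(index, iv.chrom, mid)
    flags = {c: False for c in CONTEXTS}
    flags["tss_proximal"] = gene is not None and d <= proximity_bp
    if iv.chrom in index:
        for g in index[iv.chrom][1]:
            gi = g.interval
            if gi.start <= mid < gi.end:
                flags["intragenic"] = True
            # region straddles a gene edge
            if iv.start <= gi.start < iv.end or iv.start < gi.end <= iv.end:
                flags["boundary"] = True
    flags["intergenic"] = not (flags["tss_proximal"] or flags["intragenic"] or flags["boundary"])
    for label in CONTEXTS:
        if flags[label]:
            return label, flags
    return "intergenic", flags


def annotate_to_tss(
    regions: Sequence[DifferentialRegion],
    genes: Sequence[GeneModel],
    tss_window_bp: int = 50_000,
    proximity_bp: int = 25_000,
) -> list[GeneRegionAnnotation]:
    """Assign each region to the gene with the nearest TSS within the
    window ("non-redundantly": one gene per region).

    The anchor is the region midpoint; regions with no TSS within
    ``tss_window_bp`` get ``gene_id=None``.  Distances are signed along
    the gene strand (negative = upstream of the TSS).
    """
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValueError("gene ids must be distinct")
    index = _tss_index(genes)
    out: list[GeneRegionAnnotation] = []
    for r in regions:
        mid = r.interval.midpoint
        gene, d = _nearest_tss(index, r.interval.chrom, mid)
        context, flags = _classify(r, index, proximity_bp)
        if gene is None or d > tss_window_bp:
            out.append(GeneRegionAnnotation(r, None, None, context, flags))
        else:
            signed = mid - gene.tss if gene.strand == "+" else gene.tss - mid
            out.append(GeneRegionAnnotation(r, gene.gene_id, int(signed), context, flags))
    return out


def select_top_regions(
    regions: Sequence[DifferentialRegion],
    n: int = 2000,
    q_threshold: float = 0.01,
) -> list[DifferentialRegion]:
    """The top-n most significant regions at q < threshold.

    Rank is ascending p; ties broken by ascending (chrom, start) so the
    selection is deterministic.
    """
    passing = [r for r in regions if r.q < q_threshold]
    passing.sort(key=lambda r: (r.p, r.interval.chrom, r.interval.start))
    return passing[:n]


class _Coverage:
    """Base-pair coverage lookups over a merged interval set."""

    def __init__(self, intervals: Sequence[GenomicInterval]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.prefix: dict[str, np.ndarray] = {}
        self.total = 0
        for chrom, items in by_chrom.items():
            items.sort()
            merged: list[list[int]] = []
            for s, e in items:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            s_arr = np.array([m[0] for m in merged], dtype=np.int64)
            e_arr = np.array([m[1] for m in merged], dtype=np.int64)
            self.starts[chrom] = s_arr
            self.ends[chrom] = e_arr
            self.prefix[chrom] = np.concatenate([[0], np.cumsum(e_arr - s_arr)])
            self.total += int((e_arr - s_arr).sum())

    def covered_upto(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Covered bases in [0, pos) per query position (vectorized)."""
        if chrom not in self.starts:
            return np.zeros(np.asarray(pos).shape, dtype=np.int64)
        s, e, pre = self.starts[chrom], self.ends[chrom], self.prefix[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        i = np.searchsorted(s, pos, side="right")  # blocks starting before pos
        full = pre[np.maximum(i - 1, 0)]
        inside = np.where(
            i > 0, np.clip(pos - s[np.maximum(i - 1, 0)], 0, e[np.maximum(i - 1, 0)] - s[np.maximum(i - 1, 0)]), 0
        )
        return np.where(i > 0, full + inside, 0)

    def overlap(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        return self.covered_upto(chrom, end) - self.covered_upto(chrom, start)


@dataclasses.dataclass
class ClassEnrichment:
    label: str
    observed_fraction: float
    expected_fraction: float
    fold: float
    p: float
    n_permutations: int


def class_enrichment(
    regions: Sequence[GenomicInterval],
    annotation_classes: Mapping[str, Sequence[GenomicInterval]],
    genome: Mapping[str, int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[ClassEnrichment]:
    """Permutation enrichment of regions in labeled interval classes.

    The statistic is the fraction of region base pairs overlapping the
    class; the null re-places every region uniformly on its chromosome
    (lengths preserved).  The empirical p is two-sided with the +1
    permutation convention.
    """
    if len(regions) == 0:
        raise ValueError("empty region list: enrichment is undefined")
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, np.ndarray] = {}
    total_bp = 0
    for chrom in genome:
        lens = np.array(
            [iv.length for iv in regions if iv.chrom == chrom], dtype=np.int64
        )
        by_chrom[chrom] = lens
        total_bp += int(lens.sum())
    results: list[ClassEnrichment] = []
    for label, class_ivs in annotation_classes.items():
        if any(iv.length <= 0 for iv in class_ivs) or len(class_ivs) == 0:
            raise ValueError(f"class {label!r} has zero-length or no intervals")
        cov = _Coverage(list(class_ivs))
        obs_bp = sum(
            int(cov.overlap(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0])
            for iv in regions
        )
        obs_frac = obs_bp / total_bp
        null_bp = np.zeros(n_permutations, dtype=np.int64)
        for chrom, lens in by_chrom.items():
            if lens.size == 0:
                continue
            lim = genome[chrom] - lens  # start ranges, shape (n_regions,)
            if (lim < 0).any():
                raise ValueError(f"region longer than chromosome {chrom}")
            starts = rng.integers(0, lim + 1, size=(n_permutations, lens.size))
            ov = cov.overlap(chrom, starts.ravel(), (starts + lens).ravel())
            null_bp += ov.reshape(n_permutations, lens.size).sum(axis=1)
        null_frac = null_bp / total_bp
        expected = float(null_frac.mean())
        hi = int((null_bp >= obs_bp).sum())
        lo = int((null_bp <= obs_bp).sum())
        p = min(1.0, 2.0 * (1 + min(hi, lo)) / (n_permutations + 1))
        fold = obs_frac / expected if expected > 0 else np.inf
        results.append(
            ClassEnrichment(label, obs_frac, expected, float(fold), float(p), n_permutations)
        )
    return results
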