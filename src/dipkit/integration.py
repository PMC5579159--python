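"""Cross-dataset integration: gene-set overlap tests, in-silico replicate
pooling, K-means clustering of gene-level methylation change, and
metagene / heatmap visualization.

Overlap between gene sets (e.g. up-DMRs vs up-DHRs, 5hmC-up vs RNA-up)
is tested with a two-sided Fisher exact test on the 2x2 table implied by
the gene universe; families of such tests are BH-adjusted together.
Replicates can be pooled in silico (tag multiset union) and two pooled
libraries compared per region with Fisher tests on tag proportions —
a documented stand-in for the pooled-sample statistic of the earlier
companion analysis, which is not reproduced here.

Metagene matrices hold median-normalized tag density over fixed-width
flanks and a length-rescaled gene body, rows sorted by expression;
heatmaps are row-scaled (z-scores) and color-capped at the 80% quantile.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .differential import bh_adjust
from .genomic_io import GeneModel, GenomicInterval, TagSet
from .segmentation import count_windows


@dataclasses.dataclass
class OverlapTest:
    set_a_label: str
    set_b_label: str
    n_a: int
    n_b: int
    n_overlap: int
    universe_size: int
    odds_ratio: float
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap exceeds set size")
        if self.universe_size < self.n_a + self.n_b - self.n_overlap:
            raise ValueError("universe smaller than the union of the sets")


def overlap_test(
    genes_a: set[str],
    genes_b: set[str],
    universe: Sequence[str] | set[str],
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapTest:
    """Two-sided Fisher exact test of gene-set overlap in a universe.

    The odds ratio uses a Haldane 0.5 correction when any cell of the
    2x2 table is zero.  The test is symmetric in its two sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = genes_a & universe
    b = genes_b & universe
    k = len(a & b)
    table = np.array(
        [
            [k, len(a) - k],
            [len(b) - k, len(universe) - len(a) - len(b) + k],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapTest(label_a, label_b, len(a), len(b), k, len(universe), float(odds), float(p))


def adjust_overlap_family(tests: Sequence[OverlapTest]) -> list[OverlapTest]:
    """BH-adjust a family of overlap tests (fills the q field)."""
    q = bh_adjust([t.p for t in tests])
    return [dataclasses.replace(t, q=float(qi)) for t, qi in zip(tests, q)]


def pool_in_silico(tagsets: Sequence[TagSet]) -> TagSet:
    """Union the tags of replicate libraries into one pooled TagSet."""
    if not tagsets:
        raise ValueError("nothing to pool")
    first = tagsets[0]
    for ts in tagsets[1:]:
        if ts.genome != first.genome:
            raise ValueError("mismatched genomes")
        if ts.mark != first.mark or ts.condition != first.condition:
            raise ValueError("can only pool replicates of one mark/condition")
    positions = {
        chrom: np.concatenate([ts.positions(chrom) for ts in tagsets])
        for chrom in first.genome
    }
    strands = {
        chrom: np.concatenate([ts.strands(chrom) for ts in tagsets])
        for chrom in first.genome
    }
    return TagSet.from_arrays(
        "+".join(ts.library_id for ts in tagsets),
        first.mark,
        first.condition,
        positions,
        first.genome,
        strands,
    )


def pooled_region_test(
    pooled_a: TagSet, pooled_b: TagSet, regions: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per-region Fisher exact test of tag proportions between two pooled
    libraries (a = sham/reference, b = irradiated).

    Returns a DataFrame with counts, p, BH q and direction ("up" when
    the proportion of library-b tags in the region exceeds library a's).
    """
    n_a, n_b = pooled_a.n_tags, pooled_b.n_tags
    if n_a == 0 or n_b == 0:
        raise ValueError("a pooled library has zero tags")
    rows = []
    for iv in regions:
        k_a = pooled_a.count_in(iv)
        k_b = pooled_b.count_in(iv)
        _, p = stats.fisher_exact([[k_a, n_a - k_a], [k_b, n_b - k_b]])
        prop_diff = k_b / n_b - k_a / n_a
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "count_a": k_a,
                "count_b": k_b,
                "p": p,
                "direction": "up" if prop_diff > 0 else ("down" if prop_diff < 0 else "none"),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


@dataclasses.dataclass
class GeneMethylationProfile:
    """Per-gene feature vector of methylation change (signed -log10 best
    q for each mark plus mean normalized levels)."""

    gene_id: str
    features: np.ndarray
    cluster: int | None = None


def gene_methylation_profiles(
    gene_ids: Sequence[str],
    feature_table: pd.DataFrame,
) -> list[GeneMethylationProfile]:
    """Wrap a gene x feature DataFrame into profile records."""
    if not np.isfinite(feature_table.to_numpy(dtype=float)).all():
        raise ValueError("features must be finite")
    return [
        GeneMethylationProfile(gid, feature_table.loc[gid].to_numpy(dtype=float))
        for gid in gene_ids
    ]


def kmeans_profiles(
    profiles: Sequence[GeneMethylationProfile],
    k: int = 4,
    n_starts: int = 10,
    seed: int = 0,
) -> tuple[list[GeneMethylationProfile], float]:
    """K-means on per-dimension-standardized features.

    Best of ``n_starts`` random initializations by within-cluster sum of
    squares; deterministic for a fixed seed; labels renumbered by
    descending cluster size.  Returns (profiles with clusters, inertia).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError("k exceeds the number of genes")
    X = np.vstack([p.features for p in profiles])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw_labels = km.fit_predict(Xs)
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    out = [
        dataclasses.replace(p, cluster=int(relabel[l]))
        for p, l in zip(profiles, raw_labels)
    ]
    return out, float(km.inertia_)


def silhouette_scan(
    profiles: Sequence[GeneMethylationProfile],
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
) -> pd.Series:
    """Mean silhouette score over a range of k (cluster-count report)."""
    from sklearn.metrics import silhouette_score

    X = np.vstack([p.features for p in profiles])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    scores = {}
    for k in k_range:
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(Xs)
        scores[k] = silhouette_score(Xs, labels)
    return pd.Series(scores, name="silhouette")


def median_window_density(tags: TagSet, window_bp: int = 1000) -> float:
    """Genome-wide median tag density (tags/bp) in non-overlapping
    windows; the metagene normalizer."""
    wc = count_windows(tags, window_bp, window_bp)
    dens = []
    for chrom in wc.genome:
        widths = (wc.ends[chrom] - wc.starts[chrom]).astype(float)
        dens.append(wc.counts[chrom] / widths)
    return float(np.median(np.concatenate(dens)))


def metagene_matrix(
    tags: TagSet,
    genes: Sequence[GeneModel],
    flank_bp: int = 10_000,
    n_body_bins: int = 100,
    n_flank_bins: int = 50,
    expression: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Median-normalized tag density over flanks and rescaled gene body.

    Per gene: ``n_flank_bins`` fixed-width bins upstream, ``n_body_bins``
    body bins (gene rescaled), ``n_flank_bins`` downstream, oriented
    along the strand.  Bin counts are divided by bin width and by the
    genome-wide median window density.  Rows are ordered by descending
    ``expression``; genes shorter than ``n_body_bins`` bp are skipped
    with a warning.
    """
    med = median_window_density(tags)
    if med <= 0:
        raise ValueError("median window density is zero; library too sparse")
    flank_width = flank_bp / n_flank_bins
    cols = (
        [f"up_{i + 1}" for i in range(n_flank_bins)]
        + [f"body_{i + 1}" for i in range(n_body_bins)]
        + [f"down_{i + 1}" for i in range(n_flank_bins)]
    )
    rows: dict[str, np.ndarray] = {}
    skipped = 0
    for g in genes:
        if g.length < n_body_bins:
            skipped += 1
            continue
        pos = tags.positions(g.chrom)
        chrom_len = tags.genome[g.chrom]
        s, e = g.interval.start, g.interval.end
        # bin edges left-to-right in genomic coordinates
        up_edges = s + np.round(np.linspace(-flank_bp, 0, n_flank_bins + 1)).astype(np.int64)
        body_edges = np.round(np.linspace(s, e, n_body_bins + 1)).astype(np.int64)
        down_edges = e + np.round(np.linspace(0, flank_bp, n_flank_bins + 1)).astype(np.int64)
        edges = np.concatenate([up_edges[:-1], body_edges[:-1], down_edges])
        clipped = np.clip(edges, 0, chrom_len)
        counts = np.diff(np.searchsorted(pos, clipped, side="left")).astype(float)
        widths = np.diff(edges).astype(float)
        dens = counts / np.maximum(widths, 1.0) / med
        # mark bins that fell off the chromosome as the genome average
        off = np.diff(clipped) <= 0
        dens[off] = 1.0
        if g.strand == "-":
            dens = dens[::-1]
        rows[g.gene_id] = dens
    if skipped:
        warnings.warn(f"skipped {skipped} gene(s) shorter than {n_body_bins} bp")
    order = list(rows)
    if expression is not None:
        order.sort(key=lambda gid: (-expression.get(gid, 0.0), gid))
    mat = pd.DataFrame([rows[g] for g in order], index=order, columns=cols)
    return mat, order


def row_scaled_heatmap(
    matrix: pd.DataFrame | np.ndarray,
    cap_quantile: float = 0.80,
    path: str | None = None,
) -> tuple[plt.Figure, np.ndarray]:
    """Row z-scored heatmap with the color map capped at a quantile.

    Rows are centered and scaled to unit (population) variance;
    zero-variance rows become all zeros.  Returns the figure and the
    scaled matrix (for testing); saves to ``path`` when given.
    """
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population SD
    scaled = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    cap = float(np.quantile(scaled, cap_quantile))
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(scaled, aspect="auto", cmap="RdYlGn_r", vmax=cap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="row z-score (capped)")
    ax.set_xlabel("bin")
    ax.set_ylabel("region / gene")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, scaled
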