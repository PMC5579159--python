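"""Bidirectional intragenic 5hmC remodeling statistics.

A "bidirectional" gene carries both an up- and a down-regulated DHR
(differentially hydroxymethylated region).  This module detects such
genes, tests whether the up/down gene-set overlap exceeds chance
(upper-tail hypergeometric), quantifies intragenic DHR density in four
50 kb bins laid along the direction of transcription after removing
genes shorter than 200 kb, compares bin densities between gene classes
with a label-permutation test, and correlates per-gene density with DHR
significance rank (score = -log10 of the gene's most significant DHR).

"Distal to the gene start" is read as bins along the gene body
downstream of the TSS; upstream flanks are excluded.  A DHR belongs to
a bin when its midpoint falls inside that stretch of the gene body.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneRegionAnnotation
from .differential import bh_adjust
from .genomic_io import GeneModel

CLASS_LABELS = ("bidirectional", "up_only", "down_only", "control")


@dataclasses.dataclass
class BidirectionalResult:
    up_genes: set[str]
    down_genes: set[str]
    bidirectional_genes: set[str]
    universe_size: int
    overlap_p: float
    density_table: pd.DataFrame | None = None
    class_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.bidirectional_genes != self.up_genes & self.down_genes:
            raise ValueError("bidirectional set must equal up ∩ down")


def hypergeom_overlap_p(n_up: int, n_down: int, n_overlap: int, universe: int) -> float:
    """Upper-tail hypergeometric P(X >= n_overlap); an observed overlap
    of 0 therefore gives p = 1."""
    if universe < max(n_up, n_down):
        raise ValueError("universe smaller than one of the sets")
    return float(stats.hypergeom.sf(n_overlap - 1, universe, n_up, n_down))


def _gene_set(annotations: Sequence[GeneRegionAnnotation]) -> set[str]:
    return {a.gene_id for a in annotations if a.gene_id is not None}


def find_bidirectional_genes(
    up_annot: Sequence[GeneRegionAnnotation] | set[str],
    down_annot: Sequence[GeneRegionAnnotation] | set[str],
    universe: Sequence[str] | int,
) -> BidirectionalResult:
    """Genes associated with both an up- and a down-regulated DHR.

    Accepts either annotation lists or plain gene-id sets (the results
    are identical by construction).  ``universe`` is the gene universe
    (ids or its size) against which the overlap is tested.
    """
    up = set(up_annot) if isinstance(up_annot, (set, frozenset)) else _gene_set(up_annot)
    down = set(down_annot) if isinstance(down_annot, (set, frozenset)) else _gene_set(down_annot)
    n_universe = universe if isinstance(universe, int) else len(set(universe))
    both = up & down
    p = hypergeom_overlap_p(len(up), len(down), len(both), n_universe)
    return BidirectionalResult(up, down, both, n_universe, p)


def _body_offset(gene: GeneModel, midpoint: int) -> int:
    """Distance from the TSS along the direction of transcription."""
    return midpoint - gene.interval.start if gene.strand == "+" else gene.interval.end - 1 - midpoint


def dhr_density_bins(
    genes: Sequence[GeneModel],
    dhr_annot: Sequence[GeneRegionAnnotation],
    min_gene_length_bp: int = 200_000,
    bin_bp: int = 50_000,
    n_bins: int = 4,
) -> pd.DataFrame:
    """DHR counts per gene per 50 kb bin along the gene body.

    Genes shorter than ``min_gene_length_bp`` are removed; bins run from
    the TSS in the direction of transcription.  A DHR contributes to the
    bin containing its midpoint, regardless of which gene it was
    annotated to by TSS distance.
    """
    if n_bins * bin_bp > min_gene_length_bp:
        raise ValueError("bins extend past the minimum gene length")
    long_genes = [g for g in genes if g.length >= min_gene_length_bp]
    table = pd.DataFrame(
        0,
        index=[g.gene_id for g in long_genes],
        columns=[f"bin_{i + 1}" for i in range(n_bins)],
        dtype=np.int64,
    )
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in long_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for a in dhr_annot:
        iv = a.region.interval
        mid = iv.midpoint
        for g in by_chrom.get(iv.chrom, []):
            if g.interval.start <= mid < g.interval.end:
                off = _body_offset(g, mid)
                b = off // bin_bp
                if 0 <= b < n_bins:
                    table.loc[g.gene_id, f"bin_{b + 1}"] += 1
    return table


def assign_gene_classes(
    density_genes: Sequence[str], up_genes: set[str], down_genes: set[str]
) -> dict[str, str]:
    """Classify genes as bidirectional / up_only / down_only / control."""
    labels = {}
    for gid in density_genes:
        if gid in up_genes and gid in down_genes:
            labels[gid] = "bidirectional"
        elif gid in up_genes:
            labels[gid] = "up_only"
        elif gid in down_genes:
            labels[gid] = "down_only"
        else:
            labels[gid] = "control"
    return labels


@dataclasses.dataclass
class DensityTestResult:
    statistic_per_bin: np.ndarray  # mean(class A) - mean(class B) per bin
    p_per_bin: np.ndarray
    q_per_bin: np.ndarray
    global_statistic: float
    global_p: float
    n_permutations: int
    exact: bool


def permutation_density_test(
    density_table: pd.DataFrame,
    class_labels: dict[str, str],
    contrast: tuple[str, str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> DensityTestResult:
    """Label-permutation test of per-bin mean density between two classes.

    The statistic per bin is mean(A) - mean(B); the global statistic is
    the sum of per-bin differences.  Two-sided empirical p-values use
    (1 + #{|T_perm| >= |T_obs|}) / (B + 1); when the number of distinct
    label splits is <= ``n_permutations`` all splits are enumerated and
    the p-value is the exact proportion.  Per-bin p-values are
    BH-adjusted across bins.
    """
    a_label, b_label = contrast
    rows_a = [g for g in density_table.index if class_labels.get(g) == a_label]
    rows_b = [g for g in density_table.index if class_labels.get(g) == b_label]
    if not rows_a or not rows_b:
        raise ValueError("both contrast classes must be non-empty")
    data = density_table.loc[rows_a + rows_b].to_numpy(dtype=float)
    n_a = len(rows_a)
    n_tot = data.shape[0]

    def stat(idx_a: np.ndarray) -> np.ndarray:
        mask = np.zeros(n_tot, dtype=bool)
        mask[idx_a] = True
        return data[mask].mean(axis=0) - data[~mask].mean(axis=0)

    t_obs = stat(np.arange(n_a))
    g_obs = t_obs.sum()
    eps = 1e-12

    n_splits = math.comb(n_tot, n_a)
    exact = n_splits <= n_permutations
    if exact:
        hits_bin = np.zeros(data.shape[1], dtype=np.int64)
        hits_global = 0
        for combo in itertools.combinations(range(n_tot), n_a):
            t = stat(np.array(combo))
            hits_bin += np.abs(t) >= np.abs(t_obs) - eps
            hits_global += abs(t.sum()) >= abs(g_obs) - eps
        p_bin = hits_bin / n_splits
        p_global = hits_global / n_splits
        n_used = n_splits
    else:
        rng = np.random.default_rng(seed)
        hits_bin = np.zeros(data.shape[1], dtype=np.int64)
        hits_global = 0
        idx = np.arange(n_tot)
        for _ in range(n_permutations):
            perm = rng.permutation(idx)[:n_a]
            t = stat(perm)
            hits_bin += np.abs(t) >= np.abs(t_obs) - eps
            hits_global += abs(t.sum()) >= abs(g_obs) - eps
        p_bin = (1 + hits_bin) / (n_permutations + 1)
        p_global = (1 + hits_global) / (n_permutations + 1)
        n_used = n_permutations
    return DensityTestResult(
        statistic_per_bin=t_obs,
        p_per_bin=np.asarray(p_bin, dtype=float),
        q_per_bin=bh_adjust(np.asarray(p_bin, dtype=float)),
        global_statistic=float(g_obs),
        global_p=float(p_global),
        n_permutations=n_used,
        exact=exact,
    )


@dataclasses.dataclass
class DensitySignificance:
    rho: float
    p: float
    degenerate: bool  # zero variance in density or score


def density_vs_significance(
    genes: Sequence[GeneModel],
    dhr_annot: Sequence[GeneRegionAnnotation],
    density_table: pd.DataFrame,
) -> DensitySignificance:
    """Spearman correlation of intragenic DHR density with DHR
    significance (per gene: -log10 of its minimum DHR p; density is the
    density-table row sum divided by gene length)."""
    gene_by_id = {g.gene_id: g for g in genes}
    min_p: dict[str, float] = {}
    for a in dhr_annot:
        iv = a.region.interval
        mid = iv.midpoint
        for gid in density_table.index:
            g = gene_by_id[gid]
            if g.chrom == iv.chrom and g.interval.start <= mid < g.interval.end:
                min_p[gid] = min(min_p.get(gid, 1.0), a.region.p)
    gids = [gid for gid in density_table.index if gid in min_p]
    if len(gids) < 3:
        raise ValueError("need >= 3 genes with at least one DHR each")
    score = np.array([-np.log10(max(min_p[g], 1e-300)) for g in gids])
    density = np.array(
        [density_table.loc[g].sum() / gene_by_id[g].length for g in gids]
    )
    if np.allclose(density, density[0]) or np.allclose(score, score[0]):
        return DensitySignificance(0.0, 1.0, True)
    rho, p = stats.spearmanr(density, score)
    return DensitySignificance(float(rho), float(p), False)


def bidirectional_recovery_report(
    result: BidirectionalResult, truth_bidirectional: Sequence[str]
) -> tuple[float, float]:
    """(recall, precision) of detected bidirectional genes vs planted
    truth; precision is NaN when nothing was detected."""
    truth = set(truth_bidirectional)
    detected = result.bidirectional_genes
    recall = len(detected & truth) / len(truth) if truth else 1.0
    precision = len(detected & truth) / len(detected) if detected else float("nan")
    return recall, precision
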