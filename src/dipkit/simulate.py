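"""Synthetic genomes, DIP-Seq tag libraries and RNA-Seq counts with
planted ground truth.

The generator emulates the statistical structure the pipeline assumes,
at desk scale: a toy genome (2 chromosomes x 10 Mb) with 160
non-overlapping genes of which a stated fraction are >= 200 kb; DIP-Seq
tag sets for 2 replicate pools x 2 conditions (sham, irradiated) x 2
marks (5mC, 5hmC) drawn from a piecewise-constant intensity — uniform
background, multiplied by an enrichment fold inside planted enriched
regions and by condition-specific folds inside planted differential
regions, with gamma (NB mixing) replicate noise on planted regions;
expression-coupled structure (5mC depleted around active TSSs and
mildly elevated in low-expression bodies, 5hmC enriched in active gene
bodies); planted "bidirectional" genes >= 200 kb carrying both up- and
down-shifted 5hmC regions in distinct 50 kb body bins; and matched
RNA-Seq counts in which a configurable fraction of 5hmC-up genes is
co-up-regulated.

Tag positions are sampled independently given the intensity (no
fragment-length autocorrelation); total library depth is allocated by a
single multinomial draw so a requested depth is hit exactly.  All
outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomicInterval, TagSet

MARKS = ("5mC", "5hmC")
CONDITIONS = ("sham", "irradiated")


@dataclasses.dataclass
class SimParams:
    """Generator settings; defaults are the desk-scale study conditions.

    ``background_tag_density`` is in tags/kb (5 tags/kb puts ~5 tags in
    a 1000 bp window, the segmentation design point).  When
    ``depth_per_library`` is None the depth equals the integrated
    intensity, so realized background density matches the requested one;
    a given depth is hit exactly by multinomial allocation.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 10_000_000
    n_genes: int = 160
    long_gene_fraction: float = 0.2
    long_gene_length_range: tuple[int, int] = (200_000, 300_000)
    short_gene_length_range: tuple[int, int] = (5_000, 50_000)
    background_tag_density: float = 5.0  # tags per kb
    enrichment_fold: float = 5.0
    differential_fold: float = 4.0
    nb_dispersion: float = 0.05
    n_replicates_per_condition: int = 2
    depth_per_library: int | None = None
    expression_coupling: bool = True
    tss_depletion_factor: float = 0.3
    tss_depletion_halfwidth_bp: int = 2_000
    body_enrichment_max_fold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_length_bp",
            "background_tag_density",
            "enrichment_fold",
            "differential_fold",
            "n_replicates_per_condition",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0 or self.nb_dispersion < 0:
            raise ValueError("n_genes and nb_dispersion must be >= 0")
        if not (0.0 <= self.long_gene_fraction <= 1.0):
            raise ValueError("long_gene_fraction must lie in [0, 1]")


@dataclasses.dataclass
class TruthSpec:
    """How many elements of each kind to plant (per mark where relevant).

    ``n_differential_per_mark`` counts unidirectional differential
    regions planted at random positions (half up, half down), in
    addition to the DHRs carried by bidirectional genes.
    """

    n_enriched_per_mark: int = 60
    n_differential_per_mark: int = 24
    n_bidirectional_genes: int = 8
    n_up_per_bidir: int = 2
    n_down_per_bidir: int = 2
    region_width_bp: int = 3_000
    min_region_gap_bp: int = 10_000


@dataclasses.dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    enriched_regions: list[tuple[GenomicInterval, str, float]]
    differential_regions: list[tuple[GenomicInterval, str, str, float]]
    bidirectional_genes: list[str]
    de_genes: list[tuple[str, str]]
    seed: int

    def differential_by(self, mark: str, direction: str) -> list[GenomicInterval]:
        return [
            iv for iv, m, d, _ in self.differential_regions if m == mark and d == direction
        ]

    def enriched_by(self, mark: str) -> list[GenomicInterval]:
        return [iv for iv, m, _ in self.enriched_regions if m == mark]

    def validate(self, genes: Sequence[GeneModel], min_gene_length_bp: int = 200_000) -> None:
        """Check the planted-structure invariants."""
        enriched_keys = {(iv.chrom, iv.start, iv.end, m) for iv, m, _ in self.enriched_regions}
        for iv, m, _, _ in self.differential_regions:
            if (iv.chrom, iv.start, iv.end, m) not in enriched_keys:
                raise ValueError("differential region without matching enriched region")
        by_id = {g.gene_id: g for g in genes}
        for gid in self.bidirectional_genes:
            g = by_id[gid]
            if g.length < min_gene_length_bp:
                raise ValueError(f"bidirectional gene {gid} shorter than {min_gene_length_bp}")
            ups = downs = 0
            for iv, m, d, _ in self.differential_regions:
                if m == "5hmC" and iv.chrom == g.chrom and g.interval.start <= iv.midpoint < g.interval.end:
                    ups += d == "up"
                    downs += d == "down"
            if ups < 1 or downs < 1:
                raise ValueError(f"bidirectional gene {gid} lacks an up or down DHR")

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "mark": m, "fold": f}
                for iv, m, f in self.enriched_regions
            ]
        ).to_csv(directory / "truth_enriched.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "mark": m,
                 "direction": d, "fold": f}
                for iv, m, d, f in self.differential_regions
            ]
        ).to_csv(directory / "truth_differential.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": self.bidirectional_genes}).to_csv(
            directory / "truth_bidirectional.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.de_genes, columns=["gene_id", "direction"]).to_csv(
            directory / "truth_de_genes.tsv", sep="\t", index=False
        )


def simulate_genome(params: SimParams) -> tuple[dict[str, int], list[GeneModel]]:
    """A toy genome with non-overlapping, randomly placed genes.

    Gene lengths follow a two-component mixture: with probability
    ``long_gene_fraction`` the gene is "long" (uniform in
    ``long_gene_length_range``, i.e. >= 200 kb by default), otherwise
    "short".  Both strands are drawn uniformly.  Raises when the drawn
    genes cannot fit on a chromosome.
    """
    rng = np.random.default_rng([params.seed, 1])
    genome = {f"chr{i + 1}": params.chrom_length_bp for i in range(params.n_chroms)}
    genes: list[GeneModel] = []
    per_chrom = np.full(params.n_chroms, params.n_genes // params.n_chroms)
    per_chrom[: params.n_genes % params.n_chroms] += 1
    gi = 0
    for ci, (chrom, length) in enumerate(genome.items()):
        n_c = int(per_chrom[ci])
        if n_c == 0:
            continue
        is_long = rng.random(n_c) < params.long_gene_fraction
        lo_l, hi_l = params.long_gene_length_range
        lo_s, hi_s = params.short_gene_length_range
        lens = np.where(
            is_long,
            rng.integers(lo_l, hi_l + 1, size=n_c),
            rng.integers(lo_s, hi_s + 1, size=n_c),
        )
        free = length - int(lens.sum())
        if free < n_c + 1:
            raise ValueError(
                f"cannot place {n_c} genes totalling {lens.sum()} bp on a "
                f"{length} bp chromosome without overlap"
            )
        gaps = rng.multinomial(free, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = 0
        for k in range(n_c):
            pos += int(gaps[k])
            start, end = pos, pos + int(lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(
                GeneModel(f"gene_{gi:04d}", GenomicInterval(chrom, start, end, strand), strand)
            )
            pos = end
    return genome, genes


def gene_expression_levels(params: SimParams, genes: Sequence[GeneModel]) -> dict[str, float]:
    """Baseline expression per gene (lognormal), deterministic for a
    fixed seed; shared by the DIP-Seq and RNA-Seq generators."""
    rng = np.random.default_rng([params.seed, 7])
    return {g.gene_id: float(v) for g, v in zip(genes, rng.lognormal(0.0, 1.0, len(genes)))}


def _place_region(
    rng: np.random.Generator,
    genome: Mapping[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    width: int,
    gap: int,
    max_tries: int = 1000,
) -> GenomicInterval:
    chroms = list(genome)
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome[chrom] - width))
        end = start + width
        if all(end + gap <= s or e + gap <= start for s, e in occupied[chrom]):
            occupied[chrom].append((start, end))
            return GenomicInterval(chrom, start, end)
    raise ValueError("could not place a region without overlap; genome too crowded")


def _plant_truth(
    rng: np.random.Generator,
    params: SimParams,
    truth_spec: TruthSpec,
    genome: Mapping[str, int],
    genes: Sequence[GeneModel],
) -> SimTruth:
    width = truth_spec.region_width_bp
    gap = truth_spec.min_region_gap_bp
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    enriched: list[tuple[GenomicInterval, str, float]] = []
    differential: list[tuple[GenomicInterval, str, str, float]] = []

    n_bins_needed = truth_spec.n_up_per_bidir + truth_spec.n_down_per_bidir
    bin_bp = 50_000
    long_genes = [g for g in genes if g.length >= 200_000]
    if len(long_genes) < truth_spec.n_bidirectional_genes:
        raise ValueError("not enough >=200 kb genes to plant bidirectional set")
    if n_bins_needed > 4:
        raise ValueError("cannot place more than 4 DHRs in 4 distinct 50 kb bins")
    chosen = rng.choice(len(long_genes), size=truth_spec.n_bidirectional_genes, replace=False)
    bidirectional = []
    for idx in chosen:
        g = long_genes[int(idx)]
        bidirectional.append(g.gene_id)
        bins = rng.permutation(4)[:n_bins_needed]
        directions = ["up"] * truth_spec.n_up_per_bidir + ["down"] * truth_spec.n_down_per_bidir
        for b, d in zip(bins, directions):
            margin = 1_000
            off = int(b) * bin_bp + int(rng.integers(margin, bin_bp - width - margin))
            if g.strand == "+":
                start = g.interval.start + off
            else:
                start = g.interval.end - off - width
            iv = GenomicInterval(g.chrom, start, start + width)
            enriched.append((iv, "5hmC", params.enrichment_fold))
            differential.append((iv, "5hmC", d, params.differential_fold))
        # keep random regions out of bidirectional gene bodies so the
        # planted bin structure stays clean
        occupied[g.chrom].append((g.interval.start, g.interval.end))

    for mark in MARKS:
        n_diff = truth_spec.n_differential_per_mark
        for k in range(n_diff):
            iv = _place_region(rng, genome, occupied, width, gap)
            d = "up" if k < (n_diff + 1) // 2 else "down"
            enriched.append((iv, mark, params.enrichment_fold))
            differential.append((iv, mark, d, params.differential_fold))
        for _ in range(truth_spec.n_enriched_per_mark):
            iv = _place_region(rng, genome, occupied, width, gap)
            enriched.append((iv, mark, params.enrichment_fold))
    return SimTruth(enriched, differential, bidirectional, [], params.seed)


def _segment_weights(
    length: int,
    intervals: list[tuple[int, int, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant multiplier from multiplicative intervals.

    Returns (breakpoints[n+1], factor[n]) where factor applies on
    [breakpoints[i], breakpoints[i+1]).
    """
    pts = {0, length}
    for s, e, _ in intervals:
        pts.add(max(0, s))
        pts.add(min(length, e))
    bp = np.array(sorted(pts), dtype=np.int64)
    logf = np.zeros(bp.size - 1)
    for s, e, f in intervals:
        s, e = max(0, s), min(length, e)
        if e <= s:
            continue
        i = np.searchsorted(bp, s)
        j = np.searchsorted(bp, e)
        logf[i:j] += np.log(f)
    return bp, np.exp(logf)


def simulate_dipseq(
    params: SimParams,
    truth_spec: TruthSpec | None = None,
    genome: Mapping[str, int] | None = None,
    genes: Sequence[GeneModel] | None = None,
) -> tuple[list[TagSet], SimTruth]:
    """DIP-Seq tag libraries for 2 marks x 2 conditions x replicates.

    Tag positions are drawn from a piecewise-constant intensity:
    background everywhere, times ``enrichment_fold`` inside planted
    enriched regions, times condition-specific folds inside planted
    differential regions ("up" regions gain ``differential_fold`` in the
    irradiated condition, "down" regions lose it), times the
    expression-coupled gene-body/TSS factors when enabled.  Planted
    regions receive per-library gamma multipliers with variance
    ``nb_dispersion`` so replicate counts are NB-distributed around the
    library intensity.
    """
    if truth_spec is None:
        truth_spec = TruthSpec()
    if genome is None or genes is None:
        genome, genes = simulate_genome(params)
    rng = np.random.default_rng([params.seed, 2])
    truth = _plant_truth(rng, params, truth_spec, genome, genes)
    truth.validate(genes) if truth.bidirectional_genes else None

    expr = gene_expression_levels(params, genes)
    ranks = pd.Series(expr).rank(pct=True)

    # structural (condition-independent) factors per mark
    structural: dict[str, dict[str, list[tuple[int, int, float]]]] = {
        m: {c: [] for c in genome} for m in MARKS
    }
    if params.expression_coupling:
        for g in genes:
            r = float(ranks[g.gene_id])
            s, e = g.interval.start, g.interval.end
            body_5hmc = 1.0 + (params.body_enrichment_max_fold - 1.0) * r**2
            if body_5hmc > 1.0:
                structural["5hmC"][g.chrom].append((s, e, body_5hmc))
            body_5mc = 1.0 + (1.0 - r)
            structural["5mC"][g.chrom].append((s, e, body_5mc))
            if r > 2.0 / 3.0:
                hw = params.tss_depletion_halfwidth_bp
                structural["5mC"][g.chrom].append(
                    (g.tss - hw, g.tss + hw, params.tss_depletion_factor)
                )

    planted: dict[str, list[tuple[GenomicInterval, float, str | None, float]]] = {m: [] for m in MARKS}
    diff_keys = {
        (iv.chrom, iv.start, iv.end, m): (d, f) for iv, m, d, f in truth.differential_regions
    }
    for iv, m, base_fold in truth.enriched_regions:
        d_f = diff_keys.get((iv.chrom, iv.start, iv.end, m))
        planted[m].append((iv, base_fold, d_f[0] if d_f else None, d_f[1] if d_f else 1.0))

    base_rate = params.background_tag_density / 1000.0  # tags per bp
    tagsets: list[TagSet] = []
    for mark in MARKS:
        for condition in CONDITIONS:
            for rep in range(params.n_replicates_per_condition):
                intervals_by_chrom: dict[str, list[tuple[int, int, float]]] = {
                    c: list(structural[mark][c]) for c in genome
                }
                for iv, base_fold, d, dfold in planted[mark]:
                    fold = base_fold
                    if d is not None and condition == "irradiated":
                        fold = fold * (dfold if d == "up" else 1.0 / dfold)
                    if params.nb_dispersion > 0:
                        shape = 1.0 / params.nb_dispersion
                        fold = fold * rng.gamma(shape, 1.0 / shape)
                    intervals_by_chrom[iv.chrom].append((iv.start, iv.end, fold))
                seg_bp: dict[str, np.ndarray] = {}
                weights = []
                chrom_order = list(genome)
                for chrom in chrom_order:
                    bp, factor = _segment_weights(genome[chrom], intervals_by_chrom[chrom])
                    seg_bp[chrom] = bp
                    weights.append(factor * np.diff(bp) * base_rate)
                w = np.concatenate(weights)
                total = w.sum()
                depth = (
                    params.depth_per_library
                    if params.depth_per_library is not None
                    else int(round(total))
                )
                if depth <= 0 or (w > 0).sum() == 0:
                    raise ValueError("intensity produces zero expected tags")
                counts = rng.multinomial(depth, w / total)
                positions: dict[str, np.ndarray] = {}
                strands: dict[str, np.ndarray] = {}
                offset = 0
                for chrom in chrom_order:
                    bp = seg_bp[chrom]
                    n_seg = bp.size - 1
                    c = counts[offset : offset + n_seg]
                    offset += n_seg
                    pos_parts = [
                        rng.integers(bp[i], bp[i + 1], size=int(c[i]))
                        for i in np.flatnonzero(c)
                    ]
                    pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
                    positions[chrom] = pos
                    strands[chrom] = np.where(rng.random(pos.size) < 0.5, "+", "-").astype("U1")
                tagsets.append(
                    TagSet.from_arrays(
                        f"{mark}_{condition}_rep{rep + 1}",
                        mark,
                        condition,
                        positions,
                        genome,
                        strands,
                    )
                )
    return tagsets, truth


def simulate_rnaseq(
    params: SimParams,
    genes: Sequence[GeneModel],
    truth: SimTruth,
    coupled_fraction: float = 0.5,
    expression_fold: float = 2.0,
    mean_scale: float = 100.0,
    n_background_de: int = 10,
) -> tuple[pd.DataFrame, SimTruth]:
    """NB-distributed RNA-Seq counts matched to the DIP-Seq truth.

    A ``coupled_fraction`` of 5hmC-up genes (gene bodies containing an
    up-shifted 5hmC differential region) is up-regulated by
    ``expression_fold`` in the irradiated condition, so the planted
    5hmC-up ∩ RNA-up overlap is enriched; ``n_background_de`` additional
    genes change direction-balanced at random.  ``truth.de_genes`` is
    filled in and the updated truth returned.
    """
    if not (0.0 <= coupled_fraction <= 1.0):
        raise ValueError("coupled_fraction must lie in [0, 1]")
    rng = np.random.default_rng([params.seed, 3])
    expr = gene_expression_levels(params, genes)
    if expression_fold == 1.0:  # fold 1 = no change: nothing is planted
        coupled_fraction, n_background_de = 0.0, 0
    up_5hmc = hmc_up_genes(genes, truth)
    up_list = sorted(up_5hmc)
    n_coupled = int(round(coupled_fraction * len(up_list)))
    coupled = set(
        np.array(up_list)[rng.choice(len(up_list), size=n_coupled, replace=False)]
    ) if n_coupled else set()
    others = [g.gene_id for g in genes if g.gene_id not in up_5hmc]
    bg_idx = rng.choice(len(others), size=min(n_background_de, len(others)), replace=False)
    de: list[tuple[str, str]] = [(g, "up") for g in sorted(coupled)]
    for j, i in enumerate(bg_idx):
        de.append((others[int(i)], "up" if j % 2 == 0 else "down"))
    de_map = dict(de)

    lib_names = [
        f"RNA_{cond}_rep{r + 1}"
        for cond in CONDITIONS
        for r in range(params.n_replicates_per_condition)
    ]
    data = np.zeros((len(genes), len(lib_names)), dtype=np.int64)
    for j, name in enumerate(lib_names):
        irr = "irradiated" in name
        for i, g in enumerate(genes):
            mu = expr[g.gene_id] * mean_scale
            d = de_map.get(g.gene_id)
            if irr and d is not None:
                mu *= expression_fold if d == "up" else 1.0 / expression_fold
            if params.nb_dispersion > 0:
                shape = 1.0 / params.nb_dispersion
                lam = mu * rng.gamma(shape, 1.0 / shape)
            else:
                lam = mu
            data[i, j] = rng.poisson(lam)
    counts = pd.DataFrame(data, index=[g.gene_id for g in genes], columns=lib_names)
    updated = dataclasses.replace(truth, de_genes=de)
    return counts, updated


def hmc_up_genes(genes: Sequence[GeneModel], truth: SimTruth) -> set[str]:
    """Genes whose body contains the midpoint of an up-shifted 5hmC
    differential region."""
    out = set()
    for g in genes:
        for iv in truth.differential_by("5hmC", "up"):
            if iv.chrom == g.chrom and g.interval.start <= iv.midpoint < g.interval.end:
                out.add(g.gene_id)
                break
    return out
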