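import numpy as np
import pytest

from dipkit.genomic_io import GenomicInterval, TagSet
from dipkit.simulate import SimParams, simulate_dipseq, simulate_genome


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, frac: float = 0.5) -> bool:
    ov = a.overlap_length(b)
    return ov >= frac * a.length and ov >= frac * b.length


@pytest.fixture(scope="session")
def desk_sim():
    """One full desk-scale simulation (expression coupling on), shared
    across tests that only read from it."""
    params = SimParams(seed=11)
    genome, genes = simulate_genome(params)
    tags, truth = simulate_dipseq(params, genome=genome, genes=genes)
    return params, genome, genes, tags, truth


@pytest.fixture(scope="session")
def flat_sim():
    """Simulation without expression coupling: uniform lambda=5
    background plus planted 5x enriched / 4x differential regions — the
    segmentation- and differential-recovery study condition."""
    params = SimParams(expression_coupling=False, seed=5)
    genome, genes = simulate_genome(params)
    tags, truth = simulate_dipseq(params, genome=genome, genes=genes)
    return params, genome, genes, tags, truth


@pytest.fixture(scope="session")
def seg_sim():
    """Noise-free simulation (exact 5x planted enrichment, uniform
    lambda=5 background): the segmentation-recovery study condition."""
    params = SimParams(expression_coupling=False, nb_dispersion=0.0, seed=5)
    genome, genes = simulate_genome(params)
    tags, truth = simulate_dipseq(params, genome=genome, genes=genes)
    return params, genome, genes, tags, truth


@pytest.fixture(scope="session")
def uniform_tags():
    """Background-only tag library: 5 tags/kb over 2 x 10 Mb."""
    rng = np.random.default_rng(0)
    genome = {"chr1": 10_000_000, "chr2": 10_000_000}
    pos = {c: np.sort(rng.integers(0, genome[c], size=50_000)) for c in genome}
    return TagSet.from_arrays("bg", "5mC", "sham", pos, genome)
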