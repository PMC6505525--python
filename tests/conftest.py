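import numpy as np
import pytest

from t2dnet.core import AnnotatedSite, GenomicInterval
from t2dnet.loops import Loop


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def site(chrom, start, end, state="EnhA1", support=1):
    return AnnotatedSite(GenomicInterval(chrom, start, end), state, support)


def loop_at(chrom, mid1, mid2, resolution=5000, source="pooled", depth=1e9):
    half = resolution // 2
    return Loop(
        GenomicInterval(chrom, mid1 - half, mid1 - half + resolution),
        GenomicInterval(chrom, mid2 - half, mid2 - half + resolution),
        resolution,
        source,
        depth,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic bundle shared by integration-style tests."""
    from t2dnet.simulate import SimulationConfig, simulate_all

    cfg = SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=20_000_000,
        n_sites=1200,
        n_genes=500,
        n_loops=250,
        n_signals=25,
        n_null_windows=50,
        variants_per_signal=30,
    )
    return simulate_all(cfg)
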