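import numpy as np
import pytest

from dhsdyn.core import CutSiteTrack, GenomeModel
from dhsdyn.synthetic import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study: 100 genes on a 2 Mb chromosome, default rates."""
    return SimConfig(seed=7, n_genes=100, n_chroms=1, chrom_length=2_000_000,
                     n_enhancers=30)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture
def genome_50kb() -> GenomeModel:
    return GenomeModel({"chrA": 50_000})


def uniform_track(genome: GenomeModel, n: int, seed: int) -> CutSiteTrack:
    rng = np.random.default_rng(seed)
    return CutSiteTrack(
        {c: rng.integers(0, L, size=n) for c, L in genome.chrom_lengths.items()},
        genome,
    )
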