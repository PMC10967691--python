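import numpy as np
import pandas as pd
import pytest

from allelome.simulate import SimConfig, simulate_genomes, simulate_methylomes


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(seed=101, n_gene_pairs=16, n_chromosomes=2)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    bundle, truth = simulate_genomes(tiny_config)
    return bundle, truth


@pytest.fixture(scope="session")
def tiny_methylomes(tiny_bundle, tiny_config):
    bundle, truth = tiny_bundle
    tracks, dmr_truth, asmr_truth = simulate_methylomes(
        bundle, tiny_config, truth, phases=["LE", "DP1"]
    )
    return tracks, dmr_truth, asmr_truth


def make_track(rows):
    """Build a methylation track frame from (chrom, pos0, strand, ctx, mc, uc) rows."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos0", "strand", "context", "mc", "uc"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
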