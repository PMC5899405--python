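import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from capmeth import (
    ReadSimParams,
    SimulationConfig,
    bisulphite_convert,
    build_genome,
    simulate_reads,
)
from capmeth.io import simulated_to_aligned

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model():
    """Small polyploid genome with homoeologous and varietal SNPs."""
    return build_genome(SimulationConfig(
        n_contigs=4, contig_length=2000,
        homoeo_snp_rate=0.01, varietal_snp_rate=0.002, seed=11))


def clean_params(depth=30.0, seed=5, **kw):
    """Error-free, duplicate-free, full-MAPQ on-target read parameters."""
    defaults = dict(depth=depth, error_rate=0.0, duplicate_rate=0.0,
                    on_target_fraction=1.0,
                    mapq_distribution=((60, 1.0),), seed=seed)
    defaults.update(kw)
    return ReadSimParams(**defaults)


@pytest.fixture(scope="session")
def clean_reads(model):
    """Error-free untreated reads at 30x over the capture space."""
    return simulate_reads(model, clean_params())


@pytest.fixture(scope="session")
def clean_alignments(clean_reads):
    return simulated_to_aligned(clean_reads)


@pytest.fixture(scope="session")
def bisulphite_alignments(model):
    """Error-free bisulphite reads at 30x, 99% conversion."""
    reads = simulate_reads(model, clean_params(seed=21))
    converted = bisulphite_convert(reads, model, 0.99, seed=22)
    return simulated_to_aligned(converted)
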