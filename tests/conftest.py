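import numpy as np
import pytest

from ltrburst import call_insertions
from ltrburst.simulate import SimulationConfig, simulate_sample


def tiny_config(**overrides) -> SimulationConfig:
    """A fast, small-genome configuration for unit tests."""
    defaults = dict(
        seed=0,
        contig_lengths={"chr1": 6_000, "chloro": 2_000},
        te_length=500,
        ltr_length=80,
        n_insertions=0,
        coverage=5.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def std_sample():
    """The standard study conditions: 20 insertions (TSD 5-8 bp, mixed
    strands) at 30x coverage on a 200 kb two-contig genome plus a 10 kb
    chloroplast-like control."""
    return simulate_sample(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def std_calls(std_sample):
    calls, stats = call_insertions(
        std_sample.genome_alignments,
        std_sample.te_alignments,
        annotation=std_sample.bundle.annotation,
    )
    return calls, stats


@pytest.fixture(scope="session")
def control_sample():
    """Insertion-free control under otherwise identical conditions."""
    return simulate_sample(SimulationConfig(seed=103, n_insertions=0))


@pytest.fixture(scope="session")
def toy_reference():
    rng = np.random.default_rng(7)
    decode = np.frombuffer(b"ACGT", dtype=np.uint8)
    return decode[rng.integers(0, 4, size=1000)].tobytes().decode()
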