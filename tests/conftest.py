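import pytest
from hypothesis import HealthCheck, settings

from hotpep.ppr import ENZYME_PRESET, train_bank
from hotpep.synth import SynthFamilySpec, generate_benchmark

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: High-signal benchmark: 2 families x 20 training members, 20 fresh query
#: members each (40 positives) and 50 pure-background decoys.
BENCH_SPECS = [
    SynthFamilySpec(
        name="GH5", motif_frequency=0.8, ec_label="3.2.1.4", labeled_fraction=0.5, seed=0
    ),
    SynthFamilySpec(
        name="CBM2", motif_frequency=0.8, ec_label="3.2.1.8", labeled_fraction=0.5, seed=1
    ),
]


@pytest.fixture(scope="session")
def benchmark():
    return generate_benchmark(BENCH_SPECS, n_negatives=50, seed=7)


@pytest.fixture(scope="session")
def bank(benchmark):
    return train_bank(
        {name: truth.records for name, truth in benchmark.training.items()},
        ENZYME_PRESET,
        provenance="synthetic benchmark",
    )
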