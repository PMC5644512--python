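import warnings

import pytest

from chromatex import analysis, generate_class_dataset, pipeline

#: Fixed study conditions of the synthetic 7-class benchmark.
BENCHMARK_SEED = 11
BENCHMARK_N_PER_CLASS = 20
BALANCE_TARGET = 40
BALANCE_SEED = 5


@pytest.fixture(scope="session")
def benchmark_table():
    """Labeled 46-feature table of the default 7-class synthetic benchmark."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, table = generate_class_dataset(
            n_per_class=BENCHMARK_N_PER_CLASS, seed=BENCHMARK_SEED
        )
    return table


@pytest.fixture(scope="session")
def balanced_benchmark(benchmark_table):
    """Normalized, ADASYN-balanced version of the benchmark table."""
    norm = analysis.normalize_features(benchmark_table)
    return pipeline.adasyn_balance(norm, BALANCE_TARGET, seed=BALANCE_SEED)
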