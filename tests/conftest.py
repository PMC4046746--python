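import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from dgetag import (
    build_virtual_tag_db,
    clean_raw_reads,
    generate_transcriptome,
    sample_expression,
    simulate_tag_library,
)


@pytest.fixture(scope="session")
def small_reference():
    """200 synthetic unigenes, 5% guaranteed CATG-free."""
    return generate_transcriptome(200, mean_length=300, seed=11)


@pytest.fixture(scope="session")
def small_index(small_reference):
    return build_virtual_tag_db(small_reference)


@pytest.fixture(scope="session")
def two_condition_truth(small_reference):
    return sample_expression(
        small_reference, ["control", "cold"], de_fraction=0.1, effect_log2=3.0, seed=12
    )


@pytest.fixture(scope="session")
def noiseless_reads(small_reference, two_condition_truth):
    return simulate_tag_library(
        small_reference, two_condition_truth, "control", depth=20_000,
        error_rate=0.0, adaptor_only_rate=0.0, n_read_rate=0.0, seed=13,
    )


@pytest.fixture(scope="session")
def noisy_reads(small_reference, two_condition_truth):
    return simulate_tag_library(
        small_reference, two_condition_truth, "control", depth=20_000,
        error_rate=0.01, adaptor_only_rate=0.06, n_read_rate=0.025, seed=14,
    )


@pytest.fixture(scope="session")
def noisy_library(noisy_reads):
    return clean_raw_reads(noisy_reads)
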