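import numpy as np
import pytest

from paleodemo import SequenceAlignment
from paleodemo.scenario import DemographicScenario


@pytest.fixture
def toy_alignment() -> SequenceAlignment:
    # 4 sequences, 8 sites, 3 haplotypes (counts 2, 1, 1)
    return SequenceAlignment.from_strings(
        ["s1", "s2", "s3", "s4"],
        ["ACGTACGT", "ACGTACGT", "ACGTACGA", "ACGAACGA"],
        demes=[1, 1, 2, 2],
    )


@pytest.fixture
def constant_scenario() -> DemographicScenario:
    return DemographicScenario.constant(0.01)


@pytest.fixture
def two_deme_scenario() -> DemographicScenario:
    return DemographicScenario.constant([0.01, 0.02], mig=3.0)


def random_clean_alignment(rng: np.random.Generator, n: int, L: int) -> SequenceAlignment:
    seqs = rng.integers(0, 4, size=(n, L)).astype(np.uint8)
    return SequenceAlignment([f"s{i}" for i in range(n)],
                             np.ones(n, dtype=int), seqs)
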