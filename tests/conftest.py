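import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from spikequant import matcher, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.default_config(n_samples=3, n_reads=20_000, seed=11)


@pytest.fixture(scope="session")
def small_transect(small_config):
    return synthetic.build_transect(small_config)


@pytest.fixture(scope="session")
def small_sample_run(small_transect):
    """(sample, truth, standards, reads, true_counts) for the first sample."""
    tr = small_transect
    sample, truth, stds = tr.samples[0], tr.truths[0], tr.standards_by_sample[0]
    reads, counts = synthetic.simulate_reads(truth, stds, sample)
    return sample, truth, stds, reads, counts


@pytest.fixture(scope="session")
def small_references(small_transect):
    return matcher.references_from_transect(small_transect)
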