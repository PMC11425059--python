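import pytest

from ploidyscape import simwgd


@pytest.fixture(scope="session")
def mixed_history_config() -> simwgd.HistoryConfig:
    """A history in which most loci resolved promptly after the WGD and the
    rest rediploidized after the first speciation (delayed, LORe)."""
    return simwgd.HistoryConfig(
        n_families=200, seq_len_codons=150,
        rediploidization_law=("prompt_or_delayed", 0.387), seed=11)


@pytest.fixture(scope="session")
def mixed_families(mixed_history_config):
    return simwgd.simulate_families(mixed_history_config)
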