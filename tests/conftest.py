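import pytest

from abc_structevol import SimConfig, simulate_history


@pytest.fixture(scope="session")
def homofusion_dataset():
    """Small homofusion history: 4 full + 4 half family-B genes."""
    return simulate_history(SimConfig(scenario="homofusion", n_taxa=4, seed=11))


@pytest.fixture(scope="session")
def heterofusion_dataset():
    """Heterofusion history with long pre-fusion divergence."""
    return simulate_history(
        SimConfig(
            scenario="heterofusion", n_taxa=4, seed=12, pre_fusion_divergence=0.8
        )
    )


@pytest.fixture(scope="session")
def half_only_dataset():
    """Two half-structure lineages (families A and B), 6 tips each."""
    return simulate_history(
        SimConfig(
            scenario="half_only", n_taxa=6, seed=13, pre_fusion_divergence=0.4
        )
    )
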