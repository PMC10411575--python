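import pytest

from homeocollapse import synthio


def small_config(seed: int = 7) -> synthio.SimConfig:
    """Desk-scale-in-miniature study conditions used across the suite:
    2 homeolog pairs x 1 Mbp with a 300 kbp collapsed span."""
    return synthio.SimConfig(
        seed=seed,
        n_homeolog_pairs=2,
        chrom_length=1_000_000,
        collapsed_spans=[(0, 200_000, 500_000)],
        genes_per_chrom=10,
        allelic_snp_rate=0.0005,
        depth_window_bp=10_000,
    )


@pytest.fixture(scope="session")
def sim_small():
    return synthio.simulate(small_config())


@pytest.fixture(scope="session")
def sim_default():
    """The full default study conditions (4 pairs x 10 Mbp, one 3 Mbp
    collapsed span, 20 diploids + 1 DH, mean depth 30)."""
    return synthio.simulate(synthio.SimConfig())


@pytest.fixture(scope="session")
def sample_ids(sim_small):
    return [s.sample_id for s in sim_small.samples]
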