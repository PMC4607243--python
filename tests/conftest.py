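import pytest
from hypothesis import settings

from ervmap.synthetic_data import SimulationConfig, simulate, simulate_reads

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale universe: two short chromosomes, four insertions, 30x."""
    cfg = SimulationConfig(
        chrom_lengths=(150_000, 120_000), n_integrations=4, seed=7
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_library(small_sim, tmp_path_factory):
    """One sequenced library of the small universe (truth SAM pair)."""
    d = tmp_path_factory.mktemp("small_lib")
    host = d / "lib1.host.sam"
    ltr = d / "lib1.ltr.sam"
    simulate_reads(small_sim, 11, host, ltr, sample_id="lib1")
    return {"host_sam": host, "ltr_sam": ltr, "sample_id": "lib1"}


@pytest.fixture(scope="session")
def small_sites(small_sim, small_library):
    from ervmap.site_detection import detect_sites

    sites, depth = detect_sites(
        small_library["host_sam"],
        small_library["ltr_sam"],
        small_sim.chrom_lengths,
        small_library["sample_id"],
    )
    return sites, depth
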