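import pytest

from capfilter.cap_tag import classify_alignments
from capfilter.simdata import SimConfig, simulate_genome, simulate_library


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """One simulated genome + library + start-base calls, shared read-only."""
    sim = simulate_genome(default_config, seed=11)
    lib = simulate_library(sim, default_config, seed=12)
    calls = classify_alignments(lib.truth_alignments, sim.genome)
    return sim, lib, calls


@pytest.fixture(scope="session")
def capped_only_config():
    """Capped reads only, no artifact classes: isolates the cap signature."""
    return SimConfig(
        n_capped=3000,
        n_uncapped_body=0,
        n_strand_invasion=0,
        n_rrna=0,
        n_invasion_sites=0,
    )
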