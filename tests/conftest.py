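import pytest

from policyspill import SimConfig, simulate_all

from _helpers import COMPACT_WINDOWS


@pytest.fixture(scope="session")
def noiseless_sim():
    """6 states x 3 counties x 120 days, zero noise: exact identification."""
    cfg = SimConfig(
        n_states=6, counties_per_state=3, n_days=120,
        noise_sd=0.0, seed=3, max_dyad_pairs=150,
    )
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """12 counties / 4 states / 20 days with noise, compact adoption windows."""
    cfg = SimConfig(
        n_states=4, counties_per_state=3, n_days=20,
        start_date="2020-03-01", adoption_windows=dict(COMPACT_WINDOWS),
        noise_sd=0.05, seed=7,
    )
    return simulate_all(cfg, dyads=False)


@pytest.fixture(scope="session")
def dyad_sim():
    """3 states, 8 sampled directed cross-state pairs, noisy."""
    cfg = SimConfig(
        n_states=3, counties_per_state=2, n_days=20,
        start_date="2020-03-01", adoption_windows=dict(COMPACT_WINDOWS),
        noise_sd=0.05, seed=5, frac_untreated=0.0, frac_no_sh=0.4,
        frac_no_ro=0.0, max_dyad_pairs=8,
    )
    return simulate_all(cfg)
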