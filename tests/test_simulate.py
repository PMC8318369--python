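"""The generator's bookkeeping, determinism, and distributional contracts."""

import numpy as np
import pandas as pd
import pytest

from policyspill import (
    GroundTruth,
    SimConfig,
    fit_dyadic_did,
    fit_spillover_did,
    simulate_all,
    simulate_connectivity,
    simulate_dyad_panel,
    simulate_geography,
    simulate_policy_timelines,
)
from policyspill.errors import ConfigError, ConsistencyError
from policyspill.exposures import POLICIES

from _helpers import COMPACT_WINDOWS


def test_geography_counts_and_labels():
    cfg = SimConfig(n_states=2, counties_per_state=3, seed=1)
    geo = simulate_geography(cfg)
    assert len(geo) == 6
    assert geo.groupby("state").size().tolist() == [3, 3]
    assert (geo["population"] > 0).all()
    assert geo["lat"].between(-90, 90).all() and geo["lon"].between(-180, 180).all()


def test_same_seed_bitwise_identical_tables():
    cfg = SimConfig(n_states=4, counties_per_state=2, n_days=120, seed=42, max_dyad_pairs=30)
    a, b = simulate_all(cfg), simulate_all(cfg)
    for kind in ("geography", "timelines", "sci", "county_panel", "dyad_panel"):
        pd.testing.assert_frame_equal(a[kind], b[kind])


def test_invalid_counts_rejected():
    with pytest.raises(ConfigError):
        SimConfig(n_states=1)
    with pytest.raises(ConfigError):
        SimConfig(counties_per_state=0)
    with pytest.raises(ConfigError):
        SimConfig(n_days=1)


def test_population_lognormal_location():
    # mean of log-population within 3 SE of 10.5 at n = 10,000
    cfg = SimConfig(n_states=100, counties_per_state=100, seed=9)
    geo = simulate_geography(cfg)
    logpop = np.log(geo["population"])
    se = 1.0 / np.sqrt(len(geo))
    assert abs(logpop.mean() - 10.5) < 3 * se
    assert abs(logpop.std() - 1.0) < 0.05


def test_timeline_ordering_invariant_over_many_seeds():
    for seed in range(1000):
        cfg = SimConfig(n_states=5, counties_per_state=1, seed=seed)
        tl = simulate_policy_timelines(cfg)
        for a, b in (("ip_date", "sh_date"), ("sh_date", "ro_date")):
            both = tl[a].notna() & tl[b].notna()
            assert (tl.loc[both, a] <= tl.loc[both, b]).all()


def test_degenerate_windows_force_identical_timelines():
    win = {"ip": ("2020-03-10", "2020-03-10"),
           "sh": ("2020-03-20", "2020-03-20"),
           "ro": ("2020-04-05", "2020-04-05")}
    cfg = SimConfig(n_states=8, counties_per_state=1, adoption_windows=win,
                    frac_untreated=0.0, frac_no_sh=0.0, frac_no_ro=0.0, seed=2)
    tl = simulate_policy_timelines(cfg)
    assert tl["ip_date"].nunique() == 1
    assert tl["sh_date"].nunique() == 1
    assert tl["ro_date"].nunique() == 1


def test_infeasible_window_ordering_rejected():
    win = {"ip": ("2020-04-01", "2020-04-20"),
           "sh": ("2020-03-01", "2020-03-10"),  # ends before ip can finish
           "ro": ("2020-05-01", "2020-06-01")}
    with pytest.raises(ConfigError):
        SimConfig(adoption_windows=win)


def test_adoption_spread_under_14_day_window():
    win = {"ip": ("2020-03-01", "2020-03-15"),
           "sh": ("2020-03-16", "2020-03-30"),
           "ro": ("2020-04-01", "2020-04-15")}
    cfg = SimConfig(n_states=50, counties_per_state=1, adoption_windows=win,
                    frac_untreated=0.0, frac_no_sh=0.0, frac_no_ro=0.0, seed=4)
    tl = simulate_policy_timelines(cfg)
    assert tl["ip_date"].nunique() >= 10


def test_partial_adoption_fractions_respected():
    cfg = SimConfig(n_states=20, counties_per_state=1, seed=6,
                    frac_untreated=0.1, frac_no_sh=0.1, frac_no_ro=0.1)
    tl = simulate_policy_timelines(cfg)
    assert (tl["ip_date"].isna()).sum() == 2          # untreated states
    assert (tl["ip_date"].notna() & tl["sh_date"].isna()).sum() >= 2


class TestConnectivity:
    def test_symmetric_scores_at_equal_population(self):
        geo = pd.DataFrame(
            {"county": ["a", "b"], "state": ["A", "B"],
             "lat": [30.0, 30.0], "lon": [-90.0, -90.0],
             "population": [100.0, 100.0], "mean_devices": [1e3, 1e3]}
        )
        sci = simulate_connectivity(geo, SimConfig(seed=0))
        wide = sci.set_index(["ego", "alter"])["sci"]
        assert wide[("a", "b")] == wide[("b", "a")]

    def test_eta_zero_removes_distance_dependence(self):
        geo = pd.DataFrame(
            {"county": ["a", "b", "c"], "state": ["A", "B", "C"],
             "lat": [30.0, 30.0, 45.0], "lon": [-90.0, -91.0, -70.0],
             "population": [100.0, 200.0, 200.0], "mean_devices": [1e3] * 3}
        )
        sci = simulate_connectivity(geo, SimConfig(eta=0.0, seed=0))
        wide = sci.set_index(["ego", "alter"])["sci"]
        assert wide[("a", "b")] == pytest.approx(wide[("a", "c")])

    def test_tripling_alter_population_triples_score(self):
        base = pd.DataFrame(
            {"county": ["a", "b"], "state": ["A", "B"],
             "lat": [30.0, 31.0], "lon": [-90.0, -90.0],
             "population": [100.0, 50.0], "mean_devices": [1e3, 1e3]}
        )
        tripled = base.assign(population=[100.0, 150.0])
        cfg = SimConfig(seed=0)
        s1 = simulate_connectivity(base, cfg).set_index(["ego", "alter"])["sci"]
        s3 = simulate_connectivity(tripled, cfg).set_index(["ego", "alter"])["sci"]
        assert s3[("a", "b")] / s1[("a", "b")] == pytest.approx(3.0, rel=1e-12)

    def test_single_county_rejected(self):
        geo = pd.DataFrame(
            {"county": ["a"], "state": ["A"], "lat": [0.0], "lon": [0.0],
             "population": [1.0], "mean_devices": [1.0]}
        )
        with pytest.raises(ConsistencyError):
            simulate_connectivity(geo, SimConfig(seed=0))


def test_noiseless_county_panel_recovery(noiseless_sim):
    truth = noiseless_sim["county_truth"]
    expected = np.r_[truth.delta, truth.gamma, truth.theta]
    for outcome in ("locations_visited", "prop_leaving_home"):
        fit = fit_spillover_did(noiseless_sim["county_panel"], model="eq2", outcome=outcome)
        assert np.abs(fit.beta - expected).max() < 1e-8


def test_noiseless_eq1_recovery_without_spillovers():
    cfg = SimConfig(n_states=6, counties_per_state=2, n_days=120, noise_sd=0.0,
                    true_gamma=(0.0, 0.0, 0.0), control_coeffs=(0.0, 0.0), seed=11)
    out = simulate_all(cfg, dyads=False)
    fit = fit_spillover_did(out["county_panel"], model="eq1")
    assert np.abs(fit.beta[:3] - np.asarray(cfg.true_delta)).max() < 1e-8


def test_effect_size_faithfulness_zero_noise_zero_controls():
    # with no spillovers, controls, fixed effects or noise, the log-outcome
    # shift after entering a period equals the cumulative sum of delta
    cfg = SimConfig(n_states=4, counties_per_state=2, n_days=120, noise_sd=0.0,
                    true_gamma=(0.0, 0.0, 0.0), control_coeffs=(0.0, 0.0),
                    fe_sd_county=0.0, fe_sd_day=0.0,
                    frac_untreated=0.0, frac_no_sh=0.0, frac_no_ro=0.0, seed=13)
    out = simulate_all(cfg, dyads=False)
    panel = out["county_panel"]
    logy = np.log(panel["locations_visited"])
    base = logy[(panel[["d_ip", "d_sh", "d_ro"]].sum(axis=1) == 0)].mean()
    in_sh = (panel["d_sh"] == 1) & (panel["d_ro"] == 0)
    delta = np.asarray(cfg.true_delta)
    assert logy[in_sh].mean() - base == pytest.approx(delta[0] + delta[1], abs=1e-10)


class TestDyadPanel:
    def test_cross_state_pair_count(self):
        cfg = SimConfig(n_states=2, counties_per_state=2, n_days=30,
                        start_date="2020-03-01",
                        adoption_windows=dict(COMPACT_WINDOWS), seed=1)
        out = simulate_all(cfg)
        dyad = out["dyad_panel"]
        # 4x4 ordered pairs minus 8 same-state pairs
        assert dyad["pair"].nunique() == 8
        assert (dyad["o_state"] != dyad["d_state"]).all()
        assert dyad["proportion"].between(0, 1).all()
        assert (dyad["distance_km"] > 0).all()

    def test_single_state_rejected(self):
        cfg = SimConfig(n_states=2, counties_per_state=2, seed=1)
        geo = simulate_geography(cfg)
        tl = simulate_policy_timelines(cfg)
        with pytest.raises(ConsistencyError):
            simulate_dyad_panel(cfg, geo[geo["state"] == "S00"], tl)

    def test_zero_interactions_estimated_as_zero_under_zero_noise(self):
        cfg = SimConfig(n_states=6, counties_per_state=2, n_days=120, noise_sd=0.0,
                        true_pi=((0.0,) * 3,) * 3, seed=17, max_dyad_pairs=120)
        out = simulate_all(cfg)
        fit = fit_dyadic_did(out["dyad_panel"], interactions=True, outcome="count")
        pi_hat = [fit.coef(nm) for nm in fit.names if ":" in nm]
        assert np.abs(pi_hat).max() < 1e-8

    def test_noiseless_eq4_recovery_both_outcomes(self, noiseless_sim):
        truth = noiseless_sim["dyad_truth"]
        expected = np.r_[truth.lam, truth.psi, np.ravel(truth.pi),
                         truth.theta, truth.theta]
        for outcome in ("count", "proportion"):
            fit = fit_dyadic_did(noiseless_sim["dyad_panel"], interactions=True,
                                 outcome=outcome)
            assert np.abs(fit.beta - expected).max() < 1e-8


def test_ground_truth_yaml_round_trip(noiseless_sim):
    truth = noiseless_sim["county_truth"]
    restored = GroundTruth.from_yaml(truth.to_yaml())
    assert restored == truth


def test_unbalanced_option_drops_rows():
    cfg = SimConfig(n_states=4, counties_per_state=2, n_days=120,
                    missing_fraction=0.2, seed=19)
    out = simulate_all(cfg, dyads=False)
    full = 8 * 120
    kept = len(out["county_panel"])
    assert 0.7 * full < kept < 0.9 * full
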