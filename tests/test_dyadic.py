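"""Distances, subgroup masks, dyadic fits, and interaction marginal effects."""

import numpy as np
import pandas as pd
import pytest

from policyspill import (
    SimConfig,
    classify_pairs,
    fit_dyadic_did,
    haversine_distance,
    marginal_interaction_effects,
    percent_effect,
    simulate_all,
)
from policyspill.errors import ConfigError

from _helpers import COMPACT_WINDOWS, dummy_variable_wls


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_distance(42.0, -71.0, 42.0, -71.0) == 0.0

    def test_antipodal_closed_form(self):
        assert haversine_distance(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            np.pi * 6371.0088, rel=1e-12
        )

    def test_one_degree_arc_at_equator(self):
        assert haversine_distance(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.195, abs=5e-4)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            haversine_distance(95.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            haversine_distance(0.0, 200.0, 0.0, 0.0)


class TestClassifyPairs:
    def _panel(self, distances):
        return pd.DataFrame({"distance_km": distances})

    def test_boundary_semantics(self):
        masks = classify_pairs(self._panel([99.9, 100.0, 100.1]), 100.0)
        assert masks["nearby"].tolist() == [True, False, False]
        assert masks["distant"].tolist() == [False, False, True]

    def test_zero_threshold_all_distant(self):
        masks = classify_pairs(self._panel([1.0, 50.0, 1000.0]), 0.0)
        assert masks["distant"].all() and not masks["nearby"].any()

    def test_disjoint_partition(self):
        d = np.array([10.0, 100.0, 250.0, 99.99, 100.0])
        masks = classify_pairs(self._panel(d), 100.0)
        at_threshold = d == 100.0
        assert not (masks["nearby"] & masks["distant"]).any()
        assert (masks["nearby"] | masks["distant"] | at_threshold).all()


class TestDyadicFit:
    def test_matches_dummy_variable_oracle(self, dyad_sim):
        panel = dyad_sim["dyad_panel"]
        for outcome, ycol in (("count", "flow"), ("proportion", "proportion")):
            fit = fit_dyadic_did(panel, outcome=outcome)
            w = (panel["o_population"] if outcome == "proportion"
                 else pd.Series(np.ones(len(panel))))
            oracle = dummy_variable_wls(
                np.log(panel[ycol]), panel[fit.names],
                panel["pair"], panel["date"], w,
            )
            np.testing.assert_allclose(fit.beta, oracle.to_numpy(), atol=1e-8)

    def test_count_and_proportion_coincide_with_constant_devices(self, noiseless_sim):
        # origin device counts are constant over days in the generator, so the
        # two outcomes differ by a pair-level shift absorbed by pair effects
        panel = noiseless_sim["dyad_panel"]
        fc = fit_dyadic_did(panel, outcome="count")
        # proportion model refit without weights to isolate the outcome change
        fp_panel = panel.assign(flow=panel["proportion"])
        fp = fit_dyadic_did(fp_panel, outcome="count")
        np.testing.assert_allclose(fc.beta, fp.beta, atol=1e-8)

    def test_empty_subgroup_rejected(self, dyad_sim):
        with pytest.raises(ConfigError):
            fit_dyadic_did(dyad_sim["dyad_panel"], subgroup="nearby",
                           threshold_km=0.0)

    def test_subgroup_refits_on_masked_sample(self):
        cfg = SimConfig(n_states=8, counties_per_state=2, n_days=120,
                        noise_sd=0.02, seed=29, max_dyad_pairs=150)
        out = simulate_all(cfg)
        panel = out["dyad_panel"]
        masks = classify_pairs(panel, 500.0)
        if masks["nearby"].sum() == 0 or masks["distant"].sum() == 0:
            pytest.skip("draw produced no mixed-distance pairs")
        fit = fit_dyadic_did(panel, outcome="count", subgroup="distant",
                             threshold_km=500.0)
        assert fit.nobs == int(masks["distant"].sum())

    def test_zero_flow_handling(self, dyad_sim):
        panel = dyad_sim["dyad_panel"].copy()
        panel.loc[panel.index[:5], "flow"] = 0.0
        fit = fit_dyadic_did(panel, outcome="count", zero_flow="drop")
        assert fit.nobs == len(panel) - 5
        fit1p = fit_dyadic_did(panel, outcome="count", zero_flow="log1p")
        assert fit1p.nobs == len(panel)


class TestMarginalEffects:
    def test_identity_and_baseline(self, noiseless_sim):
        fit = fit_dyadic_did(noiseless_sim["dyad_panel"], interactions=True,
                             outcome="count")
        grid = marginal_interaction_effects(fit)
        psi = {n: fit.coef(f"d_{n}") for n in ("ip", "sh", "ro")}
        for n in ("ip", "sh", "ro"):
            # origin at pre-policy baseline: marginal effect is psi alone
            assert grid.lookup("pre", n)["estimate"] == pytest.approx(psi[n])
            for m in ("ip", "sh", "ro"):
                expected = psi[n] + fit.coef(f"o_{m}:d_{n}")
                assert grid.lookup(m, n)["estimate"] == pytest.approx(expected)
                assert grid.lookup(m, n)["pct"] == pytest.approx(
                    percent_effect(expected)
                )

    def test_delta_method_against_brute_force(self, noiseless_sim):
        fit = fit_dyadic_did(noiseless_sim["dyad_panel"], interactions=True,
                             outcome="count")
        grid = marginal_interaction_effects(fit)
        j = fit.names.index("d_ro")
        i = fit.names.index("o_sh:d_ro")
        gradient = np.zeros(len(fit.names))
        gradient[j] = gradient[i] = 1.0
        brute = float(np.sqrt(gradient @ fit.vcov @ gradient))
        assert grid.lookup("sh", "ro")["se"] == pytest.approx(brute, rel=1e-12)

    def test_zero_covariance_toy(self):
        # Cov(psi, pi) = 0 -> SE = sqrt(Var psi + Var pi)
        from policyspill.twfe import FitResult

        names = (["o_ip", "o_sh", "o_ro", "d_ip", "d_sh", "d_ro"]
                 + [f"o_{m}:d_{n}" for m in ("ip", "sh", "ro")
                    for n in ("ip", "sh", "ro")])
        beta = np.zeros(len(names))
        beta[names.index("d_sh")] = 0.05
        vcov = np.diag(np.full(len(names), 1e-4))
        fit = FitResult(names=names, beta=beta, vcov=vcov, nobs=100, n_units=10,
                        n_times=10, weights_desc="", cluster_desc="",
                        df_inference=9, demean_sweeps=1)
        grid = marginal_interaction_effects(fit)
        assert grid.lookup("ip", "sh")["estimate"] == pytest.approx(0.05)
        assert grid.lookup("ip", "sh")["se"] == pytest.approx(np.sqrt(2e-4))
        assert grid.lookup("pre", "sh")["se"] == pytest.approx(0.01)

    def test_requires_interaction_fit(self, dyad_sim):
        fit = fit_dyadic_did(dyad_sim["dyad_panel"], interactions=False)
        with pytest.raises(ConfigError):
            marginal_interaction_effects(fit)


def test_subgroup_coherence_with_homogeneous_effects():
    # same DGP everywhere: nearby and distant estimates agree within noise
    cfg = SimConfig(n_states=10, counties_per_state=2, n_days=120,
                    noise_sd=0.05, seed=31, max_dyad_pairs=200)
    out = simulate_all(cfg)
    panel = out["dyad_panel"]
    med = float(panel["distance_km"].median())
    near = fit_dyadic_did(panel, outcome="count", subgroup="nearby", threshold_km=med)
    far = fit_dyadic_did(panel, outcome="count", subgroup="distant", threshold_km=med)
    for nm in ("d_sh", "d_ro"):
        diff = abs(near.coef(nm) - far.coef(nm))
        joint_se = np.hypot(near.se()[near.names.index(nm)],
                            far.se()[far.names.index(nm)])
        assert diff < 4 * joint_se
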