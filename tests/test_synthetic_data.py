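"""Dilution pools, affinity correlation structure and hybridization model."""

import numpy as np
import pandas as pd
import pytest

import tilecode as tc
from tilecode.synthetic_data import (
    _noise_lognormal_params,
    draw_correlated_log_affinities,
)


class TestDilutionPools:
    def test_reference_pool_is_equimolar(self, dilution_noiseless):
        spec = dilution_noiseless["pool_spec"]
        ids = list(spec.subpool_assignment)
        pools = tc.make_dilution_pools(ids, spec)
        assert (pools["reference"] == 1.0).all()

    @pytest.mark.parametrize(
        "pool,subpool,factor",
        [
            ("test_pool_1", 2, 1e-03),
            ("test_pool_1", 3, 1e-04),
            ("test_pool_2", 4, 1e-05),
            ("test_pool_3", 5, 1e-06),
            ("test_pool_3", 1, 2e-03),
        ],
    )
    def test_scheme_factors(self, pool, subpool, factor):
        assert tc.DILUTION_SCHEME[pool][subpool] == factor

    def test_unassigned_construct_rejected(self, dilution_noiseless):
        spec = dilution_noiseless["pool_spec"]
        with pytest.raises(ValueError, match="not assigned"):
            tc.make_dilution_pools(["GHOST1"], spec)

    def test_all_factors_one_gives_reference_copy(self):
        spec = tc.PoolSpec(
            subpool_assignment={"A": 0, "B": 1},
            dilution_factors={("reference", 0): 1.0, ("reference", 1): 1.0,
                              ("p", 0): 1.0, ("p", 1): 1.0},
        )
        pools = tc.make_dilution_pools(["A", "B"], spec)
        pd.testing.assert_series_equal(
            pools["p"], pools["reference"], check_names=False
        )

    def test_subpool0_must_stay_equimolar(self):
        with pytest.raises(ValueError, match="equimolar"):
            tc.PoolSpec(subpool_assignment={"A": 0},
                        dilution_factors={("p", 0): 0.5})


class TestAffinities:
    def test_zero_sigma_degenerates_to_equal_affinities(self, layout12):
        aff = tc.simulate_probe_affinities(layout12, 0.0, 0.5, seed=1)
        assert set(aff.values()) == {1.0}

    def test_determinism(self, layout12):
        a1 = tc.simulate_probe_affinities(layout12, 1.0, 0.5, seed=9)
        a2 = tc.simulate_probe_affinities(layout12, 1.0, 0.5, seed=9)
        assert a1 == a2

    def test_replicate_features_share_affinity(self, layout12):
        aff = tc.simulate_probe_affinities(layout12, 1.0, 0.5, seed=2)
        df = layout12.frame()
        per_probe = pd.Series(aff).groupby(
            [df["construct_id"], df["kind"], df["offset"]]
        ).nunique()
        assert (per_probe == 1).all()

    def test_adjacent_probe_log_affinity_correlation(self):
        """MC correlation of adjacent probes matches rho x 18/25."""
        rho = 0.7
        n = 100_000
        la = draw_correlated_log_affinities(
            n, [0, 7, 14, 21, 28, 35], 1.0, rho, rng=np.random.default_rng(9)
        )
        target = rho * 18 / 25
        se = (1 - target**2) / np.sqrt(n)
        r = np.corrcoef(la[:, 0], la[:, 1])[0, 1]
        assert abs(r - target) < 3 * se
        # zero-overlap pair decorrelated
        r0 = np.corrcoef(la[:, 0], la[:, 5])[0, 1]
        assert abs(r0) < 3 / np.sqrt(n) * (1 + 1)

    def test_parameter_validation(self, layout12):
        with pytest.raises(ValueError):
            tc.simulate_probe_affinities(layout12, -1.0, 0.5, seed=0)
        with pytest.raises(ValueError):
            tc.simulate_probe_affinities(layout12, 1.0, 1.5, seed=0)


class TestHybridization:
    def test_noiseless_signal_is_affinity_times_abundance(self, layout12):
        feats = layout12.sample_features()
        aff = tc.simulate_probe_affinities(layout12, 0.8, 0.0, seed=3)
        ab = {c: 100.0 for c in feats["construct_id"].unique()}
        sig = tc.simulate_hybridization(feats, ab, aff)
        expected = np.array([aff[p] * 100.0 for p in feats.index])
        np.testing.assert_allclose(sig.to_numpy(), expected, rtol=1e-12)

    def test_zero_abundance_leaves_background_only(self, layout12):
        feats = layout12.sample_features()
        aff = {p: 1.0 for p in feats.index}
        sig = tc.simulate_hybridization(
            feats, {}, aff, background_level=5.0, rng=np.random.default_rng(1)
        )
        assert (sig >= 0).all()
        # half-normal mean with MC error over ~330 features
        se = 5.0 * np.sqrt(1 - 2 / np.pi) / np.sqrt(len(sig))
        assert sig.mean() == pytest.approx(5.0 * np.sqrt(2 / np.pi), abs=4 * se)

    def test_negative_abundance_rejected(self, layout12):
        feats = layout12.sample_features()
        aff = {p: 1.0 for p in feats.index}
        with pytest.raises(ValueError, match="negative abundance"):
            tc.simulate_hybridization(feats, {"SH0001": -1.0}, aff)

    def test_saturation_monotone_and_bounded(self, layout12):
        feats = layout12.sample_features().head(3)
        aff = {p: 1.0 for p in feats.index}
        smax = 500.0
        prev = -np.inf
        for x in np.logspace(-2, 7, 40):
            sig = tc.simulate_hybridization(
                feats, {feats["construct_id"].iloc[0]: x}, aff, saturation_smax=smax
            ).iloc[0]
            assert prev < sig < smax
            prev = sig

    def test_noise_factor_is_unit_mean(self):
        mu, s = _noise_lognormal_params(0.3)
        draws = np.random.default_rng(4).lognormal(mu, s, 200_000)
        assert draws.mean() == pytest.approx(1.0, abs=3 * 0.3 / np.sqrt(200_000))


class TestNegativeSelection:
    def test_null_effects_give_unit_ratios(self, layout12):
        scenario = tc.ScreenScenario(noise_cv=0.0, background_level=0.0, seed=6)
        table, truth = tc.simulate_negative_selection(layout12, scenario)
        t0 = table.values[table.sample_ids(role="t_zero")].to_numpy()
        t1 = table.values[table.sample_ids(role="t_end")].to_numpy()
        nz = t0 > 0
        np.testing.assert_allclose(t1[nz] / t0[nz], 1.0, rtol=1e-12)
        assert (truth["true_log2_effect"] == 0).all()

    def test_effect_minus_one_halves_expected_signal(self, layout12):
        cid = "SH0001"
        scenario = tc.ScreenScenario(
            depleted_ids={cid}, log2_effect={cid: -1.0},
            noise_cv=0.0, background_level=0.0, seed=6,
        )
        table, _ = tc.simulate_negative_selection(layout12, scenario)
        feats = layout12.sample_features()
        sel = feats.index[feats["construct_id"] == cid]
        r = table.values.loc[sel, "t_end_r1"] / table.values.loc[sel, "t_zero_r1"]
        np.testing.assert_allclose(r, 0.5, rtol=1e-12)

    def test_determinism_bit_identical(self, layout12):
        scenario = tc.ScreenScenario(seed=8)
        t1, g1 = tc.simulate_negative_selection(layout12, scenario)
        t2, g2 = tc.simulate_negative_selection(layout12, scenario)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(g1, g2)

    def test_unknown_depleted_id_rejected(self, layout12):
        scenario = tc.ScreenScenario(depleted_ids={"GHOST"}, log2_effect={"GHOST": -1})
        with pytest.raises(ValueError, match="depleted_ids"):
            tc.simulate_negative_selection(layout12, scenario)

    def test_stray_effect_outside_depleted_set_rejected(self):
        with pytest.raises(ValueError, match="outside depleted_ids"):
            tc.ScreenScenario(depleted_ids={"A"}, log2_effect={"B": -1.0})

    def test_depletion_recovered_within_band(self, screen_sim):
        """Full pipeline recovers a -2 log2 effect within +/-0.3."""
        res = screen_sim["results"]
        depleted = screen_sim["depleted"]
        mean = res.loc[res.index.isin(depleted), "mean_log2"].mean()
        assert mean == pytest.approx(-2.0, abs=0.3)
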