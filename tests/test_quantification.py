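"""Background, thresholds, normalization, ratio cascade and aggregation."""

import numpy as np
import pandas as pd
import pytest

import tilecode as tc
from tilecode.quantification import RATIO_COLUMNS


def _table(values: dict, roles: dict | None = None) -> tc.IntensityTable:
    df = pd.DataFrame(values)
    df.index.name = "probe_id"
    roles = roles or {c: "reference" for c in df.columns}
    samples = pd.DataFrame(
        {"role": [roles[c] for c in df.columns], "replicate": 1},
        index=pd.Index(df.columns, name="sample_id"),
    )
    return tc.IntensityTable(values=df, samples=samples)


class TestBackground:
    def test_constant_negatives(self):
        t = _table({"s1": [7.0, 7.0, 100.0]})
        t.values.index = ["n1", "n2", "p1"]
        bg = tc.median_background(t, ["n1", "n2"])
        assert bg.median_background["s1"] == 7.0
        assert bg.n_negative_probes == 2

    def test_median_is_robust(self):
        t = _table({"s1": [1.0, 2.0, 100.0]})
        t.values.index = ["n1", "n2", "n3"]
        bg = tc.median_background(t, ["n1", "n2", "n3"])
        assert bg.median_background["s1"] == 2.0

    def test_missing_negatives_error(self):
        t = _table({"s1": [1.0]})
        t.values.index = ["p1"]
        with pytest.raises(ValueError, match="negative"):
            tc.median_background(t, ["ghost"])
        with pytest.raises(ValueError, match="negative"):
            tc.median_background(t, [])


class TestDetectionMask:
    def test_zero_threshold_passes_positives(self):
        t = _table({"s1": [0.5, 3.0, 0.0]})
        t.values.index = ["a", "b", "n"]
        bg = tc.median_background(t, ["n"])
        mask = tc.detection_mask(t, bg, 0.0)
        assert mask["s1"].tolist() == [True, True, False]  # strict >

    def test_exact_boundary_fails(self):
        t = _table({"s1": [40.0, 40.0001, 10.0]})
        t.values.index = ["a", "b", "n"]
        bg = tc.median_background(t, ["n"])
        mask = tc.detection_mask(t, bg, 4.0)
        assert not mask.loc["a", "s1"]   # exactly 4x background
        assert mask.loc["b", "s1"]

    def test_mask_nesting_on_simulated_table(self, screen_sim):
        """Detected set at 10-fold is a subset of the 4-fold set."""
        table, layout = screen_sim["table"], screen_sim["layout"]
        norm = tc.normalize_to_array_median(table)
        bg = tc.median_background(norm, layout.negative_probe_ids())
        m4 = tc.detection_mask(norm, bg, 4.0)
        m10 = tc.detection_mask(norm, bg, 10.0)
        assert (m10 & ~m4).to_numpy().sum() == 0


class TestNormalization:
    def test_output_median_is_one(self, screen_sim):
        norm = tc.normalize_to_array_median(screen_sim["table"])
        np.testing.assert_allclose(norm.values.median(axis=0), 1.0, rtol=1e-12)

    def test_scale_invariance(self):
        t = _table({"s1": [1.0, 2.0, 3.0, 4.0]})
        scaled = _table({"s1": [10.0, 20.0, 30.0, 40.0]})
        n1 = tc.normalize_to_array_median(t)
        n2 = tc.normalize_to_array_median(scaled)
        pd.testing.assert_frame_equal(n1.values, n2.values)

    def test_all_equal_sample_becomes_ones(self):
        t = _table({"s1": [5.0, 5.0, 5.0]})
        assert (tc.normalize_to_array_median(t).values == 1.0).all().all()

    def test_zero_median_rejected(self):
        t = _table({"s1": [0.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="median"):
            tc.normalize_to_array_median(t)


class TestProbeRatios:
    def _features(self):
        cons = tc.random_constructs(2, seed=55)
        layout = tc.build_array_layout(cons, n_subarrays=1)
        feats = layout.sample_features()
        return feats[feats["kind"] == "tiling"]

    def test_identical_samples_give_zero_log2(self):
        feats = self._features()
        sig = pd.Series(10.0, index=feats.index)
        mask = pd.Series(True, index=feats.index)
        r = tc.probe_log2_ratios(sig, sig, mask, feats, experiment="e")
        assert len(r) == 12  # 2 constructs x 6 probes
        np.testing.assert_allclose(r["log2_ratio"], 0.0)
        assert (r["n_features"] == 3).all()

    def test_masked_reference_emits_no_ratio(self):
        feats = self._features()
        sig = pd.Series(10.0, index=feats.index)
        mask = pd.Series(False, index=feats.index)
        cid = feats["construct_id"].iloc[0]
        mask[feats.index[feats["construct_id"] != cid]] = True
        r = tc.probe_log2_ratios(sig, sig, mask, feats, experiment="e")
        assert cid not in set(r["construct_id"])

    def test_missing_probe_in_reference_rejected(self):
        feats = self._features()
        sig = pd.Series(10.0, index=feats.index)
        with pytest.raises(ValueError, match="absent from the reference"):
            tc.probe_log2_ratios(sig, sig.iloc[:-1], pd.Series(True, index=feats.index),
                                 feats, experiment="e")

    def test_noiseless_dilution_ratio_per_probe(self, dilution_noiseless):
        """In the linear regime every probe reports log2(0.0001..1) exactly."""
        d = dilution_noiseless
        q = tc.quantify_dilution(d["table"], d["layout"], d["pool_spec"], k_fold=4)
        for (cid, pool), grp in q.probe_ratios.groupby(["construct_id", "experiment"]):
            expected = np.log2(d["pool_spec"].factor_of(pool, cid))
            np.testing.assert_allclose(grp["log2_ratio"], expected, atol=1e-9)


class TestSubpoolRenormalization:
    def _ratios(self, values, constructs):
        return pd.DataFrame({
            "construct_id": constructs,
            "position": ["TP1"] * len(values),
            "experiment": ["e"] * len(values),
            "log2_ratio": values,
            "n_features": [3] * len(values),
        }, columns=RATIO_COLUMNS)

    def test_subpool0_mean_is_one_after(self):
        r = self._ratios([0.3, -0.2, 1.4, -2.0], ["a", "b", "c", "d"])
        out = tc.normalize_to_reference_subpool(r, ["a", "b"])
        lin = 2.0 ** out.loc[out["construct_id"].isin(["a", "b"]), "log2_ratio"]
        assert lin.mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_become_one(self):
        r = self._ratios([0.7, 0.7, 0.7], ["a", "b", "c"])
        out = tc.normalize_to_reference_subpool(r, ["a", "b", "c"])
        np.testing.assert_allclose(out["log2_ratio"], 0.0, atol=1e-12)

    def test_non_subpool0_rescaled_by_same_factor(self):
        """Brute-force oracle: every linear ratio divided by subpool-0 mean."""
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 20)
        cons = [f"c{i}" for i in range(20)]
        r = self._ratios(list(vals), cons)
        subpool0 = cons[:5]
        out = tc.normalize_to_reference_subpool(r, subpool0)
        factor = np.mean(2.0 ** vals[:5])
        np.testing.assert_allclose(
            2.0 ** out["log2_ratio"], 2.0 ** vals / factor, rtol=1e-12
        )

    def test_empty_subpool0_rejected(self):
        r = self._ratios([0.1], ["a"])
        with pytest.raises(ValueError, match="subpool-0"):
            tc.normalize_to_reference_subpool(r, [])
        with pytest.raises(ValueError, match="subpool-0"):
            tc.normalize_to_reference_subpool(r, ["ghost"])


class TestFilterAndAggregate:
    def _long(self, rows):
        return pd.DataFrame(rows, columns=RATIO_COLUMNS)

    def test_probe_below_four_of_nine_dropped(self):
        rows = [("c1", "TP1", f"rep{i}", -1.0, 1) for i in (1, 2, 3)]  # 3 of 9
        rows += [("c1", p, f"rep{i}", -1.0, 3) for p in ("TP2", "TP3") for i in (1, 2, 3)]
        agg = tc.filter_and_aggregate(self._long(rows))
        assert ("probe", "c1", "TP1") in {
            tuple(r[:3]) for r in agg.drop_log.itertuples(index=False)
        }
        assert agg.constructs.loc["c1", "n_probes_used"] == 2
        assert np.isnan(agg.constructs.loc["c1", "TP1"])

    def test_construct_with_single_probe_excluded(self):
        rows = [("c1", "TP1", f"rep{i}", -1.0, 3) for i in (1, 2, 3)]
        agg = tc.filter_and_aggregate(self._long(rows))
        assert "c1" not in agg.constructs.index
        assert (agg.drop_log["level"] == "construct").any()

    def test_mean_of_probe_means(self):
        rows = [("c1", "TP1", f"rep{i}", -1.0, 3) for i in (1, 2, 3)]
        rows += [("c1", "TP2", f"rep{i}", -2.0, 3) for i in (1, 2, 3)]
        agg = tc.filter_and_aggregate(self._long(rows))
        assert agg.constructs.loc["c1", "mean_log2"] == pytest.approx(-1.5)
        assert agg.constructs.loc["c1", "n_ratio_values"] == 18

    def test_conservation_every_construct_reported_or_logged(self, screen_sim):
        """Included + excluded constructs partition the screened set."""
        agg = screen_sim["agg"]
        layout = screen_sim["layout"]
        in_play = set(layout.sample_features()["construct_id"]) - set(
            layout.negative_construct_ids
        )
        excluded = set(agg.drop_log.loc[agg.drop_log["level"] == "construct",
                                        "construct_id"])
        included = set(agg.constructs.index)
        assert included | excluded == in_play
        assert included.isdisjoint(excluded)
        assert (agg.drop_log["reason"] != "").all()


class TestHalfHairpinFilter:
    def _setup(self, n_pass):
        cons = tc.random_constructs(1, seed=77)
        layout = tc.build_array_layout(cons, n_subarrays=1)
        feats = layout.sample_features()
        hh = feats[feats["kind"].str.startswith("half_hairpin")]
        mask = pd.Series(False, index=feats.index)
        mask[hh.index[:n_pass]] = True
        return layout, feats, mask

    @pytest.mark.parametrize("n_pass,detected", [(4, True), (3, True), (2, False), (0, False)])
    def test_replicate_thresholds(self, n_pass, detected):
        layout, feats, mask = self._setup(n_pass)
        found = tc.half_hairpin_filter(mask, feats)
        assert ("SH0001" in found) is detected


class TestDilutionSummary:
    def test_noiseless_means_equal_factors(self, dilution_noiseless):
        d = dilution_noiseless
        q = tc.quantify_dilution(d["table"], d["layout"], d["pool_spec"], k_fold=4)
        summ = tc.dilution_summary(q.construct_pools)
        np.testing.assert_allclose(summ["mean_ratio"], summ.index, atol=1e-9)
        assert summ.loc[1.0, "mean_ratio"] == pytest.approx(1.0, abs=1e-12)
        assert summ.loc[1.0, "p_value"] == 1.0

    def test_sigma_blank_below_three(self):
        cp = pd.DataFrame({
            "construct_id": ["a", "b", "c", "d", "e"],
            "pool": ["p"] * 5,
            "ratio": [0.5, 0.6, 1.0, 1.1, 0.9],
            "mean_log2": np.log2([0.5, 0.6, 1.0, 1.1, 0.9]),
            "n_probes": [6] * 5,
            "dilution_factor": [0.5, 0.5, 1.0, 1.0, 1.0],
        })
        summ = tc.dilution_summary(cp, test="t")
        assert np.isnan(summ.loc[0.5, "sigma"])  # n=2
        assert not np.isnan(summ.loc[1.0, "sigma"])  # n=3
        assert summ.loc[0.5, "n"] == 2
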