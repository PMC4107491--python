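import numpy as np
import pandas as pd
import pytest

import mirserum as m
from mirserum.panel import SCENARIOS


class TestPanelDesign:
    def test_default_design_invariants(self, design):
        t = design.table
        assert len(t) == 742
        assert t["reference_flag"].sum() == 2
        assert t["spike_in_flag"].sum() == 1
        assert t["blood_cell_flag"].sum() == 162
        assert (t["hemolysis_slope"] >= 0).all()
        assert (t.loc[~t["blood_cell_flag"], "hemolysis_slope"] == 0).all()

    def test_design_is_deterministic(self):
        a = m.default_panel().table
        b = m.default_panel().table
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_designs_rejected(self, design):
        broken = design.table.copy()
        broken.loc["miR-serum-000", "reference_flag"] = True
        with pytest.raises(ValueError, match="2 reference"):
            m.PanelDesign(broken)
        broken2 = design.table.copy()
        broken2.loc["miR-serum-000", "hemolysis_slope"] = 1.0
        with pytest.raises(ValueError, match="non-blood"):
            m.PanelDesign(broken2)


class TestNoiseModel:
    def test_sigma_rises_then_saturates(self):
        nm = m.NoiseModel()
        assert nm.sigma(20.0) == nm.sigma_low
        assert nm.sigma(30.0) == nm.sigma_max
        s = nm.sigma(np.array([22.0, 28.5, 33.0]))
        assert s[0] < s[1] <= s[2]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            m.NoiseModel(sigma_low=0.0)
        with pytest.raises(ValueError):
            m.NoiseModel(knee_ct=36.0, detect_ct=35.0)
        with pytest.raises(ValueError):
            m.NoiseModel(sigma_max=0.01)


class TestCohortSpec:
    def test_unknown_scenario_rejected(self, design):
        with pytest.raises(ValueError, match="unknown scenario"):
            m.CohortSpec(design=design, scenario="whatever")

    def test_nonpositive_subjects_rejected(self, design):
        with pytest.raises(ValueError, match="n_subjects"):
            m.CohortSpec(design=design, scenario="hemolysis_pairs", n_subjects=0)

    def test_unknown_scenario_param_rejected(self, design):
        with pytest.raises(ValueError, match="scenario_params"):
            m.CohortSpec(design=design, scenario="hemolysis_pairs",
                         scenario_params={"bogus": 1})

    def test_defaults_merged(self, design):
        spec = m.CohortSpec(design=design, scenario="hemolysis_pairs",
                            scenario_params={"hb_lysed": (0.2, 1.0)})
        assert spec.scenario_params["hb_lysed"] == (0.2, 1.0)
        assert "hb_clean" in spec.scenario_params


class TestGenerateCohort:
    def test_bit_reproducible(self, design):
        spec = m.CohortSpec(design=design, scenario="hemolysis_pairs", n_subjects=4)
        a = m.generate_cohort(spec, seed=9)
        b = m.generate_cohort(spec, seed=9)
        pd.testing.assert_frame_equal(a.ct.values, b.ct.values)
        pd.testing.assert_frame_equal(a.samples.table, b.samples.table)
        pd.testing.assert_frame_equal(a.ipc, b.ipc)

    def test_different_seeds_differ(self, design):
        spec = m.CohortSpec(design=design, scenario="hemolysis_pairs", n_subjects=4)
        a = m.generate_cohort(spec, seed=1)
        b = m.generate_cohort(spec, seed=2)
        assert not a.ct.values.equals(b.ct.values)

    def test_zero_noise_limit_gives_identical_replicates(self, design):
        noise = m.NoiseModel(sigma_low=1e-12, sigma_slope=0.0, sigma_max=1e-12,
                             jump_prob_max=0.0)
        spec = m.CohortSpec(design=design, noise=noise,
                            scenario="technical_repeat", n_subjects=3,
                            plate_offset_sd=0.0)
        c = m.generate_cohort(spec, seed=0)
        vals = c.ct.values.drop(index=design.spike_in_assay)
        for a, b in c.samples.pairs():
            pd.testing.assert_series_equal(
                vals[a], vals[b], check_names=False
            )

    def test_hemolysis_pairs_hemoglobin_separation(self, hemolysis_cohort):
        sheet = hemolysis_cohort.samples
        hb = sheet.hemoglobin()
        lysed = sheet.group_samples("lysed")
        clean = sheet.group_samples("unlysed")
        assert len(lysed) == len(clean) == 10
        assert (hb[lysed] > 0.1).all()
        assert (hb[clean] < 0.1).all()

    def test_sheet_absorbances_recover_hemoglobin(self, hemolysis_cohort):
        t = hemolysis_cohort.samples.table
        back = m.harboe_hemoglobin(
            t["a380"].to_numpy(), t["a415"].to_numpy(), t["a450"].to_numpy()
        )
        np.testing.assert_allclose(back, t["hemoglobin"], atol=1e-9)

    def test_spike_in_independent_of_hemoglobin(self, design):
        spec = m.CohortSpec(design=design, scenario="hemolysis_pairs",
                            n_subjects=40)
        c = m.generate_cohort(spec, seed=4)
        spike = c.ct.values.loc[design.spike_in_assay]
        hb = c.samples.hemoglobin()
        r = np.corrcoef(spike, hb)[0, 1]
        assert abs(r) < 0.3
        assert spike.notna().all()

    def test_undetected_reactions_are_missing_not_clipped(self, hemolysis_cohort):
        vals = hemolysis_cohort.ct.values
        present = vals.to_numpy()[~np.isnan(vals.to_numpy())]
        assert present.max() <= 35.0 + 3 * 0.15 + 1e-9  # ceiling + plate offset
        assert np.isnan(vals.to_numpy()).any()

    @pytest.mark.parametrize("scenario", SCENARIOS)
    def test_every_scenario_produces_valid_cohort(self, design, scenario):
        spec = m.CohortSpec(design=design, scenario=scenario, n_subjects=3)
        c = m.generate_cohort(spec, seed=1)
        assert c.ct.values.shape[0] == 742
        assert len(c.samples.pairs()) == 3
        if scenario == "smoker_cohort":
            assert c.ct.values.shape[1] == 6

    def test_replicate_noise_grows_with_ct(self, design):
        """Empirical replicate SD at Ct ~33 exceeds the SD at Ct ~22."""
        spec = m.CohortSpec(design=design, scenario="technical_repeat",
                            n_subjects=700, plate_offset_sd=0.0)
        c = m.generate_cohort(spec, seed=2)
        vals = c.ct.values
        r1 = vals[[a for a, _ in c.samples.pairs()]].to_numpy()
        r2 = vals[[b for _, b in c.samples.pairs()]].to_numpy()
        mean_ct = (r1 + r2) / 2
        diff = (r1 - r2) / np.sqrt(2)
        lo = np.abs(diff[(mean_ct > 21) & (mean_ct < 23)])
        hi = np.abs(diff[(mean_ct > 32) & (mean_ct < 34)])
        assert len(lo) > 1000 and len(hi) > 1000
        assert np.std(hi) > np.std(lo)


class TestHemoglobinToAbsorbances:
    def test_zero_hb_zero_background(self):
        assert m.hemoglobin_to_absorbances(0.0, background=(0, 0)) == (0, 0, 0)

    @pytest.mark.parametrize("hb", [0.05, 0.1, 2.428])
    def test_round_trip(self, hb):
        a380, a415, a450 = m.hemoglobin_to_absorbances(hb, rng=1)
        assert m.harboe_hemoglobin(a380, a415, a450) == pytest.approx(hb, abs=1e-9)

    def test_solved_a415_zero_background(self):
        # 167.2 * A415 / 1000 = 0.05852  =>  A415 = 0.35
        _, a415, _ = m.hemoglobin_to_absorbances(0.05852, background=(0, 0))
        assert a415 == pytest.approx(0.35)

    def test_negative_hb_rejected(self):
        with pytest.raises(ValueError):
            m.hemoglobin_to_absorbances(-0.1)


class TestConstructCorrelatedProfiles:
    def test_exact_target_correlations(self):
        cov = pd.Series(np.arange(14, dtype=float) + np.random.default_rng(0).normal(size=14),
                        index=[f"s{i}" for i in range(14)])
        targets = m.triglyceride_correlations()
        prof = m.construct_correlated_profiles(cov, targets, n_null=30, seed=5)
        for name, r in targets.items():
            got = np.corrcoef(cov, prof.loc[name])[0, 1]
            assert got == pytest.approx(r, abs=1e-12)
        for i in range(30):
            got = np.corrcoef(cov, prof.loc[f"null-{i:04d}"])[0, 1]
            assert got == pytest.approx(0.0, abs=1e-10)

    def test_invalid_r_rejected(self):
        cov = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            m.construct_correlated_profiles(cov, pd.Series({"a": 1.5}))
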