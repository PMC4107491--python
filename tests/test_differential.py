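import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

import mirserum as m
from mirserum.differential import _mann_whitney


class TestFoldChange:
    def test_equal_delta_gives_one(self):
        assert m.fold_change(-2.0, -2.0) == 1.0

    def test_hand_example(self):
        # control: ref 25, assay 30 -> dCt -5; case: ref 25, assay 27 -> dCt -2
        assert m.fold_change(-2.0, -5.0) == pytest.approx(8.0)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_reciprocal_symmetry(self, a, b):
        assert m.fold_change(a, b) * m.fold_change(b, a) == pytest.approx(1.0)

    def test_missing_delta_propagates(self):
        assert np.isnan(m.fold_change(np.nan, -2.0))

    def test_composed_with_normalize_is_shift_invariant(self, tiny_ct):
        norm = m.normalize(tiny_ct, "a1")
        shifted = m.CtMatrix(tiny_ct.values + [0.7, -1.3, 2.0, 0.0])
        norm2 = m.normalize(shifted, "a1")
        fc1 = m.fold_change(norm["s1"], norm["s2"])
        fc2 = m.fold_change(norm2["s1"], norm2["s2"])
        np.testing.assert_allclose(fc1, fc2)


class TestCalibrateCutoff:
    def _profiles(self, diffs):
        a = pd.Series(0.0, index=[f"x{i}" for i in range(len(diffs))])
        b = a + diffs
        return a, b

    def test_identical_replicates_choose_twofold(self):
        a, b = self._profiles(np.zeros(20))
        cal = m.calibrate_cutoff(a, b)
        assert cal.fractions == {2.0: 0.0, 3.0: 0.0, 4.0: 0.0}
        assert cal.cutoff == 2.0

    def test_measured_fraction_profile_chooses_threefold(self):
        # 31% of assays >=2-fold, 9% >=3-fold, 3% >=4-fold apart
        diffs = np.zeros(100)
        diffs[:31] = 1.01
        diffs[:9] = np.log2(3) + 0.01
        diffs[:3] = 2.01
        cal = m.calibrate_cutoff(*self._profiles(diffs), budget=0.10)
        assert cal.cutoff == 3.0
        assert cal.fractions[2.0] == pytest.approx(0.31)

    def test_generous_budget_chooses_twofold(self):
        diffs = np.zeros(100)
        diffs[:31] = 1.01
        cal = m.calibrate_cutoff(*self._profiles(diffs), budget=0.35)
        assert cal.cutoff == 2.0

    def test_fractions_weakly_decreasing(self):
        rng = np.random.default_rng(0)
        a, b = self._profiles(rng.normal(0, 1.2, size=200))
        cal = m.calibrate_cutoff(a, b)
        fr = list(cal.fractions.values())
        assert fr == sorted(fr, reverse=True)

    def test_too_few_codetected_raises(self):
        a, b = self._profiles(np.zeros(5))
        with pytest.raises(ValueError, match="unreliable"):
            m.calibrate_cutoff(a, b)


def _exact_mw_oracle(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of group labels."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 3), (4, 4), (3, 5), (2, 7), (5, 5)])
    def test_exact_path_matches_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(5):
            x = rng.normal(size=na)
            y = rng.normal(0.5, size=nb)
            _, p = _mann_whitney(x, y)
            assert p == pytest.approx(_exact_mw_oracle(x, y))

    def test_two_vs_two_hand_enumeration(self):
        # {1,2} vs {3,4}: 1 of 6 assignments is as extreme, both tails -> 1/3
        _, p = _mann_whitney(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_give_p_one(self):
        _, p = _mann_whitney(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0, 2.0]))
        assert p == 1.0

    def test_tied_data_uses_corrected_approximation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 8.0, 9.0, 10.0, 11.0, 12.0])
        y = np.array([2.0, 4.0, 5.0, 6.0, 7.0, 7.5, 8.5, 9.5, 10.5])
        _, p = _mann_whitney(x, y)
        assert 0.0 < p <= 1.0


class TestGroupComparison:
    def _normalized(self, shift=0.0, n_assays=20, seed=0):
        rng = np.random.default_rng(seed)
        cases = [f"c{i}" for i in range(8)]
        ctrls = [f"k{i}" for i in range(8)]
        vals = rng.normal(size=(n_assays, 16))
        vals[:, :8] += shift
        df = pd.DataFrame(vals, columns=cases + ctrls,
                          index=[f"a{i}" for i in range(n_assays)])
        return df, cases, ctrls

    def test_bh_adjustment_matches_statsmodels(self):
        norm, cases, ctrls = self._normalized(shift=1.5)
        res = m.mann_whitney_bh(norm, cases, ctrls)
        expected = multipletests(res.table["p"], method="fdr_bh")[1]
        np.testing.assert_allclose(res.table["p_adj"], expected)
        assert (res.table["p_adj"] >= res.table["p"] - 1e-12).all()

    def test_all_missing_assay_skipped(self):
        norm, cases, ctrls = self._normalized()
        norm.loc["a0", cases] = np.nan
        res = m.mann_whitney_bh(norm, cases, ctrls)
        assert "a0" in res.skipped
        assert "a0" not in res.table.index

    def test_groups_must_be_disjoint_and_large_enough(self):
        norm, cases, ctrls = self._normalized()
        with pytest.raises(ValueError):
            m.mann_whitney_bh(norm, cases, cases)
        with pytest.raises(ValueError):
            m.mann_whitney_bh(norm, cases[:2], ctrls)

    def test_null_cohorts_stay_clean_family_wise(self, design):
        """Global-null smoker cohorts yield no BH-significant assay in >=95%
        of simulations at alpha 0.05."""
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            spec = m.CohortSpec(design=design, scenario="smoker_cohort",
                                n_subjects=10)
            c = m.generate_cohort(spec, seed=seed)
            norm = m.normalize(c.ct, design.reference_assays)
            norm = norm.drop(index=[design.spike_in_assay, *design.reference_assays])
            sm = c.samples.group_samples("smoker")
            ns = c.samples.group_samples("non_smoker")
            keep = m.detection_filter(c.ct, sm, ns).intersection(norm.index)
            res = m.mann_whitney_bh(norm.loc[keep], sm, ns)
            if len(res.significant):
                hits += 1
        assert hits <= 0.05 * n_runs


def test_bh_is_monotone_and_order_invariant():
    raw = pd.Series([0.01, 0.02, 0.03, 0.04])
    adj = multipletests(raw, method="fdr_bh")[1]
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])  # hand BH
    rng = np.random.default_rng(1)
    p = rng.uniform(size=50)
    adj1 = multipletests(p, method="fdr_bh")[1]
    order = rng.permutation(50)
    adj2 = multipletests(p[order], method="fdr_bh")[1]
    np.testing.assert_allclose(adj1[order], adj2)
    # monotone: adjusted order preserves raw order
    assert (np.diff(adj1[np.argsort(p)]) >= -1e-12).all()


class TestCorrelationScreen:
    def test_affine_function_gives_r_plus_minus_one(self):
        cov = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        norm = pd.DataFrame(
            [2 * cov + 1, -0.5 * cov + 3], index=["up", "down"]
        )
        res = m.covariate_correlation_screen(norm, cov)
        assert res.table.loc["up", "r"] == pytest.approx(1.0)
        assert res.table.loc["down", "r"] == pytest.approx(-1.0)
        assert res.table.loc["up", "direction"] == "direct"
        assert res.table.loc["down", "direction"] == "inverse"

    def test_r_057_at_n_14_is_significant(self):
        """A sample correlation of 0.57 over 14 samples gives p ~ 0.033
        under the t transform with 12 df."""
        tg = m.triglyceride_pairs()
        cov = pd.Series(
            np.concatenate([tg["non_fasting"], tg["fasting"]]),
            index=[f"s{i}" for i in range(14)],
        )
        prof = m.construct_correlated_profiles(cov, pd.Series({"a": 0.57}), seed=0)
        res = m.covariate_correlation_screen(prof, cov)
        assert res.table.loc["a", "r"] == pytest.approx(0.57)
        assert res.table.loc["a", "p"] == pytest.approx(0.033, abs=0.0015)

    def test_constant_covariate_rejected(self):
        cov = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        norm = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["a"], columns=list("abcd"))
        with pytest.raises(ValueError, match="zero variance"):
            m.covariate_correlation_screen(norm, cov)


class TestClusterSamples:
    def test_duplicated_sample_merges_first_at_zero_distance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        df = pd.DataFrame(
            {"s1": base, "s2": base, "s3": rng.normal(size=20)},
            index=[f"a{i}" for i in range(20)],
        )
        res = m.cluster_samples(df)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        left, right = res.top_split()
        assert sorted(left + right, key=str) == ["s1", "s2", "s3"]
        assert {"s1", "s2"} in (set(left), set(right))

    def test_three_sample_merge_order_matches_hand_upgma(self):
        # profiles built so corr(s1,s2) ~ 0.9, corr with s3 ~ 0
        rng = np.random.default_rng(3)
        shared = rng.normal(size=50)
        df = pd.DataFrame({
            "s1": shared + 0.3 * rng.normal(size=50),
            "s2": shared + 0.3 * rng.normal(size=50),
            "s3": rng.normal(size=50),
        })
        res = m.cluster_samples(df)
        d = res.distances
        # hand UPGMA: first merge = closest pair; root height = mean of the
        # two remaining distances
        assert res.linkage[0, 2] == pytest.approx(d.loc["s1", "s2"])
        expected_root = (d.loc["s1", "s3"] + d.loc["s2", "s3"]) / 2
        assert res.linkage[1, 2] == pytest.approx(expected_root)

    def test_newick_is_parseable_and_complete(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 5)),
                          columns=[f"s{i}" for i in range(5)])
        res = m.cluster_samples(df)
        import io as _io

        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(res.newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(df.columns)

    def test_default_hemolysis_cohort_splits_by_hemolysis(self, design,
                                                          hemolysis_cohort):
        c = hemolysis_cohort
        norm = m.normalize(c.ct, design.reference_assays)
        lysed = c.samples.group_samples("lysed")
        clean = c.samples.group_samples("unlysed")
        keep = m.detection_filter(c.ct, lysed, clean)
        keep = keep.drop([design.spike_in_assay, *design.reference_assays],
                         errors="ignore")
        res = m.cluster_samples(norm.loc[keep])
        left, right = res.top_split()
        groups = c.samples.table["group"]
        sides = {frozenset(groups[left]), frozenset(groups[right])}
        assert sides == {frozenset({"lysed"}), frozenset({"unlysed"})}

    def test_too_few_shared_assays_raises(self):
        df = pd.DataFrame(
            {"s1": [1.0, 2.0, np.nan, np.nan],
             "s2": [np.nan, np.nan, 1.0, 2.0]},
        )
        with pytest.raises(ValueError, match="fewer"):
            m.cluster_samples(df)


class TestLongitudinalConcordance:
    def test_identical_profiles_give_r_one(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=30)
        df = pd.DataFrame({"t1": prof, "t2": prof})
        res = m.longitudinal_concordance(df, [("t1", "t2")], min_detect_frac=0.5)
        assert res.per_pair["r"].iloc[0] == pytest.approx(1.0)

    def test_planted_dropout_listed(self):
        rng = np.random.default_rng(1)
        firsts = [f"f{i}" for i in range(12)]
        seconds = [f"s{i}" for i in range(12)]
        df = pd.DataFrame(rng.normal(size=(30, 24)), columns=firsts + seconds,
                          index=[f"a{i}" for i in range(30)])
        # present in 7 of 12 first samples, absent from all matched seconds
        df.loc["dropout"] = np.nan
        df.loc["dropout", firsts[:7]] = -3.0
        pairs = list(zip(firsts, seconds))
        res = m.longitudinal_concordance(df, pairs, min_detect_frac=0.5)
        assert "dropout" in res.dropouts.index
        assert res.dropouts.loc["dropout", "direction"] == "first_only"

    def test_dropout_cross_referenced_against_hemolysis_list(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(6, 4)),
                          columns=["f0", "f1", "s0", "s1"],
                          index=[f"a{i}" for i in range(6)])
        df.loc["drop"] = [-3.0, -3.0, np.nan, np.nan]
        res = m.longitudinal_concordance(
            df, [("f0", "s0"), ("f1", "s1")], min_detect_frac=0.4,
            hemolysis_flagged=["drop"],
        )
        assert bool(res.dropouts.loc["drop", "in_hemolysis_list"])

    def test_default_cohort_min_r(self, design):
        spec = m.CohortSpec(design=design, scenario="longitudinal_pairs",
                            n_subjects=12)
        c = m.generate_cohort(spec, seed=11)
        norm = m.normalize(c.ct, design.reference_assays)
        norm = norm.drop(index=design.spike_in_assay)
        res = m.longitudinal_concordance(norm, c.samples.pairs())
        assert len(res.per_pair) == 12
        assert res.min_r >= 0.87
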