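"""Severity association, threshold derivation, stratified ratios, subsets."""

import numpy as np
import pandas as pd
import pytest

from sigscore import (
    SigscoreError,
    associate_biomarkers,
    association_table,
    call_positivity,
    derive_repression_threshold,
    find_activation_threshold,
    mean_of_biomarkers,
    score_matrix,
    simulate_bulk,
    simulate_single_cell,
    stratified_activity_ratio,
    subset_roc_comparison,
    SimulationConfig,
)
from sigscore.normalize import log_transform, quantile_normalize


def _biomarkers(dux4, pax7, group=None):
    idx = [f"s{i}" for i in range(len(dux4))]
    table = pd.DataFrame({"DUX4": dux4, "PAX7": pax7}, index=pd.Index(idx, name="sample"))
    if group is not None:
        table["group"] = group
    return table


class TestDeriveRepressionThreshold:
    def test_mean_over_high_activation_samples(self):
        table = _biomarkers([6.0, 7.0, 1.0], [-8.0, -10.0, 5.0])
        assert derive_repression_threshold(table, "DUX4", "PAX7", 5.25) == pytest.approx(-9.0)

    def test_no_qualifying_samples_rejected(self):
        table = _biomarkers([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(SigscoreError, match=">=2 samples"):
            derive_repression_threshold(table, "DUX4", "PAX7", 5.25)

    def test_low_activation_samples_do_not_affect_threshold(self):
        base = _biomarkers([6.0, 7.0], [-8.0, -10.0])
        extra = _biomarkers([6.0, 7.0, 0.5], [-8.0, -10.0, 42.0])
        assert (derive_repression_threshold(base, "DUX4", "PAX7", 5.25)
                == derive_repression_threshold(extra, "DUX4", "PAX7", 5.25))

    def test_shift_equivariance(self):
        table = _biomarkers([6.0, 7.0], [-8.0, -10.0])
        shifted = table.assign(PAX7=table["PAX7"] + 3.0)
        assert derive_repression_threshold(shifted, "DUX4", "PAX7", 5.25) == pytest.approx(
            derive_repression_threshold(table, "DUX4", "PAX7", 5.25) + 3.0)


class TestFindActivationThreshold:
    def test_max_inactive_score(self):
        scores = pd.Series([1.0, 5.25, 6.0, 7.0], index=list("abcd"))
        active = pd.Series([False, False, True, True], index=list("abcd"))
        assert find_activation_threshold(scores, active) == pytest.approx(5.25)

    def test_all_active_gives_minus_inf(self):
        scores = pd.Series([1.0, 2.0], index=list("ab"))
        active = pd.Series([True, True], index=list("ab"))
        assert find_activation_threshold(scores, active) == -np.inf


class TestStratifiedActivityRatio:
    def _severity(self, activities, ids=None):
        ids = ids or [f"s{i}" for i in range(len(activities))]
        return pd.DataFrame({"activity": activities}, index=pd.Index(ids, name="sample"))

    def test_two_to_one_ratio(self):
        table = _biomarkers([6, 6, 6, 6], [-12, -12, -5, -5])
        sev = self._severity([4.0, 4.0, 2.0, 2.0])
        res = stratified_activity_ratio(table, sev, "DUX4", "PAX7", 5.25, -9.0)
        assert res.activity_ratio == pytest.approx(2.0)
        assert res.ratio_defined

    def test_identical_strata_give_unit_ratio(self):
        table = _biomarkers([6, 6], [-12, -5])
        sev = self._severity([3.0, 3.0])
        res = stratified_activity_ratio(table, sev, "DUX4", "PAX7", 5.25, -9.0)
        assert res.activity_ratio == pytest.approx(1.0)

    def test_threshold_equality_falls_in_low_repression_stratum(self):
        table = _biomarkers([6, 6], [-9.0, -12.0])  # -9.0 is not < -9.0
        sev = self._severity([1.0, 2.0])
        res = stratified_activity_ratio(table, sev, "DUX4", "PAX7", 5.25, -9.0)
        assert res.low_repression_samples == ("s0",)
        assert res.high_repression_samples == ("s1",)

    def test_empty_stratum_rejected(self):
        table = _biomarkers([6, 6], [-12, -13])
        sev = self._severity([1.0, 2.0])
        with pytest.raises(SigscoreError, match="empty repression stratum"):
            stratified_activity_ratio(table, sev, "DUX4", "PAX7", 5.25, -9.0)

    def test_zero_denominator_flagged(self):
        table = _biomarkers([6, 6], [-12, -5])
        sev = self._severity([3.0, 0.0])
        res = stratified_activity_ratio(table, sev, "DUX4", "PAX7", 5.25, -9.0)
        assert not res.ratio_defined and np.isnan(res.activity_ratio)

    def test_sample_order_invariance(self):
        table = _biomarkers([6, 6, 6, 6], [-12, -12, -5, -5])
        sev = self._severity([4.0, 4.0, 2.0, 2.0])
        res1 = stratified_activity_ratio(table, sev, "DUX4", "PAX7", 5.25, -9.0)
        perm = table.iloc[::-1]
        res2 = stratified_activity_ratio(perm, sev, "DUX4", "PAX7", 5.25, -9.0)
        assert res1.activity_ratio == pytest.approx(res2.activity_ratio)

    def test_planted_multiplier_recovered_via_full_workflow(self):
        # stratified generator: bursting samples are active; the high-repression
        # half carries 2x the activity; the data-driven thresholds recover it
        hits = 0
        for seed in range(30):
            cfg = SimulationConfig(
                n_cases=32, n_controls=0, n_genes=1200, seed=seed,
                repression_effect=0.3, activation_effect=0.5,
                burst_fraction=0.5, activity_mode="stratified",
                activity_multiplier=2.0, activity_noise_frac=0.1)
            sim = simulate_bulk(cfg)
            table = score_matrix(sim.matrix, sim.signatures)
            table["DUX4_mean"] = mean_of_biomarkers(
                table, [n for n in sim.signatures if n.startswith("DUX4")])
            active = sim.severity["activity"] > 0.5 * cfg.activity_base
            act_thr = find_activation_threshold(table["DUX4_mean"], active)
            rep_thr = derive_repression_threshold(table, "DUX4_mean", "PAX7", act_thr)
            res = stratified_activity_ratio(table, sim.severity, "DUX4_mean",
                                            "PAX7", act_thr, rep_thr)
            if 1.6 <= res.activity_ratio <= 2.4:
                hits += 1
        assert hits >= 27  # >= 90%


class TestAssociateBiomarkers:
    def test_duplicated_covariate_rejected(self, rng):
        table = _biomarkers(rng.normal(size=10), rng.normal(size=10))
        sev = pd.DataFrame({"activity": rng.normal(size=10)}, index=table.index)
        with pytest.raises(SigscoreError, match="collinear"):
            associate_biomarkers(table, sev, multivariate_sets=[("DUX4", "DUX4")])

    def test_insufficient_complete_cases_skipped_with_warning(self, rng, caplog):
        table = _biomarkers(rng.normal(size=5), rng.normal(size=5))
        sev = pd.DataFrame({"activity": [1.0, 2.0, np.nan, np.nan, np.nan]},
                           index=table.index)
        with caplog.at_level("WARNING", logger="sigscore"):
            results = associate_biomarkers(table, sev)
        assert results == []
        assert "complete cases" in caplog.text

    def test_univariate_and_multivariate_fits_reported(self, rng):
        n = 40
        pax7 = rng.normal(size=n)
        dux4 = rng.normal(size=n)
        activity = 1.0 - 2.0 * pax7 + 1.5 * dux4 + 0.5 * rng.normal(size=n)
        table = _biomarkers(dux4, pax7)
        sev = pd.DataFrame({"activity": activity}, index=table.index)
        results = associate_biomarkers(table, sev, multivariate_sets=[("PAX7", "DUX4")])
        flat = association_table(results)
        assert set(flat["model"]) == {"DUX4", "PAX7", "PAX7+DUX4"}
        multi = flat[flat["model"] == "PAX7+DUX4"].set_index("term")
        assert multi.loc["PAX7", "estimate"] < 0 < multi.loc["DUX4", "estimate"]
        assert (multi["p_value"] < 0.05).all()

    def test_null_covariate_p_values_are_calibrated(self, rng):
        # activity independent of scores: per-fit p-values should be uniform
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            table = _biomarkers(rng.normal(size=20), rng.normal(size=20))
            sev = pd.DataFrame({"activity": rng.normal(size=20)}, index=table.index)
            res = associate_biomarkers(table, sev)
            p = res[0].fit.pvalues.drop("intercept").iloc[0]
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.03


class TestSubsetRocComparison:
    def _scored_sc(self, seed=5):
        cfg = SimulationConfig.single_cell_default(
            seed=seed, n_cases=400, n_controls=200, n_genes=700,
            repression_up_size=120, repression_down_size=120,
            activation_sizes=(60,), repression_effect=0.12)
        sim = simulate_single_cell(cfg)
        normed = quantile_normalize(log_transform(sim.matrix))
        table = score_matrix(normed, sim.signatures, sim.labels)
        calls = call_positivity(sim.matrix, sim.signatures["DUX4_60"], min_genes=1)
        return table, calls

    def test_positive_and_negative_subsets_partition_samples(self):
        table, calls = self._scored_sc()
        pos = subset_roc_comparison(table, calls, "positive")
        neg = subset_roc_comparison(table, calls, "negative")
        assert set(pos.sample_ids) | set(neg.sample_ids) == set(table.index)
        assert set(pos.sample_ids) & set(neg.sample_ids) == set()

    def test_all_positive_subset_equals_unrestricted(self):
        table, calls = self._scored_sc()
        everything = calls.copy()
        everything["is_positive"] = True
        full = subset_roc_comparison(table, everything, "positive")
        assert len(full.sample_ids) == len(table)
        # AUCs must match a direct computation on the full table
        from sigscore import roc_curve
        y = (table["group"] == "case").astype(int).to_numpy()
        for name, auc in full.aucs.items():
            assert auc == pytest.approx(roc_curve(table[name].to_numpy(), y).auc)

    def test_constant_biomarker_on_subset_keeps_half_auc(self):
        table, calls = self._scored_sc()
        table = table.copy()
        table["flat"] = 0.0
        cols = ["PAX7", "flat", "group"]
        neg = subset_roc_comparison(table[cols], calls, "negative")
        assert neg.aucs["flat"] == pytest.approx(0.5)
        assert neg.aucs["PAX7"] > 0.5

    def test_subset_without_both_classes_rejected(self):
        table, calls = self._scored_sc()
        only_cases = table[table["group"] == "case"]
        with pytest.raises(SigscoreError, match="lacks a class"):
            subset_roc_comparison(only_cases, calls.loc[only_cases.index], "negative")
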