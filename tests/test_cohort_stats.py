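import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dmdgait as dg
from dmdgait.cohort_stats import (
    NSAASeverity,
    component_correlations,
    feature_summary,
    group_ttest,
    mobility_projection,
    mobility_reduction,
    nsaa_band,
    step_length_by_speed_report,
)
from dmdgait.core_io import Activity
from dmdgait.gait_features import FEATURE_NAMES


class TestGroupTTest:
    def test_identical_groups(self):
        t, p = group_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_large_shift_tiny_variance(self):
        a = [1.0, 1.001, 1.002]
        b = [11.0, 11.001, 11.002]
        _, p = group_ttest(a, b)
        assert p < 1e-6

    def test_matches_independent_computation(self):
        # worked two-sample pooled-variance example, checked by closed form
        a = np.array([19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0])
        b = np.array([28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7,
                      23.2, 17.5, 20.6, 18.0, 23.9, 21.6, 24.3, 20.4, 24.0, 13.2])
        t, p = group_ttest(a, b)
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_manual = 2 * stats.t.sf(abs(t_manual), n1 + n2 - 2)
        assert t == pytest.approx(t_manual, abs=1e-10)
        assert p == pytest.approx(p_manual, abs=1e-4)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [1.0, 2.0])


class TestCorrelations:
    def _scores_table(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "activity": "SC-L3",
            "group": ["DMD"] * (n // 2) + ["TD"] * (n - n // 2),
            "nsaa": rng.integers(8, 35, n),
            **{f: rng.normal(size=n) for f in FEATURE_NAMES},
        })
        return table

    def test_identical_series_r_one(self):
        table = self._scores_table()
        scores = pd.DataFrame({"participant_id": table["participant_id"],
                               "LDA1": table["sl"]})
        cells = component_correlations(scores, table, "LDA1", activity="SC-L3")
        cell = next(c for c in cells if c.feature == "SL")
        assert cell.r == pytest.approx(1.0)
        assert cell.p_adj <= 1.0

    def test_spearman_for_nsaa_and_rank_invariance(self):
        table = self._scores_table(seed=4)
        scores = pd.DataFrame({"participant_id": table["participant_id"],
                               "LDA1": table["nsaa"].astype(float)})
        cells = component_correlations(scores, table, "LDA1", activity="SC-L3")
        nsaa_cell = next(c for c in cells if c.feature == "NSAA")
        assert nsaa_cell.method.value == "spearman"
        assert nsaa_cell.r == pytest.approx(1.0)
        # monotone transform of the scores leaves Spearman r unchanged
        scores2 = scores.copy()
        scores2["LDA1"] = np.exp(scores2["LDA1"] / 10.0)
        cells2 = component_correlations(scores2, table, "LDA1", activity="SC-L3")
        nsaa2 = next(c for c in cells2 if c.feature == "NSAA")
        assert nsaa2.r == pytest.approx(nsaa_cell.r)

    def test_bonferroni_monotone_and_capped(self):
        table = self._scores_table(seed=1)
        rng = np.random.default_rng(9)
        scores = pd.DataFrame({"participant_id": table["participant_id"],
                               "LDA1": rng.normal(size=len(table))})
        cells = component_correlations(scores, table, "LDA1", activity="SC-L3")
        for c in cells:
            if np.isfinite(c.r):
                v = table["nsaa"] if c.feature == "NSAA" else table[c.feature.lower()]
                if c.method.value == "pearson":
                    _, p_raw = stats.pearsonr(scores["LDA1"], v)
                else:
                    _, p_raw = stats.spearmanr(scores["LDA1"], v)
                assert c.p_adj >= p_raw - 1e-12
                assert c.p_adj <= 1.0

    def test_independent_pairs_mostly_nonsignificant(self):
        n_sig = 0
        total = 0
        for seed in range(20):
            table = self._scores_table(n=18, seed=seed)
            rng = np.random.default_rng(seed + 1000)
            scores = pd.DataFrame({"participant_id": table["participant_id"],
                                   "LDA1": rng.normal(size=len(table))})
            cells = component_correlations(scores, table, "LDA1", activity="SC-L3")
            for c in cells:
                total += 1
                if np.isfinite(c.p_adj) and c.p_adj < 0.05:
                    n_sig += 1
        assert n_sig / total < 0.05  # Bonferroni keeps family-wise rate low

    def test_constant_series_flagged(self):
        table = self._scores_table()
        table["sl"] = 1.0
        scores = pd.DataFrame({"participant_id": table["participant_id"],
                               "LDA1": np.arange(len(table), dtype=float)})
        cells = component_correlations(scores, table, "LDA1", activity="SC-L3")
        cell = next(c for c in cells if c.feature == "SL")
        assert np.isnan(cell.r) and np.isnan(cell.p_adj)


class TestNSAABands:
    def test_exhaustive_partition(self):
        expected = {}
        for s in range(35):
            if s >= 30:
                expected[s] = NSAASeverity.NEAR_TD
            elif s >= 20:
                expected[s] = NSAASeverity.MILD
            elif s >= 10:
                expected[s] = NSAASeverity.MODERATE
            else:
                expected[s] = NSAASeverity.SEVERE
        assert {s: nsaa_band(s) for s in range(35)} == expected

    def test_out_of_range_rejected(self):
        for bad in (-1, 35):
            with pytest.raises(ValueError):
                nsaa_band(bad)


class TestMobilityProjection:
    def test_reference_child(self):
        td = mobility_projection(128.0, 11000, 0.40)
        assert td.step_length_cm == pytest.approx(51.2)
        assert td.daily_distance_m == pytest.approx(5632.0)

    def test_mild_and_progressed_scenarios(self):
        td = mobility_projection(128.0, 11000, 0.40)
        mild = mobility_projection(128.0, 11000, 0.35)
        severe = mobility_projection(128.0, 11000, 0.30)
        assert mild.step_length_cm == pytest.approx(44.8)
        assert mild.daily_distance_m == pytest.approx(4928.0)
        assert mobility_reduction(td, mild) == (pytest.approx(704.0), 12.5)
        assert severe.step_length_cm == pytest.approx(38.4)
        assert severe.daily_distance_m == pytest.approx(4224.0)
        assert mobility_reduction(td, severe) == (pytest.approx(1408.0), 25.0)
        assert mobility_reduction(mild, severe) == (pytest.approx(704.0), 14.2)

    def test_identities_hold_exactly(self):
        p = mobility_projection(150.0, 9000, 0.37)
        assert p.step_length_cm == pytest.approx(0.37 * 150.0, abs=1e-9)
        assert p.daily_distance_m == pytest.approx(9000 * p.step_length_cm / 100,
                                                   abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mobility_projection(-1, 100, 0.4)
        with pytest.raises(ValueError):
            mobility_projection(128, 100, 1.2)


class TestStepLengthReports:
    @pytest.fixture(scope="class")
    def severity_table(self):
        cohort, _ = dg.generate_cohort(10, 10, [Activity.SC_L3], seed=21)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return dg.build_feature_table(cohort)

    def test_band_means_ordered_by_severity(self, severity_table):
        rep = step_length_by_speed_report(severity_table, "NSAA_bands")
        order = [b.value for b in NSAASeverity]
        means = (rep.set_index("band").loc[[b for b in order
                                            if b in set(rep["band"])], "sl_mean"])
        assert list(means) == sorted(means, reverse=True)

    def test_neartd_filter_contract(self, severity_table):
        rep = step_length_by_speed_report(severity_table, "TD_vs_nearTD_DMD")
        n_neartd = ((severity_table["group"] == "DMD")
                    & (severity_table["nsaa"] >= 30)).sum()
        dmd_rows = rep[rep["band"] == "DMD"]
        assert (dmd_rows["n"] == n_neartd).all()

    def test_row_count(self, severity_table):
        rep = step_length_by_speed_report(severity_table, "NSAA_bands")
        bands_present = severity_table.loc[severity_table["group"] == "DMD", "nsaa"] \
            .map(lambda s: nsaa_band(int(s)).value).nunique()
        assert len(rep) == bands_present  # one activity in fixture


class TestFeatureSummary:
    def test_summary_shape_and_pvalues(self, contrast_table):
        summary = feature_summary(contrast_table)
        # 1 activity + pooled "All", 8 features each
        assert len(summary) == 2 * 8
        sl = summary[(summary["activity"] == "SC-L3") & (summary["feature"] == "sl")]
        assert sl["p_value"].iloc[0] < 0.05  # patterned contrast on step length
        assert (sl["td_mean"] > sl["dmd_mean"]).all()
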