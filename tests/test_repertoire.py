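"""Cohort statistics: frequencies, ratios, heat maps, t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bactoline import (ScreenCounts, frequencies, cohort_summary, switch_ratio,
                       specific_fraction, crossreactivity, heatmap,
                       heatmap_difference, ttest_two_tailed, round_half_up)
from bactoline.calibration import KD_CLASSES, EPITOPE_CLASSES


def records_frame(rows):
    return pd.DataFrame(rows, columns=["kd_class", "epitope_class"]).assign(
        excluded_reason=None)


class TestFrequencies:
    def test_lambda_scaling(self):
        """30,000 droplets at occupancy 0.1 and 90 IgG-SCs is 3.0%."""
        c = ScreenCounts(n_droplets=30_000, lambda_occupancy=0.1, n_igg_sc=90)
        f = frequencies(c)
        assert f["cells_screened"] == 3000
        assert f["freq_igg"] == pytest.approx(3.0)

    def test_total_is_sum_of_isotypes(self):
        c = ScreenCounts(30_000, 0.1, n_igg_sc=90, n_igm_sc=60)
        f = frequencies(c)
        assert f["freq_ig_total"] == pytest.approx(f["freq_igg"] + f["freq_igm"])

    def test_no_secretors_flags_ratio_undefined(self):
        f = frequencies(ScreenCounts(1000, 0.2))
        assert f["freq_ig_total"] == 0.0
        assert np.isnan(f["switch_ratio"])

    def test_estimator_consistency_binomial(self):
        """A configured 3% rate is recovered within the binomial 95% CI."""
        rng = np.random.default_rng(21)
        n_cells, p = 3000, 0.03
        k = rng.binomial(n_cells, p)
        c = ScreenCounts(n_droplets=n_cells * 10, lambda_occupancy=0.1, n_igg_sc=k)
        est = frequencies(c)["freq_igg"] / 100.0
        half_ci = 1.96 * np.sqrt(p * (1 - p) / n_cells)
        assert abs(est - p) < half_ci


class TestRatios:
    def test_switch_ratio_near_one(self):
        assert switch_ratio(3.12, 3.2) == pytest.approx(0.975)
        assert round_half_up(switch_ratio(3.12, 3.2), 1) == 1.0

    def test_switch_ratio_edge_cases(self):
        assert switch_ratio(0.0, 2.0) == 0.0
        assert np.isnan(switch_ratio(1.0, 0.0))

    def test_specific_fractions_of_immunised_cohorts(self):
        assert specific_fraction(0.68, 3.12) == pytest.approx(0.218, abs=5e-4)
        assert specific_fraction(0.40, 2.17) == pytest.approx(0.184, abs=5e-4)
        assert specific_fraction(0.0, 3.0) == 0.0

    def test_crossreactivity(self):
        assert crossreactivity(0.6, 0.6) == pytest.approx(1.0)
        assert np.isnan(crossreactivity(0.5, 0.0))


class TestCohortSummary:
    def test_identical_mice_have_zero_spread(self):
        df = pd.DataFrame({"freq_igg": [2.0, 2.0, 2.0]})
        out = cohort_summary(df)
        assert out.loc[0, "sd"] == 0.0

    def test_adjuvant_only_cohort_prints_as_1_8_percent(self):
        """IgM 1.6% + IgG 0.15% totals 1.75%, printed 1.8% at one decimal."""
        df = pd.DataFrame({"freq_ig_total": [1.75, 1.75, 1.75]})
        out = cohort_summary(df)
        assert round_half_up(out.loc[0, "center"], 1) == 1.8

    def test_single_mouse_sd_undefined(self):
        out = cohort_summary(pd.DataFrame({"freq_igg": [2.0]}))
        assert np.isnan(out.loc[0, "sd"])

    def test_rates_summarised_by_median(self):
        df = pd.DataFrame({"sr": [100.0, 250.0, 1000.0]})
        out = cohort_summary(df, freq_cols=[], rate_cols=["sr"])
        assert out.loc[0, "center"] == 250.0
        assert out.loc[0, "center_kind"] == "median"


class TestHeatmap:
    def test_single_bin_concentration(self):
        recs = records_frame([("high", "high")] * 7)
        m = heatmap(recs)
        assert m.loc["high", "high"] == pytest.approx(1.0)
        assert m.loc["sum", "sum"] == pytest.approx(1.0)

    def test_uniform_mixture_near_one_ninth(self):
        rng = np.random.default_rng(17)
        rows = [(KD_CLASSES[rng.integers(3)], EPITOPE_CLASSES[rng.integers(3)])
                for _ in range(3000)]
        m = heatmap(records_frame(rows))
        inner = m.loc[list(KD_CLASSES), list(EPITOPE_CLASSES)].to_numpy()
        # multinomial 99.9% band around 1/9 at n = 3000
        assert np.all(np.abs(inner - 1 / 9) < 3.3 * np.sqrt((1 / 9) * (8 / 9) / 3000))

    def test_normalisation_and_marginals(self):
        rng = np.random.default_rng(23)
        rows = [(KD_CLASSES[rng.integers(3)], EPITOPE_CLASSES[rng.integers(3)])
                for _ in range(500)]
        m = heatmap(records_frame(rows))
        inner = m.loc[list(KD_CLASSES), list(EPITOPE_CLASSES)]
        assert inner.to_numpy().sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(m.loc[list(KD_CLASSES), "sum"],
                                   inner.sum(axis=1), rtol=1e-12)
        np.testing.assert_allclose(m.loc["sum", list(EPITOPE_CLASSES)],
                                   inner.sum(axis=0), rtol=1e-12)

    def test_empty_records_all_zero(self):
        m = heatmap(records_frame([]))
        assert (m.to_numpy() == 0).all()

    def test_difference_sums_to_zero(self):
        rng = np.random.default_rng(29)
        rows_a = [(KD_CLASSES[rng.integers(3)], EPITOPE_CLASSES[rng.integers(3)])
                  for _ in range(300)]
        rows_b = [(KD_CLASSES[rng.integers(3)], EPITOPE_CLASSES[rng.integers(3)])
                  for _ in range(400)]
        d = heatmap_difference(heatmap(records_frame(rows_a)),
                               heatmap(records_frame(rows_b)))
        inner = d.loc[list(KD_CLASSES), list(EPITOPE_CLASSES)].to_numpy()
        assert inner.sum() == pytest.approx(0.0, abs=1e-12)

    def test_identical_maps_difference_zero(self):
        m = heatmap(records_frame([("high", "low")] * 5))
        assert (heatmap_difference(m, m).to_numpy() == 0).all()


class TestTTest:
    def test_identical_groups_p_one(self):
        t, p = ttest_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_reference_implementation(self):
        """Pooled-variance closed form agrees with scipy on random fixtures."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 10))
            b = rng.normal(0.5, 2, rng.integers(3, 10))
            t, p = ttest_two_tailed(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_textbook_example(self):
        """Hand-checked 3-vs-3: t from the closed form, p via incomplete beta."""
        a, b = np.array([5.0, 6.0, 7.0]), np.array([8.0, 9.0, 10.0])
        t, p = ttest_two_tailed(a, b)
        # pooled sd = 1, se = sqrt(2/3), t = -3/sqrt(2/3)
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(t_expected, rel=1e-12)
        dof = 4
        p_expected = stats.beta.cdf(dof / (dof + t_expected ** 2), dof / 2, 0.5)
        assert p == pytest.approx(p_expected, rel=1e-10)

    def test_separated_zero_variance_groups(self):
        t, p = ttest_two_tailed([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_two_tailed([1.0], [2.0, 3.0])
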