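"""Summary-statistic tests, letter displays, credibility, threshold solve.

The four-species summary table frozen here (means, SEs, n = 3 throughout)
is the printed comparison of fitted and observed maximum electron transport
rates that the statistics must reproduce.
"""

import numpy as np
import pytest
from scipy import stats as sps

from etrfit.empirical_co2 import EmpiricalCO2Params, jfmax
from etrfit.errors import ValidationError
from etrfit.fit_engine import FitConfig
from etrfit.fvcb_model import FvCBParams, implied_f
from etrfit.intercompare import (
    GroupSummary,
    anova_letters,
    credibility_check,
    ja_max_at_b,
    observed_jfmax,
    threshold_b_coefficient,
    ttest_summary,
)
from etrfit.synthetic_data import ScenarioConfig, gen_aci, gen_jci

# species -> (sub-model I, sub-model II, empirical, observed) as (mean, se)
SUMMARY_TABLE = {
    "T_aestivum": [(316.53, 5.42), (363.02, 6.07), (291.47, 0.65), (293.78, 3.13)],
    "S_perfoliatum": [(224.04, 2.47), (255.74, 2.73), (237.76, 1.36), (235.76, 0.98)],
    "L_perenne": [(276.18, 7.20), (315.66, 8.57), (297.03, 10.23), (283.85, 3.36)],
    "T_pratense": [(214.88, 3.31), (247.48, 3.60), (256.19, 6.17), (250.17, 4.33)],
}
GROUP_KEYS = ("submodel_I", "submodel_II", "empirical", "observed")
EXPECTED_LETTERS = {
    "T_aestivum": ("b", "a", "c", "c"),
    "S_perfoliatum": ("c", "a", "b", "b"),
    "L_perenne": ("b", "a", "b", "b"),
    "T_pratense": ("b", "a", "a", "a"),
}


def table_groups(species):
    return [
        GroupSummary(k, m, se, 3)
        for k, (m, se) in zip(GROUP_KEYS, SUMMARY_TABLE[species])
    ]


class TestTTestSummary:
    def test_wheat_submodel_I_vs_observed(self):
        # t = 22.75 / sqrt(5.42^2 + 3.13^2) for equal n=3 pooled test
        res = ttest_summary(GroupSummary("I", 316.53, 5.42, 3), GroupSummary("obs", 293.78, 3.13, 3))
        assert res.t == pytest.approx(22.75 / np.sqrt(5.42**2 + 3.13**2), rel=1e-6)
        assert res.df == 4
        assert res.significant

    def test_clover_submodel_II_vs_observed_not_significant(self):
        res = ttest_summary(GroupSummary("II", 247.48, 3.60, 3), GroupSummary("obs", 250.17, 4.33, 3))
        assert abs(res.t) == pytest.approx(0.478, abs=5e-3)
        assert not res.significant

    def test_identical_groups_null(self):
        g = GroupSummary("x", 100.0, 2.0, 3)
        res = ttest_summary(g, g)
        assert res.t == 0.0
        assert res.p == 1.0
        assert not res.significant

    def test_matches_scipy_from_stats(self):
        # independent cross-check against scipy's summary-statistic t-test
        g1, g2 = GroupSummary("a", 316.53, 5.42, 3), GroupSummary("b", 293.78, 3.13, 3)
        ours = ttest_summary(g1, g2)
        t, p = sps.ttest_ind_from_stats(
            g1.mean, np.sqrt(g1.variance), g1.n, g2.mean, np.sqrt(g2.variance), g2.n
        )
        assert ours.t == pytest.approx(t, rel=1e-12)
        assert ours.p == pytest.approx(p, rel=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            ttest_summary(GroupSummary("a", 1.0, 0.0, 1), GroupSummary("b", 2.0, 1.0, 3))


class TestAnovaLetters:
    @pytest.mark.parametrize("species", list(SUMMARY_TABLE))
    def test_observed_anchored_letters_reproduce_table(self, species):
        _, letters, _ = anova_letters(table_groups(species), reference="observed")
        assert tuple(letters[k] for k in GROUP_KEYS) == EXPECTED_LETTERS[species]

    def test_standard_display_wheat(self):
        # with a clear separation structure both conventions agree
        _, letters, _ = anova_letters(table_groups("T_aestivum"))
        assert tuple(letters[k] for k in GROUP_KEYS) == ("b", "a", "c", "c")

    def test_same_letter_iff_not_significant_in_standard_display(self):
        _, letters, pairwise = anova_letters(table_groups("S_perfoliatum"))
        for (l1, l2), res in pairwise.items():
            shared = set(letters[l1]) & set(letters[l2])
            assert bool(shared) == (not res.significant)

    def test_identical_groups_share_a(self):
        groups = [GroupSummary(f"g{i}", 100.0, 0.0, 3) for i in range(3)]
        _, letters, _ = anova_letters(groups)
        assert set(letters.values()) == {"a"}

    def test_anova_f_matches_scipy_oneway_on_raw_data(self, rng):
        # build raw groups, summarize, and compare the summary-based F with
        # scipy.stats.f_oneway on the raw values
        raw = [rng.normal(loc, 2.0, 6) for loc in (10.0, 12.0, 15.0)]
        groups = [GroupSummary(f"g{i}", v.mean(), v.std(ddof=1) / np.sqrt(v.size), v.size)
                  for i, v in enumerate(raw)]
        anova, _, _ = anova_letters(groups)
        f_ref, p_ref = sps.f_oneway(*raw)
        assert anova.f == pytest.approx(f_ref, rel=1e-10)
        assert anova.p == pytest.approx(p_ref, rel=1e-10)


class TestObservedJfmax:
    def test_single_replicate_flagged_with_zero_se(self):
        ds = gen_jci(ScenarioConfig(truth=EmpiricalCO2Params(1.88, 0.0005, 0.004, 60.0),
                                    n_reps=1, noise_sd=0.0, seed=3))
        with pytest.warns(UserWarning, match="single replicate"):
            g = observed_jfmax(ds.curves)
        assert g.n == 1 and g.se == 0.0

    def test_noiseless_replicates_zero_se(self):
        ds = gen_jci(ScenarioConfig(truth=EmpiricalCO2Params(1.88, 0.0005, 0.004, 60.0),
                                    n_reps=3, noise_sd=0.0, seed=3))
        g = observed_jfmax(ds.curves)
        assert g.se == 0.0 and g.n == 3

    def test_mean_near_generating_jfmax(self):
        truth = EmpiricalCO2Params(0.9, 0.0005, 0.004, 20.0)  # Jf-max = 132.5
        ds = gen_jci(ScenarioConfig(truth=truth, n_reps=3, noise_sd=1.0, seed=11))
        g = observed_jfmax(ds.curves)
        # grid max <= true max; noise sd 1.0 across 12 levels
        assert abs(g.mean - jfmax(truth)) < 2.0

    def test_aci_curves_rejected(self):
        from etrfit.synthetic_data import DEFAULT_FVCB_TRUTH

        ds = gen_aci(ScenarioConfig(truth=DEFAULT_FVCB_TRUTH, n_reps=1, noise_sd=0.0, seed=1))
        with pytest.raises(ValidationError):
            observed_jfmax(ds.curves)


class TestCredibility:
    def test_wheat_style_overestimate(self):
        v = credibility_check(GroupSummary("I", 316.53, 5.42, 3), GroupSummary("obs", 293.78, 3.13, 3))
        assert v.is_overestimate

    def test_estimate_below_observation_consistent(self):
        v = credibility_check(GroupSummary("I", 224.04, 2.47, 3), GroupSummary("obs", 235.76, 0.98, 3))
        assert v.status == "consistent"

    def test_equal_means_consistent(self):
        a = GroupSummary("I", 250.0, 3.0, 3)
        b = GroupSummary("obs", 250.0, 3.0, 3)
        assert credibility_check(a, b).status == "consistent"

    def test_antisymmetric_under_swap(self):
        a = GroupSummary("I", 316.53, 5.42, 3)
        b = GroupSummary("obs", 293.78, 3.13, 3)
        assert credibility_check(a, b).is_overestimate
        assert credibility_check(b, a).status == "consistent"


@pytest.fixture(scope="module")
def threshold_scenario(light_config):
    """Warm-leaf truth whose RuBP-limited phase sits at low-mid Ci, giving
    the Gamma*-coefficient real leverage over the fitted J."""
    truth = FvCBParams(vcmax=200.0, j=200.0, tpu=12.0, rd=1.5, gamma_star=55.0)
    ds = gen_aci(ScenarioConfig(truth=truth, n_reps=3, noise_sd=0.3, seed=123))
    fixed = {"rd": truth.rd, "gamma_star": truth.gamma_star}
    j8 = ja_max_at_b(ds.curves, 8.0, light_config, fixed=fixed)
    return ds.curves, fixed, j8


class TestThreshold:
    def test_fixed_point_at_b8(self, threshold_scenario, light_config):
        curves, fixed, j8 = threshold_scenario
        res = threshold_b_coefficient(curves, j8, light_config, fixed=fixed)
        assert res.found
        assert res.b_star == pytest.approx(8.0, abs=0.05)

    def test_lower_target_gives_smaller_b_and_larger_f(self, threshold_scenario, light_config):
        curves, fixed, j8 = threshold_scenario
        res = threshold_b_coefficient(curves, 0.9 * j8, light_config, fixed=fixed)
        assert res.found and res.b_star < 8.0
        assert res.implied_f > 0.5
        assert res.implied_f == pytest.approx(implied_f(res.b_star), rel=1e-12)

    def test_higher_target_gives_larger_b(self, threshold_scenario, light_config):
        curves, fixed, j8 = threshold_scenario
        res = threshold_b_coefficient(curves, 1.1 * j8, light_config, fixed=fixed)
        assert res.found and res.b_star > 8.0

    def test_mean_j_monotone_in_b(self, threshold_scenario, light_config):
        curves, fixed, _ = threshold_scenario
        js = [ja_max_at_b(curves, b, light_config, fixed=fixed) for b in (4.5, 6.0, 8.0, 10.0, 12.0)]
        assert np.all(np.diff(js) > 0)

    def test_unreachable_target_reports_no_solution(self, threshold_scenario, light_config):
        curves, fixed, j8 = threshold_scenario
        res = threshold_b_coefficient(curves, 3.0 * j8, light_config, fixed=fixed)
        assert not res.found
        assert res.b_star is None and "no sign change" in res.message
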