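import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gazegrade as gg
from gazegrade.bias import (cohort_summary, decompose_bias, decompose_rater,
                            fixation_shift, observed_bias, one_way_anova,
                            paired_t, per_rater_deltas, stratify_bias,
                            validate_pairing)
from gazegrade.errors import InputError, UndefinedAggregateError, ValidationError
from gazegrade.morphometry import FEATURE_NAMES
from gazegrade.profiles import RaterProfile

from oracles import paired_t_closed_form


def grades_frame(rows):
    return pd.DataFrame(rows, columns=["rater_id", "case_id", "condition",
                                       "grade"])


def paired_grades(per_rater_means):
    """One case per rater pair of condition means (simplest paired table)."""
    rows = []
    for i, (tub, sol) in enumerate(per_rater_means):
        rows.append((f"r{i}", "c0", "tubular", tub))
        rows.append((f"r{i}", "c0", "solid", sol))
    return grades_frame(rows)


class TestObservedBias:
    def test_identical_conditions_give_zero_deltas_and_t(self):
        g = paired_grades([(2.0, 2.0), (2.5, 2.5), (1.5, 1.5)])
        deltas, test = observed_bias(g)
        assert (deltas["observed_delta"] == 0).all()
        assert test.t == 0.0 and test.degenerate

    def test_three_rater_example_t2_is_eleven(self):
        g = paired_grades([(2.0, 2.4), (2.1, 2.5), (1.9, 2.2)])
        deltas, test = observed_bias(g)
        assert np.allclose(sorted(deltas["observed_delta"]), [0.3, 0.4, 0.4])
        assert test.df == 2
        assert test.t == pytest.approx(11.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        means = [(rng.uniform(1.5, 2.5), rng.uniform(1.8, 2.8))
                 for _ in range(n)]
        _, test = observed_bias(paired_grades(means))
        t, df, p = paired_t_closed_form([m[1] for m in means],
                                        [m[0] for m in means])
        assert test.t == pytest.approx(t)
        assert test.df == df
        assert test.p == pytest.approx(p)

    def test_missing_condition_partner_names_the_pair(self):
        g = grades_frame([("r0", "c0", "tubular", 2.0),
                          ("r0", "c0", "solid", 2.5),
                          ("r1", "c0", "tubular", 2.0)])
        with pytest.raises(ValidationError, match="'r1'.*'c0'"):
            validate_pairing(g)

    def test_duplicate_grade_rejected(self):
        g = grades_frame([("r0", "c0", "tubular", 2.0),
                          ("r0", "c0", "tubular", 2.5),
                          ("r0", "c0", "solid", 2.5)])
        with pytest.raises(ValidationError, match="duplicate"):
            validate_pairing(g)

    def test_mean_delta_recovery_with_null_selection(self):
        # pure architecture offset 0.40, no selection: the pipeline's mean
        # recovered delta must land within 0.05 of the generative value
        cfg = gg.default_config(selection_strength=0.0, grade_bias_delta=0.40,
                                gleason_modulation=0.0)
        deltas = []
        for seed in range(30):
            c = gg.simulate_cohort(cfg, seed=seed, render=False)
            d, _ = observed_bias(c.grades)
            deltas.append(d["observed_delta"].mean())
        assert abs(np.mean(deltas) - 0.40) < 0.05


class TestStratifyBias:
    def _cohort_grades(self, seed=0):
        c = gg.simulate_cohort(gg.default_config(n_cases=8, n_raters=8),
                               seed=seed, render=False)
        return c.grades

    def test_gleason_classes_differ_by_construction(self):
        table, test = stratify_bias(self._cohort_grades(), "gleason_delta_class")
        means = table.groupby("gleason_delta_class")["observed_delta"].mean()
        assert means["gt_1_5"] > means["eq_1_5"]
        assert set(table["gleason_delta_class"]) == {"eq_1_5", "gt_1_5"}

    def test_identical_deltas_across_groups_give_zero_f(self):
        rows = []
        for i in range(8):
            rows.append({"rater_id": f"r{i}", "case_id": "c0",
                         "condition": "tubular", "grade": 2.0,
                         "rater_group": ["a", "b"][i % 2]})
            rows.append({"rater_id": f"r{i}", "case_id": "c0",
                         "condition": "solid", "grade": 2.0 + 0.1 * (i // 2),
                         "rater_group": ["a", "b"][i % 2]})
        table, test = stratify_bias(pd.DataFrame(rows), "rater_group")
        # groups a and b see the same multiset of deltas
        assert test.F == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_strata_flagged_not_crashed(self):
        rows = []
        for i in range(4):
            for cls, d in (("eq_1_5", 0.0), ("gt_1_5", 0.25)):
                rows.append({"rater_id": f"r{i}", "case_id": f"c_{cls}",
                             "condition": "tubular", "grade": 2.0,
                             "gleason_delta_class": cls})
                rows.append({"rater_id": f"r{i}", "case_id": f"c_{cls}",
                             "condition": "solid", "grade": 2.0 + d,
                             "gleason_delta_class": cls})
        table, test = stratify_bias(pd.DataFrame(rows), "gleason_delta_class")
        assert test.degenerate

    def test_experience_groups_null_anova_p_uniform(self):
        # equal group means by construction: the ANOVA p-value over many
        # seeded cohorts must be consistent with Uniform(0, 1)
        ps = []
        for seed in range(200):
            c = gg.simulate_cohort(gg.default_config(n_cases=4, n_raters=16),
                                   seed=seed, render=False)
            _, test = stratify_bias(c.grades, "rater_group")
            ps.append(test.p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_prostate_reader_stratification_runs(self):
        # needs the full 20-rater panel so both reader groups are populated
        c = gg.simulate_cohort(gg.default_config(n_cases=4), seed=2,
                               render=False)
        table, test = stratify_bias(c.grades, "prostate_reader")
        assert test.df_between == 1
        assert test.df_within == 18

    def test_unknown_stratification_rejected(self):
        with pytest.raises(InputError):
            stratify_bias(self._cohort_grades(), "shoe_size")


class TestFixationShift:
    def _fixated(self, rows):
        recs = []
        for rid, cond, size in rows:
            recs.append({"rater_id": rid, "condition": cond,
                         "size_px": size, "hyperchromasia": 130.0,
                         "heterochromasia": 45.0, "roundness": 0.9})
        return pd.DataFrame(recs)

    def test_identical_conditions_all_t_zero(self):
        rows = [(f"r{i}", cond, 3200.0) for i in range(5)
                for cond in ("tubular", "solid")]
        sh = fixation_shift(self._fixated(rows))
        assert (sh["t"] == 0).all()
        assert sh["degenerate"].all()

    def test_constant_positive_shift_detected(self):
        rows = []
        for i in range(6):
            rows.append((f"r{i}", "tubular", 3150.0 + i))
            rows.append((f"r{i}", "solid", 3260.0 + 2 * i))
        sh = fixation_shift(self._fixated(rows)).set_index("feature")
        assert sh.loc["size_px", "shift"] == pytest.approx(110.0 + 2.5)
        assert sh.loc["size_px", "p"] < 0.01
        assert sh.loc["roundness", "t"] == 0.0


class TestDecomposition:
    def profile(self, feature="size_px", slope=0.001):
        rho = {f: 0.0 for f in FEATURE_NAMES}
        p = {f: 1.0 for f in FEATURE_NAMES}
        if feature is not None:
            rho[feature], p[feature] = 0.8, 1e-4
        return RaterProfile("r0", rho, p, preferred_feature=feature,
                            slope=None if feature is None else slope,
                            intercept=None if feature is None else 1.0)

    def test_no_preferred_feature_gives_zero_fraction(self):
        dec = decompose_rater(self.profile(None), None, observed_delta=0.4)
        assert dec.predicted_delta == 0.0
        assert dec.fraction_explained == 0.0

    def test_linear_propagation_full_fraction(self):
        # slope 0.001 grade/px and a 111 px fixated-size shift explain a
        # 0.111 observed delta entirely
        dec = decompose_rater(self.profile(), 111.0, observed_delta=0.111)
        assert dec.fraction_explained == pytest.approx(1.0)

    def test_zero_observed_delta_undefined_fraction(self):
        dec = decompose_rater(self.profile(), 50.0, observed_delta=0.0)
        assert dec.fraction_explained is None

    def test_fraction_invariant_under_affine_feature_rescaling(self):
        # feature -> a*feature + b rescales slope by 1/a and shift by a
        a = 0.037
        d1 = decompose_rater(self.profile(slope=0.001), 111.0, 0.3)
        d2 = decompose_rater(self.profile(slope=0.001 / a), 111.0 * a, 0.3)
        assert d1.fraction_explained == pytest.approx(d2.fraction_explained)

    def test_cohort_summary_recomputable_from_table(self):
        df = pd.DataFrame({
            "rater_id": ["a", "b", "c", "d"],
            "observed_delta": [0.4, 0.4, 0.4, 0.0],
            "predicted_delta": [0.04, 0.12, -0.02, 0.0],
            "fraction_explained": [0.1, 0.3, -0.05, None],
            "preferred_feature": ["size_px"] * 3 + ["none"],
            "slope": [1e-3] * 3 + [np.nan],
        })
        s = cohort_summary(df)
        assert s["n_raters"] == 3
        assert s["mean_pct"] == pytest.approx(100 * np.mean([0.1, 0.3, -0.05]))
        assert s["median_pct"] == pytest.approx(10.0)
        assert (s["min_pct"], s["max_pct"]) == (pytest.approx(-5.0),
                                                pytest.approx(30.0))
        assert s["n_outside_0_100"] == 1

    def test_summary_of_all_undefined_raises(self):
        df = pd.DataFrame({"fraction_explained": [None, None]})
        with pytest.raises(UndefinedAggregateError):
            cohort_summary(df)


class TestAnovaHelper:
    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0.4, 0.1, 5) for _ in range(4)]
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df_between == 3 and res.df_within == 16
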