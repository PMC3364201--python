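import numpy as np
import pandas as pd
import pytest

import gazegrade as gg
from gazegrade.gaze import GazeConfig, detect_fixations
from gazegrade.morphometry import FEATURE_NAMES
from gazegrade.synthetic import (RaterTruth, _rng, generate_field,
                                 round_half_step, select_fixated,
                                 simulate_grade)


class TestFieldGeneration:
    def test_zero_boundary_noise_keeps_nuclei_round(self):
        cfg = gg.default_config(boundary_noise=0.0, nuclei_per_field=25,
                                field_diameter_px=900)
        field, records = generate_field(cfg, "caseA", "tubular",
                                        np.random.default_rng(0))
        assert len(records) == 25
        assert all(r.features.roundness >= 0.95 for r in records)

    def test_same_seed_identical_rasters(self):
        cfg = gg.default_config(nuclei_per_field=15, field_diameter_px=700)
        f1, _ = generate_field(cfg, "caseA", "solid", np.random.default_rng(3))
        f2, _ = generate_field(cfg, "caseA", "solid", np.random.default_rng(3))
        assert np.array_equal(f1.labels, f2.labels)
        assert np.array_equal(f1.intensity, f2.intensity)

    def test_rendered_size_mean_matches_generative_mean(self):
        # 1000 nuclei through the render -> extract round trip
        cfg = gg.default_config(n_cases=2, nuclei_per_field=250,
                                field_diameter_px=2600, case_size_cv=0.0,
                                n_raters=1)
        cohort = gg.simulate_cohort(cfg, seed=4, render=True)
        sizes = cohort.nuclei["size_px"].to_numpy(float)
        assert len(sizes) == 1000
        se = sizes.std(ddof=1) / np.sqrt(len(sizes))
        # contour noise inflates painted area by ~boundary_noise^2
        expected = cfg.mean_size_px * (1 + cfg.boundary_noise**2)
        assert abs(sizes.mean() - expected) < 3 * se

    def test_nuclei_do_not_overlap_and_sit_inside_circle(self):
        cfg = gg.default_config(nuclei_per_field=30, field_diameter_px=1000)
        field, records = generate_field(cfg, "caseB", "tubular",
                                        np.random.default_rng(9))
        cy, cx, R = field.circle
        rr, cc = np.nonzero(field.labels)
        assert (np.hypot(rr - cy, cc - cx) <= R).all()


class TestSelection:
    def _field_nuclei(self):
        cfg = gg.default_config(n_cases=1, n_raters=1)
        c = gg.simulate_cohort(cfg, seed=0, render=False)
        return c.nuclei[c.nuclei.field_id == "case00_tub"]

    def test_null_selection_no_feature_shift(self):
        cfg = gg.default_config(selection_strength=0.0)
        nuc = self._field_nuclei()
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(200):
            s = nuc[nuc.label.isin(select_fixated(cfg, nuc, "solid", rng))]
            t = nuc[nuc.label.isin(select_fixated(cfg, nuc, "tubular", rng))]
            diffs.append(s["size_px"].mean() - t["size_px"].mean())
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_strong_selection_always_directional(self):
        cfg = gg.default_config(selection_strength=1.5)
        nuc = self._field_nuclei()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sol = [nuc[nuc.label.isin(select_fixated(cfg, nuc, "solid", rng))]
                   ["size_px"].mean() for _ in range(20)]
            tub = [nuc[nuc.label.isin(select_fixated(cfg, nuc, "tubular", rng))]
                   ["size_px"].mean() for _ in range(20)]
            assert np.mean(sol) > np.mean(tub)

    def test_selection_goes_dark_not_round(self, small_tabular_cohort):
        # solid-condition fixations prefer darker (lower grey) nuclei and
        # ignore roundness entirely under the default composite weights
        fx = small_tabular_cohort.fixated
        by = fx.groupby("condition")[list(FEATURE_NAMES)].mean()
        assert by.loc["solid", "hyperchromasia"] < by.loc["tubular",
                                                          "hyperchromasia"]


class TestGazeContract:
    def test_every_generated_fixation_survives_detection(
            self, small_rendered_cohort):
        cfg = GazeConfig()
        cohort = small_rendered_cohort
        for (rid, fid), stream in cohort.gaze.items():
            fixations = detect_fixations(stream, cfg)
            assert len(fixations) >= len(cohort.truth.fixated_labels[(rid, fid)])
            for f in fixations:
                assert f.duration_ms >= cfg.min_duration_ms

    def test_streams_are_50hz_and_within_trial(self, small_rendered_cohort):
        for stream in small_rendered_cohort.gaze.values():
            assert np.allclose(np.diff(stream.t_ms), 20.0)
            assert stream.t_ms[-1] < 8000.0


class TestGrades:
    def rater(self, slope=0.0, intercept=2.2, pref=None):
        return RaterTruth("r0", pref, slope, intercept, "junior_resident",
                          False)

    def test_flat_rater_emits_rounded_intercept(self):
        cfg = gg.default_config(grade_noise_sd=0.0)
        rng = np.random.default_rng(0)
        g = [simulate_grade(cfg, self.rater(intercept=2.2), None, 0.0, rng)
             for _ in range(10)]
        assert set(g) == {2.0}

    def test_pure_offset_shifts_every_pair_before_rounding(self):
        cfg = gg.default_config(grade_noise_sd=0.0, half_step=False)
        rng = np.random.default_rng(0)
        r = self.rater(intercept=2.0)
        tub = simulate_grade(cfg, r, None, 0.0, rng)
        sol = simulate_grade(cfg, r, None, 0.5, rng)
        assert sol - tub == pytest.approx(0.5)

    @pytest.mark.parametrize("x,expected", [
        (1.25, 1.5), (1.2, 1.0), (2.74, 2.5), (2.76, 3.0),
        (1.75, 2.0), (2.0, 2.0),
    ])
    def test_half_step_rounding_half_up(self, x, expected):
        assert round_half_step(x) == expected

    def test_grades_clamped_to_scale(self):
        cfg = gg.default_config(grade_noise_sd=2.0)
        rng = np.random.default_rng(1)
        g = [simulate_grade(cfg, self.rater(), None, 0.0, rng)
             for _ in range(200)]
        assert min(g) >= 1.0 and max(g) <= 3.0
        assert set(np.round(np.asarray(g) * 2) % 1) == {0.0}

    def test_condition_means_land_near_calibration_targets(self):
        tub, sol = [], []
        for seed in range(10):
            c = gg.simulate_cohort(gg.default_config(), seed=seed,
                                   render=False)
            d, _ = gg.observed_bias(c.grades)
            tub.append(d["mean_tubular"].mean())
            sol.append(d["mean_solid"].mean())
        assert abs(np.mean(tub) - 2.02) < 0.1
        assert abs(np.mean(sol) - 2.42) < 0.1


class TestDeterminismAndHierarchy:
    def test_same_seed_same_cohort(self):
        cfg = gg.default_config(n_cases=3, n_raters=3)
        a = gg.simulate_cohort(cfg, seed=77, render=False)
        b = gg.simulate_cohort(cfg, seed=77, render=False)
        pd.testing.assert_frame_equal(a.nuclei, b.nuclei)
        pd.testing.assert_frame_equal(a.grades, b.grades)
        pd.testing.assert_frame_equal(a.matrix_trials, b.matrix_trials)
        assert a.truth.fixated_labels == b.truth.fixated_labels

    def test_adding_raters_preserves_cases_and_existing_raters(self):
        cfg2 = gg.default_config(n_cases=3, n_raters=2)
        cfg4 = gg.default_config(n_cases=3, n_raters=4)
        a = gg.simulate_cohort(cfg2, seed=5, render=False)
        b = gg.simulate_cohort(cfg4, seed=5, render=False)
        pd.testing.assert_frame_equal(a.nuclei, b.nuclei)
        ga = a.grades.set_index(["rater_id", "field_id"]).sort_index()
        gb = (b.grades[b.grades.rater_id.isin(["r00", "r01"])]
              .set_index(["rater_id", "field_id"]).sort_index())
        pd.testing.assert_frame_equal(ga, gb)

    def test_ground_truth_reproduces_fixated_means(self, small_tabular_cohort):
        c = small_tabular_cohort
        nuc = c.nuclei.set_index(["field_id", "label"])
        for row in c.fixated.itertuples(index=False):
            labels = c.truth.fixated_labels[(row.rater_id, row.field_id)]
            sub = nuc.loc[[(row.field_id, l) for l in labels]]
            assert row.size_px == pytest.approx(sub["size_px"].mean())
            assert row.roundness == pytest.approx(sub["roundness"].mean())

    def test_case_pair_shares_nucleus_features(self, small_tabular_cohort):
        nuc = small_tabular_cohort.nuclei
        tub = nuc[nuc.field_id == "case01_tub"].set_index("label")
        sol = nuc[nuc.field_id == "case01_sol"].set_index("label")
        for col in FEATURE_NAMES:
            assert np.array_equal(tub[col].values, sol[col].values)
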