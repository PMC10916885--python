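import numpy as np
import pandas as pd
import pytest

from reference_impls import normal_quantile_high_precision
from shadowcue.sdt import (
    config_comparison_stats,
    differential_sensitivity,
    sdt_metrics,
    sliding_timecourse,
    split_half_summary,
)


class TestSDTMetrics:
    def test_chance_gives_zero(self):
        s = sdt_metrics(50, 50, 50, 50)
        assert s.dprime == pytest.approx(0.0)
        assert s.criterion == pytest.approx(0.0)
        assert s.diagonal_shift == pytest.approx(0.0)

    def test_symmetric_84_16_against_high_precision_oracle(self):
        s = sdt_metrics(84, 16, 16, 84)
        z = normal_quantile_high_precision(0.84)
        assert s.dprime == pytest.approx(2 * z, abs=1e-9)
        assert s.dprime == pytest.approx(1.989, abs=1e-3)
        assert s.criterion == pytest.approx(0.0, abs=1e-12)

    def test_extreme_proportion_correction(self):
        s = sdt_metrics(25, 25, 0, 50)
        assert s.p_fa == pytest.approx(1.0 / 100)
        s2 = sdt_metrics(50, 0, 10, 40)
        assert s2.p_hit == pytest.approx(1.0 - 1.0 / 100)

    def test_symmetries(self):
        a = sdt_metrics(70, 30, 20, 80)
        # swapping hit/fa proportions flips d' and preserves c
        b = sdt_metrics(20, 80, 70, 30)
        assert b.dprime == pytest.approx(-a.dprime)
        assert b.criterion == pytest.approx(a.criterion)
        # complementing both proportions flips both d' and c
        c = sdt_metrics(30, 70, 80, 20)
        assert c.dprime == pytest.approx(-a.dprime)
        assert c.criterion == pytest.approx(-a.criterion)

    def test_diagonal_shift_linearity(self):
        a = sdt_metrics(70, 30, 20, 80)
        assert a.diagonal_shift == pytest.approx(a.dprime - a.criterion)

    def test_missing_class_raises(self):
        with pytest.raises(ValueError):
            sdt_metrics(0, 0, 10, 40)


def make_frame(rows):
    return pd.DataFrame(rows)


def trials_for(observer, itype, n_cong_correct, n_cong, n_incong_correct, n_incong,
               t0=0.0, dt=3.0, mode="reliable", start=0):
    rows = []
    k = start
    for i in range(n_cong):
        correct = i < n_cong_correct
        rows.append(dict(observer_id=observer, block_id="b0", trial_index=k,
                         t_probe=t0 + k * dt, shadow_mode=mode, insertion_type=itype,
                         insertion_col=45, insertion_row=50, local_orientation=0.0,
                         congruent=True,
                         response="congruent" if correct else "incongruent",
                         correct=correct, consecutive_errors_after=0,
                         model_image_diff=0.0, model_object_diff=0.0,
                         model_excluded=False))
        k += 1
    for i in range(n_incong):
        correct = i < n_incong_correct
        rows.append(dict(observer_id=observer, block_id="b0", trial_index=k,
                         t_probe=t0 + k * dt, shadow_mode=mode, insertion_type=itype,
                         insertion_col=45, insertion_row=50, local_orientation=0.0,
                         congruent=False,
                         response="incongruent" if correct else "congruent",
                         correct=correct, consecutive_errors_after=0,
                         model_image_diff=0.0, model_object_diff=0.0,
                         model_excluded=False))
        k += 1
    return rows


class TestDifferentialSensitivity:
    def test_identical_statistics_give_zero(self):
        rows = trials_for("o1", "image_driven", 40, 50, 35, 50)
        rows += trials_for("o1", "object_driven", 40, 50, 35, 50, start=100)
        assert differential_sensitivity(make_frame(rows)) == pytest.approx(0.0)

    def test_composition_of_sdt_metrics(self):
        # image: hits 42/50, fa 10/50 ; object: hits 35/50, fa 15/50
        rows = trials_for("o1", "image_driven", 42, 50, 40, 50)
        rows += trials_for("o1", "object_driven", 35, 50, 35, 50, start=100)
        d_img = sdt_metrics(42, 8, 10, 40).dprime
        d_obj = sdt_metrics(35, 15, 15, 35).dprime
        assert differential_sensitivity(make_frame(rows)) == pytest.approx(d_img - d_obj)

    def test_insufficient_data_marker(self):
        rows = trials_for("o1", "image_driven", 40, 50, 35, 50)
        assert np.isnan(differential_sensitivity(make_frame(rows)))

    def test_invalid_responses_ignored(self):
        rows = trials_for("o1", "image_driven", 40, 50, 35, 50)
        rows += trials_for("o1", "object_driven", 40, 50, 35, 50, start=100)
        base = differential_sensitivity(make_frame(rows))
        extra = dict(rows[0], response="invalid", correct=None, trial_index=999,
                     t_probe=1.5)
        assert differential_sensitivity(make_frame(rows + [extra])) == pytest.approx(base)


class TestSlidingTimecourse:
    def _stationary_frame(self):
        rng = np.random.default_rng(0)
        rows = []
        for obs in ("o1", "o2", "o3"):
            k = 0
            for itype in ("image_driven", "object_driven"):
                for i in range(150):
                    cong = bool(rng.random() < 0.5)
                    correct = bool(rng.random() < 0.75)
                    resp = ("congruent" if cong else "incongruent") if correct else (
                        "incongruent" if cong else "congruent")
                    rows.append(dict(observer_id=obs, block_id="b", trial_index=k,
                                     t_probe=rng.uniform(0, 300), shadow_mode="reliable",
                                     insertion_type=itype, insertion_col=0,
                                     insertion_row=0, local_orientation=0.0,
                                     congruent=cong, response=resp, correct=correct,
                                     consecutive_errors_after=0, model_image_diff=0.0,
                                     model_object_diff=0.0, model_excluded=False))
                    k += 1
        return make_frame(rows)

    def test_whole_block_window_matches_block_level(self):
        df = self._stationary_frame()
        tc = sliding_timecourse(df, window=300.0, step=300.0)
        assert tc.centers.size == 1
        per_obs = [differential_sensitivity(df[df.observer_id == o])
                   for o in ("o1", "o2", "o3")]
        assert tc.delta_sensitivity[0] == pytest.approx(np.mean(per_obs))

    def test_stationary_flat_within_error(self):
        df = self._stationary_frame()
        tc = sliding_timecourse(df, window=120.0, step=30.0)
        vals = tc.delta_sensitivity[~np.isnan(tc.delta_sensitivity)]
        assert vals.size > 3
        assert np.nanstd(vals) < 0.6

    def test_empty_selection_flagged_not_raised(self):
        df = self._stationary_frame().iloc[:20]
        tc = sliding_timecourse(df, window=20.0, step=50.0)
        assert np.isnan(tc.delta_sensitivity).any() or (tc.n_valid == 0).any()


class TestSplitHalf:
    def test_stationary_early_equals_late(self):
        rows = []
        for obs in ("o1", "o2"):
            for half_start, start in ((0.0, 0), (150.0, 1000)):
                r1 = trials_for(obs, "image_driven", 40, 50, 35, 50, t0=half_start,
                                dt=0.01, start=start)
                r2 = trials_for(obs, "object_driven", 38, 50, 37, 50, t0=half_start,
                                dt=0.01, start=start + 200)
                rows += r1 + r2
        out = split_half_summary(make_frame(rows))
        early = out[out.half == "early"].set_index("observer_id").delta_sensitivity
        late = out[out.half == "late"].set_index("observer_id").delta_sensitivity
        assert np.allclose(early, late)

    def test_ci_attrs_present(self):
        rows = []
        for obs in ("o1", "o2", "o3"):
            rows += trials_for(obs, "image_driven", 40, 50, 35, 50, dt=0.01)
            rows += trials_for(obs, "object_driven", 30, 50, 30, 50, dt=0.01, start=200)
            rows += trials_for(obs, "image_driven", 40, 50, 35, 50, t0=200, dt=0.01,
                               start=400)
            rows += trials_for(obs, "object_driven", 30, 50, 30, 50, t0=200, dt=0.01,
                               start=600)
        out = split_half_summary(make_frame(rows))
        lo, hi = out.attrs["ci"]["early"]
        assert lo <= hi


class TestConfigComparison:
    def _shifts(self, effect=0.0, seed=0, n_obs=11):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_obs):
            base = rng.normal(1.0, 0.3)
            rows.append(dict(observer_id=f"o{i}", shadow_mode="reliable",
                             insertion_type="image_driven", dprime=0, criterion=0,
                             diagonal_shift=base + effect + rng.normal(0, 0.05)))
            rows.append(dict(observer_id=f"o{i}", shadow_mode="reliable",
                             insertion_type="object_driven", dprime=0, criterion=0,
                             diagonal_shift=base))
        return pd.DataFrame(rows)

    def test_null_by_construction(self):
        rep = config_comparison_stats(self._shifts(effect=0.0, seed=1), run_anova=False)
        assert rep["wilcoxon"]["reliable"]["p_corrected"] >= 0.05

    def test_strong_separation_significant(self):
        rep = config_comparison_stats(self._shifts(effect=1.0, seed=2), run_anova=False)
        w = rep["wilcoxon"]["reliable"]
        # all 11 observers positive: exact signed-rank minimum p = 2/2^11
        assert w["p_raw"] == pytest.approx(2 / 2**11, rel=0.01)
        assert w["p_corrected"] < 0.05

    def test_permuting_labels_destroys_significance(self):
        df = self._shifts(effect=1.0, seed=3)
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(20):
            perm = df.copy()
            for obs, sub in perm.groupby("observer_id"):
                if rng.random() < 0.5:
                    idx = sub.index
                    perm.loc[idx, "diagonal_shift"] = sub.diagonal_shift.values[::-1]
            rep = config_comparison_stats(perm, run_anova=False)
            ps.append(rep["wilcoxon"]["reliable"]["p_corrected"])
        assert np.median(ps) > 0.05

    def test_too_few_observers_raises(self):
        with pytest.raises(ValueError):
            config_comparison_stats(self._shifts(n_obs=3), run_anova=False)

    def test_bonferroni_cap(self):
        rep = config_comparison_stats(self._shifts(effect=0.0, seed=5), run_anova=False)
        assert rep["wilcoxon"]["reliable"]["p_corrected"] <= 1.0
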