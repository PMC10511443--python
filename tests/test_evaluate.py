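"""Split protocols and agreement statistics, with brute-force and closed forms."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from dualppg import (
    ErrorStats,
    MLPConfig,
    ValidationError,
    aami_check,
    bhs_grade,
    bland_altman_limits,
    compute_error_stats,
    loso_folds,
    pooled_split,
    run_loso_experiment,
)


def make_index(n_subjects: int, sessions_each: int):
    return [
        (f"S{i:03d}-r{j:02d}", f"S{i:03d}")
        for i in range(n_subjects)
        for j in range(sessions_each)
    ]


class TestLosoFolds:
    def test_eighteen_subjects_give_eighteen_folds(self):
        plan = loso_folds(make_index(18, 17), seed=0)
        assert len(plan.folds) == 18

    def test_test_subject_absent_from_train_and_val(self):
        plan = loso_folds(make_index(6, 3), seed=1)
        for fold in plan.folds:
            test_subjects = {sid.split("-")[0] for sid in fold.test}
            assert len(test_subjects) == 1
            other = set(fold.train) | set(fold.val)
            assert not any(sid.split("-")[0] in test_subjects for sid in other)
            assert fold.violations() == []

    def test_val_gets_fifteen_percent_of_remaining_sessions(self):
        # 17 remaining subjects x 17 sessions = 289; 15% is 43.35
        plan = loso_folds(make_index(18, 17), seed=2)
        for fold in plan.folds:
            assert len(fold.val) in (43, 44)
            assert len(fold.train) + len(fold.val) == 289

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            loso_folds(make_index(1, 5))


class TestPooledSplit:
    def test_hundred_sessions_split_70_15_15(self):
        plan = pooled_split(make_index(25, 4), seed=0)
        fold = plan.folds[0]
        assert (len(fold.train), len(fold.val), len(fold.test)) == (70, 15, 15)

    def test_sets_are_disjoint_and_exhaustive(self):
        index = make_index(10, 3)
        fold = pooled_split(index, seed=3).folds[0]
        union = set(fold.train) | set(fold.val) | set(fold.test)
        assert union == {sid for sid, _ in index}
        assert fold.violations() == []

    def test_same_seed_reproduces_the_plan(self):
        index = make_index(10, 3)
        assert pooled_split(index, seed=5) == pooled_split(index, seed=5)

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValidationError):
            pooled_split(make_index(3, 2))


class TestErrorStats:
    def test_perfect_agreement_gives_zero_me_and_sd(self):
        s = compute_error_stats(np.array([100.0, 120.0]), np.array([100.0, 120.0]))
        assert s.me == 0.0 and s.sd == 0.0

    def test_symmetric_unit_errors_give_sd_sqrt2(self):
        s = compute_error_stats(np.array([99.0, 101.0]), np.array([100.0, 100.0]))
        assert s.me == 0.0
        assert s.sd == pytest.approx(np.sqrt(2.0))

    def test_monte_carlo_recovers_the_generating_moments(self):
        rng = np.random.default_rng(17)
        err = rng.normal(0.44, 6.00, size=100_000)
        s = compute_error_stats(err + 100.0, np.full(err.size, 100.0))
        assert s.me == pytest.approx(0.44, abs=0.06)
        assert s.sd == pytest.approx(6.00, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_error_stats(np.zeros(3), np.zeros(4))


class TestBlandAltman:
    def test_zero_mean_limits_are_symmetric(self):
        ba = bland_altman_limits(0.0, 3.0)
        assert ba.loa_lower == -ba.loa_upper == pytest.approx(-5.88)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(me=st.floats(-20, 20), sd=st.floats(0, 20))
    def test_loa_identities_hold_exactly(self, me, sd):
        ba = bland_altman_limits(me, sd)
        assert ba.loa_upper - ba.loa_lower == pytest.approx(2 * 1.96 * sd, rel=1e-12, abs=1e-12)
        assert ba.loa_lower == me - 1.96 * sd
        assert ba.loa_upper == me + 1.96 * sd

    def test_normal_errors_fall_inside_the_limits_95pct_of_the_time(self):
        rng = np.random.default_rng(23)
        err = rng.normal(1.0, 5.0, size=100_000)
        stats = compute_error_stats(err, np.zeros(err.size))
        ba = bland_altman_limits(stats.me, stats.sd)
        frac = np.mean((err >= ba.loa_lower) & (err <= ba.loa_upper))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman_limits(0.0, -1.0)


class TestAami:
    @pytest.mark.parametrize(
        "me, sd, expected",
        [(0.44, 6.00, True), (5.0, 6.0, False), (0.0, 8.0, False), (-4.99, 7.99, True)],
    )
    def test_strict_boundaries(self, me, sd, expected):
        assert aami_check(ErrorStats(me=me, sd=sd, n=100)) is expected


class TestBhs:
    def test_all_zero_errors_grade_a(self):
        g = bhs_grade(np.zeros(50))
        assert (g.grade, g.pct_le5, g.pct_le10, g.pct_le15) == ("A", 100.0, 100.0, 100.0)

    def test_constructed_vector_matches_brute_force_count(self):
        errors = np.array([4, 4, 4, 4, 4, 12, 12, 12, 12, 16], dtype=float)
        g = bhs_grade(errors)
        assert (g.pct_le5, g.pct_le10, g.pct_le15) == (50.0, 50.0, 90.0)
        assert g.grade == "D"  # 50% within 10 mmHg fails even grade C's 65%

    def test_cumulative_percentages_are_non_decreasing(self, rng):
        g = bhs_grade(rng.normal(0, 8, 1000))
        assert g.pct_le5 <= g.pct_le10 <= g.pct_le15

    def test_folded_normal_matches_the_closed_form_within_half_point(self):
        rng = np.random.default_rng(31)
        err = np.abs(rng.normal(0.0, 6.0, size=100_000))
        g = bhs_grade(err)
        for pct, thr in ((g.pct_le5, 5.0), (g.pct_le10, 10.0), (g.pct_le15, 15.0)):
            want = 100.0 * (2.0 * spstats.norm.cdf(thr / 6.0) - 1.0)
            assert pct == pytest.approx(want, abs=0.5)
        assert g.grade == "B"


@pytest.fixture(scope="module")
def toy_features():
    """Tiny linear cohort: 5 subjects x 2 sessions x 25 windows."""
    import pandas as pd
    from dualppg.features import DBP_FEATURES

    rng = np.random.default_rng(41)
    rows = []
    for i in range(5):
        subj_shift = rng.normal(0, 1)
        for j in range(2):
            base = {n: rng.normal(0, 1) for n in DBP_FEATURES}
            for k in range(25):
                feats = {n: base[n] + rng.normal(0, 0.1) for n in DBP_FEATURES}
                y = 100 + 5 * feats["dc_difference"] + 2 * feats["k_value"] + subj_shift
                rows.append(
                    {
                        "session_id": f"S{i}-r{j}",
                        "subject_id": f"S{i}",
                        "window_start_s": 2.0 * k,
                        **feats,
                        "sbp_ref": y + 20,
                        "dbp_ref": y - 20,
                        "n_beats": 12,
                        "valid": True,
                    }
                )
    return pd.DataFrame(rows)


class TestExperimentHarness:
    def test_loso_report_is_complete_and_deterministic(self, toy_features):
        cfg = MLPConfig(max_epochs=30, early_stop_patience=5, seed=0)
        r1 = run_loso_experiment(toy_features, "SBP", cfg, seed=4)
        r2 = run_loso_experiment(toy_features, "SBP", cfg, seed=4)
        assert r1.stats.n == r2.stats.n
        assert r1.stats.me == pytest.approx(r2.stats.me, abs=1e-9)
        assert len(r1.per_fold) == 5
        assert set(r1.per_subject) == {f"S{i}" for i in range(5)}
        assert r1.bland_altman.loa_upper == pytest.approx(
            r1.stats.me + 1.96 * r1.stats.sd
        )

    def test_baseline_predictor_errors_match_manual_computation(self, toy_features):
        # the report's baseline is the train-mean predictor under the same folds
        cfg = MLPConfig(max_epochs=2, early_stop_patience=5, seed=0)
        rep = run_loso_experiment(toy_features, "SBP", cfg, seed=4)
        plan = loso_folds(
            list(dict.fromkeys(zip(toy_features["session_id"], toy_features["subject_id"]))),
            seed=4,
        )
        errs = []
        for fold in plan.folds:
            tr = toy_features[toy_features["session_id"].isin(fold.train)]
            te = toy_features[toy_features["session_id"].isin(fold.test)]
            errs.append(tr["sbp_ref"].mean() - te["sbp_ref"].to_numpy())
        manual = np.concatenate(errs)
        assert rep.baseline.me == pytest.approx(manual.mean())
        assert rep.baseline.sd == pytest.approx(manual.std(ddof=1))
        assert rep.baseline.n == manual.size
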