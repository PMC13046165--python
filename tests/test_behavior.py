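import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gradientshift.behavior import (build_behavior_table, compute_reactivity,
                                    compute_success, exclude_outliers,
                                    normalize_within_study, orient_ratings)


def _trials(look=(), regulate=(), lo=1.0, hi=9.0,
            orientation="higher_is_more_negative"):
    rows = []
    for cond, ratings in (("Look", look), ("Regulate", regulate)):
        for r in ratings:
            rows.append(("s1", "st1", cond, r, lo, hi, orientation))
    return pd.DataFrame(rows, columns=["subject_id", "study_id", "condition",
                                       "rating", "scale_min", "scale_max",
                                       "orientation"])


class TestSuccess:
    def test_oriented_difference(self):
        assert compute_success(_trials([3.0, 3.4], [2.0, 2.4])) == pytest.approx(1.0)

    def test_identical_conditions_zero(self):
        assert compute_success(_trials([2, 3, 4], [2, 3, 4])) == pytest.approx(0.0)

    def test_orientation_flip_on_1_5_scale(self):
        # higher = more positive, Look {2,2}, Regulate {4,4} on 1-5:
        # oriented via 6 - x -> Look {4,4}, Regulate {2,2} -> success +2
        t = _trials([2, 2], [4, 4], lo=1, hi=5,
                    orientation="higher_is_more_positive")
        assert compute_success(t) == pytest.approx(2.0)

    def test_missing_condition_named(self):
        with pytest.raises(ValueError, match="Regulate"):
            compute_success(_trials([2.0], []))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1, 9), min_size=1, max_size=10),
           st.lists(st.floats(1, 9), min_size=1, max_size=10))
    def test_orientation_invariance(self, look, regulate):
        # flipping the declared orientation together with the ratings
        # leaves success unchanged
        t1 = _trials(look, regulate)
        t2 = _trials([10 - x for x in look], [10 - x for x in regulate],
                     orientation="higher_is_more_positive")
        assert compute_success(t1) == pytest.approx(compute_success(t2), abs=1e-9)


class TestReactivity:
    def test_mean_of_look(self):
        assert compute_reactivity(_trials([2, 4], [1])) == pytest.approx(3.0)

    def test_single_trial(self):
        assert compute_reactivity(_trials([5], [1])) == pytest.approx(5.0)

    def test_matches_direct_mean(self, rng):
        ratings = rng.uniform(1, 9, size=1000)
        t = _trials(ratings, [1.0])
        assert compute_reactivity(t) == pytest.approx(float(np.mean(ratings)),
                                                      abs=1e-12)

    def test_no_look_trials_error(self):
        with pytest.raises(ValueError, match="Look"):
            compute_reactivity(_trials([], [2.0]))


class TestNormalize:
    def test_sample_sd_convention(self):
        z = normalize_within_study(pd.Series([1.0, 2.0, 3.0]),
                                   pd.Series(["a", "a", "a"]))
        assert np.allclose(z, [-1, 0, 1])

    def test_single_subject_study_error(self):
        with pytest.raises(ValueError, match="2 subjects"):
            normalize_within_study(pd.Series([1.0, 2.0, 3.0]),
                                   pd.Series(["a", "a", "b"]))

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_within_study(pd.Series([2.0, 2.0]), pd.Series(["a", "a"]))

    def test_matches_groupwise_oracle(self, rng):
        vals = pd.Series(rng.normal(5, 2, size=60))
        studies = pd.Series(rng.choice(["a", "b", "c"], size=60))
        z = normalize_within_study(vals, studies)
        for s in "abc":
            sel = studies == s
            expect = (vals[sel] - vals[sel].mean()) / vals[sel].std(ddof=1)
            assert np.allclose(z[sel], expect)
            assert abs(z[sel].mean()) < 1e-10
            assert abs(z[sel].std(ddof=1) - 1) < 1e-10


class TestOutliers:
    def test_borderline_not_flagged(self):
        # {0 x 9, 10}: mean 1, sd ~3.162; |10-1| = 9 < 3*3.162 -> kept
        scores = np.array([0.0] * 9 + [10.0])
        sd = scores.std(ddof=1)
        assert 9 < 3 * sd
        assert not exclude_outliers(scores).any()

    def test_all_equal_none_flagged(self):
        assert not exclude_outliers(np.full(5, 2.0)).any()

    def test_far_outlier_flagged(self, rng):
        scores = rng.normal(0, 1, size=200)
        scores[0] = scores.mean() + 5 * scores.std(ddof=1)
        flags = exclude_outliers(scores)
        assert flags[0]


class TestBehaviorTable:
    def test_full_table_from_cohort(self, cohort):
        table = build_behavior_table(cohort.trials, cohort.covariates,
                                     cohort.esm)
        assert len(table) == len(cohort.truth.subject_ids)
        # z-scores: mean 0, sd 1 within each study
        for _, grp in table.groupby("study_id"):
            assert abs(grp["success_z"].mean()) < 1e-10
            assert abs(grp["success_z"].std(ddof=1) - 1) < 1e-10
        # success_raw is close to the latent success the generator used
        latent = pd.Series(cohort.truth.latent_success,
                           index=cohort.truth.subject_ids)
        err = (table["success_raw"] - latent).abs()
        assert err.median() < 0.6   # trial-level noise only
        # table values agree with the per-subject scoring operations
        for sid in list(table.index)[:5]:
            grp = cohort.trials[cohort.trials["subject_id"] == sid]
            assert table.loc[sid, "success_raw"] == pytest.approx(
                compute_success(grp), abs=1e-12)
            assert table.loc[sid, "reactivity"] == pytest.approx(
                compute_reactivity(grp), abs=1e-12)

    def test_excluded_subjects_carry_reason(self, cohort):
        table = build_behavior_table(cohort.trials)
        flagged = table[table["excluded"]]
        assert (flagged["exclusion_reason"].str.len() > 0).all()
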