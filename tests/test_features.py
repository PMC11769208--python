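"""Tests for motion-feature extraction and likelihood derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msdrisk.core import DegenerateInputError, InvalidInputError
from msdrisk.features import (
    LikelihoodClippedWarning,
    MotionTrial,
    composite_parametric_score,
    compute_cumulative_moment,
    compute_max_moment,
    compute_rom,
    compute_side_shares,
    derive_likelihood,
    extract_features,
    segment_population,
    side_shares_table,
    split_trials,
    trials_to_frame,
)


class TestScalarMetrics:
    def test_rom_is_max_minus_min(self):
        assert compute_rom([0, 30, 80, 45]) == 80

    def test_rom_constant_series_is_zero(self):
        assert compute_rom([12.0] * 5) == 0

    def test_rom_sign_symmetric(self):
        series = np.array([0.0, 30.0, 80.0, 45.0])
        assert compute_rom(series) == compute_rom(-series)

    def test_rom_needs_two_samples(self):
        with pytest.raises(InvalidInputError):
            compute_rom([1.0])

    def test_max_moment_uses_magnitude(self):
        assert compute_max_moment([-12, 5, 9]) == 12

    def test_max_moment_homogeneous(self):
        m = np.array([-3.0, 7.0, 2.0])
        assert compute_max_moment(2 * m) == 2 * compute_max_moment(m)

    def test_cumulative_constant_moment(self):
        t = np.linspace(0, 3, 31)
        assert compute_cumulative_moment(np.full(31, 10.0), t) == pytest.approx(30.0)

    def test_cumulative_linear_ramp(self):
        t = np.linspace(0, 2, 21)
        assert compute_cumulative_moment(5.0 * t, t) == pytest.approx(10.0)

    def test_cumulative_additive_over_concatenation(self):
        t = np.linspace(0, 2, 21)
        m = np.sin(t) + 1
        whole = compute_cumulative_moment(m, t)
        parts = compute_cumulative_moment(m[:11], t[:11]) + \
            compute_cumulative_moment(m[10:], t[10:])
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_cumulative_misaligned_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_cumulative_moment([1.0, 2.0], [0.0, 1.0, 2.0])


class TestSideShares:
    def test_sixty_forty(self):
        assert compute_side_shares(60, 40) == (0.6, 0.4)

    def test_balanced(self):
        assert compute_side_shares(7.5, 7.5) == (0.5, 0.5)

    def test_one_sided(self):
        assert compute_side_shares(0, 5) == (0, 1)

    def test_both_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_side_shares(0, 0)

    @given(l=st.floats(0.01, 1e4), r=st.floats(0.01, 1e4))
    @settings(deadline=None)
    def test_shares_sum_to_one(self, l, r):
        a, b = compute_side_shares(l, r)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestLikelihoods:
    def test_male_segment_five_percent_above(self):
        assert derive_likelihood(1.05 * 42.0, 42.0) == pytest.approx(1.05)

    def test_female_segment_ten_percent_below(self):
        assert derive_likelihood(0.9 * 42.0, 42.0) == pytest.approx(0.9)

    def test_identity(self):
        assert derive_likelihood(3.3, 3.3) == 1.0

    def test_outlier_clipped_with_warning(self):
        with pytest.warns(LikelihoodClippedWarning):
            assert derive_likelihood(100.0, 1.0) == 3.0

    def test_nonpositive_population_rejected(self):
        with pytest.raises(InvalidInputError):
            derive_likelihood(1.0, 0.0)

    def test_composite_unit(self):
        assert composite_parametric_score(1, 1, 1) == 1

    def test_composite_double_weighted_cumulative(self):
        assert composite_parametric_score(1.0, 1.0, 1.2) == pytest.approx(1.1)

    def test_composite_symmetric_in_unit_weights(self):
        assert composite_parametric_score(1.3, 0.8, 1.0) == \
            composite_parametric_score(0.8, 1.3, 1.0)

    def test_composite_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            composite_parametric_score(1.0, 0.0, 1.0)


def _make_trial(subject="S1", scenario="no_assist", joint="shoulder",
                side="left", trial=0, scale=1.0):
    t = np.linspace(0, 2, 21)
    return MotionTrial(
        subject_id=subject, scenario=scenario, joint=joint, side=side,
        trial=trial, time=t, angle=40 * np.sin(np.pi * t / 2),
        moment=scale * 30 * np.sin(np.pi * t / 2) ** 2,
    )


class TestExtractFeatures:
    def test_averages_over_trials(self):
        trials = [_make_trial(trial=k, scale=s) for k, s in enumerate((1.0, 2.0))]
        feats = extract_features(trials)
        assert len(feats) == 1
        row = feats.iloc[0]
        # per-trial max moments are 30 and 60; the subject value is their mean
        assert row.max_moment == pytest.approx(45.0)
        assert row.n_trials == 2

    def test_scale_covariance_of_moments(self):
        base = extract_features([_make_trial()])
        scaled = extract_features([_make_trial(scale=3.0)])
        assert scaled.max_moment[0] == pytest.approx(3 * base.max_moment[0])
        assert scaled.cumulative_moment[0] == pytest.approx(
            3 * base.cumulative_moment[0])
        assert scaled.rom[0] == base.rom[0]

    def test_side_shares_table(self):
        trials = [_make_trial(side="left", scale=1.0),
                  _make_trial(side="right", scale=1.5)]
        shares = side_shares_table(extract_features(trials))
        row = shares.iloc[0]
        assert row.share_left == pytest.approx(1 / 2.5)
        assert row.share_left + row.share_right == pytest.approx(1.0)

    def test_midline_joint_defaults_to_even_shares(self):
        shares = side_shares_table(
            extract_features([_make_trial(joint="neck", side="midline")]))
        assert (shares.share_left == 0.5).all()

    def test_trial_validation(self):
        with pytest.raises(InvalidInputError):
            MotionTrial("S1", "belt", "neck", "midline",
                        time=[0.0, 1.0, 1.0], angle=[0, 1, 2], moment=[0, 1, 2])


class TestSegmentPopulation:
    @staticmethod
    def _metrics_frame(n_per_seg, male_shift, rng):
        rows = []
        for sex, mult in (("male", male_shift), ("female", 1.0)):
            for _ in range(n_per_seg):
                base = rng.lognormal(0, 0.1)
                rows.append({"sex": sex, "rom": 50 * mult * base,
                             "max_moment": 30 * base,
                             "cumulative_moment": 60 * base})
        return pd.DataFrame(rows)

    def test_equal_segments_unit_likelihood(self):
        frame = pd.DataFrame({
            "sex": ["male", "male", "female", "female"],
            "rom": [50.0] * 4, "max_moment": [30.0] * 4,
            "cumulative_moment": [60.0] * 4,
        })
        seg = segment_population(frame, "sex")
        assert np.allclose(seg["rom_likelihood"], 1.0)

    def test_single_segment_is_exactly_one(self):
        frame = pd.DataFrame({"sex": ["male"] * 3, "rom": [40.0, 50.0, 60.0],
                              "max_moment": [1.0] * 3,
                              "cumulative_moment": [1.0] * 3})
        seg = segment_population(frame, "sex")
        assert seg.loc["male", "rom_likelihood"] == 1.0

    def test_injected_effect_recovered(self):
        rng = np.random.default_rng(42)
        frame = self._metrics_frame(200, male_shift=1.10, rng=rng)
        seg = segment_population(frame, "sex")
        ratio = (seg.loc["male", "rom_likelihood"]
                 / seg.loc["female", "rom_likelihood"])
        assert ratio == pytest.approx(1.10, abs=0.02)
        # untouched metric stays near parity
        assert seg.loc["male", "max_moment_likelihood"] == pytest.approx(1.0, abs=0.03)

    def test_recovery_sharpens_with_sample_size(self):
        errs = []
        for n in (50, 200, 800):
            rng = np.random.default_rng(7)
            frame = self._metrics_frame(n, male_shift=1.10, rng=rng)
            seg = segment_population(frame, "sex")
            ratio = (seg.loc["male", "rom_likelihood"]
                     / seg.loc["female", "rom_likelihood"])
            # delta-method SE of a ratio of segment means with lognormal
            # (sigma=0.1) subject noise: ratio * sigma * sqrt(2/n)
            errs.append((abs(ratio - 1.10), 1.10 * 0.1 * np.sqrt(2.0 / n)))
        assert errs[-1][0] < 3 * errs[-1][1]
        assert errs[-1][0] < errs[0][0] + 3 * errs[0][1]

    def test_small_segment_warns(self):
        frame = pd.DataFrame({"sex": ["male", "female", "female"],
                              "rom": [50.0, 40.0, 45.0],
                              "max_moment": [1.0] * 3,
                              "cumulative_moment": [1.0] * 3})
        with pytest.warns(UserWarning, match="only 1 subject"):
            segment_population(frame, "sex")

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            segment_population(pd.DataFrame(), "sex")

    def test_scale_invariance_of_likelihoods(self):
        rng = np.random.default_rng(3)
        frame = self._metrics_frame(50, male_shift=1.2, rng=rng)
        seg1 = segment_population(frame, "sex")
        frame2 = frame.copy()
        for m in ("max_moment", "cumulative_moment"):
            frame2[m] *= 7.0
        seg2 = segment_population(frame2, "sex")
        for m in ("rom", "max_moment", "cumulative_moment"):
            assert np.allclose(seg1[f"{m}_likelihood"], seg2[f"{m}_likelihood"])


class TestSplitTrials:
    def test_two_bumps_with_rest_between(self):
        t = np.linspace(0, 10, 1001)
        angle = np.where((t > 1) & (t < 4), 30 * np.sin(np.pi * (t - 1) / 3), 0)
        angle = angle + np.where((t > 6) & (t < 9),
                                 30 * np.sin(np.pi * (t - 6) / 3), 0)
        segments = split_trials(t, angle)
        assert len(segments) == 2
        s0, s1 = segments
        assert t[s0[0]] == pytest.approx(1.0, abs=0.2)
        assert t[s1[0]] == pytest.approx(6.0, abs=0.2)
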