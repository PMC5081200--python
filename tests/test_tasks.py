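"""Cue trains, filtered noise and the experiment target functions."""

import numpy as np
import pytest

from delayrc.exceptions import ConfigurationError
from delayrc.tasks import (
    CUE_MINUS,
    CUE_PLUS,
    gaussian_filter_steps,
    generate_cue_train,
    generate_filtered_noise,
    make_experiment,
    phased_cue_train,
    product_target,
    ramp_feedback,
    sine_drive,
    targets_experiment1,
    targets_experiment2,
    targets_experiment3,
    two_level_feedback,
)


class TestCueTrain:
    def test_pulses_span_exactly_the_cue_duration(self):
        cues = generate_cue_train(2, (50, 400), 5, 5000, seed=0)
        ind = cues.indicators()
        for onset in cues.onsets[:-1]:
            assert ind[onset : onset + 5].sum() == 5.0
            assert ind[onset - 1].sum() == 0.0

    def test_identities_alternate_strictly(self):
        cues = generate_cue_train(2, (50, 400), 5, 20000, seed=1)
        assert np.all(np.abs(np.diff(cues.channels)) == 1)

    def test_gap_distribution_mean(self):
        # pooled over seeds: uniform [100, 800] has mean 450
        gaps = []
        for seed in range(20):
            cues = generate_cue_train(2, (100, 800), 5, 100_000, seed=seed)
            gaps.extend(np.diff(cues.onsets))
        assert abs(np.mean(gaps) - 450) < 15  # ~5 sigma for this pool

    def test_overlapping_gap_range_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cue_train(2, (5, 400), 5, 1000, seed=0)

    def test_gap_range_switches_between_regions(self):
        regions = [(0, 50_000, (50, 400)), (50_000, 100_000, (100, 800))]
        cues = phased_cue_train(2, regions, 5, 100_000, seed=2)
        early = np.diff(cues.onsets[cues.onsets < 49_000])
        late_idx = cues.onsets > 51_000
        late = np.diff(cues.onsets[late_idx])
        assert early.max() <= 400 and late.min() >= 100

    def test_last_cue_and_time_since_are_consistent(self):
        cues = generate_cue_train(2, (50, 400), 5, 10_000, seed=3)
        last, tsc = cues.last_cue(), cues.time_since_cue()
        assert np.all(tsc[cues.onsets] == 0)
        for onset, ch in zip(cues.onsets, cues.channels):
            assert last[onset] == ch
        assert np.all(last[: cues.onsets[0]] == -1)


class TestFiltering:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(gaussian_filter_steps(x, 5.0), x)

    def test_zero_std_is_identity(self):
        x = np.random.default_rng(0).normal(size=100)
        np.testing.assert_array_equal(gaussian_filter_steps(x, 0.0), x)

    def test_unit_impulse_keeps_mass_and_peak(self):
        x = np.zeros(201)
        x[100] = 1.0
        y = gaussian_filter_steps(x, 5.0)
        assert y.sum() == pytest.approx(1.0, rel=1e-6)
        assert np.argmax(y) == 100

    def test_noise_prefilter_mean_and_variance_reduction(self):
        raw = generate_filtered_noise(-5, 15, 0.0, 10_000, seed=4)
        smooth = generate_filtered_noise(-5, 15, 5.0, 10_000, seed=4)
        assert abs(raw.mean() - 5.0) < 0.3
        assert smooth.var() < raw.var()

    def test_noise_is_reproducible(self):
        a = generate_filtered_noise(-5, 15, 5.0, 1000, seed=9)
        b = generate_filtered_noise(-5, 15, 5.0, 1000, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_bad_range_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_filtered_noise(5, 5, 1.0, 100)


class TestSwitchingTargets:
    def _signals(self, seed=0, length=20_000):
        cues = generate_cue_train(2, (100, 800), 5, length, seed=seed)
        sine = sine_drive(length)
        return cues, targets_experiment1(cues, sine)

    def test_minus_branch_outputs_the_constant(self):
        cues, sig = self._signals()
        d = sig.output_targets["d"]
        minus = sig.last_cue == CUE_MINUS
        assert np.all(d[minus] == 5.0)

    def test_plus_branch_outputs_the_sine(self):
        cues, sig = self._signals()
        d = sig.output_targets["d"]
        plus = sig.last_cue == CUE_PLUS
        np.testing.assert_array_equal(d[plus], sig.inputs["u_sin"][plus])

    def test_branch_switches_exactly_at_onsets(self):
        cues, sig = self._signals()
        last = sig.last_cue
        for onset, ch in zip(cues.onsets, cues.channels):
            assert last[onset] == ch
            if onset > 0:
                assert last[onset - 1] != ch or onset == cues.onsets[0]

    def test_two_level_feedback_levels(self):
        cues, _ = self._signals()
        z = two_level_feedback(cues, 18.0, 10.0)
        assert set(np.unique(z)) <= {10.0, 18.0}
        assert np.all(z[: cues.onsets[0]] == 10.0)  # u- branch before first cue


class TestConcurrentTargets:
    def test_printed_substitution_examples(self):
        # one u+ cue at step 10; constant streams chosen per the worked examples
        cues = phased_cue_train(2, [(0, 100, (10, 10))], 5, 100, seed=0)
        assert cues.onsets[0] == 10 and cues.channels[0] == CUE_PLUS
        u1 = np.full(100, 3.0)
        u2 = np.full(100, 5.0)
        sig = targets_experiment2(cues, u1, u2)
        # before the first cue: u- branch
        assert sig.output_targets["d1"][5] == pytest.approx(10.0)  # 2*u2
        assert sig.output_targets["d2"][5] == pytest.approx(2.0)   # |3-5|
        # after the u+ cue
        assert sig.output_targets["d1"][15] == pytest.approx(3.0)  # u1
        assert sig.output_targets["d2"][15] == pytest.approx(8.0)  # u1+u2
        # cue-independent cubic: 0.1*27 + 0.2*15
        assert sig.output_targets["d3"][50] == pytest.approx(5.7)

    def test_cubic_example(self):
        cues = phased_cue_train(2, [(0, 50, (10, 10))], 5, 50, seed=0)
        sig = targets_experiment2(cues, np.full(50, 2.0), np.full(50, 1.0))
        assert sig.output_targets["d3"][0] == pytest.approx(1.2)

    def test_brute_force_scan_oracle(self):
        """Eq targets match an independent per-step scan on a random instance."""
        length = 10_000
        rng = np.random.default_rng(5)
        cues = generate_cue_train(2, (50, 400), 5, length, seed=11)
        u1 = generate_filtered_noise(-5, 15, 5.0, length, seed=12)
        u2 = generate_filtered_noise(-5, 15, 5.0, length, seed=13)
        sig = targets_experiment2(cues, u1, u2)
        onsets = dict(zip(cues.onsets.tolist(), cues.channels.tolist()))
        last = CUE_MINUS  # convention: u- branch before the first cue
        for t in range(length):
            last = onsets.get(t, last)
            if last == CUE_PLUS:
                d1, d2 = u1[t], u1[t] + u2[t]
            else:
                d1, d2 = 2.0 * u2[t], abs(u1[t] - u2[t])
            d3 = 0.1 * u1[t] ** 3 + 0.2 * u1[t] * u2[t]
            assert sig.output_targets["d1"][t] == d1
            assert sig.output_targets["d2"][t] == d2
            assert sig.output_targets["d3"][t] == pytest.approx(d3, rel=1e-12)


class TestRampTargets:
    def _cues(self, length=3000):
        return phased_cue_train(1, [(0, length, (400, 400))], 5, length, seed=0)

    def test_drop_ramp_and_hold(self):
        cues = self._cues()
        z = ramp_feedback(cues, 300, low=5.0, high=9.0)
        onset = cues.onsets[0]
        assert z[onset] == 5.0
        assert z[onset + 150] == pytest.approx(7.0)  # linear midpoint
        assert z[onset + 300] == 9.0
        assert np.all(z[:onset] == 9.0)  # as if a cue completed long ago

    def test_new_cue_resets_mid_ramp(self):
        length = 2000
        cues = phased_cue_train(1, [(0, length, (200, 200))], 5, length, seed=0)
        z = ramp_feedback(cues, 600, low=5.0, high=9.0)
        for onset in cues.onsets:
            assert z[onset] == 5.0

    def test_elapsed_time_output_examples(self):
        cues = self._cues(100)
        uarb = np.full(100, 4.0)
        fast = np.full(100, 2.0)
        sig = targets_experiment3(cues, uarb, ramps=(300, 600))
        d3 = np.abs(uarb) - 2.5 * fast
        assert d3[0] == pytest.approx(-1.0)
        # symmetry in the noise stream
        sig_neg = targets_experiment3(cues, -uarb, ramps=(300, 600))
        np.testing.assert_array_equal(
            sig.output_targets["d3"], sig_neg.output_targets["d3"]
        )

    def test_elapsed_time_oracle_scan(self):
        length = 10_000
        cues = phased_cue_train(1, [(0, length, (100, 800))], 5, length, seed=21)
        uarb = generate_filtered_noise(-5, 15, 5.0, length, seed=22)
        sig = targets_experiment3(cues, uarb, ramps=(300, 600))
        onset_set = set(cues.onsets.tolist())
        since = 300  # ramp completed before the first cue
        for t in range(length):
            since = 0 if t in onset_set else since + 1
            fast = 5.0 + 4.0 * min(since / 300.0, 1.0)
            assert sig.feedback_targets["fast"][t] == pytest.approx(fast)
            assert sig.output_targets["d3"][t] == pytest.approx(
                abs(uarb[t]) - 2.5 * fast
            )

    def test_product_task(self):
        assert product_target(np.array([3.0]), np.array([2.0]))[0] == 6.0
        assert product_target(np.array([-3.0]), np.array([2.0]))[0] == 6.0
        assert product_target(np.array([9.0]), np.array([0.0]))[0] == 0.0

    def test_bad_ramp_rejected(self):
        with pytest.raises(ConfigurationError):
            ramp_feedback(self._cues(100), 0)


class TestExperimentFactory:
    @pytest.mark.parametrize("name,n_in,n_fb,n_out", [
        ("exp1", 3, 1, 1),
        ("exp2", 4, 1, 3),
        ("exp3", 2, 2, 1),
        ("exp4", 3, 1, 0),
    ])
    def test_channel_counts(self, name, n_in, n_fb, n_out):
        sig = make_experiment(name, 2000, 1000, seed=0)
        assert sig.n_inputs == n_in
        assert sig.n_feedback == n_fb
        assert len(sig.output_targets) == n_out

    def test_generation_is_bit_deterministic(self):
        a = make_experiment("exp2", 3000, 1500, seed=7)
        b = make_experiment("exp2", 3000, 1500, seed=7)
        for k in a.inputs:
            np.testing.assert_array_equal(a.inputs[k], b.inputs[k])
        for k in a.output_targets:
            np.testing.assert_array_equal(a.output_targets[k], b.output_targets[k])

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ConfigurationError):
            make_experiment("exp9", 100, 50)

    def test_frame_export_is_aligned(self):
        sig = make_experiment("exp1", 500, 250, seed=0)
        frame = sig.to_frame()
        assert len(frame) == 500
        assert "u_sin" in frame.columns and "d_d" in frame.columns
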