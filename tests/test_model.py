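"""Phase orchestration, the model/results objects and the stability test."""

import numpy as np
import pandas as pd
import pytest

from delayrc.exceptions import (
    ConfigurationError,
    UndefinedCorrelationError,
)
from delayrc.model import (
    FeedbackReservoir,
    PhaseSchedule,
    ReservoirConfig,
    pearson,
    run_dcr_baseline,
    run_phases,
    run_stability_test,
)
from delayrc.tasks import TaskSignals, generate_filtered_noise, make_experiment


class TestPearson:
    def test_perfect_and_anti_correlation(self, rng):
        y = rng.normal(size=100)
        assert pearson(y, y) == pytest.approx(1.0)
        assert pearson(y, -y) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(pearson(a, b)) < 0.05

    def test_zero_variance_is_an_error(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(np.ones(10), np.arange(10.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            pearson(np.ones(3), np.ones(4))


class TestSchedule:
    def test_published_phase_totals(self):
        sch = PhaseSchedule.full("exp1")
        # offset + TF + offset + training + offset + validation
        assert sch.total == 50 + 50000 + 50 + 10000 + 50 + 10000
        sch3 = PhaseSchedule.full("exp3")
        assert (sch3.teacher_forcing, sch3.training, sch3.validation) == (
            50000, 20000, 20000,
        )

    def test_window_bookkeeping(self, tiny_schedule):
        sch = tiny_schedule
        assert sch.tf_rows == slice(10, 310)
        assert sch.train_rows == slice(320, 520)
        assert sch.val_rows == slice(530, 730)
        labels = sch.phase_labels()
        assert labels.size == sch.total
        assert set(labels) == {"offset", "teacher_forcing", "training", "validation"}
        assert (labels == "offset").sum() == 3 * sch.offset

    def test_negative_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            PhaseSchedule(offset=-1)


class TestReservoirConfig:
    def test_defaults_are_the_published_values(self):
        res = ReservoirConfig()
        assert (res.n, res.tau, res.grid, res.mu) == (300, 600.0, 600, 0.1)
        assert (res.mg.gamma, res.mg.eta, res.mg.rho) == (0.01, 0.5, 1.0)
        assert res.h == 1.0

    def test_more_nodes_than_grid_points_rejected(self):
        with pytest.raises(ConfigurationError):
            ReservoirConfig(n=601)


def _linear_task(length, seed=0):
    """No cues, no feedback: target is a pure linear mix of two streams."""
    u1 = generate_filtered_noise(-5, 15, 5.0, length, seed=seed)
    u2 = generate_filtered_noise(-5, 15, 5.0, length, seed=seed + 1)
    return TaskSignals(
        inputs={"u1": u1, "u2": u2},
        feedback_targets={},
        output_targets={"lin": 2.0 * u1 + 0.5 * u2},
        last_cue=np.full(length, -1, dtype=np.intp),
        time_since_cue=np.arange(length, dtype=np.intp),
    )


class TestFit:
    def test_linear_target_recovery_without_feedback(self):
        sch = PhaseSchedule(offset=50, teacher_forcing=0, training=2000,
                            validation=500)
        task = _linear_task(sch.total)
        result = FeedbackReservoir(task, sch, seed=0).fit()
        assert result.correlations.loc["lin", "validation"] > 0.99

    def test_baseline_equals_model_when_no_feedback_channels(self):
        sch = PhaseSchedule(offset=50, teacher_forcing=0, training=1000,
                            validation=400)
        task = _linear_task(sch.total, seed=3)
        a = run_phases(task, sch, seed=5)
        b = run_dcr_baseline(task, sch, seed=5)
        pd.testing.assert_frame_equal(a.correlations, b.correlations)

    def test_refit_is_bit_identical(self, small_reservoir, tiny_schedule):
        r1 = FeedbackReservoir.from_experiment(
            "exp1", tiny_schedule, seed=2, reservoir=small_reservoir
        ).fit()
        r2 = FeedbackReservoir.from_experiment(
            "exp1", tiny_schedule, seed=2, reservoir=small_reservoir
        ).fit()
        pd.testing.assert_frame_equal(r1.traces, r2.traces)
        pd.testing.assert_frame_equal(r1.correlations, r2.correlations)

    def test_task_shorter_than_schedule_rejected(self, small_reservoir):
        sch = PhaseSchedule(offset=10, teacher_forcing=100, training=100,
                            validation=100)
        task = make_experiment("exp1", 100, 50, seed=0)
        with pytest.raises(ConfigurationError):
            FeedbackReservoir(task, sch, reservoir=small_reservoir)

    def test_offset_steps_never_enter_fits_or_metrics(self, small_reservoir,
                                                      tiny_schedule):
        """Poisoning every offset-row target changes nothing downstream."""
        sch = tiny_schedule
        task = make_experiment("exp1", sch.total, sch.t1, seed=4)
        poisoned = make_experiment("exp1", sch.total, sch.t1, seed=4)
        labels = sch.phase_labels()
        off = labels == "offset"
        for d in poisoned.output_targets.values():
            d[off] = 1e6
        r_clean = FeedbackReservoir(task, sch, reservoir=small_reservoir,
                                    seed=1).fit()
        r_poison = FeedbackReservoir(poisoned, sch, reservoir=small_reservoir,
                                     seed=1).fit()
        pd.testing.assert_frame_equal(r_clean.correlations, r_poison.correlations)
        for k in r_clean.alpha:
            np.testing.assert_array_equal(
                r_clean.alpha[k].coeffs, r_poison.alpha[k].coeffs
            )

    def test_concurrent_readouts_are_independent(self, small_reservoir,
                                                 tiny_schedule):
        """Dropping sibling targets does not change a readout's fit."""
        sch = tiny_schedule
        task = make_experiment("exp2", sch.total, sch.t1, seed=6)
        solo = make_experiment("exp2", sch.total, sch.t1, seed=6)
        solo.output_targets = {"d3": solo.output_targets["d3"]}
        r_all = FeedbackReservoir(task, sch, reservoir=small_reservoir,
                                  seed=2).fit()
        r_solo = FeedbackReservoir(solo, sch, reservoir=small_reservoir,
                                   seed=2).fit()
        np.testing.assert_array_equal(
            r_all.alpha["d3"].coeffs, r_solo.alpha["d3"].coeffs
        )

    def test_results_surface(self, small_reservoir, tiny_schedule):
        result = FeedbackReservoir.from_experiment(
            "exp1", tiny_schedule, seed=3, reservoir=small_reservoir
        ).fit()
        assert set(result.correlations.columns) == {"training", "validation"}
        assert result.correlations.values.min() >= -1.0
        assert result.correlations.values.max() <= 1.0
        assert len(result.traces) == tiny_schedule.total
        text = result.summary()
        assert "Pearson r" in text and "teacher_forcing=300" in text
        # feedback weights carry their role
        assert all(w.role == "feedback" for w in result.beta.values())


class TestStability:
    def test_infinite_margin_runs_to_budget(self, small_reservoir):
        sch = PhaseSchedule(offset=10, teacher_forcing=200, training=0,
                            validation=0)
        report = run_stability_test(
            seed=0, schedule=sch, reservoir=small_reservoir,
            margin=np.inf, max_steps=50, cue_test=30,
        )
        assert report.terminated_by == "step-budget"
        assert report.survived_steps == 50

    def test_untrained_feedback_breaches_immediately(self, small_reservoir):
        sch = PhaseSchedule(offset=10, teacher_forcing=200, training=0,
                            validation=0)
        report = run_stability_test(
            seed=0, schedule=sch, reservoir=small_reservoir,
            max_steps=100, cue_test=30,
            beta_override=np.zeros(small_reservoir.n + 1),
        )
        assert report.terminated_by == "margin-breach"
        assert report.survived_steps < 5

    def test_default_margin_is_half_the_level_gap(self, small_reservoir):
        sch = PhaseSchedule(offset=10, teacher_forcing=200, training=0,
                            validation=0)
        report = run_stability_test(
            seed=0, schedule=sch, reservoir=small_reservoir,
            max_steps=10, cue_test=20, levels=(18.0, 10.0),
        )
        assert report.margin == 4.0
        assert report.desired_level in (10.0, 18.0)
        assert {"step", "feedback"} <= set(report.trace.columns)
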