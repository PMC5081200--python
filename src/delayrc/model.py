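"""Experiment orchestration: the fitted-feedback reservoir model.

:class:`FeedbackReservoir` is the model object: it couples a
:class:`~delayrc.tasks.TaskSignals` data set to a delay-coupled reservoir
configuration and a phase schedule.  ``fit()`` runs the three consecutive
phases -- teacher forcing (feedback readouts beta), training (feedforward
readouts alpha) and validation (frozen weights) -- each preceded by a
brief offset whose steps are excluded from every regression and metric,
and returns a :class:`FeedbackReservoirResults` carrying weights,
per-phase correlations, the full step-resolved traces and a ``summary()``.

``feedback=False`` gives the standard open-loop reservoir baseline (no
feedback channels, teacher forcing skipped); it runs the identical task
and seeds so the two are directly comparable.

:func:`run_stability_test` implements the longitudinal experiment: after
teacher forcing, the free-running feedback loop must hold the level of the
last cue with no further cue input until it breaches an error margin or
exhausts the step budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import tasks as tasks_mod
from .dde import MGParams
from .exceptions import ConfigurationError, UndefinedCorrelationError
from .multiplexing import (
    Mask,
    NodeLayout,
    generate_layout,
    generate_mask,
    node_forcing_values,
)
from ._kernel import run_cycle
from .readout import (
    NoiseSpec,
    ReadoutWeights,
    RegressionData,
    add_bias,
    fit_least_squares,
    predict,
    predict_many,
    teacher_force_collect,
)

__all__ = [
    "PhaseSchedule",
    "ReservoirConfig",
    "FeedbackReservoir",
    "FeedbackReservoirResults",
    "StabilityReport",
    "pearson",
    "fading_memory_convergence",
    "branch_memory_span",
    "run_phases",
    "run_dcr_baseline",
    "run_stability_test",
]


@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (reservoir steps) of the simulation phases.

    Every phase is preceded by ``offset`` wash-out steps that never enter
    a regression or a metric.  The published schedule is 50000 /
    10000 / 10000 (20000 / 20000 for the elapsed-time experiment) with
    offset 50; :meth:`reduced` gives the desk-scale 5000 / 2000 / 2000
    variant used for fast runs and acceptance checks.
    """

    offset: int = 50
    teacher_forcing: int = 50000
    training: int = 10000
    validation: int = 10000

    def __post_init__(self):
        for name in ("offset", "teacher_forcing", "training", "validation"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"schedule {name} must be >= 0")

    @classmethod
    def full(cls, experiment: str = "exp1") -> "PhaseSchedule":
        if experiment == "exp3":
            return cls(50, 50000, 20000, 20000)
        return cls(50, 50000, 10000, 10000)

    @classmethod
    def reduced(cls) -> "PhaseSchedule":
        return cls(50, 5000, 2000, 2000)

    # -- window bookkeeping -------------------------------------------------
    @property
    def t1(self) -> int:
        """First step of the training block (its offset)."""
        return self.offset + self.teacher_forcing

    @property
    def t2(self) -> int:
        """First step of the validation block (its offset)."""
        return self.t1 + self.offset + self.training

    @property
    def total(self) -> int:
        return self.t2 + self.offset + self.validation

    @property
    def tf_rows(self) -> slice:
        return slice(self.offset, self.t1)

    @property
    def train_rows(self) -> slice:
        return slice(self.t1 + self.offset, self.t2)

    @property
    def val_rows(self) -> slice:
        return slice(self.t2 + self.offset, self.total)

    def phase_labels(self) -> np.ndarray:
        lab = np.empty(self.total, dtype=object)
        lab[:] = "offset"
        lab[self.tf_rows] = "teacher_forcing"
        lab[self.train_rows] = "training"
        lab[self.val_rows] = "validation"
        return lab


@dataclass(frozen=True)
class ReservoirConfig:
    """Physical configuration of the delay-coupled reservoir.

    Defaults follow the published values: n=300 virtual nodes on a delay
    of tau=600 time units evaluated at 600 simulation points (h=1), mask
    amplitude mu=0.1, Mackey-Glass parameters gamma=0.01, eta=0.5, rho=1.
    """

    mg: MGParams = field(default_factory=MGParams)
    n: int = 300
    tau: float = 600.0
    grid: int = 600
    mu: float = 0.1

    def __post_init__(self):
        if self.n < 1 or self.grid < 1:
            raise ConfigurationError("n and grid must be positive")
        if self.n > self.grid:
            raise ConfigurationError(
                f"cannot place {self.n} virtual nodes on {self.grid} grid points"
            )
        if not self.tau > 0:
            raise ConfigurationError(f"tau must be > 0, got {self.tau}")
        if not self.mu > 0:
            raise ConfigurationError(f"mu must be > 0, got {self.mu}")

    @property
    def h(self) -> float:
        return self.tau / self.grid


def pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation; zero-variance input is an error, not silently 0."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ConfigurationError("pearson needs two equal-length series (>= 2)")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a zero-variance series"
        )
    return float(scipy.stats.pearsonr(y, yhat).statistic)


def _safe_r(y, yhat) -> float:
    """Pearson r for result tables; NaN where the metric is undefined
    (e.g. no cue fell inside a short phase window, leaving a constant
    target) instead of aborting the whole fit."""
    try:
        return pearson(y, yhat)
    except UndefinedCorrelationError:
        return float("nan")


class _Engine:
    """Steps the reservoir one delay cycle at a time."""

    def __init__(self, config: ReservoirConfig, mask: Mask, layout: NodeLayout,
                 use_numba: bool = True):
        self.config = config
        self.mask = mask
        self.layout = layout
        self.seg = layout.segment_of_grid
        self.sample_idx = layout.offsets + 1  # samples sit at segment ends
        self.state = np.zeros(config.grid + 1)  # constant-zero initial history
        self.t = 0
        self.use_numba = use_numba

    def step(self, channels: np.ndarray) -> np.ndarray:
        """Drive one reservoir step; returns the n virtual-node activities."""
        vals = node_forcing_values(channels, self.mask, self.config.mg.gamma)
        forcing = vals[self.seg]
        p = self.config.mg
        self.state = run_cycle(
            self.state, forcing, self.config.h, p.eta, p.rho, p.denom_guard,
            t0=self.t * self.config.tau, use_numba=self.use_numba,
        )
        self.t += 1
        return self.state[self.sample_idx]


@dataclass
class FeedbackReservoirResults:
    """Fit results: weights, per-phase correlations, traces, metadata."""

    correlations: pd.DataFrame
    feedback_correlations: pd.DataFrame | None
    alpha: dict[str, ReadoutWeights]
    beta: dict[str, ReadoutWeights]
    traces: pd.DataFrame
    schedule: PhaseSchedule
    reservoir: ReservoirConfig
    metadata: dict

    def summary(self) -> str:
        sch = self.schedule
        res = self.reservoir
        lines = [
            "Delay-coupled reservoir" + (
                " with trained feedback" if self.beta else " (open-loop baseline)"
            ),
            "=" * 60,
            f"virtual nodes n={res.n}  tau={res.tau:g}  grid={res.grid}  "
            f"mu={res.mu:g}",
            f"Mackey-Glass gamma={res.mg.gamma:g}  eta={res.mg.eta:g}  "
            f"rho={res.mg.rho:g}",
            f"schedule offset={sch.offset}  teacher_forcing={sch.teacher_forcing}  "
            f"training={sch.training}  validation={sch.validation}",
            "",
            "Pearson r (desired vs observed output)",
            self.correlations.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.feedback_correlations is not None:
            lines += [
                "",
                "Pearson r (feedback target vs free-running feedback)",
                self.feedback_correlations.to_string(
                    float_format=lambda v: f"{v:.4f}"
                ),
            ]
        return "\n".join(lines)

    def plot_traces(self, targets=None, window: str = "validation", ax=None):
        """Desired vs observed outputs over one phase window."""
        import matplotlib.pyplot as plt

        sub = self.traces[self.traces["phase"] == window]
        names = targets or list(self.alpha)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 2 + 1.5 * len(names)))
        for name in names:
            ax.plot(sub["step"], sub[f"d_{name}"], lw=1.0, label=f"{name} desired")
            ax.plot(
                sub["step"], sub[f"dhat_{name}"], lw=0.8, ls="--",
                label=f"{name} observed",
            )
        ax.set_xlabel("reservoir step")
        ax.set_ylabel("output")
        ax.legend(loc="best", fontsize="small")
        ax.set_title(f"{window} phase")
        return ax


class FeedbackReservoir:
    """Delay-coupled reservoir with trained linear feedback.

    Parameters
    ----------
    task
        The per-step signal set (inputs, feedback targets, output targets).
    schedule
        Phase durations; the task must cover ``schedule.total`` steps.
    reservoir
        Physical configuration; defaults to the published values.
    feedback
        If False, run the open-loop baseline: no feedback channels, no
        teacher forcing, same task, mask seed and layout.
    ridge
        L2 regularisation for all readout fits (0 = plain least squares).
    fb_noise_scale
        Standard deviation of the teacher-forcing noise, in target units.
        None selects 1% of each feedback target's peak-to-peak range.
    seed
        Single seed from which mask, layout and noise seeds are derived.
    """

    def __init__(
        self,
        task: tasks_mod.TaskSignals,
        schedule: PhaseSchedule | None = None,
        reservoir: ReservoirConfig | None = None,
        feedback: bool = True,
        ridge: float = 0.0,
        fb_noise_scale: float | None = None,
        seed=0,
        use_numba: bool = True,
    ):
        self.task = task
        self.schedule = schedule or PhaseSchedule.full()
        self.reservoir = reservoir or ReservoirConfig()
        self.feedback = feedback and task.n_feedback > 0
        self.ridge = ridge
        self.fb_noise_scale = fb_noise_scale
        self.seed = seed
        self.use_numba = use_numba
        if task.length < self.schedule.total:
            raise ConfigurationError(
                f"task provides {task.length} steps but the schedule "
                f"needs {self.schedule.total}"
            )

    @classmethod
    def from_experiment(
        cls,
        name: str,
        schedule: PhaseSchedule | None = None,
        seed=0,
        reservoir: ReservoirConfig | None = None,
        feedback: bool = True,
        ridge: float = 0.0,
        fb_noise_scale: float | None = None,
        use_numba: bool = True,
        **task_params,
    ) -> "FeedbackReservoir":
        """Build task and model for one of the named experiments."""
        if schedule is None:
            schedule = PhaseSchedule.full(name)
        ss = np.random.SeedSequence(seed) if not isinstance(
            seed, np.random.SeedSequence
        ) else seed
        task_ss, model_ss = ss.spawn(2)
        task = tasks_mod.make_experiment(
            name, schedule.total, schedule.t1, seed=task_ss, **task_params
        )
        return cls(
            task,
            schedule,
            reservoir=reservoir,
            feedback=feedback,
            ridge=ridge,
            fb_noise_scale=fb_noise_scale,
            seed=model_ss,
            use_numba=use_numba,
        )

    # ------------------------------------------------------------------
    def fit(self) -> FeedbackReservoirResults:
        """Run all phases, fit beta then alpha, return the results object."""
        sch = self.schedule
        task = self.task
        res = self.reservoir
        T = sch.total
        m = task.n_inputs
        q_task = task.n_feedback
        q = q_task if self.feedback else 0

        ss = np.random.SeedSequence(self.seed) if not isinstance(
            self.seed, np.random.SeedSequence
        ) else self.seed
        mask_ss, layout_ss, eps_ss = ss.spawn(3)
        # The mask always spans m + q_task columns so that baseline and
        # feedback runs share identical input mask bits.
        full_mask = generate_mask(res.n, m, q_task, res.mu, mask_ss)
        if q == 0:
            mask = Mask(
                bits=full_mask.bits[:, :m], mu=res.mu,
                n_inputs=m, n_feedback=0, seed=mask_ss,
            )
        else:
            mask = full_mask
        layout = generate_layout(res.n, res.grid, layout_ss)
        engine = _Engine(res, mask, layout, use_numba=self.use_numba)

        U = task.input_matrix[:, :T]
        Z = task.feedback_matrix[:, :T]
        fb_names = list(task.feedback_targets)

        # teacher-forcing noise: one stream per feedback channel over the
        # teacher-forcing block (offset included)
        noise_scales = np.zeros(q)
        ztilde = np.zeros((q, sch.t1))
        if q:
            eps_children = eps_ss.spawn(q)
            for c in range(q):
                ptp = np.ptp(Z[c, : sch.t1])
                scale = (
                    self.fb_noise_scale
                    if self.fb_noise_scale is not None
                    else 0.01 * ptp
                )
                noise_scales[c] = scale
                spec = NoiseSpec(scale=scale, seed=eps_children[c])
                ztilde[c] = Z[c, : sch.t1] + spec.sample(sch.t1)

        X = np.empty((T, res.n))
        PHI = np.zeros((q, T))
        beta: list[ReadoutWeights] = []
        phi = np.zeros(q)
        for t in range(T):
            if q:
                if t == sch.t1:
                    beta = [
                        fit_least_squares(
                            teacher_force_collect(
                                X[: sch.t1], ztilde[c], sch.offset
                            ),
                            ridge=self.ridge,
                            role="feedback",
                        )
                        for c in range(q)
                    ]
                if t < sch.t1:
                    phi = ztilde[:, t - 1] if t > 0 else Z[:, 0]
                elif t == sch.t1 or t == sch.t2:
                    phi = Z[:, t]  # phase anchor: first feedback target value
                else:
                    phi = np.array([predict(b, X[t - 1]) for b in beta])
                PHI[:, t] = phi
                ch = np.concatenate([U[:, t], phi])
            else:
                ch = U[:, t]
            X[t] = engine.step(ch)

        # feedforward readouts on the training phase
        Xa = add_bias(X)
        tr, va = sch.train_rows, sch.val_rows
        alpha: dict[str, ReadoutWeights] = {}
        preds: dict[str, np.ndarray] = {}
        corr_rows = []
        for name, d in task.output_targets.items():
            d = np.asarray(d[:T], dtype=np.float64)
            w = fit_least_squares(
                RegressionData(X=Xa[tr], y=d[tr]), ridge=self.ridge
            )
            alpha[name] = w
            yhat = predict_many(w, X)
            preds[name] = yhat
            corr_rows.append(
                {
                    "target": name,
                    "training": _safe_r(d[tr], yhat[tr]),
                    "validation": _safe_r(d[va], yhat[va]),
                }
            )
        correlations = pd.DataFrame(
            corr_rows, columns=["target", "training", "validation"]
        ).set_index("target")

        fb_corr = None
        if q:
            fb_rows = [
                {
                    "channel": fb_names[c],
                    "training": _safe_r(Z[c, tr], PHI[c, tr]),
                    "validation": _safe_r(Z[c, va], PHI[c, va]),
                }
                for c in range(q)
            ]
            fb_corr = pd.DataFrame(
                fb_rows, columns=["channel", "training", "validation"]
            ).set_index("channel")

        trace_data: dict[str, np.ndarray] = {
            "step": np.arange(T),
            "phase": sch.phase_labels(),
        }
        for i, name in enumerate(task.inputs):
            trace_data[name] = U[i]
        for c in range(q):
            trace_data[f"z_{fb_names[c]}"] = Z[c]
            trace_data[f"phi_{fb_names[c]}"] = PHI[c]
        for name, d in task.output_targets.items():
            trace_data[f"d_{name}"] = np.asarray(d[:T], dtype=np.float64)
            trace_data[f"dhat_{name}"] = preds[name]
        traces = pd.DataFrame(trace_data)

        metadata = {
            "seed": repr(self.seed),
            "mask_seed": repr(mask_ss),
            "layout_seed": repr(layout_ss),
            "noise_seed": repr(eps_ss),
            "task_meta": dict(task.meta),
            "feedback": bool(q),
            "ridge": self.ridge,
            "noise_scales": noise_scales.tolist(),
        }
        return FeedbackReservoirResults(
            correlations=correlations,
            feedback_correlations=fb_corr,
            alpha=alpha,
            beta=dict(zip(fb_names, beta)) if q else {},
            traces=traces,
            schedule=sch,
            reservoir=res,
            metadata=metadata,
        )


def run_phases(task, schedule, **kwargs) -> FeedbackReservoirResults:
    """Teacher forcing, training and validation for a prepared task."""
    return FeedbackReservoir(task, schedule, **kwargs).fit()


def run_dcr_baseline(task, schedule, **kwargs) -> FeedbackReservoirResults:
    """The no-feedback comparison baseline on the identical task."""
    kwargs.pop("feedback", None)
    return FeedbackReservoir(task, schedule, feedback=False, **kwargs).fit()


def fading_memory_convergence(
    seed=0,
    n_cycles: int = 30,
    reservoir: ReservoirConfig | None = None,
    history_range: tuple[float, float] = (-0.5, 0.5),
) -> np.ndarray:
    """Echo-state check: per-cycle max difference between paired runs.

    Two reservoirs start from independent i.i.d. uniform initial
    histories over ``history_range`` and receive identical forcing drawn
    from the concurrent-task input distribution (two cue channels, two
    bounded filtered noise streams, the two-level feedback target as the
    clamped feedback channel).  Returns the max-norm state difference
    after each cycle; with the default parameters it contracts
    geometrically at rate ~eta = 0.5 per cycle.

    Note the contraction basin: the unforced system's unstable
    equilibrium sits at eta - 1 = -0.5, exactly the lower edge of the
    default range, so histories concentrated there converge arbitrarily
    slowly; random histories shed that edge within a cycle.
    """
    res = reservoir or ReservoirConfig()
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence
    ) else seed
    task_ss, mask_ss, layout_ss, hist_ss = ss.spawn(4)
    task = tasks_mod.make_experiment(
        "exp2", n_cycles + 10, n_cycles + 10, seed=task_ss
    )
    mask = generate_mask(res.n, task.n_inputs, 1, res.mu, mask_ss)
    layout = generate_layout(res.n, res.grid, layout_ss)
    U = task.input_matrix
    z = task.feedback_matrix[0]
    rng = np.random.default_rng(hist_ss)
    lo, hi = history_range
    e1 = _Engine(res, mask, layout)
    e2 = _Engine(res, mask, layout)
    e1.state = rng.uniform(lo, hi, res.grid + 1)
    e2.state = rng.uniform(lo, hi, res.grid + 1)
    diffs = np.empty(n_cycles)
    for t in range(n_cycles):
        ch = np.concatenate([U[:, t], [z[t]]])
        e1.step(ch)
        e2.step(ch)
        diffs[t] = np.max(np.abs(e1.state - e2.state))
    return diffs


def branch_memory_span(
    baseline: FeedbackReservoirResults,
    target: str = "d",
    window: int = 40,
    plateau_from: int = 25,
) -> tuple[int, np.ndarray]:
    """Fading-memory bound of the open-loop reservoir, read off its traces.

    Averages the absolute output error over the steps following each
    validation cue onset.  Without trained feedback the output tracks the
    freshly-cued branch only while the cue's trace persists in the delay
    line; the error then grows to its asymptote (branch information
    lost).  Returns the last post-onset step at which the mean error is
    still below half its plateau -- the effective memory of the cue,
    about the pulse duration plus the ~10-step fading-memory span -- and
    the full mean-error curve.
    """
    tr = baseline.traces
    val = tr[tr["phase"] == "validation"]
    err = np.abs(val[f"d_{target}"].to_numpy() - val[f"dhat_{target}"].to_numpy())
    cue_cols = [c for c in ("u_plus", "u_minus", "u_cue") if c in val.columns]
    pulse = (val[cue_cols].to_numpy() > 0).any(axis=1).astype(int)
    onsets = np.flatnonzero(np.diff(pulse) == 1) + 1
    onsets = onsets[onsets + window < err.size]
    if onsets.size == 0:
        raise ConfigurationError("no usable cue onsets in the validation phase")
    curves = np.stack([err[o : o + window] for o in onsets])
    mean_curve = curves.mean(axis=0)
    plateau = mean_curve[plateau_from:].mean()
    below = np.flatnonzero(mean_curve < 0.5 * plateau)
    span = int(below[-1]) if below.size else 0
    return span, mean_curve


@dataclass
class StabilityReport:
    """Outcome of the longitudinal stability test."""

    survived_steps: int
    terminated_by: str  # 'margin-breach' | 'step-budget'
    margin: float
    desired_level: float
    max_steps: int
    trace: pd.DataFrame
    metadata: dict

    def summary(self) -> str:
        return (
            f"stability test: survived {self.survived_steps} steps "
            f"(budget {self.max_steps}), terminated by {self.terminated_by}; "
            f"holding level {self.desired_level:g} within margin "
            f"{self.margin:g}"
        )


def run_stability_test(
    seed=0,
    schedule: PhaseSchedule | None = None,
    reservoir: ReservoirConfig | None = None,
    margin: float | None = None,
    max_steps: int = 50000,
    cue_test: int = 1000,
    levels: tuple[float, float] = (18.0, 10.0),
    noise_range: tuple[float, float] = (-5.0, 15.0),
    filter_std: float = 5.0,
    gap_tf: tuple[int, int] = (50, 400),
    gap: tuple[int, int] = (100, 800),
    cue_duration: int = 5,
    ridge: float = 0.0,
    fb_noise_scale: float | None = None,
    beta_override: np.ndarray | None = None,
    trace_every: int = 25,
    use_numba: bool = True,
) -> StabilityReport:
    """How long does the free-running feedback hold the last cue's level?

    The input mirrors the switching experiment with the sinusoidal drive
    replaced by bounded filtered noise.  One feedback readout is trained
    by teacher forcing; the loop then runs closed over ``cue_test`` cued
    steps, after which no cues are shown and the feedback must hold the
    level of the last cue.  The run stops at the first step where
    ``|feedback - level| > margin`` (survived_steps = completed steps
    before the breach) or when ``max_steps`` is exhausted.  ``margin``
    defaults to half the gap between the two feedback levels: a breach
    means the signal is closer to the wrong attractor than the right one.

    ``beta_override`` substitutes the trained coefficients, e.g. zeros to
    demonstrate immediate failure without training.
    """
    sch = schedule or PhaseSchedule.reduced()
    if margin is None:
        margin = abs(levels[0] - levels[1]) / 2.0
    res = reservoir or ReservoirConfig()
    t1 = sch.offset + sch.teacher_forcing
    ts = t1 + cue_test  # first stability step
    total = ts + max_steps

    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence
    ) else seed
    cue_ss, noise_ss, mask_ss, layout_ss, eps_ss = ss.spawn(5)
    cues = tasks_mod.phased_cue_train(
        2,
        [(0, t1, tuple(gap_tf)), (t1, ts, tuple(gap))],
        cue_duration,
        total,
        cue_ss,
    )
    ind = cues.indicators()
    uarb = tasks_mod.generate_filtered_noise(
        *noise_range, filter_std, total, noise_ss
    )
    z = tasks_mod.two_level_feedback(cues, *levels)
    desired = float(z[-1])

    mask = generate_mask(res.n, 3, 1, res.mu, mask_ss)
    layout = generate_layout(res.n, res.grid, layout_ss)
    engine = _Engine(res, mask, layout, use_numba=use_numba)

    scale = fb_noise_scale if fb_noise_scale is not None else 0.01 * np.ptp(z[:t1])
    spec = NoiseSpec(scale=scale, seed=eps_ss)
    ztilde = z[:t1] + spec.sample(t1)

    X_tf = np.empty((t1, res.n))
    for t in range(t1):
        phi = ztilde[t - 1] if t > 0 else z[0]
        X_tf[t] = engine.step(
            np.array([ind[t, 0], ind[t, 1], uarb[t], phi])
        )
    if beta_override is not None:
        beta = ReadoutWeights(coeffs=np.asarray(beta_override), role="feedback")
    else:
        beta = fit_least_squares(
            teacher_force_collect(X_tf, ztilde, sch.offset),
            ridge=ridge,
            role="feedback",
        )

    # cued closed-loop test phase
    prev = X_tf[-1]
    phi = z[t1]  # phase anchor
    for t in range(t1, ts):
        if t > t1:
            phi = predict(beta, prev)
        prev = engine.step(np.array([ind[t, 0], ind[t, 1], uarb[t], phi]))

    # stability phase: cue channels silent, noise keeps flowing
    rec_steps, rec_phi = [], []
    survived = max_steps
    terminated = "step-budget"
    for s in range(max_steps):
        t = ts + s
        phi = predict(beta, prev)
        if s % trace_every == 0:
            rec_steps.append(s)
            rec_phi.append(phi)
        if abs(phi - desired) > margin:
            survived = s
            terminated = "margin-breach"
            break
        prev = engine.step(np.array([0.0, 0.0, uarb[t], phi]))

    trace = pd.DataFrame({"step": rec_steps, "feedback": rec_phi})
    metadata = {
        "seed": repr(seed),
        "levels": tuple(levels),
        "noise_scale": scale,
        "cue_test": cue_test,
        "schedule": sch,
        "beta_overridden": beta_override is not None,
    }
    return StabilityReport(
        survived_steps=survived,
        terminated_by=terminated,
        margin=margin,
        desired_level=desired,
        max_steps=max_steps,
        trace=trace,
        metadata=metadata,
    )
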