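"""Synthetic task signals: cue trains, filtered noise, targets.

Every experiment runs on fully synthetic inputs built here:

* irregular rectangular cue pulses whose inter-onset gaps are drawn
  uniformly (shorter gaps during teacher forcing so the regression sees
  enough cues),
* bounded uniform noise streams smoothed with a Gaussian kernel,
* a smoothed sinusoidal drive,
* feedback targets (two-level cue codes and post-cue rising ramps) and the
  output target functions of the three computational experiments.

All generators are deterministic pure functions of their seeds and
parameters.  Before the first cue every task behaves as if a "minus" cue
had occurred at step 0 (for ramps: as if the ramp had already completed),
so targets are total functions; phase offsets discard the early steps
anyway.  Cue switches take effect at the cue ONSET step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .exceptions import ConfigurationError

__all__ = [
    "CueTrain",
    "TaskSignals",
    "generate_cue_train",
    "phased_cue_train",
    "gaussian_filter_steps",
    "generate_filtered_noise",
    "sine_drive",
    "two_level_feedback",
    "ramp_feedback",
    "targets_experiment1",
    "targets_experiment2",
    "targets_experiment3",
    "product_target",
    "make_experiment",
]

CUE_PLUS = 0   # channel index of the u+ cue
CUE_MINUS = 1  # channel index of the u- cue


@dataclass
class CueTrain:
    """Irregularly spaced rectangular cue pulses on 1 or 2 channels.

    ``onsets[k]`` is the reservoir step at which the k-th cue starts;
    ``channels[k]`` names its channel.  In two-channel tasks cue
    identities alternate strictly (u+, u-, u+, ...).
    """

    onsets: np.ndarray
    channels: np.ndarray
    n_channels: int
    duration: int
    length: int

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=np.intp)
        self.channels = np.asarray(self.channels, dtype=np.intp)
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ConfigurationError("cue onsets must be strictly increasing")

    def indicators(self) -> np.ndarray:
        """(length, n_channels) array: 1 during a cue pulse, else 0."""
        ind = np.zeros((self.length, self.n_channels))
        for onset, ch in zip(self.onsets, self.channels):
            ind[onset : min(onset + self.duration, self.length), ch] = 1.0
        return ind

    def last_cue(self) -> np.ndarray:
        """Per-step channel of the most recent onset; -1 before the first."""
        out = np.full(self.length, -1, dtype=np.intp)
        for onset, ch in zip(self.onsets, self.channels):
            out[onset:] = ch
        return out

    def time_since_cue(self) -> np.ndarray:
        """Steps since the most recent onset; resets to 0 exactly at onsets.

        Before the first cue the count runs from a virtual onset at step 0.
        """
        out = np.arange(self.length, dtype=np.intp)
        for onset in self.onsets:
            out[onset:] = np.arange(self.length - onset)
        return out


@dataclass
class TaskSignals:
    """All per-step series of one experiment, sharing one length.

    ``inputs`` are the reservoir's input channels in mask-column order;
    ``feedback_targets`` the desired feedback series z per feedback
    channel; ``output_targets`` the desired outputs d per task.
    """

    inputs: dict[str, np.ndarray]
    feedback_targets: dict[str, np.ndarray]
    output_targets: dict[str, np.ndarray]
    last_cue: np.ndarray
    time_since_cue: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {
            len(v)
            for group in (self.inputs, self.feedback_targets, self.output_targets)
            for v in group.values()
        }
        lengths.add(len(self.last_cue))
        if len(lengths) != 1:
            raise ConfigurationError("all task series must share one length")

    @property
    def length(self) -> int:
        return len(self.last_cue)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_feedback(self) -> int:
        return len(self.feedback_targets)

    @property
    def input_matrix(self) -> np.ndarray:
        return np.vstack(list(self.inputs.values())) if self.inputs else np.empty((0, self.length))

    @property
    def feedback_matrix(self) -> np.ndarray:
        if not self.feedback_targets:
            return np.empty((0, self.length))
        return np.vstack(list(self.feedback_targets.values()))

    def to_frame(self) -> pd.DataFrame:
        data = {"step": np.arange(self.length)}
        for name, v in self.inputs.items():
            data[name] = v
        for name, v in self.feedback_targets.items():
            data[f"z_{name}"] = v
        for name, v in self.output_targets.items():
            data[f"d_{name}"] = v
        data["last_cue"] = self.last_cue
        data["time_since_cue"] = self.time_since_cue
        return pd.DataFrame(data)


def phased_cue_train(
    n_channels: int,
    regions: list[tuple[int, int, tuple[int, int]]],
    duration: int,
    length: int,
    seed=None,
    first_channel: int = CUE_PLUS,
) -> CueTrain:
    """Cue train whose gap range depends on the simulation region.

    ``regions`` is a list of (start, stop, (lo, hi)); the gap to the next
    onset is drawn uniformly (integers, inclusive) from the range of the
    region containing the current position.  Steps not covered by any
    region receive no cues.  Onsets start from a virtual cue at step 0.
    """
    if n_channels not in (1, 2):
        raise ConfigurationError("cue trains support 1 or 2 channels")
    for start, stop, (lo, hi) in regions:
        if lo > hi or lo <= duration:
            raise ConfigurationError(
                f"gap range [{lo}, {hi}] must satisfy lo > duration={duration}"
            )
    rng = np.random.default_rng(seed)
    onsets, channels = [], []
    pos = 0
    ch = first_channel
    while True:
        rng_range = None
        for start, stop, gr in regions:
            if start <= pos < stop:
                rng_range = gr
                break
        if rng_range is None:
            break
        gap = int(rng.integers(rng_range[0], rng_range[1] + 1))
        pos = pos + gap
        if pos >= length:
            break
        in_region = any(start <= pos < stop for start, stop, _ in regions)
        if not in_region:
            # advanced past the cue-permitted span (e.g. stability phase)
            break
        onsets.append(pos)
        channels.append(ch)
        if n_channels == 2:
            ch = 1 - ch
    return CueTrain(
        onsets=np.array(onsets, dtype=np.intp),
        channels=np.array(channels, dtype=np.intp),
        n_channels=n_channels,
        duration=duration,
        length=length,
    )


def generate_cue_train(
    channels: int,
    gap_range: tuple[int, int],
    duration: int,
    length: int,
    seed=None,
) -> CueTrain:
    """Cue train with one uniform gap range over the whole run."""
    return phased_cue_train(
        channels, [(0, length, tuple(gap_range))], duration, length, seed
    )


def gaussian_filter_steps(signal: np.ndarray, std: float) -> np.ndarray:
    """Smooth a per-step series with a normalised Gaussian kernel.

    The kernel is truncated at 4 standard deviations with reflected
    boundaries; std=0 returns the series unchanged.
    """
    if std < 0:
        raise ConfigurationError(f"filter std must be >= 0, got {std}")
    signal = np.asarray(signal, dtype=np.float64)
    if std == 0:
        return signal.copy()
    return gaussian_filter1d(signal, sigma=std, mode="reflect", truncate=4.0)


def generate_filtered_noise(
    lo: float, hi: float, std: float, length: int, seed=None
) -> np.ndarray:
    """I.i.d. uniform(lo, hi) per step, then Gaussian smoothing."""
    if not lo < hi:
        raise ConfigurationError(f"need lo < hi, got [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    return gaussian_filter_steps(rng.uniform(lo, hi, size=length), std)


def sine_drive(
    length: int,
    amplitude: float = 1.0,
    period: float = 100.0,
    mean: float = 1.0 / 3.0,
    filter_std: float = 5.0,
) -> np.ndarray:
    """Smoothed sinusoidal input amplitude*sin(2 pi t/period) + mean."""
    t = np.arange(length)
    raw = amplitude * np.sin(2.0 * np.pi * t / period) + mean
    return gaussian_filter_steps(raw, filter_std)


def two_level_feedback(
    cues: CueTrain, level_plus: float = 9.0, level_minus: float = 5.0
) -> np.ndarray:
    """Two-level cue code: level_plus after u+, level_minus after u- onsets.

    Steps before the first cue carry the u- branch.
    """
    last = cues.last_cue()
    return np.where(last == CUE_PLUS, level_plus, level_minus).astype(np.float64)


def ramp_feedback(
    cues: CueTrain,
    ramp_len: int,
    low: float = 5.0,
    high: float = 9.0,
) -> np.ndarray:
    """Elapsed-time code: drop to ``low`` at each onset, ramp back to ``high``.

    The value is ``high`` before any cue (as if a cue occurred ramp_len
    steps ago); at an onset it drops to ``low`` and then increases
    linearly, reaching ``high`` after ``ramp_len`` steps and holding.  A
    new cue mid-ramp resets the ramp.
    """
    if ramp_len <= 0:
        raise ConfigurationError(f"ramp_len must be > 0, got {ramp_len}")
    tsc = cues.time_since_cue().astype(np.float64)
    if cues.onsets.size:
        first = cues.onsets[0]
        tsc[:first] = ramp_len  # ramp already completed before the first cue
    else:
        tsc[:] = ramp_len
    frac = np.minimum(tsc / ramp_len, 1.0)
    return low + (high - low) * frac


def _base_signals(cues: CueTrain, inputs, feedback, outputs, meta) -> TaskSignals:
    return TaskSignals(
        inputs=inputs,
        feedback_targets=feedback,
        output_targets=outputs,
        last_cue=cues.last_cue(),
        time_since_cue=cues.time_since_cue(),
        meta=meta,
    )


def targets_experiment1(
    cues: CueTrain,
    sine: np.ndarray,
    constant: float = 5.0,
    levels: tuple[float, float] = (18.0, 10.0),
) -> TaskSignals:
    """Switching task: output follows the sine after u+, the constant after u-.

    The branch changes at the cue onset step; before the first cue the
    constant (u-) branch applies.  The feedback target is the two-level
    cue code with the given (plus, minus) levels.
    """
    if cues.n_channels != 2:
        raise ConfigurationError("experiment 1 needs two cue channels")
    ind = cues.indicators()
    last = cues.last_cue()
    d = np.where(last == CUE_PLUS, sine, constant)
    return _base_signals(
        cues,
        inputs={"u_plus": ind[:, 0], "u_minus": ind[:, 1], "u_sin": np.asarray(sine)},
        feedback={"tf": two_level_feedback(cues, *levels)},
        outputs={"d": d},
        meta={"experiment": "exp1", "levels": levels, "constant": constant},
    )


def targets_experiment2(
    cues: CueTrain,
    u1: np.ndarray,
    u2: np.ndarray,
    levels: tuple[float, float] = (18.0, 10.0),
) -> TaskSignals:
    """Concurrent tasks on two noise streams, two of them cue-switched.

    d1 = u1 after u+, 2*u2 after u- (linear, cued);
    d2 = u1 + u2 after u+, |u1 - u2| after u- (nonlinear, cued);
    d3 = 0.1*u1^3 + 0.2*u1*u2 (nonlinear, cue-independent).
    """
    if cues.n_channels != 2:
        raise ConfigurationError("experiment 2 needs two cue channels")
    u1 = np.asarray(u1, dtype=np.float64)
    u2 = np.asarray(u2, dtype=np.float64)
    ind = cues.indicators()
    plus = cues.last_cue() == CUE_PLUS
    d1 = np.where(plus, u1, 2.0 * u2)
    d2 = np.where(plus, u1 + u2, np.abs(u1 - u2))
    d3 = 0.1 * u1**3 + 0.2 * u1 * u2
    return _base_signals(
        cues,
        inputs={"u_plus": ind[:, 0], "u_minus": ind[:, 1], "u1": u1, "u2": u2},
        feedback={"tf": two_level_feedback(cues, *levels)},
        outputs={"d1": d1, "d2": d2, "d3": d3},
        meta={"experiment": "exp2", "levels": levels},
    )


def targets_experiment3(
    cues: CueTrain,
    uarb: np.ndarray,
    ramps: tuple[int, int] = (300, 600),
    low: float = 5.0,
    high: float = 9.0,
) -> TaskSignals:
    """Elapsed-time task with two ramping feedback loops.

    The fast (short, default 300 steps) and slow (long, default 600 steps)
    ramps both drop to ``low`` at a cue onset and climb back to ``high``.
    The output is d3 = |uarb| - 2.5 * fast_ramp.
    """
    if cues.n_channels != 1:
        raise ConfigurationError("experiment 3 uses a single cue channel")
    uarb = np.asarray(uarb, dtype=np.float64)
    fast = ramp_feedback(cues, ramps[0], low=low, high=high)
    slow = ramp_feedback(cues, ramps[1], low=low, high=high)
    d3 = np.abs(uarb) - 2.5 * fast
    return _base_signals(
        cues,
        inputs={"u_cue": cues.indicators()[:, 0], "u_arb": uarb},
        feedback={"fast": fast, "slow": slow},
        outputs={"d3": d3},
        meta={"experiment": "exp3", "ramps": tuple(ramps)},
    )


def product_target(uarb: np.ndarray, ramp: np.ndarray) -> np.ndarray:
    """Product task d = ramp * |uarb| (sign of the noise is irrelevant)."""
    uarb = np.asarray(uarb, dtype=np.float64)
    ramp = np.asarray(ramp, dtype=np.float64)
    if uarb.shape != ramp.shape:
        raise ConfigurationError("series must be aligned")
    return ramp * np.abs(uarb)


def make_experiment(
    name: str,
    length: int,
    tf_end: int,
    seed=None,
    cue_duration: int = 5,
    gap_tf: tuple[int, int] = (50, 400),
    gap: tuple[int, int] = (100, 800),
    levels: tuple[float, float] = (18.0, 10.0),
    constant: float = 5.0,
    sine_amplitude: float = 1.0,
    sine_period: float = 100.0,
    sine_mean: float = 1.0 / 3.0,
    noise_range: tuple[float, float] = (-5.0, 15.0),
    filter_std: float = 5.0,
    ramps: tuple[int, int] = (300, 600),
    ramp_levels: tuple[float, float] = (9.0, 5.0),
) -> TaskSignals:
    """Build the full signal set for one experiment.

    ``tf_end`` is the last step of the teacher-forcing block (offset
    included): cue gaps are drawn from ``gap_tf`` up to it and from
    ``gap`` afterwards.  Component seeds (cues, each noise stream) are
    derived from ``seed`` deterministically.  ``levels`` are the
    two-level feedback code of the switching experiments;
    ``ramp_levels`` the (high, low) amplitudes of the elapsed-time ramps.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    cue_ss, n1_ss, n2_ss = ss.spawn(3)
    regions = [(0, tf_end, tuple(gap_tf)), (tf_end, length, tuple(gap))]
    if name == "exp1":
        cues = phased_cue_train(2, regions, cue_duration, length, cue_ss)
        sine = sine_drive(length, sine_amplitude, sine_period, sine_mean, filter_std)
        sig = targets_experiment1(cues, sine, constant=constant, levels=levels)
    elif name == "exp2":
        cues = phased_cue_train(2, regions, cue_duration, length, cue_ss)
        u1 = generate_filtered_noise(*noise_range, filter_std, length, n1_ss)
        u2 = generate_filtered_noise(*noise_range, filter_std, length, n2_ss)
        sig = targets_experiment2(cues, u1, u2, levels=levels)
    elif name == "exp3":
        cues = phased_cue_train(1, regions, cue_duration, length, cue_ss)
        uarb = generate_filtered_noise(*noise_range, filter_std, length, n1_ss)
        sig = targets_experiment3(
            cues, uarb, ramps=ramps, low=ramp_levels[1], high=ramp_levels[0]
        )
    elif name == "exp4":
        cues = phased_cue_train(2, regions, cue_duration, length, cue_ss)
        uarb = generate_filtered_noise(*noise_range, filter_std, length, n1_ss)
        ind = cues.indicators()
        sig = _base_signals(
            cues,
            inputs={"u_plus": ind[:, 0], "u_minus": ind[:, 1], "u_arb": uarb},
            feedback={"tf": two_level_feedback(cues, *levels)},
            outputs={},
            meta={"experiment": "exp4", "levels": levels},
        )
    else:
        raise ConfigurationError(f"unknown experiment '{name}'")
    sig.meta.update({"seed": repr(seed), "tf_end": tf_end})
    return sig
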