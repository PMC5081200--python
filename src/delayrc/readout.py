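"""Linear readouts: feedforward task outputs and trained feedback.

Only the readouts of a reservoir computer are trained.  Feedforward
coefficients (alpha) map the n virtual-node activities of a step to a task
output; feedback coefficients (beta) are trained by *teacher forcing* --
during an initial phase the feedback channel is clamped to a noise-corrupted
copy of its target, and beta is fit by least squares so that the readout of
step t reproduces the (noisy) target at t.  In the closed loop the readout
of step t-1 becomes the feedback channel value at step t.

All regressions include a trailing constant bias column: the printed readout
formula has no intercept, but constant targets (e.g. the value 5) would
otherwise waste node dimensions, and the bias can fit to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import ConfigurationError, RegressionDataError

__all__ = [
    "RegressionData",
    "ReadoutWeights",
    "NoiseSpec",
    "add_bias",
    "fit_least_squares",
    "predict",
    "predict_many",
    "noisy_targets",
    "teacher_force_collect",
    "closed_loop_step",
    "weights_frame",
]


def add_bias(X: np.ndarray) -> np.ndarray:
    """Append the constant bias column (last) to a node-activity matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return np.hstack([X, np.ones((X.shape[0], 1))])


@dataclass
class RegressionData:
    """Design matrix (bias column last) and aligned target vector."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] == 0:
            raise RegressionDataError("empty regression data")
        if self.y.shape != (self.X.shape[0],):
            raise RegressionDataError(
                f"target length {self.y.shape} does not match "
                f"{self.X.shape[0]} design rows"
            )
        bad_x = ~np.isfinite(self.X).all(axis=1)
        bad = bad_x | ~np.isfinite(self.y)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise RegressionDataError(f"non-finite value in regression row {row}")


@dataclass
class ReadoutWeights:
    """Fitted linear readout; ``coeffs`` has length n_nodes + 1, bias last."""

    coeffs: np.ndarray
    role: str = "feedforward"
    ridge: float = 0.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.ndim != 1:
            raise ConfigurationError("readout coefficients must be a vector")

    @property
    def bias(self) -> float:
        return float(self.coeffs[-1])

    @property
    def node_coeffs(self) -> np.ndarray:
        return self.coeffs[:-1]


@dataclass
class NoiseSpec:
    """Teacher-forcing noise: zero-mean, ``scale`` in target units."""

    scale: float
    kind: str = "gaussian"
    seed: object = None

    def __post_init__(self):
        if self.scale < 0:
            raise ConfigurationError(f"noise scale must be >= 0, got {self.scale}")
        if self.kind not in ("gaussian", "uniform"):
            raise ConfigurationError(f"unknown noise kind '{self.kind}'")

    def sample(self, length: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.kind == "gaussian":
            return rng.normal(0.0, self.scale, size=length)
        half = self.scale * np.sqrt(3.0)  # matching standard deviation
        return rng.uniform(-half, half, size=length)


def fit_least_squares(
    data: RegressionData,
    ridge: float = 0.0,
    role: str = "feedforward",
    cond: float | None = 1e-8,
) -> ReadoutWeights:
    """Least-squares readout fit.

    ridge=0 gives the plain least-squares solution, minimum-norm with
    respect to the numerical rank of the design: singular values below
    ``cond`` times the largest are treated as zero.  Reservoir design
    matrices are severely ill-conditioned (neighbouring virtual nodes are
    nearly collinear; relative singular values reach 1e-13), and
    directions that small carry no information at float64 precision but
    amplify target noise by >1e8, which destabilises the closed feedback
    loop.  The 1e-8 default keeps every direction that is numerically
    meaningful; pass ``cond=None`` for the LAPACK machine-precision
    cutoff.  ridge>0 adds an L2 penalty on all coefficients except the
    bias instead.
    """
    if ridge < 0:
        raise ConfigurationError(f"ridge must be >= 0, got {ridge}")
    if ridge == 0.0:
        coeffs, *_ = scipy.linalg.lstsq(
            data.X, data.y, cond=cond, lapack_driver="gelsd"
        )
    else:
        p = data.X.shape[1]
        penalty = ridge * np.eye(p)
        penalty[-1, -1] = 0.0  # bias unpenalised
        coeffs = scipy.linalg.solve(
            data.X.T @ data.X + penalty, data.X.T @ data.y, assume_a="pos"
        )
    return ReadoutWeights(coeffs=coeffs, role=role, ridge=ridge)


def predict(w: ReadoutWeights, x: np.ndarray) -> float:
    """Readout output for one step's node activities (bias added here)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (w.coeffs.size - 1,):
        raise ConfigurationError(
            f"expected {w.coeffs.size - 1} node activities, got {x.shape}"
        )
    return float(x @ w.node_coeffs + w.bias)


def predict_many(w: ReadoutWeights, X: np.ndarray) -> np.ndarray:
    """Vectorised :func:`predict` over rows of a (T, n) activity matrix."""
    X = np.asarray(X, dtype=np.float64)
    return X @ w.node_coeffs + w.bias


def noisy_targets(z: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Noise-corrupted feedback target series z~ = z + eps."""
    z = np.asarray(z, dtype=np.float64)
    return z + noise.sample(z.size)


def teacher_force_collect(
    nodes: np.ndarray, ztilde: np.ndarray, offset: int
) -> RegressionData:
    """Regression data for a feedback readout from a teacher-forced phase.

    ``nodes`` are the per-step activities over the phase (offset steps
    included, discarded here); the regression target is the *noisy* target
    series z~ -- the objective is sum over steps of (z~ - z^)^2, not the
    clean target.
    """
    nodes = np.asarray(nodes, dtype=np.float64)
    ztilde = np.asarray(ztilde, dtype=np.float64)
    if nodes.shape[0] <= offset:
        raise ConfigurationError(
            f"teacher-forcing phase of {nodes.shape[0]} steps is not longer "
            f"than its {offset}-step offset"
        )
    return RegressionData(X=add_bias(nodes[offset:]), y=ztilde[offset:])


def closed_loop_step(
    weights_beta: list[ReadoutWeights], prev_nodes: np.ndarray
) -> np.ndarray:
    """Feedback channel values for step t from the activities at t-1."""
    return np.array([predict(w, prev_nodes) for w in weights_beta])


def weights_frame(w: ReadoutWeights) -> pd.DataFrame:
    """Serializable columnar view (index, coefficient); bias has index -1."""
    n = w.coeffs.size - 1
    return pd.DataFrame(
        {"index": list(range(n)) + [-1], "coefficient": w.coeffs}
    )
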