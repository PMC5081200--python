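"""Time-multiplexing: random binary masks, virtual-node layouts, forcing.

Instead of distributing input spatially over many neurons, a delay-coupled
reservoir distributes it in time: each reservoir step holds the input
constant for one delay interval while a piecewise-constant +/-mu mask
modulates it along the delay line.  The mask segments end at n *virtual
nodes*, whose activities (one sample each per delay cycle) are the
regression predictors.

Feedback channels are treated exactly like input channels: they occupy
additional columns of the single mask matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dde import HistoryBuffer
from .exceptions import ConfigurationError

__all__ = [
    "Mask",
    "NodeLayout",
    "StepInput",
    "generate_mask",
    "generate_layout",
    "build_forcing",
    "node_forcing_values",
    "sample_virtual_nodes",
    "multiplex_frame",
    "multiplex_from_frame",
]


@dataclass
class Mask:
    """Random binary mask over input and feedback channels.

    ``bits`` has shape (n, m+q) with every entry in {-mu, +mu}; row i is
    the weight vector of virtual node i.
    """

    bits: np.ndarray
    mu: float
    n_inputs: int
    n_feedback: int
    seed: object = None

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.float64)
        if self.bits.shape[1] != self.n_inputs + self.n_feedback:
            raise ConfigurationError("mask columns must equal m + q")

    @property
    def n_nodes(self) -> int:
        return self.bits.shape[0]

    @property
    def n_channels(self) -> int:
        return self.bits.shape[1]


@dataclass
class NodeLayout:
    """Placement of virtual nodes on the simulation grid of one delay cycle.

    ``offsets`` are the strictly increasing grid indices at which each
    node is sampled (the END of its mask segment).  The inter-node delays
    ``thetas`` tile the cycle exactly: node i's segment covers the
    ``theta_i`` grid intervals ending at ``offsets[i]``, with the
    wrap-around gap past the last node assigned to the first node of the
    next cycle, so ``sum(thetas) == grid`` (= tau in grid units).
    """

    offsets: np.ndarray
    grid: int
    seed: object = None
    _segment_of_grid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=np.intp)
        if self.offsets.size == 0 or self.offsets.size > self.grid:
            raise ConfigurationError("need 1 <= n nodes <= grid points")
        if np.any(np.diff(self.offsets) <= 0):
            raise ConfigurationError("node offsets must be strictly increasing")
        if self.offsets[0] < 0 or self.offsets[-1] >= self.grid:
            raise ConfigurationError("node offsets must lie within the grid")

    @property
    def n_nodes(self) -> int:
        return self.offsets.size

    @property
    def thetas(self) -> np.ndarray:
        """Per-node delays in grid units; sums to ``grid`` exactly."""
        th = np.empty(self.n_nodes, dtype=np.intp)
        th[0] = self.grid + self.offsets[0] - self.offsets[-1]
        th[1:] = np.diff(self.offsets)
        return th

    @property
    def segment_of_grid(self) -> np.ndarray:
        """For each grid interval, the index of the node segment covering it."""
        if self._segment_of_grid is None:
            g = np.arange(self.grid)
            self._segment_of_grid = (
                np.searchsorted(self.offsets, g, side="left") % self.n_nodes
            )
        return self._segment_of_grid


@dataclass
class StepInput:
    """Channel values held constant over one reservoir time step."""

    u: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        self.u = np.atleast_1d(np.asarray(self.u, dtype=np.float64))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=np.float64))
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.phi))):
            raise ConfigurationError("step input values must be finite")

    @property
    def channels(self) -> np.ndarray:
        return np.concatenate([self.u, self.phi])


def generate_mask(n: int, m: int, q: int, mu: float, seed=None) -> Mask:
    """Draw an (n, m+q) mask with entries independently +/-mu (p = 1/2)."""
    if n < 1 or m + q < 1 or m < 0 or q < 0:
        raise ConfigurationError(
            f"mask dimensions must be positive (n={n}, m={m}, q={q})"
        )
    if not mu > 0:
        raise ConfigurationError(f"mask amplitude mu must be > 0, got {mu}")
    rng = np.random.default_rng(seed)
    bits = mu * (2.0 * rng.integers(0, 2, size=(n, m + q)) - 1.0)
    return Mask(bits=bits, mu=mu, n_inputs=m, n_feedback=q, seed=seed)


def generate_layout(n: int, grid: int, seed=None) -> NodeLayout:
    """Place n virtual nodes uniformly at random (without replacement)."""
    if n > grid:
        raise ConfigurationError(f"cannot place {n} nodes on {grid} grid points")
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.choice(grid, size=n, replace=False))
    return NodeLayout(offsets=offsets, grid=grid, seed=seed)


def node_forcing_values(
    channels: np.ndarray, mask: Mask, gamma: float
) -> np.ndarray:
    """Per-node forcing gamma * (M_i . [u; phi]) for one reservoir step."""
    channels = np.asarray(channels, dtype=np.float64)
    if channels.shape != (mask.n_channels,):
        raise ConfigurationError(
            f"got {channels.shape[0]} channel values for a "
            f"{mask.n_channels}-channel mask"
        )
    return gamma * (mask.bits @ channels)


def build_forcing(
    step: StepInput, mask: Mask, layout: NodeLayout, gamma: float
) -> np.ndarray:
    """Piecewise-constant forcing over one delay cycle.

    Grid interval g carries the masked, scaled value of the node segment
    containing it; intervals past the last sampling point belong to the
    first node's (wrap-around) segment.
    """
    if layout.n_nodes != mask.n_nodes:
        raise ConfigurationError("mask and layout node counts differ")
    vals = node_forcing_values(step.channels, mask, gamma)
    return vals[layout.segment_of_grid]


def sample_virtual_nodes(buffer: HistoryBuffer, layout: NodeLayout) -> np.ndarray:
    """Node activities of the just-completed cycle, in mask row order.

    Node i is read out at the end of its segment, i.e. at grid offset
    ``offsets[i]`` of the cycle's samples.
    """
    if buffer.n_samples != layout.grid:
        raise ConfigurationError("buffer resolution does not match layout grid")
    return buffer.samples[layout.offsets]


def multiplex_frame(mask: Mask, layout: NodeLayout) -> pd.DataFrame:
    """Mask + layout as one columnar table for exact experiment replay."""
    data = {
        "node": np.arange(mask.n_nodes),
        "offset": layout.offsets,
        "theta": layout.thetas,
    }
    for c in range(mask.n_channels):
        kind = "u" if c < mask.n_inputs else "phi"
        idx = c if c < mask.n_inputs else c - mask.n_inputs
        data[f"bit_{kind}{idx}"] = mask.bits[:, c]
    return pd.DataFrame(data)


def multiplex_from_frame(
    frame: pd.DataFrame, mu: float, grid: int
) -> tuple[Mask, NodeLayout]:
    bit_cols = [c for c in frame.columns if c.startswith("bit_")]
    m = sum(c.startswith("bit_u") for c in bit_cols)
    q = len(bit_cols) - m
    mask = Mask(
        bits=frame[bit_cols].to_numpy(),
        mu=mu,
        n_inputs=m,
        n_feedback=q,
    )
    layout = NodeLayout(offsets=frame["offset"].to_numpy(), grid=grid)
    return mask, layout
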