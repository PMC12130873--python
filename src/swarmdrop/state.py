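"""State containers: the (h, b, c) field triplet and simulation output."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .grid import Grid1D
from .params import DimensionlessParams

__all__ = ["SwarmState", "SimulationOutput"]


@dataclass
class SwarmState:
    """The model state at one instant.

    Attributes
    ----------
    t :
        Time.
    h :
        Swarm height field (>= precursor everywhere).
    b :
        Depth-integrated bacteria quantity (>= 0).
    c :
        Chemoattractant concentration (>= 0).
    """

    t: float
    h: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not (self.h.shape == self.b.shape == self.c.shape):
            raise ValueError("h, b, c must share one grid")

    def validate(self, params: DimensionlessParams, *, atol: float = 1e-9) -> None:
        """Raise if any field is non-finite or violates positivity."""
        for name, f in (("h", self.h), ("b", self.b), ("c", self.c)):
            if not np.all(np.isfinite(f)):
                raise FloatingPointError(f"non-finite values in {name}")
        if self.h.min() < params.precursor - atol:
            raise ValueError("h dropped below the precursor film")
        if self.b.min() < -atol or self.c.min() < -atol:
            raise ValueError("negative bacteria or chemoattractant")

    def copy(self) -> "SwarmState":
        return SwarmState(self.t, self.h.copy(), self.b.copy(), self.c.copy())


@dataclass
class SimulationOutput:
    """A time-stamped sequence of states plus run metadata.

    ``events`` holds solver events (currently pinch-off detections as
    ``(time, position)`` pairs); ``provenance`` records the configuration
    hash, solver tolerances and any seed, so a run can be reproduced exactly.
    """

    times: np.ndarray
    states: list[SwarmState]
    params: DimensionlessParams
    grid: Grid1D
    events: list[tuple[float, float]] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != len(self.states):
            raise ValueError("one state per output time required")
        if self.times.size > 1 and np.diff(self.times).min() <= 0:
            raise ValueError("times must be strictly increasing")

    @property
    def h(self) -> np.ndarray:
        """Height kymograph, shape (n_times, n_nodes)."""
        return np.stack([s.h for s in self.states])

    @property
    def b(self) -> np.ndarray:
        """Bacteria kymograph, shape (n_times, n_nodes)."""
        return np.stack([s.b for s in self.states])

    @property
    def c(self) -> np.ndarray:
        """Chemoattractant kymograph, shape (n_times, n_nodes)."""
        return np.stack([s.c for s in self.states])

    def swarm_volume(self) -> np.ndarray:
        """Integral of (h - precursor) over the domain at each output time."""
        hs = self.params.precursor
        return np.trapezoid(np.clip(self.h - hs, 0.0, None), self.grid.x, axis=1)
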