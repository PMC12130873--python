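"""Synthetic kymographs emulating light-sheet swarm quantification.

These generators produce (h, b, c) kymographs with the geometry seen in
side-view imaging of a feeding front — a smooth swarm hump 100-200 um tall
and 200-400 um long, a leading bacteria peak of up to twice the lawn level,
and a depleted trailing lawn — without running the PDE.  They exercise the
metrics pipeline against constructions whose ground truth (boundaries,
speeds, gradients, event times) is known analytically.

All lengths and heights are in units of 100 um and times in hours, matching
the reference nondimensionalization.
"""

from __future__ import annotations

import numpy as np

from .grid import Grid1D
from .params import DimensionlessParams, reference_dimensionless
from .state import SimulationOutput, SwarmState

__all__ = ["synthetic_traveling_swarm", "synthetic_shedding_run"]


def _hump(x: np.ndarray, center: float, length: float, height: float,
          precursor: float) -> np.ndarray:
    u = 2.0 * (x - center) / length
    return precursor + height * np.clip(1.0 - u**2, 0.0, None) ** 1.5


def _bacteria(x: np.ndarray, front: float, lawn: float, peak_factor: float,
              peak_width: float, depletion_width: float) -> np.ndarray:
    """Lawn ahead, Gaussian accumulation peak at the front, cleared behind."""
    step = lawn / (1.0 + np.exp(-(x - front) / (depletion_width / 4)))
    peak = lawn * peak_factor * np.exp(-((x - front) / peak_width) ** 2)
    return np.maximum(step, peak)


def synthetic_traveling_swarm(*, speed: float = 1.4, height: float = 1.5,
                              length: float = 3.0, lawn: float = 1.0,
                              peak_factor: float = 2.0, t_end: float = 10.0,
                              output_interval: float = 0.25,
                              n_nodes: int = 768, domain: float = 40.0,
                              params: DimensionlessParams | None = None) -> SimulationOutput:
    """A steadily advancing swarm hump with a leading bacteria peak.

    The swarm travels at exactly ``speed``; the chemoattractant is a smoothed
    copy of the bacteria profile, so its gradient is localized at the front
    like the self-generated gradient in the full model.
    """
    params = params or reference_dimensionless()
    grid = Grid1D.uniform(0.0, domain, n_nodes)
    times = np.arange(0.0, t_end + 1e-9, output_interval)
    states = []
    for t in times:
        center = 0.15 * domain + speed * t
        front = center + length / 2
        h = _hump(grid.x, center, length, height, params.precursor)
        b = _bacteria(grid.x, front, lawn, peak_factor, length / 4, length / 2)
        c = params.production / params.decay * _smooth(b, grid, 3)
        states.append(SwarmState(t, h, b, c))
    return SimulationOutput(times, states, params, grid,
                            provenance={"generator": "synthetic_traveling_swarm"})


def _smooth(f: np.ndarray, grid: Grid1D, n_pass: int) -> np.ndarray:
    g = f.astype(float).copy()
    for _ in range(n_pass):
        g[1:-1] = 0.25 * g[:-2] + 0.5 * g[1:-1] + 0.25 * g[2:]
    return g


def synthetic_shedding_run(*, n_cycles: int = 3, period: float = 4.0,
                           speed: float = 1.0, base_length: float = 3.0,
                           stretch: float = 3.0, clump_height: float = 0.7,
                           n_nodes: int = 1024, domain: float = 40.0,
                           output_interval: float = 0.2,
                           params: DimensionlessParams | None = None) -> SimulationOutput:
    """Sawtooth shedding kymograph with pinches co-located with collapses.

    Each cycle the swarm elongates linearly by ``stretch`` over the last
    quarter of the period, then instantaneously sheds a clump (a stationary
    hump left at the rear position) and snaps back to ``base_length``; the
    height between the clump and the swarm dips below the pinch threshold at
    the event, so both the length-collapse rule and the pinch detector fire.
    """
    params = params or reference_dimensionless()
    grid = Grid1D.uniform(0.0, domain, n_nodes)
    t_end = n_cycles * period + period / 2
    times = np.arange(0.0, t_end + 1e-9, output_interval)
    states = []
    for t in times:
        cycle, phase = divmod(t, period)
        center = 0.12 * domain + speed * t
        if phase < 0.75 * period:
            L = base_length
        else:
            L = base_length + stretch * (phase / period - 0.75) / 0.25
        # elongation stretches the rear backwards
        front = center + base_length / 2
        rear = front - L
        h = _hump(grid.x, 0.5 * (front + rear), L, 1.5 * base_length / L,
                  params.precursor)
        for k in range(int(cycle)):
            shed_t = (k + 1) * period
            shed_front = 0.12 * domain + speed * shed_t + base_length / 2
            clump_x = shed_front - base_length - stretch
            h = np.maximum(h, _hump(grid.x, clump_x, 1.2, clump_height,
                                    params.precursor))
        b = _bacteria(grid.x, front, 1.0, 2.0, base_length / 4, base_length / 2)
        c = params.production / params.decay * _smooth(b, grid, 3)
        states.append(SwarmState(t, h, b, c))
    out = SimulationOutput(times, states, params, grid,
                           provenance={"generator": "synthetic_shedding_run"})
    # pinch events at each snap-back, at the neck between clump and swarm
    for k in range(1, n_cycles + 1):
        t_ev = k * period
        front = 0.12 * domain + speed * t_ev + base_length / 2
        out.events.append((t_ev, front - base_length - stretch / 2))
    return out
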