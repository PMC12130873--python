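"""Uniform 1D grids for the swarm cross-section."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid1D"]


@dataclass(frozen=True)
class Grid1D:
    """A uniform 1D grid of node positions.

    Parameters
    ----------
    x :
        Monotone, uniformly spaced node positions.
    boundary_kind :
        ``"far_field_film"`` (height clamped to the precursor film, zero flux
        for bacteria and chemoattractant) or ``"periodic"`` (used for
        convergence tests).
    """

    x: np.ndarray
    boundary_kind: str = "far_field_film"
    dx: float = field(init=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size < 16:
            raise ValueError("grid needs at least 16 nodes")
        d = np.diff(x)
        if d.min() <= 0:
            raise ValueError("grid positions must be strictly increasing")
        dx = float(d.mean())
        if np.abs(d - dx).max() > 1e-12 * max(abs(x[0]), abs(x[-1]), dx):
            raise ValueError("grid spacing must be uniform to 1e-12 relative")
        if self.boundary_kind not in ("far_field_film", "periodic"):
            raise ValueError(f"unknown boundary_kind {self.boundary_kind!r}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "dx", dx)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def length(self) -> float:
        return float(self.x[-1] - self.x[0])

    @classmethod
    def uniform(cls, x0: float, x1: float, n: int,
                boundary_kind: str = "far_field_film") -> "Grid1D":
        """Build a uniform grid of ``n`` nodes on ``[x0, x1]``."""
        return cls(np.linspace(x0, x1, n), boundary_kind)

    def gradient(self, field_values: np.ndarray) -> np.ndarray:
        """Second-order first derivative (central; one-sided at the ends)."""
        f = np.asarray(field_values, dtype=float)
        if self.boundary_kind == "periodic":
            return (np.roll(f, -1) - np.roll(f, 1)) / (2 * self.dx)
        return np.gradient(f, self.dx, edge_order=2)

    def laplacian(self, field_values: np.ndarray) -> np.ndarray:
        """Second-order second derivative.

        For ``far_field_film`` grids the end values are mirrored (zero-flux),
        for periodic grids the stencil wraps.
        """
        f = np.asarray(field_values, dtype=float)
        out = np.empty_like(f)
        dx2 = self.dx**2
        out[1:-1] = (f[2:] - 2 * f[1:-1] + f[:-2]) / dx2
        if self.boundary_kind == "periodic":
            out[0] = (f[1] - 2 * f[0] + f[-1]) / dx2
            out[-1] = (f[0] - 2 * f[-1] + f[-2]) / dx2
        else:
            out[0] = 2 * (f[1] - f[0]) / dx2
            out[-1] = 2 * (f[-2] - f[-1]) / dx2
        return out
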