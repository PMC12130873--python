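"""Constitutive pieces of the active thin-film model.

The depth-averaged momentum balance of a thin viscous film with a Navier
slip floor and a chemotactically biased active stress acting like a surface
stress gradient yields the cell flux

    Q = m_p(h) * (-dp/dx) + m_a(h) * (d sigma_a/dx),

with the pressure-flux mobility ``m_p = h**3/3 + slip*h**2`` and the
active-flux mobility ``m_a = h**2/2 + slip*h`` (depth integrals of the
parabolic slip velocity profile).  The pressure combines the capillary
(Laplace) pressure with a disjoining pressure that stabilizes the precursor
wetting film and selects a unit equilibrium contact angle, so stationary
passive droplets are parabolic caps of length sqrt(6 V).

All functions are pure and vectorized; identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import numpy as np

from .grid import Grid1D
from .params import DimensionlessParams

__all__ = [
    "mobility",
    "capillary_pressure",
    "disjoining_pressure",
    "film_pressure",
    "active_stress",
    "growth_term",
    "bacteria_rhs",
    "chemo_rhs",
]


def mobility(h, slip: float):
    """Pressure-flux and active-flux mobilities of the slip-parabola profile.

    Parameters
    ----------
    h :
        Film height (scalar or array), must be >= 0.
    slip :
        Dimensionless Navier slip length.

    Returns
    -------
    (m_p, m_a) :
        ``m_p = h**3/3 + slip*h**2`` and ``m_a = h**2/2 + slip*h``; both are
        nonnegative and strictly increasing in ``h``.  At ``slip = 0`` they
        reduce to the no-slip Poiseuille values ``h**3/3`` and ``h**2/2``.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("mobility requires h >= 0")
    if slip < 0:
        raise ValueError("slip must be >= 0")
    m_p = h**3 / 3.0 + slip * h**2
    m_a = h**2 / 2.0 + slip * h
    if m_p.ndim == 0:
        return float(m_p), float(m_a)
    return m_p, m_a


def capillary_pressure(h: np.ndarray, grid: Grid1D, Ca_kappa: float) -> np.ndarray:
    """Laplace pressure ``p = -(1/Ca_kappa) * d2h/dx2`` (conservative stencil).

    The flux later uses ``dp/dx``, i.e. the third derivative of ``h``.
    """
    h = np.asarray(h, dtype=float)
    if h.size < 5:
        raise ValueError("capillary pressure needs at least 5 nodes")
    return -grid.laplacian(h) / Ca_kappa


def disjoining_pressure(h: np.ndarray, precursor: float,
                        contact_angle: float = 1.0) -> np.ndarray:
    """Wetting (disjoining) pressure stabilizing the precursor film.

    Standard (3, 2)-exponent form

        Pi(h) = (theta**2 / precursor) * ((precursor/h)**3 - (precursor/h)**2),

    scaled so the equilibrium contact angle of a macroscopic droplet sitting
    on the precursor film equals ``theta`` in rescaled units.  It is repulsive
    below the precursor height and weakly attractive above it, which lets
    necks dewet cleanly during pinch-off without any topological surgery.
    ``h`` is floored at ``0.3 * precursor`` for evaluation only, as a guard
    against transient undershoots of the implicit time stepper.
    """
    hp = np.maximum(np.asarray(h, dtype=float), 0.3 * precursor)
    r = precursor / hp
    return (contact_angle**2 / precursor) * (r**3 - r**2)


def film_pressure(h: np.ndarray, grid: Grid1D, params: DimensionlessParams) -> np.ndarray:
    """Total pressure: capillary part plus the (Ca-scaled) wetting part."""
    pi = disjoining_pressure(h, params.precursor, params.contact_angle)
    return capillary_pressure(h, grid, params.Ca_kappa) - pi / params.Ca_kappa


def active_stress(c: np.ndarray, grid: Grid1D, params: DimensionlessParams,
                  *, gate_sensing: bool = False) -> np.ndarray:
    """Chemotactic active stress ``sigma_a = Ca_xi * f(dc/dx)``.

    The gradient response ``f(g) = g / (saturation + |g|)`` is odd, monotone
    and saturates at +-1, encoding receptor saturation: for weak gradients the
    stress is linear in the gradient, for strong gradients it is capped at
    ``Ca_xi``.  With ``gate_sensing=True`` the response is zeroed where
    ``|dc/dx|`` falls below the sensing threshold (by default the threshold is
    purely diagnostic and the dynamics are not gated).
    """
    g = grid.gradient(np.asarray(c, dtype=float))
    f = g / (params.saturation + np.abs(g))
    if gate_sensing:
        f = np.where(np.abs(g) < params.sensing, 0.0, f)
    return params.Ca_xi * f


def growth_term(h: np.ndarray, b: np.ndarray, params: DimensionlessParams) -> np.ndarray:
    """Proliferation source ``s = growth * phi(b) * (h - precursor)``.

    ``phi(b) = b / (growth_half_sat + b)`` saturates in the local bacteria
    quantity (phi(0) = 0), and the ``(h - precursor)`` factor excludes the
    dry precursor film: no cells, no growth.
    """
    bp = np.clip(np.asarray(b, dtype=float), 0.0, None)
    phi = bp / (params.growth_half_sat + bp)
    psi = np.clip(np.asarray(h, dtype=float) - params.precursor, 0.0, None)
    return params.growth * phi * psi


def bacteria_rhs(h: np.ndarray, b: np.ndarray, params: DimensionlessParams) -> np.ndarray:
    """Bacteria consumption ``db/dt = -consumption * (h - precursor)_+ * b``.

    The rate vanishes on the precursor film and at ``b = 0``, so ``b`` stays
    nonnegative under any positivity-preserving integrator.
    """
    psi = np.clip(np.asarray(h, dtype=float) - params.precursor, 0.0, None)
    return -params.consumption * psi * np.clip(np.asarray(b, dtype=float), 0.0, None)


def chemo_rhs(c: np.ndarray, b: np.ndarray, grid: Grid1D,
              params: DimensionlessParams) -> np.ndarray:
    """Chemoattractant kinetics: screened diffusion sourced by bacteria.

    ``dc/dt = (1/peclet) * d2c/dx2 + production * b - decay * c``; the
    quasi-steady response to a localized source decays over the screening
    length ``sqrt(1 / (peclet * decay))``.
    """
    bp = np.clip(np.asarray(b, dtype=float), 0.0, None)
    return (grid.laplacian(np.asarray(c, dtype=float)) / params.peclet
            + params.production * bp - params.decay * np.asarray(c, dtype=float))
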