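"""Swarm and gradient diagnostics on (h, b, c) kymographs.

Implements the quantification rules used for the light-sheet data on model
output: 30 um-equivalent boundary threshold, 6-cell-width gradient window,
second-order central differences for boundary velocities, the
positional-information fraction m_ch, the shape parameter S, shedding-event
detection and the traveling/shedding phase rule, plus morphology phase
diagrams over the capillary numbers and floor friction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid1D
from .params import DimensionlessParams, with_friction_factor
from .state import SimulationOutput, SwarmState

__all__ = [
    "SwarmMetricsRecord",
    "SheddingEvent",
    "swarm_boundary",
    "boundary_velocity",
    "bacteria_gradient_stats",
    "m_ch",
    "shape_parameter",
    "passive_cap_length",
    "compute_metrics",
    "detect_shedding_events",
    "classify_phase",
    "phase_diagram",
]

#: boundary threshold: 30 um in units of a 100 um height scale
DEFAULT_BOUNDARY_THRESHOLD = 0.3
#: cell width for the gradient window: 10 um in units of a 100 um length scale
DEFAULT_CELL_WIDTH = 0.1


class NoSwarmError(ValueError):
    """The height field has no super-threshold region."""


@dataclass
class SwarmMetricsRecord:
    """Derived quantities at one output time (one kymograph column)."""

    t: float
    front_x: float
    rear_x: float
    length: float
    volume: float
    front_v: float = np.nan
    rear_v: float = np.nan
    elongation_rate: float = np.nan
    grad_min: float = np.nan
    grad_max: float = np.nan
    grad_ratio: float = np.nan
    neg_grad_pos: float = np.nan
    m_ch: float = np.nan
    S: float = np.nan
    phase: str = ""


@dataclass
class SheddingEvent:
    """One length-collapse + pinch event."""

    t_event: float
    position: float
    clump_volume: float
    spacing_to_previous: float = np.nan
    period_to_previous: float = np.nan


def _leading_region(h: np.ndarray, threshold: float) -> tuple[int, int]:
    """Index span [lo, hi] of the connected super-threshold region containing
    the global peak."""
    above = h > threshold
    if not above.any():
        raise NoSwarmError("no region above the boundary threshold")
    i = int(np.argmax(h))
    lo = i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i
    while hi < h.size - 1 and above[hi + 1]:
        hi += 1
    return lo, hi


def swarm_boundary(h: np.ndarray, grid: Grid1D,
                   threshold: float = DEFAULT_BOUNDARY_THRESHOLD) -> tuple[float, float]:
    """(rear_x, front_x): threshold crossings of the leading swarm.

    The leading swarm is the connected super-threshold region containing the
    global height peak; the front is its forward (downward) threshold
    crossing and the rear its backward (upward) crossing, both located by
    linear interpolation.
    """
    h = np.asarray(h, dtype=float)
    lo, hi = _leading_region(h, threshold)
    x = grid.x
    if lo == 0:
        rear = float(x[0])
    else:
        f = (h[lo - 1] - threshold) / (h[lo - 1] - h[lo])
        rear = float(x[lo - 1] + f * grid.dx)
    if hi == h.size - 1:
        front = float(x[-1])
    else:
        f = (h[hi] - threshold) / (h[hi] - h[hi + 1])
        front = float(x[hi] + f * grid.dx)
    return rear, front


def boundary_velocity(times: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Second-order finite-difference velocity of a boundary trajectory.

    Central differences at interior samples, second-order one-sided at the
    ends; exact for linear trajectories at interior points.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(positions, dtype=float)
    if t.size < 2:
        return np.full_like(p, np.nan)
    return np.gradient(p, t, edge_order=2 if t.size > 2 else 1)


def bacteria_gradient_stats(b: np.ndarray, grid: Grid1D, rear_x: float,
                            front_x: float, *,
                            cell_width: float = DEFAULT_CELL_WIDTH,
                            peak_x: float | None = None) -> dict:
    """Windowed bacteria-gradient statistics within the swarm.

    The gradient at x is ``(b(x + w/2) - b(x - w/2)) / w`` with window
    ``w = 6 * cell_width``.  ``grad_min`` is taken between the swarm rear and
    the swarm peak, ``grad_max`` over the whole swarm (so the leading
    bacteria peak is captured).  ``neg_grad_pos`` is the position of the
    negative-gradient point closest to the swarm peak, measured relative to
    the rear: positive inside the swarm, negative behind it, NaN when no
    negative gradient exists anywhere behind the peak.
    """
    b = np.asarray(b, dtype=float)
    x = grid.x
    w = 6.0 * cell_width
    if w < 2 * grid.dx:
        raise ValueError("gradient window must be at least 2*dx")
    if front_x - rear_x < w:
        w = max(2 * grid.dx, front_x - rear_x)  # degenerate: narrow swarm
    half = w / 2.0
    grad = (np.interp(x + half, x, b) - np.interp(x - half, x, b)) / w
    if peak_x is None:
        peak_x = x[int(np.argmax(b * ((x >= rear_x) & (x <= front_x))))]
    sel_full = (x >= rear_x) & (x <= front_x)
    sel_rear = (x >= rear_x) & (x <= peak_x)
    if not sel_rear.any():
        sel_rear = sel_full
    gmin = float(grad[sel_rear].min()) if sel_rear.any() else np.nan
    gmax = float(grad[sel_full].max()) if sel_full.any() else np.nan
    ratio = gmin / gmax if gmax > 0 else np.nan
    # furthest-forward negative gradient at or behind the peak; reversals
    # smaller than 2% of the peak gradient are indistinguishable from noise
    neg_tol = max(1e-12, 0.02 * abs(gmax)) if np.isfinite(gmax) else 1e-12
    neg = (grad < -neg_tol) & (x <= peak_x)
    if neg.any():
        pos = float(x[neg][-1]) - rear_x
    else:
        pos = np.nan
    return {"grad_min": gmin, "grad_max": gmax, "grad_ratio": ratio,
            "neg_grad_pos": pos}


def m_ch(h: np.ndarray, c: np.ndarray, grid: Grid1D, rear_x: float,
         front_x: float, sensing_threshold: float, *,
         precursor: float = 0.0) -> float:
    """Fraction of swarm mass lacking positional information.

    The mass-weighted fraction of the swarm where the chemoattractant
    gradient magnitude is below the cells' sensing threshold:
    ``int h * 1[|dc/dx| < s] dx / int h dx`` over [rear, front].
    """
    h = np.asarray(h, dtype=float)
    g = np.abs(grid.gradient(np.asarray(c, dtype=float)))
    sel = (grid.x >= rear_x) & (grid.x <= front_x)
    hx = np.clip(h[sel] - precursor, 0.0, None)
    total = np.trapezoid(hx, grid.x[sel])
    if total <= 0:
        return np.nan
    blind = np.trapezoid(hx * (g[sel] < sensing_threshold), grid.x[sel])
    return float(blind / total)


def shape_parameter(length: float, volume: float,
                    cap_length: float | None = None) -> float:
    """Shape parameter ``S = L / L_passive(V)``.

    By default ``L_passive = sqrt(6 V)``, the length of a stationary passive
    parabolic-cap droplet of volume V at unit contact angle (the macroscopic
    limit), so relaxed passive droplets have S ~ 1 and elongated swarms
    S > 1.  When the measured length is taken at a finite cut height on a
    droplet whose size is not huge compared to the precursor film, pass the
    model-consistent ``cap_length`` from ``passive_cap_length`` instead.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    ref_len = cap_length if cap_length is not None else np.sqrt(6.0 * volume)
    return float(length / ref_len)


def passive_cap_length(volume: float, *, cut: float = 0.1,
                       precursor: float = 0.05,
                       contact_angle: float = 1.0) -> float:
    """Length at height ``cut`` of the model's stationary passive droplet.

    Computed independently of the PDE solver from the first integral of the
    equilibrium equation ``h'' + Pi(h) = const``: the droplet of volume V
    coexists with a film slightly above the precursor height, and

        h'(h)**2 = 2 [C (h - h_f) + W(h) - W(h_f)],

    with ``W`` the wetting potential and ``C`` the (negative) rescaled
    Laplace pressure fixed by the volume constraint.  For huge droplets this
    approaches the parabolic-cap value ``sqrt(6V) * sqrt(1 - 4 cut /
    (theta sqrt(6V)))``; at laboratory swarm sizes the attractive wetting
    tail widens the droplet by 10-20%, and this quadrature is the correct
    like-for-like normalization for the shape parameter.
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq

    if volume <= 0:
        raise ValueError("volume must be > 0")
    th, hs = contact_angle, precursor

    def W(h):
        return th**2 * (-hs / h + hs**2 / (2 * h**2))

    def Pi(h):
        r = hs / h
        return (th**2 / hs) * (r**3 - r**2)

    def cap(C):
        h_f = brentq(lambda h: Pi(h) - C, hs * (1 + 1e-9),
                     1.5 * hs * (1 - 1e-9))

        def F(h):
            return 2 * (C * (h - h_f) + W(h) - W(h_f))

        h_up = 10.0 + th**2 / abs(C)  # F is negative again well beyond h0
        h_m = brentq(lambda h: Pi(h) - C, 1.5 * hs, h_up)
        if F(h_m) <= 0:
            return h_f, np.nan, 0.0, F
        h0 = brentq(F, h_m, h_up)
        vol = 2 * quad(lambda h: (h - h_f) / np.sqrt(max(F(h), 1e-300)),
                       h_f * (1 + 1e-6), h0, limit=200,
                       points=[1.5 * hs, 3 * hs])[0]
        return h_f, h0, vol, F

    Pi_min = (th**2 / hs) * ((2 / 3)**3 - (2 / 3)**2)
    C = brentq(lambda c: cap(c)[2] - volume, 0.95 * Pi_min, -1e-6, xtol=1e-10)
    _, h0, _, F = cap(C)
    if not np.isfinite(h0) or cut >= h0:
        return np.nan
    return 2 * quad(lambda h: 1.0 / np.sqrt(max(F(h), 1e-300)), cut, h0,
                    limit=200)[0]


def compute_metrics(output: SimulationOutput, *,
                    threshold: float = DEFAULT_BOUNDARY_THRESHOLD,
                    cell_width: float = DEFAULT_CELL_WIDTH,
                    sensing_threshold: float | None = None,
                    shape_cut: float = 0.1) -> pd.DataFrame:
    """One SwarmMetricsRecord row per output time of a simulation.

    Boundary velocities and the elongation rate d(L)/dt use second-order
    differences in time; the phase column is filled by ``classify_phase``.
    """
    grid = output.grid
    p = output.params
    s_thr = p.sensing if sensing_threshold is None else sensing_threshold
    rows = []
    for st in output.states:
        try:
            rear, front = swarm_boundary(st.h, grid, threshold)
        except NoSwarmError:
            rows.append(SwarmMetricsRecord(st.t, np.nan, np.nan, np.nan, np.nan))
            continue
        lo, hi = _leading_region(st.h, threshold)
        vol = float(np.trapezoid(np.clip(st.h[lo:hi + 1] - p.precursor, 0, None),
                                 grid.x[lo:hi + 1]))
        rec = SwarmMetricsRecord(st.t, front, rear, front - rear, vol)
        peak_x = float(grid.x[lo + int(np.argmax(st.h[lo:hi + 1]))])
        rec.__dict__.update(bacteria_gradient_stats(
            st.b, grid, rear, front, cell_width=cell_width, peak_x=peak_x))
        rec.m_ch = m_ch(st.h, st.c, grid, rear, front, s_thr,
                        precursor=p.precursor)
        L_cut, V_dr = _droplet_extent(st.h, grid, p.precursor, cut=shape_cut)
        if np.isfinite(L_cut) and V_dr > 0:
            cap_len = _cached_cap_length(round(V_dr, 4), shape_cut,
                                         p.precursor, p.contact_angle)
            rec.S = shape_parameter(L_cut, V_dr, cap_len)
        rows.append(rec)
    df = pd.DataFrame([r.__dict__ for r in rows])
    ok = df["front_x"].notna()
    if ok.sum() >= 2:
        t = df.loc[ok, "t"].to_numpy()
        df.loc[ok, "front_v"] = boundary_velocity(t, df.loc[ok, "front_x"].to_numpy())
        df.loc[ok, "rear_v"] = boundary_velocity(t, df.loc[ok, "rear_x"].to_numpy())
        df.loc[ok, "elongation_rate"] = boundary_velocity(t, df.loc[ok, "length"].to_numpy())
    df["phase"] = classify_phase(df)
    return df


from functools import lru_cache


@lru_cache(maxsize=4096)
def _cached_cap_length(volume: float, cut: float, precursor: float,
                       contact_angle: float) -> float:
    return passive_cap_length(volume, cut=cut, precursor=precursor,
                              contact_angle=contact_angle)


def _droplet_extent(h: np.ndarray, grid: Grid1D, precursor: float,
                    cut: float = 0.1) -> tuple[float, float]:
    """Length at the cut height and full excess volume of the leading droplet.

    The droplet is the connected region above ``1.25 * precursor`` containing
    the global peak (its extent down to the film, so the volume is the full
    droplet volume); the length is measured between the interpolated
    crossings of ``cut`` so it can be compared like for like with
    ``passive_cap_length``.
    """
    lo, hi = _leading_region(h, 1.25 * precursor)
    x = grid.x
    seg = h[lo:hi + 1]
    vol = float(np.trapezoid(np.clip(seg - precursor, 0, None), x[lo:hi + 1]))
    above = np.flatnonzero(seg > cut)
    if above.size == 0:
        return np.nan, vol
    a, b = lo + above[0], lo + above[-1]
    if a > 0 and h[a - 1] < cut:
        f = (h[a - 1] - cut) / (h[a - 1] - h[a])
        x_lo = x[a - 1] + f * grid.dx
    else:
        x_lo = x[a]
    if b < h.size - 1 and h[b + 1] < cut:
        f = (h[b] - cut) / (h[b] - h[b + 1])
        x_hi = x[b] + f * grid.dx
    else:
        x_hi = x[b]
    return float(x_hi - x_lo), vol


def classify_phase(df: pd.DataFrame, *, baseline_factor: float = 2.0,
                   m_ch_crit: float = 0.3) -> pd.Series:
    """Label each record ``traveling`` or ``shedding``.

    A record is in the shedding phase iff the rear of the swarm has lost
    positional information and the elongation rate exceeds
    ``baseline_factor`` times the run's travelling baseline (the lower
    quartile of the positive elongation rates); otherwise traveling.

    The positional-information condition is a negative bacteria gradient
    inside the swarm (``neg_grad_pos > 0``), as seen in imaging-style
    kymographs where the swarm piles bacteria up at its front.  The model
    consumes bacteria without pushing them, so its bacteria profiles are
    monotone and never show a gradient reversal; when no record in the run
    has a negative gradient the condition falls back to the model's own
    blind-mass diagnostic, ``m_ch > m_ch_crit``.
    """
    el = df["elongation_rate"].to_numpy(dtype=float)
    pos = el[np.isfinite(el) & (el > 0)]
    baseline = np.quantile(pos, 0.25) if pos.size else np.inf
    neg = df["neg_grad_pos"].to_numpy(dtype=float)
    if np.isfinite(neg).any():
        blind = neg > 0
    else:
        blind = df["m_ch"].to_numpy(dtype=float) > m_ch_crit
    shed = blind & (el > baseline_factor * baseline)
    return pd.Series(np.where(shed, "shedding", "traveling"), index=df.index)


def detect_shedding_events(df: pd.DataFrame, output: SimulationOutput, *,
                           collapse_fraction: float = 0.25,
                           lookback: int = 6,
                           threshold: float = DEFAULT_BOUNDARY_THRESHOLD) -> list[SheddingEvent]:
    """Shedding events: length collapse co-located in time with a pinch.

    An event is recorded when the leading-swarm length drops by more than
    ``collapse_fraction`` below its maximum over the preceding ``lookback``
    output intervals (pinch-off completes over one to two hours, so the
    collapse may straddle a few intervals) and the solver reported a
    pinch-off detection in that window.  The clump volume integrates
    ``h - precursor`` over the connected above-threshold region immediately
    behind the new rear at the event time.
    """
    grid = output.grid
    hs = output.params.precursor
    L = df["length"].to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    ev_times = np.array([e[0] for e in output.events])
    ev_pos = np.array([e[1] for e in output.events])
    events: list[SheddingEvent] = []
    last_k = -10 * lookback
    for k in range(1, L.size):
        j0 = max(k - lookback, 0)
        recent = L[j0:k]
        if not (np.isfinite(recent).any() and np.isfinite(L[k])):
            continue
        if k - last_k <= lookback:
            continue  # debounce: one event per collapse
        ref = np.nanmax(recent)
        if L[k] > (1.0 - collapse_fraction) * ref:
            continue
        sel = (ev_times > t[j0]) & (ev_times <= t[k] + 0.5 * (t[k] - t[k - 1]))
        if not sel.any():
            continue
        pinch_x = float(ev_pos[sel][-1])
        st = output.states[k]
        vol, center = _clump_region(st, grid, pinch_x, hs, threshold)
        events.append(SheddingEvent(float(t[k]),
                                    center if np.isfinite(center) else pinch_x,
                                    vol))
        last_k = k
    for prev, cur in zip(events, events[1:]):
        cur.spacing_to_previous = cur.position - prev.position
        cur.period_to_previous = cur.t_event - prev.t_event
    return events


def _clump_region(state: SwarmState, grid: Grid1D, pinch_x: float,
                  precursor: float, threshold: float) -> tuple[float, float]:
    """Volume and center of the above-threshold hump behind a pinch position."""
    h, x = state.h, grid.x
    behind = np.flatnonzero((x < pinch_x) & (h > threshold))
    if behind.size == 0:
        return 0.0, np.nan
    hi = behind[-1]
    lo = hi
    while lo > 0 and h[lo - 1] > threshold:
        lo -= 1
    vol = float(np.trapezoid(np.clip(h[lo:hi + 1] - precursor, 0, None),
                             x[lo:hi + 1]))
    center = float(x[lo + int(np.argmax(h[lo:hi + 1]))])
    return vol, center


def phase_diagram(ca_kappa_values, ca_xi_values, base_params: DimensionlessParams,
                  grid: Grid1D, *, friction_factors=None, t_max: float = 40.0,
                  droplet_volume: float = 1.8, scenario: str = "line_track",
                  morphology_cut: float = 2.0,
                  output_interval: float = 0.5) -> pd.DataFrame:
    """Morphology and front-speed maps over (Ca_kappa, Ca_xi [, friction]).

    For each grid point the line-track scenario is run to the first
    pinch-off (or ``t_max``); the row records the shape parameter S just
    before that first pinch, the mean front speed, and the morphology
    label: ``clump`` if S at shedding is below ``morphology_cut``,
    ``trail`` otherwise, and ``no-shedding`` on timeout (e.g. everywhere in
    the passive column Ca_xi = 0, where droplets do not migrate).  The
    first pinch rather than the first length collapse defines shedding here
    because extended trails deposit mass continuously and may never show a
    discrete collapse.
    """
    from dataclasses import replace

    from .simulate import make_initial_condition, run

    factors = [1.0] if friction_factors is None else list(friction_factors)
    rows = []
    for fric in factors:
        for ck in np.atleast_1d(ca_kappa_values):
            for cx in np.atleast_1d(ca_xi_values):
                p = with_friction_factor(
                    replace(base_params, Ca_kappa=float(ck), Ca_xi=float(cx)), fric)
                out = run(make_initial_condition(scenario, grid, p,
                                                 droplet_volume=droplet_volume),
                          grid, p, t_max, output_interval=output_interval)
                df = compute_metrics(out)
                events = detect_shedding_events(df, out)
                speed = float(df["front_v"].iloc[2:-2].mean())
                if out.events:
                    t_pinch = out.events[0][0]
                    k = int(np.searchsorted(df["t"].to_numpy(), t_pinch))
                    s_at_shed = float(df["S"].iloc[max(k - 1, 0)])
                    label = "clump" if s_at_shed < morphology_cut else "trail"
                else:
                    s_at_shed, label = np.nan, "no-shedding"
                rows.append({"friction": fric, "Ca_kappa": float(ck),
                             "Ca_xi": float(cx), "S_at_shedding": s_at_shed,
                             "front_speed": speed, "morphology": label,
                             "n_events": len(events),
                             "n_pinches": len(out.events)})
    return pd.DataFrame(rows)
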