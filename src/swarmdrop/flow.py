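"""2D in-swarm flow reconstruction, streamlines, and synthetic cell tracks.

The lubrication solution determines the horizontal velocity at every height:
u(x, z) is the unique parabola in z satisfying the Navier slip condition at
the floor, the stress-free condition at the free surface, and the
depth-average constraint mean_z u = Q/h.  The vertical velocity follows from
incompressibility.  In the co-moving frame of a travelling swarm this field
forms a vortex: fast surface flow toward the bacteria, slow (or reversed)
floor flow — the treadmilling circulation.

Synthetic cell tracks are generated by advecting virtual cells in this flow
with an isotropic random-walk motility, and the track-averaging analysis
(15-min windows, velocities relative to the swarm peak, second-order central
differences) is re-implemented on those tracks so the flow predictions can
be tested without imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .grid import Grid1D
from .params import DimensionlessParams
from .state import SwarmState

__all__ = [
    "FlowField2D",
    "CellTrack",
    "reconstruct_flow",
    "comoving_streamlines",
    "generate_tracks",
    "track_velocities",
    "mean_velocity_field",
    "vortex_summary",
    "tracks_to_frame",
]


@dataclass
class FlowField2D:
    """Parabolic-profile velocity field over one height profile.

    The field is stored through its per-column parabola coefficients
    ``u(x, z) = a(x) + b(x) z + cc(x) z**2`` so that velocities can be
    evaluated continuously; ``sample`` renders it on a regular (x, z) grid
    with NaN above the free surface.
    """

    x: np.ndarray
    h: np.ndarray
    ubar: np.ndarray          #: depth-averaged velocity Q/h (lab frame)
    slip: float
    frame: str                #: stationary | comoving
    swarm_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.frame not in ("stationary", "comoving"):
            raise ValueError("frame must be 'stationary' or 'comoving'")
        h = np.asarray(self.h, float)
        ub = np.asarray(self.ubar, float)
        denom = 2 * h * self.slip + 2 * h**2 / 3.0
        cc = np.where(denom > 0, -ub / np.where(denom > 0, denom, 1.0), 0.0)
        b = -2.0 * cc * h
        a = self.slip * b
        self._coef = (a, b, cc)

    def _shift(self) -> float:
        return self.swarm_speed if self.frame == "comoving" else 0.0

    def u(self, xq, zq):
        """Horizontal velocity at (x, z); z measured from the floor."""
        xq = np.asarray(xq, float)
        zq = np.asarray(zq, float)
        a, b, cc = (np.interp(xq, self.x, co) for co in self._coef)
        return a + b * zq + cc * zq**2 - self._shift()

    def w(self, xq, zq, dx: float | None = None):
        """Vertical velocity from incompressibility, w(x, 0) = 0.

        ``w = -d/dx int_0^z u dz'`` evaluated by central differencing of the
        column-integrated parabola.
        """
        xq = np.asarray(xq, float)
        zq = np.asarray(zq, float)
        dx = dx if dx is not None else float(self.x[1] - self.x[0])

        def psi(xv):  # streamfunction of the lab/comoving horizontal flow
            a, b, cc = (np.interp(xv, self.x, co) for co in self._coef)
            return (a - self._shift()) * zq + b * zq**2 / 2 + cc * zq**3 / 3

        return -(psi(xq + dx / 2) - psi(xq - dx / 2)) / dx

    def sample(self, nz: int = 64) -> dict:
        """Render (u, w) on a regular grid; entries above h(x) are NaN."""
        zmax = float(self.h.max())
        z = np.linspace(0.0, zmax, nz)
        X, Z = np.meshgrid(self.x, z, indexing="ij")
        U = self.u(X, Z)
        W = self.w(X, Z)
        mask = Z > self.h[:, None]
        U[mask] = np.nan
        W[mask] = np.nan
        return {"x": self.x, "z": z, "u": U, "w": W}

    def surface_velocity(self) -> np.ndarray:
        a, b, cc = self._coef
        return a + b * self.h + cc * self.h**2 - self._shift()

    def floor_velocity(self) -> np.ndarray:
        return self._coef[0] - self._shift()


@dataclass
class CellTrack:
    """One virtual-cell trajectory sampled at a uniform interval."""

    track_id: int
    times: np.ndarray
    positions: np.ndarray  #: shape (n, 2): columns (x, z)
    alive: np.ndarray      #: in-domain flags

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 1]


def reconstruct_flow(state: SwarmState, flux: np.ndarray, grid: Grid1D,
                     params: DimensionlessParams, frame: str = "stationary",
                     swarm_speed: float = 0.0) -> FlowField2D:
    """Build the 2D velocity field from a height profile and its cell flux.

    ``flux`` is the depth-integrated flux at the nodes (for a travelling
    wave, ``U * (h - precursor)``).  Columns at the precursor film carry no
    flow.  At ``slip = 0`` the profile is Poiseuille-like: zero at the floor
    and maximal (3/2 of the depth average) at the free surface.
    """
    h = np.asarray(state.h, float)
    q = np.asarray(flux, float)
    active = h > params.precursor * 1.5
    ubar = np.where(active, q / np.where(active, h, 1.0), 0.0)
    return FlowField2D(grid.x, h, ubar, params.slip, frame, swarm_speed)


@dataclass
class StreamlineSet:
    """Closed-orbit summary of a co-moving flow field."""

    streamlines: list[np.ndarray]        #: (n, 2) polylines
    periods: list[float]                 #: return times of closed orbits
    stagnation_points: list[tuple[float, float]]
    outer_period: float = np.nan         #: period of the outermost closed orbit


def comoving_streamlines(flow: FlowField2D, *, n_seeds: int = 12,
                         t_max: float = 40.0, tol: float = 1e-8,
                         close_frac: float = 0.08) -> StreamlineSet:
    """Integrate streamlines of a steady co-moving flow and find the vortex.

    Seeds are placed between the vortex core (interior stagnation point) and
    the droplet boundary.  An orbit is closed when it re-crosses the vertical
    Poincare section through the core, on the starting side, within a small
    fraction of the seed radius; the circulation period is the return time.
    ``outer_period`` reports the outermost closed orbit (the cell-circulation
    time along the swarm boundary).  Raises no error when only open
    streamlines exist: returns an empty set (no-vortex report).
    """
    if flow.frame != "comoving":
        raise ValueError("streamlines require a co-moving frame flow")
    core = _find_stagnation(flow)
    out = StreamlineSet([], [], [])
    if core is None:
        return out
    out.stagnation_points.append(core)
    xc, zc = core
    hc = float(np.interp(xc, flow.x, flow.h))

    def rhs(t, yv):
        return [float(flow.u(yv[0], yv[1])), float(flow.w(yv[0], yv[1]))]

    def crossing(t, yv):
        return yv[0] - xc
    crossing.direction = 1.0

    for frac in np.linspace(0.15, 0.98, n_seeds):
        z0 = zc + frac * (hc - zc) * 0.98
        y0 = [xc, min(z0, hc * 0.995)]
        sol = solve_ivp(rhs, (0.0, t_max), y0, rtol=tol, atol=tol * 1e-2,
                        events=crossing, dense_output=True, max_step=t_max / 200)
        tev = sol.t_events[0]
        tev = tev[tev > 1e-6]
        if tev.size == 0:
            continue
        yev = sol.sol(tev[0])
        if abs(yev[1] - y0[1]) > close_frac * max(abs(z0 - zc), 1e-3):
            continue
        ts = np.linspace(0, tev[0], 200)
        out.streamlines.append(sol.sol(ts).T)
        out.periods.append(float(tev[0]))
    if out.periods:
        out.outer_period = out.periods[-1]
    return out


def _find_stagnation(flow: FlowField2D) -> tuple[float, float] | None:
    """Interior zero of (u, w) located via the mid-depth sign change of u."""
    sel = flow.h > flow.h.max() * 0.35
    if not sel.any():
        return None
    xs = flow.x[sel]
    hs = flow.h[sel]
    best = None
    for x0, h0 in zip(xs, hs):
        zgrid = np.linspace(1e-3 * h0, h0 * 0.999, 96)
        uvals = flow.u(np.full_like(zgrid, x0), zgrid)
        s = np.sign(uvals)
        flips = np.flatnonzero(np.diff(s) != 0)
        if flips.size == 0:
            continue
        k = flips[0]
        # linear interpolation of the zero crossing
        z0 = zgrid[k] - uvals[k] * (zgrid[k + 1] - zgrid[k]) / (uvals[k + 1] - uvals[k])
        wv = abs(float(flow.w(x0, z0)))
        if best is None or wv < best[0]:
            best = (wv, x0, z0)
    if best is None:
        return None
    return best[1], best[2]


def generate_tracks(flow, n_cells: int, motility_sigma: float,
                    dt: float, seed: int, *, t_end: float = 10.0,
                    x_range: tuple[float, float] | None = None,
                    frame_index: int = -1) -> list[CellTrack]:
    """Advect virtual cells in the flow with random-walk motility.

    Cells follow the local (u, w) with independent Gaussian increments of
    standard deviation ``motility_sigma * sqrt(dt)`` per component,
    reflecting at the floor and at the free surface.  Deterministic per seed.
    ``flow`` is a ``FlowField2D``; a ``SimulationOutput`` may be passed
    instead, in which case the flow of the frame ``frame_index`` is
    reconstructed and treated as steady over the track duration.
    """
    if n_cells < 1 or dt <= 0:
        raise ValueError("need n_cells >= 1 and dt > 0")
    if not isinstance(flow, FlowField2D):
        from .simulate import step_flux

        output = flow
        st = output.states[frame_index]
        q_faces = step_flux(st, output.grid, output.params)
        q = np.concatenate([[0.0], 0.5 * (q_faces[:-1] + q_faces[1:]), [0.0]])
        flow = reconstruct_flow(st, q, output.grid, output.params)
    rng = np.random.default_rng(seed)
    if x_range is None:
        sel = flow.h > flow.h.max() * 0.35
        x_range = (float(flow.x[sel][0]), float(flow.x[sel][-1]))
    x0 = rng.uniform(*x_range, n_cells)
    z0 = rng.uniform(0.02, 0.98, n_cells) * np.interp(x0, flow.x, flow.h)
    nt = int(round(t_end / dt)) + 1
    times = np.arange(nt) * dt
    pos = np.empty((nt, n_cells, 2))
    pos[0, :, 0] = x0
    pos[0, :, 1] = z0
    alive = np.ones((nt, n_cells), dtype=bool)
    xlo, xhi = float(flow.x[0]), float(flow.x[-1])
    for k in range(1, nt):
        xk = pos[k - 1, :, 0].copy()
        zk = pos[k - 1, :, 1].copy()
        u = flow.u(xk, zk)
        w = flow.w(xk, zk)
        kick = rng.normal(0.0, motility_sigma * np.sqrt(dt), (2, n_cells))
        xk = xk + u * dt + kick[0]
        zk = zk + w * dt + kick[1]
        hx = np.interp(np.clip(xk, xlo, xhi), flow.x, flow.h)
        zk = np.abs(zk)                      # reflect at the floor
        over = zk > hx
        zk[over] = np.clip(2 * hx[over] - zk[over], 0.0, None)
        inside = (xk > xlo) & (xk < xhi)
        alive[k] = alive[k - 1] & inside
        pos[k, :, 0] = np.clip(xk, xlo, xhi)
        pos[k, :, 1] = zk
    return [CellTrack(i, times, pos[:, i, :], alive[:, i]) for i in range(n_cells)]


def track_velocities(track: CellTrack) -> pd.DataFrame:
    """Second-order finite-difference velocities along one track.

    Central differences at interior samples and one-sided second-order at the
    ends; 2-point tracks get a first-order estimate flagged low-confidence.
    """
    t, p = track.times, track.positions
    if t.size < 2:
        raise ValueError("track needs at least 2 samples")
    low_conf = t.size == 2
    vx = np.gradient(p[:, 0], t, edge_order=1 if low_conf else 2)
    vz = np.gradient(p[:, 1], t, edge_order=1 if low_conf else 2)
    return pd.DataFrame({"t": t, "vx": vx, "vz": vz,
                         "low_confidence": np.full(t.size, low_conf)})


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    """Long-format track table with TrackMate-style columns."""
    rows = []
    for tr in tracks:
        for k in range(tr.times.size):
            rows.append((tr.track_id, k, tr.positions[k, 0], tr.positions[k, 1],
                         tr.times[k], bool(tr.alive[k])))
    return pd.DataFrame(rows, columns=["TRACK_ID", "FRAME", "POSITION_X",
                                       "POSITION_Z", "POSITION_T", "ALIVE"])


def mean_velocity_field(tracks: list[CellTrack], peak_x, *,
                        window: float = 0.25, t_center: float | None = None,
                        x_bins: np.ndarray | None = None,
                        z_bins: np.ndarray | None = None,
                        min_samples: int = 5,
                        h_profile=None) -> dict:
    """Track-averaged velocity field relative to the swarm peak.

    Velocities of every cell are referenced to the swarm-peak position and
    averaged over a time window (default 0.25 time units = 15 min with the
    hour scale) in (x - x_peak, z) bins.  Bins with fewer than
    ``min_samples`` velocity samples are masked (NaN), not zeroed.

    Returns a dict with the binned mean field and horizontal-velocity
    profiles grouped by height above the floor and, when an ``h_profile``
    callable is given, by depth below the free surface.
    """
    peak_fn = peak_x if callable(peak_x) else (lambda t: float(peak_x))
    frames = []
    for tr in tracks:
        v = track_velocities(tr)
        sel = tr.alive.copy()
        if t_center is not None:
            sel &= np.abs(tr.times - t_center) <= window / 2
        if not sel.any():
            continue
        xs = tr.x[sel] - np.array([peak_fn(t) for t in tr.times[sel]])
        frames.append(pd.DataFrame({"x_rel": xs, "z": tr.z[sel],
                                    "vx": v["vx"].to_numpy()[sel],
                                    "vz": v["vz"].to_numpy()[sel]}))
    if not frames:
        raise ValueError("no samples in the averaging window")
    df = pd.concat(frames, ignore_index=True)
    if x_bins is None:
        x_bins = np.linspace(df["x_rel"].min(), df["x_rel"].max(), 25)
    if z_bins is None:
        z_bins = np.linspace(0.0, df["z"].max() * 1.001, 9)
    ix = np.digitize(df["x_rel"], x_bins) - 1
    iz = np.digitize(df["z"], z_bins) - 1
    nx, nz = x_bins.size - 1, z_bins.size - 1
    u_mean = np.full((nx, nz), np.nan)
    n_samples = np.zeros((nx, nz), dtype=int)
    w_mean = np.full((nx, nz), np.nan)
    for i in range(nx):
        for j in range(nz):
            m = (ix == i) & (iz == j)
            n_samples[i, j] = int(m.sum())
            if n_samples[i, j] >= min_samples:
                u_mean[i, j] = float(df.loc[m, "vx"].mean())
                w_mean[i, j] = float(df.loc[m, "vz"].mean())
    out = {"x_edges": x_bins, "z_edges": z_bins, "u_mean": u_mean,
           "w_mean": w_mean, "n_samples": n_samples, "samples": df}
    # profiles by height above floor
    out["profiles_by_height"] = _group_profiles(df, "z", z_bins, x_bins, min_samples)
    if h_profile is not None:
        depth = np.asarray([h_profile(xr) for xr in df["x_rel"]]) - df["z"].to_numpy()
        df = df.assign(depth=np.clip(depth, 0.0, None))
        d_bins = np.linspace(0.0, float(df["depth"].max()) * 1.001, z_bins.size)
        out["profiles_by_depth"] = _group_profiles(df, "depth", d_bins, x_bins,
                                                   min_samples)
    return out


def _group_profiles(df: pd.DataFrame, key: str, bins: np.ndarray,
                    x_bins: np.ndarray, min_samples: int) -> pd.DataFrame:
    ib = np.digitize(df[key], bins) - 1
    ix = np.digitize(df["x_rel"], x_bins) - 1
    rows = []
    xc = 0.5 * (x_bins[:-1] + x_bins[1:])
    for j in range(bins.size - 1):
        for i in range(x_bins.size - 1):
            m = (ib == j) & (ix == i)
            if m.sum() >= min_samples:
                rows.append({key: 0.5 * (bins[j] + bins[j + 1]), "x_rel": xc[i],
                             "u_mean": float(df.loc[m, "vx"].mean()),
                             "n": int(m.sum())})
    return pd.DataFrame(rows)


def vortex_summary(flow: FlowField2D, *, n_points: int = 101,
                   with_period: bool = True) -> dict:
    """Surface / floor / half-height velocity curves and circulation period.

    Curves are reported against the distance to the swarm peak; the range
    curve is the pointwise surface-floor difference (nonnegative whenever the
    surface leads, as in the treadmilling vortex).  The circulation period is
    taken from the outermost closed co-moving streamline when ``flow`` is
    co-moving and steady.
    """
    ipk = int(np.argmax(flow.h))
    xpk = float(flow.x[ipk])
    sel = flow.h > max(0.05 * flow.h.max(), 1e-6)
    xs = np.linspace(flow.x[sel][0], flow.x[sel][-1], n_points)
    hx = np.interp(xs, flow.x, flow.h)
    surface = flow.u(xs, hx)
    floor = flow.u(xs, np.zeros_like(xs))
    half = flow.u(xs, hx / 2)
    out = {"x_rel": xs - xpk, "surface": surface, "floor": floor, "half": half,
           "range": surface - floor}
    if with_period and flow.frame == "comoving":
        out["circulation_period"] = comoving_streamlines(flow).outer_period
    return out
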