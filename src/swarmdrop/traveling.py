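"""Quasi-steady travelling-wave (TW) droplet solutions and their folds.

A swarm of quasi-constant volume V translating at speed U satisfies, in the
co-moving coordinate zeta = x - U t, the first integral of the height
equation

    Q(h, c) - U (h - h_star) = 0,

together with the quasi-steady chemoattractant balance in the moving frame

    (1/Pe) c'' + U c' - decay c + production b = 0,
    b(zeta) = exp(-(consumption/U) * int_zeta^inf (h - h_star)_+ ),

(the bacteria profile is slaved to the height profile: the lawn ahead is
intact and is progressively consumed under the droplet).  The system is
closed by the volume constraint and far-field matching to the precursor
film.  Solutions are found by damped Newton iteration with a translation
"freezing" term, and continued in V by pseudo-arclength so fold (saddle-node)
bifurcations are traversed rather than stopped at.  The two folds delimit
the bistable window between the compact fast branch and the elongated slow
branch; the critical volume V_cr is the fold beyond which only the
elongated solution exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import solve_banded

from .constitutive import disjoining_pressure, mobility
from .grid import Grid1D
from .params import DimensionlessParams

__all__ = [
    "TWSolution",
    "BifurcationBranch",
    "solve_tw",
    "continue_branch",
    "find_folds",
    "classify_tw",
    "tw_flux_field",
]


class TWConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class TWSolution:
    """A travelling-wave droplet profile in the co-moving frame."""

    zeta: np.ndarray          #: co-moving coordinate
    profile: np.ndarray       #: height h(zeta)
    chemo: np.ndarray         #: chemoattractant c(zeta)
    bacteria: np.ndarray      #: bacteria b(zeta)
    speed: float              #: wave speed U
    volume: float             #: int (h - precursor) dzeta
    length: float             #: extent at the boundary threshold
    residual_norm: float
    params: DimensionlessParams
    branch_label: str = ""    #: compact_fast | elongated_slow

    @property
    def grid(self) -> Grid1D:
        return Grid1D(self.zeta)


@dataclass
class BifurcationBranch:
    """TW solutions ordered along the continuation arclength."""

    solutions: list[TWSolution]
    arclength: np.ndarray
    folds: list[float] = field(default_factory=list)  #: V at turning points
    V_cr: float = np.nan
    complete: bool = True  #: False when continuation broke down mid-branch

    @property
    def volumes(self) -> np.ndarray:
        return np.array([s.volume for s in self.solutions])

    @property
    def speeds(self) -> np.ndarray:
        return np.array([s.speed for s in self.solutions])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.solutions])


def _bacteria_profile(h: np.ndarray, U: float, dz: float,
                      params: DimensionlessParams, lawn: float) -> np.ndarray:
    """Slaved bacteria profile: lawn ahead, exponentially consumed under the
    droplet (integrating the consumption ODE from the far field backwards)."""
    psi = np.clip(h - params.precursor, 0.0, None)
    tail = cumulative_trapezoid(psi[::-1], dx=dz, initial=0.0)[::-1]
    return lawn * np.exp(-(params.consumption / max(U, 1e-10)) * tail)


def _solve_chemo_comoving(h: np.ndarray, U: float, dz: float,
                          params: DimensionlessParams,
                          lawn: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-steady chemoattractant in the co-moving frame (c, b).

    This function isolates the closure for the chemical environment seen by
    the TW droplet; swapping in a different closure only requires replacing
    this routine.
    """
    b = _bacteria_profile(h, U, dz, params, lawn)
    n = h.size
    D = 1.0 / params.peclet
    lower = np.full(n - 1, D / dz**2 - U / (2 * dz))
    upper = np.full(n - 1, D / dz**2 + U / (2 * dz))
    diag = np.full(n, -2 * D / dz**2 - params.decay)
    rhs = -params.production * b
    # zero-gradient far fields
    diag[0] = -2 * D / dz**2 - params.decay
    upper[0] = 2 * D / dz**2
    diag[-1] = -2 * D / dz**2 - params.decay
    lower[-1] = 2 * D / dz**2
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    c = solve_banded((1, 1), ab, rhs)
    return c, b


def _tw_residual(h: np.ndarray, U: float, lam: float, V: float,
                 dz: float, params: DimensionlessParams, lawn: float,
                 zeta: np.ndarray, center: float) -> np.ndarray:
    """Residual vector: face flux balances, edge pinning, volume, phase."""
    n = h.size
    hs = params.precursor
    c, _ = _solve_chemo_comoving(h, U, dz, params, lawn)
    # pressure and active stress at nodes
    lap = np.empty(n)
    lap[1:-1] = (h[2:] - 2 * h[1:-1] + h[:-2]) / dz**2
    lap[0] = 2 * (h[1] - h[0]) / dz**2
    lap[-1] = 2 * (h[-2] - h[-1]) / dz**2
    p = -(lap + disjoining_pressure(h, hs, params.contact_angle)) / params.Ca_kappa
    gc = np.gradient(c, dz, edge_order=2)
    f = gc / (params.saturation + np.abs(gc))
    sig = params.Ca_xi * f
    hbar = np.clip(0.5 * (h[:-1] + h[1:]), 0.0, None)
    m_p, _ = mobility(hbar, params.slip)
    _, m_a = mobility(np.clip(hbar - hs, 0.0, None), params.slip)
    Q = m_p * (p[:-1] - p[1:]) / dz + m_a * (sig[1:] - sig[:-1]) / dz
    # freezing term lam * h_zeta absorbs the translation null direction
    hz_face = (h[1:] - h[:-1]) / dz
    res_face = Q - (U + 0.0) * (hbar - hs) + lam * hz_face
    excess = np.clip(h - hs, 0.0, None)
    vol = np.trapezoid(excess, dx=dz)
    res_edge0 = h[0] - hs
    res_vol = vol - V
    centroid = np.trapezoid(excess * zeta, dx=dz) / max(vol, 1e-12)
    res_phase = centroid - center
    return np.concatenate([res_face, [res_edge0, res_vol, res_phase]])


def _initial_guess(V: float, zeta: np.ndarray, params: DimensionlessParams,
                   center: float) -> np.ndarray:
    hs = params.precursor
    ell = np.sqrt(6.0 * V / params.contact_angle)
    u = 2.0 * (zeta - center) / ell
    return hs + np.where(np.abs(u) < 1, params.contact_angle * (ell / 4) * (1 - u**2), 0.0)


def solve_tw(V: float, params: DimensionlessParams, *,
             guess: np.ndarray | None = None, U_guess: float = 1.0,
             zeta: np.ndarray | None = None, lawn: float = 1.0,
             newton_tol: float = 1e-10, max_iter: int = 50,
             threshold: float = 0.3) -> TWSolution:
    """Solve the co-moving travelling-wave problem at fixed volume.

    Newton iteration on (h, U, lambda) with the chemoattractant eliminated
    by a direct solve; ``lambda`` is a translation-freezing multiplier that
    vanishes at the solution.  In the passive limit (Ca_xi = 0) the solution
    is the stationary parabolic cap with U = 0.

    Raises
    ------
    TWConvergenceError
        If Newton does not reach ``newton_tol`` in ``max_iter`` iterations;
        the error carries the last residual norm, and the caller may re-seed
        from a nearby continuation point.
    """
    if V <= 0:
        raise ValueError("V must be > 0")
    if zeta is None:
        span = max(10.0 * np.sqrt(V), 25.0)
        n = max(int(span / 0.08), 257)
        zeta = np.linspace(0.0, span, n)
    dz = float(zeta[1] - zeta[0])
    center = float(zeta[0] + 0.4 * (zeta[-1] - zeta[0]))
    h = guess.copy() if guess is not None else _initial_guess(V, zeta, params, center)
    x = np.concatenate([h, [U_guess, 0.0]])
    n = zeta.size

    def res(xv: np.ndarray) -> np.ndarray:
        return _tw_residual(xv[:n], xv[n], xv[n + 1], V, dz, params, lawn,
                            zeta, center)

    x, rnorm = _newton(res, x, newton_tol, max_iter)
    if rnorm >= newton_tol:
        if guess is None and V > 1.2:
            # re-seed from a smaller droplet and walk the volume up
            sub = solve_tw(V / 1.5, params, U_guess=U_guess, zeta=zeta,
                           lawn=lawn, newton_tol=newton_tol,
                           max_iter=max_iter, threshold=threshold)
            h_seed, U_seed = sub.profile, sub.speed
            for Vk in np.linspace(V / 1.5, V, 4)[1:]:
                excess = np.clip(h_seed - params.precursor, 0.0, None)
                x = np.concatenate([
                    params.precursor
                    + excess * (Vk / np.trapezoid(excess, dx=dz)),
                    [U_seed, 0.0]])

                def res_k(xv, _V=Vk):
                    return _tw_residual(xv[:n], xv[n], xv[n + 1], _V, dz,
                                        params, lawn, zeta, center)

                x, rnorm = _newton(res_k, x, newton_tol, max_iter)
                if rnorm >= newton_tol:
                    raise TWConvergenceError(
                        f"Newton stalled at residual {rnorm:.2e} (V={Vk:.3f})",
                        rnorm)
                h_seed, U_seed = x[:n], float(x[n])
        else:
            raise TWConvergenceError(
                f"Newton stalled at residual {rnorm:.2e}", rnorm)
    h, U = x[:n], float(x[n])
    c, b = _solve_chemo_comoving(h, U, dz, params, lawn)
    length = _threshold_length(h, zeta, threshold)
    vol = float(np.trapezoid(np.clip(h - params.precursor, 0, None), dx=dz))
    return TWSolution(zeta, h, c, b, U, vol, length, rnorm, params)


def _newton(res, x: np.ndarray, tol: float, max_iter: int,
            jac_refresh: int = 3) -> tuple[np.ndarray, float]:
    """Damped Newton with periodic Jacobian refresh (chord iterations).

    Rejecting steps that do not reduce the residual; the Jacobian is
    recomputed every ``jac_refresh`` accepted steps or after a rejection.
    Returns the best iterate and its residual norm.
    """
    r = res(x)
    rnorm = float(np.abs(r).max())
    lu = None
    since_jac = jac_refresh  # force factorization on entry
    from scipy.linalg import lu_factor, lu_solve

    for _ in range(max_iter):
        if rnorm < tol:
            return x, rnorm
        if lu is None or since_jac >= jac_refresh:
            J = _fd_jacobian(res, x, r)
            try:
                lu = lu_factor(J)
            except (ValueError, np.linalg.LinAlgError):
                return x, rnorm
            since_jac = 0
        dx = lu_solve(lu, -r)
        step, accepted = 1.0, False
        for _ in range(10):
            xn = x + step * dx
            rn = res(xn)
            rn_norm = float(np.abs(rn).max())
            if rn_norm < rnorm or rn_norm < tol:
                x, r, rnorm = xn, rn, rn_norm
                accepted = True
                break
            step *= 0.5
        if not accepted:
            if since_jac == 0:
                return x, rnorm  # fresh Jacobian and still stuck
            since_jac = jac_refresh  # retry with a fresh Jacobian
        else:
            since_jac += 1
    return x, rnorm


def _fd_jacobian(fun, x: np.ndarray, f0: np.ndarray) -> np.ndarray:
    eps = 1e-7
    J = np.empty((f0.size, x.size))
    for j in range(x.size):
        step = eps * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += step
        J[:, j] = (fun(xp) - f0) / step
    return J


def _threshold_length(h: np.ndarray, zeta: np.ndarray, threshold: float) -> float:
    above = np.flatnonzero(h > threshold)
    if above.size == 0:
        return 0.0
    return float(zeta[above[-1]] - zeta[above[0]])


def continue_branch(V_start: float, V_end: float, params: DimensionlessParams,
                    n_steps: int = 80, *, zeta: np.ndarray | None = None,
                    lawn: float = 1.0, U_guess: float = 1.0,
                    threshold: float = 0.3) -> BifurcationBranch:
    """Pseudo-arclength continuation of the TW branch in volume.

    V is appended to the Newton unknowns and steps are taken along the branch
    tangent, so turning points (folds) are traversed.  Step length adapts to
    Newton performance within [1e-4, 0.1] of the V range.  On mid-branch
    breakdown the partial branch is returned with ``complete=False``.
    """
    first = solve_tw(V_start, params, zeta=zeta, lawn=lawn, U_guess=U_guess,
                     threshold=threshold)
    zeta = first.zeta
    dz = float(zeta[1] - zeta[0])
    n = zeta.size
    center = float(zeta[0] + 0.4 * (zeta[-1] - zeta[0]))
    vrange = abs(V_end - V_start)
    # arclength steps within [1e-4, 0.1] of the volume range, but never so
    # large that a fold region can be stepped over
    ds_min, ds_max = 1e-4 * vrange, min(0.1 * vrange, 0.4)
    sols = [first]
    arcl = [0.0]

    def res_ext(xv: np.ndarray, x_pred: np.ndarray, tangent: np.ndarray) -> np.ndarray:
        r = _tw_residual(xv[:n], xv[n], xv[n + 1], xv[n + 2], dz, params,
                         lawn, zeta, center)
        return np.concatenate([r, [tangent @ (xv - x_pred)]])

    x = np.concatenate([first.profile, [first.speed, 0.0, first.volume]])
    direction = np.sign(V_end - V_start)
    tangent = np.zeros(n + 3)
    tangent[-1] = direction
    ds = 0.02 * vrange
    complete = True
    for _ in range(n_steps):
        x_pred = x + ds * tangent
        xk, rnorm = _newton(lambda xv: res_ext(xv, x_pred, tangent),
                            x_pred.copy(), 1e-10, 25)
        ok = rnorm < 1e-10
        if not ok:
            ds *= 0.4
            if ds < ds_min:
                complete = False
                break
            continue
        new_t = xk - x
        nt = np.linalg.norm(new_t)
        if nt > 0:
            tangent = new_t / nt
        x = xk
        h, U, V = x[:n], float(x[n]), float(x[n + 2])
        c, b = _solve_chemo_comoving(h, U, dz, params, lawn)
        vol = float(np.trapezoid(np.clip(h - params.precursor, 0, None), dx=dz))
        sols.append(TWSolution(zeta, h, c, b, U, vol,
                               _threshold_length(h, zeta, threshold),
                               float(np.abs(res_ext(x, x, np.zeros(n + 3))[:-1]).max()),
                               params))
        arcl.append(arcl[-1] + ds)
        ds = min(ds * 1.3, ds_max)
        vols = np.array([s.volume for s in sols])
        if len(sols) > 4:
            flips = np.flatnonzero(np.diff(np.sign(np.gradient(
                vols, np.array(arcl)))) != 0)
            # S-curve traversed: both turning points passed and the branch
            # has returned through the bistable window
            if flips.size >= 2 and (vols[-1] - V_start) * direction < 0:
                break
        beyond = (V - V_end) * direction > 0
        if beyond and len(sols) > 3:
            dV = np.diff(vols[-3:])
            if np.all(dV * direction > 0):  # moving monotonically past the end
                break
    branch = BifurcationBranch(sols, np.array(arcl), complete=complete)
    try:
        f, fprime, vcr = find_folds(branch)
        branch.folds = [f, fprime]
        branch.V_cr = vcr
    except ValueError:
        pass
    for s in branch.solutions:
        s.branch_label = classify_tw(s, branch)
    return branch


def find_folds(branch: BifurcationBranch) -> tuple[float, float, float]:
    """Locate the two turning points (f, f') and the critical volume.

    Folds are sign changes of dV/ds along the branch, refined by a local
    quadratic fit of V(s).  V_cr is the larger fold volume of the compact
    branch: beyond it only the elongated slow solution exists.

    Raises ``ValueError`` when fewer than two sign changes exist (no
    bistability, e.g. the passive limit).
    """
    V = branch.volumes
    s = branch.arclength
    if V.size < 5:
        raise ValueError("branch too short for fold detection")
    dV = np.gradient(V, s)
    signs = np.sign(dV)
    flips = np.flatnonzero(np.diff(signs) != 0)
    flips = [k for k in flips if signs[k] != 0]
    if len(flips) < 2:
        raise ValueError("no bistability: fewer than two folds on the branch")
    fold_vols = []
    for k in flips[:2]:
        lo, hi = max(k - 2, 0), min(k + 3, V.size)
        coef = np.polyfit(s[lo:hi], V[lo:hi], 2)
        s_star = -coef[1] / (2 * coef[0])
        s_star = float(np.clip(s_star, s[lo], s[hi - 1]))
        fold_vols.append(float(np.polyval(coef, s_star)))
    f, fprime = fold_vols[0], fold_vols[1]
    return f, fprime, max(f, fprime)


def classify_tw(sol: TWSolution, branch: BifurcationBranch | None = None) -> str:
    """Label a TW solution ``compact_fast`` or ``elongated_slow``.

    With a branch available the label follows the position relative to the
    folds along the arclength (before the first fold: compact; after the
    second: elongated; between: the unstable middle segment, labelled by
    compactness).  Without a branch, or in the passive limit (U ~ 0, labelled
    compact by convention), the normalized length L/sqrt(V) decides.
    """
    if branch is not None and len(branch.folds) == 2:
        idx = next((i for i, s in enumerate(branch.solutions) if s is sol), None)
        if idx is not None:
            s = branch.arclength[idx]
            dV = np.gradient(branch.volumes, branch.arclength)
            flips = np.flatnonzero(np.diff(np.sign(dV)) != 0)
            if len(flips) >= 2:
                s1, s2 = branch.arclength[flips[0]], branch.arclength[flips[1]]
                if s <= s1:
                    return "compact_fast"
                if s >= s2:
                    return "elongated_slow"
    ratio = sol.length / max(np.sqrt(sol.volume), 1e-12)
    return "compact_fast" if ratio < 3.5 else "elongated_slow"


def tw_flux_field(sol: TWSolution) -> np.ndarray:
    """Lab-frame cell flux Q(zeta) of a TW solution: Q = U (h - precursor)."""
    return sol.speed * np.clip(sol.profile - sol.params.precursor, 0.0, None)
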