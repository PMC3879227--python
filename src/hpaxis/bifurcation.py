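"""Equilibria, stability, continuation and bifurcations of the HPA models.

Equilibrium branches are traced with pseudo-arclength continuation in
``(log x, stress)``, which traverses saddle-node folds and enforces the
positivity of concentrations.  Limit points are detected by a sign change
of the stress component of the branch tangent (equivalently of det J along
arclength), confirmed by a near-zero real eigenvalue; Hopf points by a
sign change of the largest real part over complex eigenvalue pairs.  Both
are sharpened by bisection in arclength.

Limit cycles are characterised by long integration plus peak recurrence
rather than collocation: adequate for period, amplitude and phase-order
statements at the qualitative level this model is used for.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelVariant, extended_model
from .params import ExtendedParams

__all__ = [
    "EquilibriumPoint",
    "EquilibriumBranch",
    "SwitchClassification",
    "ConvergenceError",
    "jacobian",
    "rhs_stress_derivative",
    "find_equilibrium",
    "continue_equilibria",
    "classify_switch",
    "limit_cycle",
]

LOG_FLOOR = 1e-12  # nM offset floor for log-space solves


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the best residual seen."""

    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


@dataclass
class EquilibriumPoint:
    stress: float
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool

    @property
    def leading_eigenvalue(self) -> complex:
        return self.eigenvalues[np.argmax(self.eigenvalues.real)]


@dataclass
class SwitchClassification:
    kind: str          # monostable | reversible_bistable | irreversible_bistable | complex
    orientation: str   # hypo | hyper | none
    S1: float | None = None
    S2: float | None = None
    basal_stress: float = 0.1
    limit_points: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

_CS_STEP = 1e-100


def jacobian(
    state,
    params,
    stress,
    model: ModelVariant = extended_model,
    method: str = "complex",
) -> np.ndarray:
    """Jacobian of the model rhs with respect to the state.

    ``method='complex'`` uses complex-step differentiation (exact to
    machine precision); ``'central'`` uses central differences for
    cross-checking.
    """
    x = np.asarray(state, dtype=float)
    n = x.size
    J = np.empty((n, n))
    if method == "complex":
        for j in range(n):
            xc = x.astype(complex)
            xc[j] += 1j * _CS_STEP
            J[:, j] = np.imag(model.rhs(0.0, xc, params, stress)) / _CS_STEP
    elif method == "central":
        for j in range(n):
            h = 1e-6 * max(abs(x[j]), 1e-3)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (
                model.rhs(0.0, xp, params, stress)
                - model.rhs(0.0, xm, params, stress)
            ) / (2 * h)
    else:
        raise ValueError("method must be 'complex' or 'central'")
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite entries in Jacobian")
    return J


def rhs_stress_derivative(state, params, stress, model: ModelVariant = extended_model):
    """Derivative of the rhs with respect to the stress input (complex step)."""
    sc = stress + 1j * _CS_STEP
    return np.imag(model.rhs(0.0, np.asarray(state, dtype=float).astype(complex),
                             params, sc)) / _CS_STEP


def rhs_param_derivative(
    state, params, stress, name: str, model: ModelVariant = extended_model
):
    """Derivative of the rhs with respect to one parameter (complex step)."""
    p2 = copy.copy(params)
    object.__setattr__(p2, name, getattr(params, name) + 1j * _CS_STEP)
    return np.imag(model.rhs(0.0, np.asarray(state, dtype=float).astype(complex),
                             p2, stress)) / _CS_STEP


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------


def _default_guess(params, stress, model: ModelVariant):
    """Approach an attractor by integration from a generic positive state."""
    from .simulate import StressProtocol, integrate

    x0 = np.full(model.n_states, 0.1)
    if model.n_states == 15:
        x0[5] = params.v2 / params.d6
        x0[6] = params.v3 / params.d7
    traj = integrate(
        model, params, x0,
        protocol=StressProtocol(baseline=stress),
        t_grid=np.array([0.0, 3000.0, 6000.0]),
        rtol=1e-8, atol=1e-12,
    )
    return np.clip(traj.states[-1], LOG_FLOOR, None)


def find_equilibrium(
    params,
    stress: float,
    guess=None,
    model: ModelVariant = extended_model,
    tol: float = 1e-10,
    max_iter: int = 80,
) -> EquilibriumPoint:
    """Damped Newton solve of ``rhs = 0`` in log-concentration space.

    Positivity is enforced by solving for ``u = log(x)`` with an offset
    floor of 1e-12 nM; the returned state satisfies ``max|rhs| < tol``.
    """
    if guess is None:
        guess = _default_guess(params, stress, model)
    x = np.clip(np.asarray(guess, dtype=float), LOG_FLOOR, None)
    u = np.log(x)
    f = model.rhs(0.0, x, params, stress)
    best = np.max(np.abs(f))
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tol:
            break
        J = jacobian(x, params, stress, model)
        Jlog = J * x[None, :]  # d f / d log(x)
        try:
            du = np.linalg.solve(Jlog, -f)
        except np.linalg.LinAlgError:
            du = np.linalg.lstsq(Jlog, -f, rcond=None)[0]
        du = np.clip(du, -5.0, 5.0)
        lam, ok = 1.0, False
        fnorm = np.linalg.norm(f)
        for _bt in range(40):
            x_new = np.exp(u + lam * du)
            f_new = model.rhs(0.0, x_new, params, stress)
            if np.linalg.norm(f_new) < (1.0 - 0.25 * lam) * fnorm or np.max(
                np.abs(f_new)
            ) < tol:
                ok = True
                break
            lam *= 0.5
        if not ok:
            raise ConvergenceError(
                f"Newton stalled at residual {best:.3e}", residual=float(best)
            )
        u = u + lam * du
        x = np.exp(u)
        f = f_new
        best = min(best, float(np.max(np.abs(f))))
    else:
        raise ConvergenceError(
            f"Newton did not converge; best residual {best:.3e}", residual=float(best)
        )
    eigs = np.linalg.eigvals(jacobian(x, params, stress, model))
    return EquilibriumPoint(
        stress=float(stress), state=x, eigenvalues=eigs,
        stable=bool(np.max(eigs.real) < 0),
    )


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------


def distinct_attractors(
    params,
    stress: float,
    model: ModelVariant = extended_model,
    n_starts: int = 14,
    seed: int = 0,
) -> list:
    """Distinct stable equilibria at one stress level (multi-start Newton).

    Starts are drawn log-uniformly (seeded) plus the default integration
    attractor; solutions closer than 0.1 dex componentwise are merged.
    Ordered by extracellular cortisol for determinism.
    """
    rng = np.random.default_rng(seed)
    sols = []

    def add(eq):
        key = np.log10(np.clip(eq.state, 0, None) + 1e-6)
        if not any(np.max(np.abs(key - k)) < 0.1 for k, _ in sols):
            sols.append((key, eq))

    try:
        add(find_equilibrium(params, stress, model=model))
    except (ConvergenceError, Exception):
        pass
    for _ in range(n_starts):
        x0 = 10 ** rng.uniform(-2.5, 1.5, model.n_states)
        if model.n_states == 15:
            x0[5] = params.v2 / params.d6
            x0[6] = params.v3 / params.d7
        try:
            add(find_equilibrium(params, stress, guess=x0, max_iter=40,
                                 model=model))
        except (ConvergenceError, Exception):
            continue
    stable = [eq for _, eq in sols if eq.stable]
    return sorted(stable, key=lambda e: e.state[0])


@dataclass
class EquilibriumBranch:
    """Stress-continuation branch with bifurcation bookkeeping.

    ``stress``/``states`` are ordered along arclength; ``limit_points``
    holds ``(S, state)`` pairs and ``hopf_points`` ``(S, state, omega)``.
    """

    stress: np.ndarray
    states: np.ndarray
    eigenvalues: np.ndarray
    stable: np.ndarray
    limit_points: list = field(default_factory=list)
    hopf_points: list = field(default_factory=list)
    complete: bool = True
    model: str = "extended"

    @property
    def arclength(self) -> np.ndarray:
        d = np.sqrt(
            np.sum(np.diff(np.log(np.clip(self.states, LOG_FLOOR, None)), axis=0) ** 2, axis=1)
            + np.diff(self.stress) ** 2
        )
        return np.concatenate(([0.0], np.cumsum(d)))

    @property
    def lp_abscissas(self) -> list:
        return [S for S, _ in self.limit_points]

    def basal_state(self, S_target: float) -> np.ndarray:
        """State on the basal branch segment (before the first fold)
        closest to ``S_target`` in stress."""
        S = self.stress
        downs = np.where(np.diff(S) < -1e-12)[0]
        end = int(downs[0]) + 1 if downs.size else len(S)
        seg = slice(0, max(end, 2))
        i = int(np.argmin(np.abs(S[seg] - S_target)))
        return self.states[seg][i]

    def cor_ex(self) -> np.ndarray:
        return self.states[:, 0]

    def to_dataframe(self, state_names) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(state_names))
        df.insert(0, "stress", self.stress)
        df.insert(0, "arclength", self.arclength)
        df["stable"] = self.stable.astype(int)
        return df


def _tangent(Jlog_aug: np.ndarray, t_prev: np.ndarray) -> np.ndarray:
    """Null vector of the (n x n+1) augmented Jacobian, oriented along t_prev."""
    n = Jlog_aug.shape[0]
    A = np.vstack([Jlog_aug, t_prev[None, :]])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        t = np.linalg.lstsq(A, b, rcond=None)[0]
    nrm = np.linalg.norm(t)
    if nrm == 0 or not np.all(np.isfinite(t)):
        raise ConvergenceError("degenerate tangent")
    t = t / nrm
    if np.dot(t, t_prev) < 0:
        t = -t
    return t


def _corrector(y, params, model, stress_dir, n, tol=1e-11, max_iter=12):
    """Newton solve of [f(exp(u), S); c^T (y - y0)] = 0 with constraint c."""
    # stress_dir: (constraint vector c, reference point y0)
    c, y0 = stress_dir
    y = y.copy()
    for it in range(max_iter):
        u, S = y[:n], y[n]
        if S < -1e-12:
            return None
        S = max(S, 0.0)
        x = np.exp(u)
        f = model.rhs(0.0, x, params, S)
        g = np.dot(c, y - y0)
        if np.max(np.abs(f)) < tol and abs(g) < 1e-12:
            return y
        J = jacobian(x, params, S, model)
        Jlog = J * x[None, :]
        fS = rhs_stress_derivative(x, params, S, model)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = Jlog
        A[:n, n] = fS
        A[n, :] = c
        rhs_vec = np.concatenate((-f, [-g]))
        try:
            dy = np.linalg.solve(A, rhs_vec)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(dy)):
            return None
        step = np.linalg.norm(dy)
        if step > 10.0:
            dy *= 10.0 / step
        y = y + dy
        if step < 1e-13:
            u, S = y[:n], max(y[n], 0.0)
            f = model.rhs(0.0, np.exp(u), params, S)
            if np.max(np.abs(f)) < tol:
                return y
    u, S = y[:n], y[n]
    if S >= 0 and np.max(np.abs(model.rhs(0.0, np.exp(u), params, S))) < tol:
        return y
    return None


def _eig_info(x, params, S, model):
    eigs = np.linalg.eigvals(jacobian(x, params, S, model))
    stable = bool(np.max(eigs.real) < 0)
    cplx = eigs[np.abs(eigs.imag) > 1e-4]
    hopf_test = np.max(cplx.real) if cplx.size else -np.inf
    return eigs, stable, hopf_test


def continue_equilibria(
    params,
    stress_range=(0.0, 1.0),
    model: ModelVariant = extended_model,
    guess=None,
    ds0: float = 0.01,
    ds_max: float = 0.05,
    ds_min: float = 1e-9,
    max_points: int = 4000,
    lp_tol: float = 1e-6,
) -> EquilibriumBranch:
    """Trace the equilibrium branch through ``stress_range`` by
    pseudo-arclength continuation, locating limit points and Hopf points.

    The branch starts from the (stable) equilibrium at the lower end of
    the range and is followed through folds until the stress interval is
    exhausted or ``max_points`` is reached.
    """
    n = model.n_states
    S_lo, S_hi = float(stress_range[0]), float(stress_range[1])
    eq0 = find_equilibrium(params, S_lo, guess=guess, model=model)
    x = np.clip(eq0.state, LOG_FLOOR, None)
    y = np.concatenate((np.log(x), [S_lo]))

    t_prev = np.zeros(n + 1)
    t_prev[n] = 1.0  # initial direction: increasing stress

    S_list, X_list, E_list, st_list = [], [], [], []
    tangS_list = []
    limit_points, hopf_points = [], []
    complete = True

    def record(yv):
        u, S = yv[:n], max(yv[n], 0.0)
        xv = np.exp(u)
        eigs, stable, hopf_t = _eig_info(xv, params, S, model)
        S_list.append(S)
        X_list.append(xv)
        E_list.append(eigs)
        st_list.append(stable)
        return eigs, stable, hopf_t

    # tangent at the first point
    Jlog = jacobian(x, params, S_lo, model) * x[None, :]
    fS = rhs_stress_derivative(x, params, S_lo, model)
    t_cur = _tangent(np.hstack([Jlog, fS[:, None]]), t_prev)
    record(y)
    tangS_list.append(t_cur[n])
    _, _, hopf_prev = _eig_info(x, params, S_lo, model)

    ds = ds0
    while len(S_list) < max_points:
        y_pred = y + ds * t_cur
        c = t_cur
        y_new = _corrector(y_pred, params, model, (c, y_pred), n)
        if y_new is None:
            ds *= 0.5
            if ds < ds_min:
                complete = False
                break
            continue
        # new tangent
        u_new, S_new = y_new[:n], max(y_new[n], 0.0)
        x_new = np.exp(u_new)
        Jlog = jacobian(x_new, params, S_new, model) * x_new[None, :]
        fS = rhs_stress_derivative(x_new, params, S_new, model)
        try:
            t_new = _tangent(np.hstack([Jlog, fS[:, None]]), t_cur)
        except ConvergenceError:
            ds *= 0.5
            if ds < ds_min:
                complete = False
                break
            continue
        eigs, stable, hopf_cur = record(y_new)
        tangS_list.append(t_new[n])

        # --- limit point: tangent stress-component changes sign ----------
        if tangS_list[-2] * tangS_list[-1] < 0:
            lp = _bisect_fold(y, y_new, t_cur, t_new, params, model, n, lp_tol)
            if lp is not None:
                limit_points.append(lp)
        # --- Hopf: leading complex-pair real part changes sign ------------
        if np.isfinite(hopf_prev) and np.isfinite(hopf_cur) and hopf_prev * hopf_cur < 0:
            hp = _bisect_hopf(y, y_new, params, model, n, lp_tol)
            if hp is not None:
                hopf_points.append(hp)
        hopf_prev = hopf_cur

        y, t_cur = y_new, t_new
        # step-size control
        ds = min(ds * 1.4, ds_max)
        S = y[n]
        if S > S_hi + 1e-9 or (len(S_list) > 2 and S < S_lo - 1e-9):
            break

    return EquilibriumBranch(
        stress=np.array(S_list),
        states=np.array(X_list),
        eigenvalues=np.array(E_list),
        stable=np.array(st_list, dtype=bool),
        limit_points=limit_points,
        hopf_points=hopf_points,
        complete=complete,
        model=model.name,
    )


def _bisect_fold(y_a, y_b, t_a, t_b, params, model, n, tol):
    """Sharpen a bracketed fold by bisection on the tangent stress component."""
    g_a, g_b = t_a[n], t_b[n]
    d = y_b - y_a
    dn = np.linalg.norm(d)
    if dn == 0:
        return None
    c = d / dn
    lo, hi = 0.0, 1.0
    y_lo, y_hi = y_a.copy(), y_b.copy()
    t_ref = t_a
    for _ in range(60):
        if abs(y_hi[n] - y_lo[n]) < tol and abs(hi - lo) * dn < 1e-8:
            break
        mid = 0.5 * (lo + hi)
        y_pred = y_a + mid * d
        y_m = _corrector(y_pred, params, model, (c, y_pred), n)
        if y_m is None:
            return None
        x_m = np.exp(y_m[:n])
        S_m = max(y_m[n], 0.0)
        Jlog = jacobian(x_m, params, S_m, model) * x_m[None, :]
        fS = rhs_stress_derivative(x_m, params, S_m, model)
        try:
            t_m = _tangent(np.hstack([Jlog, fS[:, None]]), t_ref)
        except ConvergenceError:
            return None
        g_m = t_m[n]
        if g_a * g_m <= 0:
            hi, y_hi, g_b = mid, y_m, g_m
        else:
            lo, y_lo, g_a = mid, y_m, g_m
            t_ref = t_m
    y_lp = 0.5 * (y_lo + y_hi)
    y_ref = _corrector(y_lp, params, model, (c, y_lp), n)
    if y_ref is not None:
        y_lp = y_ref
    S_lp = float(max(y_lp[n], 0.0))
    return (S_lp, np.exp(y_lp[:n]))


def _bisect_hopf(y_a, y_b, params, model, n, tol):
    """Sharpen a bracketed Hopf point by bisection on the complex-pair
    real part; returns (S, state, omega)."""

    def gfun(yv):
        xv = np.exp(yv[:n])
        Sv = max(yv[n], 0.0)
        eigs = np.linalg.eigvals(jacobian(xv, params, Sv, model))
        cplx = eigs[np.abs(eigs.imag) > 1e-4]
        if cplx.size == 0:
            return None, 0.0
        k = np.argmax(cplx.real)
        return float(cplx[k].real), float(abs(cplx[k].imag))

    d = y_b - y_a
    dn = np.linalg.norm(d)
    if dn == 0:
        return None
    c = d / dn
    g_a, _ = gfun(y_a)
    g_b, _ = gfun(y_b)
    if g_a is None or g_b is None or g_a * g_b > 0:
        return None
    lo, hi = 0.0, 1.0
    y_lo, y_hi = y_a.copy(), y_b.copy()
    omega = 0.0
    for _ in range(60):
        if abs(y_hi[n] - y_lo[n]) < tol:
            break
        mid = 0.5 * (lo + hi)
        y_pred = y_a + mid * d
        y_m = _corrector(y_pred, params, model, (c, y_pred), n)
        if y_m is None:
            return None
        g_m, om = gfun(y_m)
        if g_m is None:
            return None
        if g_a * g_m <= 0:
            hi, y_hi, g_b = mid, y_m, g_m
        else:
            lo, y_lo, g_a = mid, y_m, g_m
        omega = om
    y_h = 0.5 * (y_lo + y_hi)
    return (float(max(y_h[n], 0.0)), np.exp(y_h[:n]), omega)


# ---------------------------------------------------------------------------
# switch classification
# ---------------------------------------------------------------------------


def classify_switch(branch: EquilibriumBranch, basal_stress: float = 0.1) -> SwitchClassification:
    """Classify the fold structure of a stress-continuation branch.

    monostable: no folds.  Bistable: two folds with abscissas S1 (first
    fold met along arclength from the basal branch) and S2 (return fold);
    irreversible iff S2 < basal stress.  Orientation compares the
    extracellular cortisol of the two outer (stable) branch segments in
    the bistable window: hyper when the branch reached by increasing
    stress past S1 runs at *higher* cortisol than the basal branch.
    """
    lps = branch.limit_points
    if len(lps) == 0:
        return SwitchClassification(
            kind="monostable", orientation="none", basal_stress=basal_stress
        )
    if len(lps) != 2:
        return SwitchClassification(
            kind="complex", orientation="none", basal_stress=basal_stress,
            limit_points=list(lps),
        )
    S1, S2 = lps[0][0], lps[1][0]
    kind = "irreversible_bistable" if S2 < basal_stress else "reversible_bistable"

    # locate the fold indices along the branch to split into segments
    S = branch.stress
    i1 = int(np.argmin(np.abs(S - S1) + np.sum(
        (np.log(np.clip(branch.states, LOG_FLOOR, None))
         - np.log(np.clip(lps[0][1], LOG_FLOOR, None))) ** 2, axis=1)))
    i2 = int(np.argmin(np.abs(S - S2) + np.sum(
        (np.log(np.clip(branch.states, LOG_FLOOR, None))
         - np.log(np.clip(lps[1][1], LOG_FLOOR, None))) ** 2, axis=1)))
    if i1 >= i2:
        i1, i2 = min(i1, i2), max(i1, i2)
    seg_basal = slice(0, max(i1, 1))
    seg_alt = slice(min(i2 + 1, len(S) - 1), len(S))
    S_mid = 0.5 * (min(S1, S2) + max(S1, S2))
    cor_basal = _interp_on_segment(S[seg_basal], branch.cor_ex()[seg_basal], S_mid)
    cor_alt = _interp_on_segment(S[seg_alt], branch.cor_ex()[seg_alt], S_mid)
    if cor_basal is None or cor_alt is None:
        orientation = "none"
    else:
        orientation = "hyper" if cor_alt > cor_basal else "hypo"
    return SwitchClassification(
        kind=kind, orientation=orientation, S1=float(S1), S2=float(S2),
        basal_stress=basal_stress, limit_points=list(lps),
    )


def _interp_on_segment(S_seg, val_seg, S_target):
    if len(S_seg) < 2:
        return None
    order = np.argsort(S_seg)
    Ss, vs = np.asarray(S_seg)[order], np.asarray(val_seg)[order]
    if not (Ss[0] - 1e-9 <= S_target <= Ss[-1] + 1e-9):
        # segment does not span the window mid-point; use nearest endpoint
        return float(vs[0] if abs(S_target - Ss[0]) < abs(S_target - Ss[-1]) else vs[-1])
    return float(np.interp(S_target, Ss, vs))


# ---------------------------------------------------------------------------
# limit cycles
# ---------------------------------------------------------------------------


def limit_cycle(
    params,
    stress: float,
    init=None,
    model: ModelVariant = extended_model,
    t_transient: float = 4000.0,
    t_observe: float = 4000.0,
    min_rel_amplitude: float = 1e-3,
    n_out: int = 4001,
) -> dict:
    """Detect a sustained oscillation by integration and peak recurrence.

    Returns a dict with ``sustained`` (bool), ``period`` [min], per-species
    ``amplitude``, the post-transient ``orbit`` and the ``phase_order`` of
    the maxima of CRH, ACTH_ex and COR_ex within one period.  A decaying
    oscillation yields ``sustained=False`` rather than an exception.
    """
    from scipy.signal import find_peaks

    from .simulate import StressProtocol, Trajectory, integrate

    if init is None:
        init = np.full(model.n_states, 0.1)
        if model.n_states == 15:
            init = _default_guess(params, stress, model) * 1.3 + 1e-3
    proto = StressProtocol(baseline=stress)
    pre = integrate(model, params, np.asarray(init, dtype=float), protocol=proto,
                    t_grid=np.linspace(0.0, t_transient, 201))
    orbit = integrate(model, params, pre.states[-1], protocol=proto,
                      t_grid=np.linspace(0.0, t_observe, n_out))
    cor = orbit.states[:, 0] if model.n_states == 15 else orbit.states[:, 3]
    scale = max(np.max(np.abs(cor)), 1e-12)
    span = np.max(cor) - np.min(cor)
    result = {
        "sustained": False,
        "period": None,
        "amplitude": {},
        "orbit": orbit,
        "phase_order": None,
    }
    if span < min_rel_amplitude * scale:
        return result
    prom = 0.1 * span
    peaks, _ = find_peaks(cor, prominence=prom)
    if len(peaks) < 4:
        return result
    ipi = np.diff(orbit.times[peaks])
    period = float(np.mean(ipi[-min(len(ipi), 10):]))
    # sustained: late peak heights do not decay
    heights = cor[peaks]
    if len(heights) >= 4 and heights[-1] < 0.8 * heights[len(heights) // 2]:
        return result
    # amplitudes over the last few periods
    t_last = orbit.times[-1] - 3 * period
    sel = orbit.times >= t_last
    amp = {
        name: float(0.5 * (orbit.states[sel, i].max() - orbit.states[sel, i].min()))
        for i, name in enumerate(model.state_names)
    }
    # phase order of maxima of the core hormones within one cycle: anchor
    # at the final cortisol peak and take each species' peak in the
    # preceding period
    core = (
        ("CRH", "ACTH_ex", "COR_ex") if model.n_states == 15
        else ("CRH", "ACTH", "COR")
    )
    t_ref = float(orbit.times[peaks[-1]])
    tmax = {core[-1]: t_ref}
    for name in core[:-1]:
        i = model.state_names.index(name)
        pk, _ = find_peaks(orbit.states[:, i],
                           prominence=0.05 * np.ptp(orbit.states[:, i]))
        tp = orbit.times[pk]
        in_cycle = tp[(tp > t_ref - period) & (tp <= t_ref)]
        if in_cycle.size == 0:
            return result
        tmax[name] = float(in_cycle[-1])
    order = tuple(sorted(core, key=lambda s: tmax[s]))
    result.update(
        sustained=True, period=period, amplitude=amp, phase_order=order,
        t_max=tmax,
    )
    return result
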