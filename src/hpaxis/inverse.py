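"""Sparse inverse-bifurcation correction of the hypercortisolism switch.

The irreversible switch is characterised by the return limit point LP2
lying below the basal stress level: once a stressor has driven the axis
to the elevated-cortisol branch, dropping back to basal stress does not
restore normal cortisol.  The correction problem asks for a parameter
change x such that the corrected model's LP2 abscissa moves past the
basal level (making the switch reversible) while the abscissa of LP1 is
maintained and as few parameters as possible are altered:

    min_x ||(S1(q0), S2*) - F(q0 + x)||^2 + alpha * phi(x/q0),  p < 1

with F mapping parameters onto the two fold abscissas and phi the same
lp penalty used for data fitting.  Corrections are taken multiplicative
(log-space moves) to keep parameters positive, and the penalty acts on
the relative changes, which is what an intervention would scale with.

Gradients of the fold abscissas use the exact saddle-node sensitivity
formula: at a fold (x*, S*) with left null vector w of the Jacobian,
dS/dq_j = - w^T f_{q_j} / (w^T f_S).  Each iteration therefore costs one
continuation plus cheap directional derivatives, and a damped Gauss-
Newton/IRLS loop with backtracking keeps the objective monotone along
accepted iterates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .bifurcation import (
    ConvergenceError,
    classify_switch,
    continue_equilibria,
    jacobian,
    rhs_param_derivative,
    rhs_stress_derivative,
)
from .fitting import penalty
from .models import ModelVariant, extended_model
from .params import FREE_PARAM_NAMES, ExtendedParams

__all__ = [
    "CorrectionProblem",
    "CorrectionResult",
    "lp_abscissas",
    "fold_sensitivities",
    "solve_correction",
    "report_intervention",
]


@dataclass
class CorrectionProblem:
    """Inverse-bifurcation problem on a hypercortisolism parameter set."""

    q0: ExtendedParams
    S2_target: float = 0.15
    basal_stress: float = 0.1
    alpha: float = 1e-3
    p: float = 0.9
    allowed: tuple = FREE_PARAM_NAMES
    max_iter: int = 30
    seed: int = 0
    stress_range: tuple = (0.0, 1.0)
    model: ModelVariant = extended_model

    def __post_init__(self) -> None:
        if self.S2_target <= self.basal_stress:
            raise ValueError("S2_target must exceed the basal stress level")
        if not (0.0 < self.p <= 2.0):
            raise ValueError("p must be in (0, 2]")
        for n in self.allowed:
            if n not in FREE_PARAM_NAMES:
                raise ValueError(f"unknown parameter {n!r}")


@dataclass
class CorrectionResult:
    """Correction vector with achieved fold abscissas and classification."""

    x: dict                    # absolute changes per parameter
    x_rel: dict                # relative changes x / q0
    achieved_S1: float
    achieved_S2: float
    target_S2: float
    support: tuple             # parameters altered by > 1% relative
    classification: object
    success: bool
    objective_trace: list = field(default_factory=list)

    @property
    def support_size(self) -> int:
        return len(self.support)


def _two_fold_branch(q, stress_range, model):
    """Continuation branch carrying two folds, trying every attractor at
    the lower end of the range as the starting point."""
    from .bifurcation import distinct_attractors

    best = None
    try:
        starts = distinct_attractors(q, stress_range[0], model=model, seed=0)
    except Exception:
        starts = []
    for eq in (starts[:3] or [None]):
        try:
            branch = continue_equilibria(
                q, stress_range, model=model,
                guess=None if eq is None else eq.state, max_points=1500,
            )
        except ConvergenceError:
            continue
        if len(branch.limit_points) == 2:
            return branch
        if best is None or len(branch.limit_points) > len(best.limit_points):
            best = branch
    return best


def lp_abscissas(q: ExtendedParams, stress_range=(0.0, 1.0),
                 model: ModelVariant = extended_model):
    """The two fold abscissas (S1 > S2) of the equilibrium branch.

    Deterministic for fixed continuation settings.  Raises if no branch
    carries exactly two folds (the best branch is attached to the error
    for diagnosis).
    """
    branch = _two_fold_branch(q, stress_range, model)
    if branch is None or len(branch.limit_points) != 2:
        err = RuntimeError(
            "expected 2 limit points, found "
            f"{0 if branch is None else len(branch.limit_points)}"
        )
        err.branch = branch
        raise err
    a = sorted(S for S, _ in branch.limit_points)
    return float(a[1]), float(a[0])


def _folds_with_states(q, stress_range, model):
    branch = _two_fold_branch(q, stress_range, model)
    if branch is None or len(branch.limit_points) != 2:
        return None, branch
    lps = sorted(branch.limit_points, key=lambda t: -t[0])  # S1 first
    return lps, branch


def fold_sensitivities(q: ExtendedParams, fold_state, fold_S, names,
                       model: ModelVariant = extended_model) -> np.ndarray:
    """dS/dq at a saddle-node via the left-null-vector formula."""
    J = jacobian(fold_state, q, fold_S, model)
    # left null vector: smallest singular value direction of J^T
    U, s, Vt = scipy.linalg.svd(J.T)
    w = Vt[-1]
    fS = rhs_stress_derivative(fold_state, q, fold_S, model)
    denom = float(w @ fS)
    if abs(denom) < 1e-14:
        raise ConvergenceError("fold sensitivity: w^T f_S numerically zero")
    sens = np.empty(len(names))
    for j, n in enumerate(names):
        fq = rhs_param_derivative(fold_state, q, fold_S, n, model)
        sens[j] = -float(w @ fq) / denom
    return sens


def solve_correction(problem: CorrectionProblem) -> CorrectionResult:
    """Damped Gauss-Newton/IRLS solve of the sparse correction problem.

    Iterates multiplicative parameter moves z (q = q0*exp(z)); the
    mismatch part is linearised through the fold sensitivities and the
    smoothed lp penalty (eps-continuation 1e-1 -> 1e-4) is handled by
    iterative reweighting.  Steps are backtracked until the objective
    decreases, so the accepted-iterate objective trace is monotone.
    """
    q0 = problem.q0
    names = list(problem.allowed)
    q0_vec = np.array([getattr(q0, n) for n in names])
    lps, branch = _folds_with_states(q0, problem.stress_range, problem.model)
    if lps is None:
        raise RuntimeError("q0 does not exhibit a two-fold branch")
    cls0 = classify_switch(branch, problem.basal_stress)
    if cls0.kind != "irreversible_bistable" or cls0.orientation != "hyper":
        raise RuntimeError(
            f"q0 must verify as (irreversible_bistable, hyper); got "
            f"({cls0.kind}, {cls0.orientation})"
        )
    S1_0 = lps[0][0]
    target = np.array([S1_0, problem.S2_target])

    def params_of(z):
        return q0.replace(**{n: float(v) for n, v in zip(names, q0_vec * np.exp(z))})

    def smoothed_pen(z, eps):
        x_rel = np.exp(z) - 1.0
        return float(np.sum((x_rel**2 + eps**2) ** (problem.p / 2.0) - eps**problem.p))

    def full_objective(z, lps_z, eps):
        S = np.array([lps_z[0][0], lps_z[1][0]])
        return float(np.sum((S - target) ** 2)) + problem.alpha * smoothed_pen(z, eps)

    z = np.zeros(len(names))
    lps_z = lps
    eps = 1e-1
    trace = []
    obj = full_objective(z, lps_z, eps)
    trace.append(obj)
    lam = 1e-3
    for it in range(problem.max_iter):
        # sensitivities of both folds w.r.t. z (chain rule dq = q*dz)
        qz = params_of(z)
        qz_vec = q0_vec * np.exp(z)
        A = np.zeros((2, len(names)))
        for k in (0, 1):
            S_k, x_k = lps_z[k]
            A[k] = fold_sensitivities(qz, x_k, S_k, names, problem.model) * qz_vec
        S_now = np.array([lps_z[0][0], lps_z[1][0]])
        r = S_now - target
        x_rel = np.exp(z) - 1.0
        wpen = (x_rel**2 + eps**2) ** (problem.p / 2.0 - 1.0)
        grad_pen = problem.alpha * problem.p * wpen * x_rel * np.exp(z)
        H_pen = np.diag(problem.alpha * problem.p * wpen * np.exp(2 * z))
        accepted = False
        for _bt in range(8):
            H = 2.0 * A.T @ A + H_pen + lam * np.eye(len(names))
            g = 2.0 * A.T @ r + grad_pen
            dz = np.linalg.solve(H, -g)
            dz = np.clip(dz, -0.5, 0.5)
            z_new = z + dz
            lps_new, _ = _folds_with_states(
                params_of(z_new), problem.stress_range, problem.model
            )
            if lps_new is not None:
                obj_new = full_objective(z_new, lps_new, eps)
                if obj_new < obj:
                    z, lps_z, obj = z_new, lps_new, obj_new
                    trace.append(obj)
                    lam = max(lam / 3.0, 1e-6)
                    accepted = True
                    break
            lam *= 8.0
        mis = float(np.sum((np.array([lps_z[0][0], lps_z[1][0]]) - target) ** 2))
        if not accepted or (mis < 1e-8 and eps <= 1e-4):
            if eps > 1e-4:
                eps *= 0.1
                obj = full_objective(z, lps_z, eps)
                trace.append(obj)
                continue
            if not accepted and eps > 1e-4:
                continue
            break

    # final verification
    q_final = params_of(z)
    lps_f, branch_f = _folds_with_states(q_final, problem.stress_range, problem.model)
    if lps_f is None:
        cls = None
        S1f = S2f = float("nan")
        success = False
    else:
        cls = classify_switch(branch_f, problem.basal_stress)
        S1f, S2f = lps_f[0][0], lps_f[1][0]
        success = (
            cls.kind == "reversible_bistable"
            and cls.orientation == "hyper"
            and S2f >= problem.basal_stress
        )
    x_rel = np.exp(z) - 1.0
    x_abs = q0_vec * x_rel
    support = tuple(
        n for n, xr in zip(names, x_rel) if abs(xr) > 0.01
    )
    return CorrectionResult(
        x={n: float(v) for n, v in zip(names, x_abs)},
        x_rel={n: float(v) for n, v in zip(names, x_rel)},
        achieved_S1=float(S1f),
        achieved_S2=float(S2f),
        target_S2=float(problem.S2_target),
        support=support,
        classification=cls,
        success=bool(success),
        objective_trace=trace,
    )


#: interpretation tags for the network parts a correction touches
_INTERPRETATION = {
    "K6": "CRH-sensitivity (TFs induction threshold of the CRHR pathway)",
    "v3": "CRH-sensitivity (CRHR receptor production)",
    "d7": "CRH-sensitivity (CRHR receptor turnover)",
    "ktl2": "GR-translation (GR mRNA translation rate)",
    "K3": "hypothalamic-side (cortisol feedback threshold on CRH production)",
    "d3": "hypothalamic-side (extracellular ACTH clearance)",
    "d2": "hypothalamic-side (CRH clearance)",
}


def report_intervention(result: CorrectionResult, threshold: float = 0.01) -> str:
    """Human-readable summary of a correction: which parameters move,
    in which direction, and which feedback controls they touch."""
    entries = [
        (n, xr) for n, xr in result.x_rel.items() if abs(xr) > threshold
    ]
    if not entries:
        return "no intervention: the correction vector is numerically zero"
    entries.sort(key=lambda t: -abs(t[1]))
    lines = [
        f"intervention on {len(entries)} parameter(s); achieved "
        f"S1={result.achieved_S1:.4f}, S2={result.achieved_S2:.4f} "
        f"(target S2={result.target_S2:.4f}; "
        f"{'reversible' if result.success else 'NOT verified reversible'})"
    ]
    for n, xr in entries:
        direction = "increase" if xr > 0 else "decrease"
        tag = _INTERPRETATION.get(n, "pituitary-cell kinetics")
        lines.append(f"  {n}: {direction} by {100 * abs(xr):.1f}%  [{tag}]")
    return "\n".join(lines)
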