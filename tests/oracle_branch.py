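"""Independent dense-grid multi-start oracle for fold abscissas.

Marches stress over a dense grid solving for ALL equilibria at each
level by damped Newton from (a) a fixed seeded set of random starts and
(b) the solutions of the neighbouring grid point (natural-parameter
warm starts; no arclength machinery is used, so this path is independent
of the pseudo-arclength continuation it checks).  A fold lies where the
root count changes; its abscissa is sharpened by bisection on the
counting function.
"""

import numpy as np

from hpaxis.bifurcation import ConvergenceError, find_equilibrium

_DISTINCT_DEX = 1e-3


def _key(state):
    return np.log10(np.clip(state, 0, None) + 1e-6)


def solutions_at(params, stress, starts, model=None, extra_random=12, seed=0):
    """Distinct equilibria from warm starts plus seeded random starts."""
    kw = {} if model is None else {"model": model}
    rng = np.random.default_rng(seed)
    n = 15 if model is None else model.n_states
    all_starts = list(starts)
    for _ in range(extra_random):
        x0 = 10 ** rng.uniform(-2.5, 1.5, n)
        if n == 15:
            x0[5] = params.v2 / params.d6
            x0[6] = params.v3 / params.d7
        all_starts.append(x0)
    sols = []
    for x0 in all_starts:
        try:
            eq = find_equilibrium(params, stress, guess=x0, max_iter=120, **kw)
        except (ConvergenceError, Exception):
            continue
        k = _key(eq.state)
        if not any(np.max(np.abs(k - _key(s))) < _DISTINCT_DEX for s in sols):
            sols.append(eq.state)
    return sols


def fold_abscissas_dense(params, stress_range=(0.0, 1.0), n_grid=30,
                         tol=1e-4, seed=0, model=None):
    """Fold abscissas located by bisection on the equilibrium count."""
    S_grid = np.linspace(stress_range[0], stress_range[1], n_grid)
    sols_per_S = []
    prev = []
    for S in S_grid:
        sols = solutions_at(params, S, prev, model=model, seed=seed)
        sols_per_S.append(sols)
        prev = sols
    folds = []
    for i in range(n_grid - 1):
        c_lo, c_hi = len(sols_per_S[i]), len(sols_per_S[i + 1])
        if c_lo == c_hi:
            continue
        lo, hi = S_grid[i], S_grid[i + 1]
        sols_lo, sols_hi = sols_per_S[i], sols_per_S[i + 1]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            sols_mid = solutions_at(params, mid, sols_lo + sols_hi,
                                    model=model, seed=seed)
            if len(sols_mid) == c_lo:
                lo, sols_lo = mid, sols_mid
            else:
                hi, sols_hi = mid, sols_mid
        folds.append(0.5 * (lo + hi))
    return folds
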