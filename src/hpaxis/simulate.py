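"""Stiff integration of the HPA models under stress protocols and doses.

Doses are modelled as instantaneous jumps of an extracellular
concentration (bolus administration into the medium); stress enters the
CRH production term only and is piecewise constant over a protocol.  The
integrator restarts at every dose time and pulse edge so that the solver
never steps across a discontinuity.

For in-vitro (cell culture) protocols the hypothalamic CRH production and
the adrenal cortisol production have no biological counterpart in the
dish; :func:`invitro_variant` returns a model with those source terms
switched off while everything cellular stays intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import ModelVariant, extended_model, parsimonious_model
from .params import EXTRACELLULAR_SPECIES, ExtendedParams, ParsimoniousParams

__all__ = [
    "StressProtocol",
    "DoseEvent",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "invitro_variant",
    "run_dose_experiment",
    "simulate_stress_response",
    "load_protocol",
    "PROTOCOL_DOSES",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails on an interval."""


@dataclass(frozen=True)
class StressProtocol:
    """Piecewise-constant stress input: a baseline plus rectangular pulses."""

    baseline: float = 0.1
    pulses: tuple = ()
    description: str = ""

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline stress must be >= 0")
        pulses = tuple(tuple(p) for p in self.pulses)
        object.__setattr__(self, "pulses", pulses)
        prev_end = -np.inf
        for t0, t1, level in sorted(pulses):
            if t0 >= t1:
                raise ValueError("pulse must have t_start < t_end")
            if level < 0:
                raise ValueError("pulse level must be >= 0")
            if t0 < prev_end:
                raise ValueError("pulses must not overlap")
            prev_end = t1


    def stress(self, t: float) -> float:
        for t0, t1, level in self.pulses:
            if t0 <= t < t1:
                return level
        return self.baseline

    def edges(self) -> list:
        out = []
        for t0, t1, _ in self.pulses:
            out.extend((t0, t1))
        return sorted(out)


@dataclass(frozen=True)
class DoseEvent:
    """Instantaneous addition of an extracellular species at a time point."""

    time: float
    species: str
    amount: float  # nM

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")


@dataclass
class Trajectory:
    """Time course of all model states on a fixed output grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_states)
    model: str = ""
    protocol: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != self.times.size:
            raise ValueError("state matrix rows must match times length")

    def species(self, name: str, state_names) -> np.ndarray:
        return self.states[:, list(state_names).index(name)]

    def to_dataframe(self, state_names) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(state_names))
        df.insert(0, "time_min", self.times)
        return df


def load_protocol(path):
    """Read a protocol file (YAML) into a StressProtocol plus dose list.

    Schema: ``{baseline, pulses: [{t_start, t_end, level}],
    doses: [{time, species, amount_nM}]}``; all sections optional.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    protocol = StressProtocol(
        baseline=float(raw.get("baseline", 0.0)),
        pulses=tuple(
            (float(p["t_start"]), float(p["t_end"]), float(p["level"]))
            for p in raw.get("pulses", []) or []
        ),
        description=str(raw.get("description", "")),
    )
    doses = [
        DoseEvent(float(d["time"]), str(d["species"]), float(d["amount_nM"]))
        for d in raw.get("doses", []) or []
    ]
    return protocol, doses


def _dose_index(model: ModelVariant, species: str) -> int:
    if model.n_states == 15:
        if species not in EXTRACELLULAR_SPECIES:
            raise ValueError(
                f"dose species must be extracellular ({EXTRACELLULAR_SPECIES})"
            )
        return model.state_names.index(species)
    # parsimonious model: map the administered hormones onto its states
    mapping = {"CRH": 0, "COR_ex": 3, "ACTH_ex": 1}
    if species not in mapping:
        raise ValueError(f"cannot dose species {species!r} in the 4-state model")
    return mapping[species]


def integrate(
    model: ModelVariant,
    params,
    initial,
    protocol: StressProtocol | None = None,
    doses=(),
    t_grid=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "BDF",
) -> Trajectory:
    """Integrate ``model`` on ``t_grid`` under a stress protocol and doses.

    The solution is deterministic given its inputs; every dose event and
    pulse edge restarts the solver, with the dosed state incremented by
    the bolus amount at the event time.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 60.0, 121)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    protocol = protocol or StressProtocol(baseline=0.0)
    doses = sorted(doses, key=lambda d: d.time)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    for d in doses:
        if not (t0 <= d.time <= t1):
            raise ValueError(f"dose at t={d.time} outside [{t0}, {t1}]")

    # breakpoints: dose times and pulse edges inside the grid span
    breaks = sorted(
        {t0, t1}
        | {d.time for d in doses}
        | {e for e in protocol.edges() if t0 < e < t1}
    )

    x = np.array(initial, dtype=float)
    if x.shape != (model.n_states,):
        raise ValueError(f"initial state must have {model.n_states} components")

    out_t, out_x = [], []
    # apply doses at the very start
    for d in doses:
        if d.time == t0:
            x[_dose_index(model, d.species)] += d.amount
    if t_grid[0] == t0:
        out_t.append(t0)
        out_x.append(x.copy())

    for a, b in zip(breaks[:-1], breaks[1:]):
        stress = protocol.stress(0.5 * (a + b))
        seg_mask = (t_grid > a) & (t_grid <= b)
        seg_eval = t_grid[seg_mask]
        t_eval = np.unique(np.concatenate((seg_eval, [b])))
        sol = solve_ivp(
            lambda t, y: model.rhs(t, y, params, stress),
            (a, b),
            x,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed on [{a:g}, {b:g}] min: {sol.message}"
            )
        in_grid = np.isin(sol.t, seg_eval)
        out_t.extend(sol.t[in_grid].tolist())
        out_x.extend(sol.y.T[in_grid].tolist())
        x = sol.y[:, -1].copy()
        for d in doses:
            if d.time == b and b != t1:
                x[_dose_index(model, d.species)] += d.amount

    traj = Trajectory(
        times=np.array(out_t),
        states=np.array(out_x),
        model=model.name,
        protocol=protocol.description,
    )
    return traj


# ---------------------------------------------------------------------------
# in-vitro dose experiments (AtT-20-like protocols)
# ---------------------------------------------------------------------------

#: Bolus doses of the two experimental protocols: A = 10 nM CRH at t=0;
#: B = 10 nM CRH plus 100 nM cortisol at t=0.
PROTOCOL_DOSES = {
    "A": (DoseEvent(0.0, "CRH", 10.0),),
    "B": (DoseEvent(0.0, "CRH", 10.0), DoseEvent(0.0, "COR_ex", 100.0)),
}


def invitro_variant(model: ModelVariant) -> ModelVariant:
    """Model with hypothalamic and adrenal source terms switched off.

    In the cell-culture setting the only CRH and extracellular cortisol
    present are the administered boluses, so the stress-driven CRH
    production and the ACTH-driven cortisol production are removed.
    """
    if model.n_states == 15:

        def rhs(t, x, p: ExtendedParams, stress=None):
            dx = model.rhs(t, x, p, 0.0)
            xa = np.asarray(x)
            dx[1] = dx[1] - p.ks * p.ksb / (1.0 + xa[0] / p.K3)
            dx[0] = dx[0] - p.v1 * xa[2] / (p.K1 + xa[2])
            return dx

    elif model.n_states == 4:

        def rhs(t, x, p: ParsimoniousParams, stress=None):
            dx = model.rhs(t, x, p, 0.0)
            xa = np.asarray(x)
            dx[0] = dx[0] - p.kc / (1.0 + xa[3] / p.ki1)
            dx[3] = dx[3] - p.ko * xa[1]
            return dx

    else:  # pragma: no cover
        raise ValueError("unsupported model")

    return ModelVariant(
        name=model.name + "-invitro",
        rhs=rhs,
        n_states=model.n_states,
        state_names=model.state_names,
        params_type=model.params_type,
        removed_terms=model.removed_terms
        + ("hypothalamic CRH production", "adrenal cortisol production"),
    )


def run_dose_experiment(
    params,
    protocol_id: str,
    sample_times,
    model: ModelVariant = extended_model,
    initial=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Extracellular ACTH read-out of an in-vitro dose protocol.

    ``protocol_id`` 'A' doses 10 nM CRH at t=0; 'B' doses 10 nM CRH plus
    100 nM cortisol.  Returns the model counterpart of the total ACTH
    concentration in the cell medium at ``sample_times`` (within 0-60 min).
    """
    if protocol_id not in PROTOCOL_DOSES:
        raise ValueError("protocol_id must be 'A' or 'B'")
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(sample_times < 0) or np.any(sample_times > 60.0):
        raise ValueError("sample times must lie within 0-60 min")
    variant = invitro_variant(model)
    if initial is None:
        if variant.n_states != 15:
            raise ValueError("an initial state is required for this model")
        initial = default_invitro_initial(params)
    grid = np.unique(np.concatenate(([0.0], sample_times)))
    traj = integrate(
        variant,
        params,
        initial,
        protocol=StressProtocol(baseline=0.0, description=f"protocol {protocol_id}"),
        doses=PROTOCOL_DOSES[protocol_id],
        t_grid=grid,
        rtol=rtol,
        atol=atol,
    )
    acth_col = 2 if variant.n_states == 15 else 1
    interp = np.interp(sample_times, traj.times, traj.states[:, acth_col])
    return interp


def default_invitro_initial(params: ExtendedParams) -> np.ndarray:
    """Pre-dose resting state of the cultured cells.

    The cells equilibrate for a long time in dose-free medium before the
    experiment; this integrates the in-vitro model to its resting state.
    """
    variant = invitro_variant(extended_model)
    x0 = np.full(15, 0.1)
    x0[5] = params.v2 / params.d6
    x0[6] = params.v3 / params.d7
    grid = np.array([0.0, 2000.0, 4000.0])
    traj = integrate(
        variant, params, x0,
        protocol=StressProtocol(baseline=0.0),
        t_grid=grid, rtol=1e-8, atol=1e-12,
    )
    return np.clip(traj.states[-1], 0.0, None)


def simulate_stress_response(
    params: ExtendedParams,
    protocol: StressProtocol,
    horizon: float,
    model: ModelVariant = extended_model,
    initial=None,
    n_out: int = 601,
    settle_tol: float = 1e-6,
):
    """Simulate a transient stress pulse starting from the resting state.

    The trajectory starts at the stable equilibrium of the pre-pulse
    (baseline) stress level and reports the asymptotic state reached
    after the pulse.  In a bistable regime ``initial`` selects which
    coexisting resting state to start from (e.g. the healthy branch);
    it is polished to the nearest equilibrium first.  Returns
    ``(trajectory, post_state)``.
    """
    from .bifurcation import find_equilibrium

    eq = find_equilibrium(params, protocol.baseline, guess=initial, model=model)
    if not eq.stable:
        raise RuntimeError(
            "no stable pre-pulse equilibrium at baseline stress; "
            "check that the parameter regime is bistable/monostable as intended"
        )
    grid = np.linspace(0.0, horizon, n_out)
    traj = integrate(model, params, eq.state, protocol=protocol, t_grid=grid)
    post = traj.states[-1]
    # continue integrating past the horizon until the state settles
    t_extra, t_end = horizon, horizon
    while True:
        res = np.max(np.abs(model.rhs(t_end, np.clip(post, 1e-300, None), params,
                                      protocol.stress(t_end))))
        if res < settle_tol or t_end > horizon + 16 * 3000.0:
            break
        seg = integrate(
            model, params, post,
            protocol=StressProtocol(baseline=protocol.baseline),
            t_grid=np.array([0.0, 3000.0]),
        )
        post = seg.states[-1]
        t_end += 3000.0
    return traj, post
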