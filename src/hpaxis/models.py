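"""Right-hand sides of the HPA-axis models and in-silico knockouts.

The extended model describes an anterior pituitary gland cell embedded in
the hormonal stress axis.  It separates the nucleus from the cytoplasm and
distinguishes three receptor-mediated feedback pathways:

* the genomic pathway of the intracellular glucocorticoid receptor GR,
  whose cortisol-bound homodimer is imported into the nucleus where it
  represses POMC transcription and enhances GR transcription;
* the non-genomic pathway of the membrane glucocorticoid receptor GPCR,
  which binds two cortisol molecules cooperatively and inhibits the
  release of vesicular ACTH within seconds;
* the CRHR pathway, by which extracellular CRH both triggers ACTH release
  and induces (via transcription factors TFs) POMC expression.

Fast receptor-ligand binding and GR dimerisation are closed as quasi
equilibria, so the membrane complexes and the cytoplasmic dimer never get
ODEs of their own.  All concentrations are nM, time is in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    EXTRACELLULAR_SPECIES,
    N_STATES,
    PARSIMONIOUS_STATE_NAMES,
    STATE_NAMES,
    ExtendedParams,
    ParsimoniousParams,
)

__all__ = [
    "membrane_complexes",
    "dimer_flux_F",
    "rhs_extended",
    "rhs_parsimonious",
    "KnockoutSpec",
    "ModelVariant",
    "apply_knockout",
    "extended_model",
    "parsimonious_model",
    "get_model",
    "KNOCKOUT_NAMES",
]


def membrane_complexes(state, params: ExtendedParams):
    """Quasi-equilibrium concentrations of the two membrane complexes.

    Returns a dict with ``CRHR_CRH = CRHR*CRH/kCRC`` (single-ligand CRH
    receptor complex) and ``GPCR_COR2 = GPCR*COR_ex**2/kGC2`` (cooperative
    two-cortisol membrane receptor complex).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components")
    if np.any(state < 0):
        raise ValueError("negative concentrations in membrane_complexes")
    COR_ex, CRH, CRHR, GPCR = state[0], state[1], state[6], state[5]
    return {
        "CRHR_CRH": CRHR * CRH / params.kCRC,
        "GPCR_COR2": GPCR * COR_ex**2 / params.kGC2,
    }


def dimer_flux_F(D_nu, COR_in, GR, params: ExtendedParams):
    """Net rate of change of free cytoplasmic cortisol (and of free GR)
    due to nuclear transport of the dimerised GR-cortisol complex.

    Under the fast-binding closure the cytoplasmic dimer is
    ``D_cyt = COR_in^2 * GR^2 / kappa`` with ``kappa = kGRC^2 * kGRdim``.
    The flux is

        F = (COR_in*GR*(COR_in+GR)/kappa) * (k_bar*k2ex*D_nu - k2in*D_cyt)

    which vanishes exactly at the transport equilibrium
    ``k_bar*k2ex*D_nu = k2in*D_cyt`` (for positive free species), is
    positive when nuclear export dominates and negative when import
    dominates.  It enters the COR_in and GR balances with one shared
    value; units are nM/min.
    """
    for name, v in (("D_nu", D_nu), ("COR_in", COR_in), ("GR", GR)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite {name} in dimer_flux_F")
    kappa = params.kappa
    D_cyt = COR_in**2 * GR**2 / kappa
    return (COR_in * GR * (COR_in + GR) / kappa) * (
        params.k_bar * params.k2ex * D_nu - params.k2in * D_cyt
    )


def _rhs_core(t, x, p: ExtendedParams, stress, gpcr_active=True):
    """Time derivatives of the 15 states; complex-step safe."""
    (COR_ex, CRH, ACTH_ex, COR_in, ACTH_in, GPCR, CRHR, GR,
     GRCOR2_nu, mPOMC, mGR, TFs_in, TFs_nu, pmPOMC, pmGR) = x

    vratio_ie = p.V_in / p.V_ex
    vratio_ni = p.V_nu / p.V_in

    # membrane complexes (quasi-equilibrium closure)
    R = CRHR * CRH / p.kCRC               # [CRHR-CRH]
    P = GPCR * COR_ex**2 / p.kGC2 if gpcr_active else 0.0

    # ACTH release from vesicles: CRHR complex catalyses, GPCR complex
    # inhibits competitively
    release = p.k1ex * R * ACTH_in / (p.K4 * (1.0 + P / p.K5) + R)

    # nuclear dimer transport flux (shared by COR_in and GR balances)
    kappa = p.kGRC**2 * p.kGRdim
    D_cyt = COR_in**2 * GR**2 / kappa
    F = (COR_in * GR * (COR_in + GR) / kappa) * (
        p.k_bar * p.k2ex * GRCOR2_nu - p.k2in * D_cyt
    )

    hill = p.v4 * R**p.h / (p.K6**p.h + R**p.h)

    dx = [
        # extracellular cortisol: diffusion, adrenal production, clearance
        vratio_ie * p.kdiff1 * (COR_in - COR_ex)
        + p.v1 * ACTH_ex / (p.K1 + ACTH_ex) - p.d1 * COR_ex,
        # CRH: stress-driven hypothalamic production inhibited by cortisol
        p.ks * (p.ksb + stress) / (1.0 + COR_ex / p.K3) - p.d2 * CRH,
        # extracellular ACTH
        vratio_ie * release - p.d3 * ACTH_ex,
        # cytoplasmic cortisol
        p.kdiff1 * (COR_ex - COR_in) - p.d4 * COR_in + F,
        # vesicular ACTH: translation of POMC mRNA minus release
        p.ktl1 * mPOMC - p.d5 * ACTH_in - release,
        # membrane receptors: constitutive production/degradation
        p.v2 - p.d6 * GPCR,
        p.v3 - p.d7 * CRHR,
        # free GR: translation plus the shared transport flux
        p.ktl2 * mGR + F - p.d8 * GR,
        # nuclear dimer balance
        p.k2in * D_cyt - p.k2ex * GRCOR2_nu - p.d9 * GRCOR2_nu,
        # cytoplasmic mRNAs
        vratio_ni * p.ktrs1 * pmPOMC - p.d10 * mPOMC,
        vratio_ni * p.ktrs2 * pmGR - p.d11 * mGR,
        # transcription factors, cytoplasm: nuclear shuttling plus
        # CRH-receptor-driven induction (Hill)
        vratio_ni * p.k3ex * TFs_nu - p.k3in * TFs_in - p.d12 * TFs_in + hill,
        # transcription factors, nucleus
        p.k3in * TFs_in - p.k3ex * TFs_nu - p.d13 * TFs_nu,
        # POMC pre-mRNA: TFs-catalysed transcription competitively
        # inhibited by the nuclear dimer
        -p.ktrs1 * pmPOMC + p.v5 - p.d14 * pmPOMC
        + p.v6 * TFs_nu / (p.K7 * (1.0 + GRCOR2_nu / p.K8) + TFs_nu),
        # GR pre-mRNA: autocatalytic enhancement by the nuclear dimer
        -p.ktrs2 * pmGR + p.v7 + p.v8 * GRCOR2_nu / (p.K9 + GRCOR2_nu)
        - p.d15 * pmGR,
    ]
    return dx


def rhs_extended(t, state, params: ExtendedParams, stress=None):
    """Right-hand side of the 15-state extended model.

    ``stress`` defaults to ``params.stress_basal``.  Accepts real or
    complex state vectors (the latter for complex-step differentiation).
    """
    if stress is None:
        stress = params.stress_basal
    if np.real(stress) < 0:
        raise ValueError("stress must be >= 0")
    x = np.asarray(state)
    if x.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to rhs_extended")
    return np.array(_rhs_core(t, x, params, stress))


def rhs_parsimonious(t, state, params: ParsimoniousParams, stress=0.0):
    """Right-hand side of the 4-state reference model.

    States: CRH, ACTH, GR, COR.  The cortisol-GR complex is closed as
    ``[COR-GR] = COR*GR`` and its homodimer drives the autocatalytic GR
    production term.
    """
    if np.real(stress) < 0:
        raise ValueError("stress must be >= 0")
    x = np.asarray(state)
    if x.shape != (4,):
        raise ValueError("state must have 4 components")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to rhs_parsimonious")
    CRH, ACTH, GR, COR = x
    p = params
    cg = COR * GR
    return np.array([
        (p.kc + stress) / (1.0 + COR / p.ki1) - p.kcd * CRH,
        p.ka * CRH / (1.0 + cg / p.ki2) - p.kad * ACTH,
        p.kr * cg**2 / (p.k + cg**2) + p.kcr - p.krd * GR,
        p.ko * ACTH - p.kod * COR,
    ])


# ---------------------------------------------------------------------------
# model variants and knockouts
# ---------------------------------------------------------------------------

KNOCKOUT_NAMES = ("gpcr_pathway", "crh_genomic_feedback", "gr_autocatalytic_loop")

_KNOCKOUT_TERMS = {
    "gpcr_pathway": (
        "d[GPCR]/dt equation removed (receptor frozen)",
        "[GPCR-(COR)2] forced to 0 in the ACTH release terms",
    ),
    "crh_genomic_feedback": (
        "v4 Hill induction of TFs_in by [CRHR-CRH] removed",
    ),
    "gr_autocatalytic_loop": (
        "v8 enhancement of pmGR transcription by the nuclear dimer removed",
    ),
}


@dataclass(frozen=True)
class KnockoutSpec:
    """Named in-silico pathway knockout."""

    name: str
    removed_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in KNOCKOUT_NAMES:
            raise ValueError(
                f"unknown knockout {self.name!r}; valid: {', '.join(KNOCKOUT_NAMES)}"
            )
        if not self.removed_terms:
            object.__setattr__(self, "removed_terms", _KNOCKOUT_TERMS[self.name])


@dataclass(frozen=True)
class ModelVariant:
    """A named ODE model: rhs(t, x, params, stress) plus bookkeeping."""

    name: str
    rhs: callable
    n_states: int
    state_names: tuple[str, ...]
    params_type: type
    removed_terms: tuple[str, ...] = ()

    def __call__(self, t, x, params, stress=None):
        return self.rhs(t, x, params, stress)


extended_model = ModelVariant(
    name="extended",
    rhs=rhs_extended,
    n_states=N_STATES,
    state_names=STATE_NAMES,
    params_type=ExtendedParams,
)

parsimonious_model = ModelVariant(
    name="parsimonious",
    rhs=lambda t, x, p, stress=0.0: rhs_parsimonious(t, x, p, 0.0 if stress is None else stress),
    n_states=4,
    state_names=PARSIMONIOUS_STATE_NAMES,
    params_type=ParsimoniousParams,
)


def _rhs_gpcr_knockout(t, state, params, stress=None):
    if stress is None:
        stress = params.stress_basal
    if np.real(stress) < 0:
        raise ValueError("stress must be >= 0")
    x = np.asarray(state)
    if x.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state in knockout rhs")
    dx = np.array(_rhs_core(0.0, x, params, stress, gpcr_active=False))
    dx[5] = 0.0 * dx[5]  # receptor equation removed; state frozen
    return dx


def _rhs_crhfb_knockout(t, state, params, stress=None):
    if stress is None:
        stress = params.stress_basal
    dx = rhs_extended(t, state, params, stress)
    x = np.asarray(state)
    R = x[6] * x[1] / params.kCRC
    hill = params.v4 * R**params.h / (params.K6**params.h + R**params.h)
    dx[11] = dx[11] - hill  # TFs production decoupled from CRHR-CRH
    return dx


def _rhs_grloop_knockout(t, state, params, stress=None):
    if stress is None:
        stress = params.stress_basal
    dx = rhs_extended(t, state, params, stress)
    x = np.asarray(state)
    dx[14] = dx[14] - params.v8 * x[8] / (params.K9 + x[8])
    return dx


_KNOCKOUT_RHS = {
    "gpcr_pathway": _rhs_gpcr_knockout,
    "crh_genomic_feedback": _rhs_crhfb_knockout,
    "gr_autocatalytic_loop": _rhs_grloop_knockout,
}

_VARIANT_ALIASES = {
    "extended": "extended",
    "parsimonious": "parsimonious",
    "extended-gpcr": "gpcr_pathway",
    "extended-crhfb": "crh_genomic_feedback",
    "extended-grloop": "gr_autocatalytic_loop",
}


def apply_knockout(spec: KnockoutSpec | str, params: ExtendedParams) -> ModelVariant:
    """Return the extended-model variant with the given pathway knocked out.

    The state dimension stays 15 for bookkeeping; removed terms are listed
    on the returned variant.  ``params`` is validated against the extended
    parameter type but not modified.
    """
    if isinstance(spec, str):
        spec = KnockoutSpec(spec)
    if not isinstance(params, ExtendedParams):
        raise TypeError("knockouts apply to the extended model only")
    return ModelVariant(
        name=f"extended-{spec.name}",
        rhs=_KNOCKOUT_RHS[spec.name],
        n_states=N_STATES,
        state_names=STATE_NAMES,
        params_type=ExtendedParams,
        removed_terms=spec.removed_terms,
    )


def get_model(name: str) -> ModelVariant:
    """Look up a model variant by name.

    Valid names: extended, parsimonious, extended-gpcr, extended-crhfb,
    extended-grloop (plus the long knockout names).
    """
    if name in ("extended", "parsimonious"):
        return extended_model if name == "extended" else parsimonious_model
    key = _VARIANT_ALIASES.get(name, name)
    if key in KNOCKOUT_NAMES:
        return ModelVariant(
            name=f"extended-{key}",
            rhs=_KNOCKOUT_RHS[key],
            n_states=N_STATES,
            state_names=STATE_NAMES,
            params_type=ExtendedParams,
            removed_terms=_KNOCKOUT_TERMS[key],
        )
    raise ValueError(
        f"unknown model {name!r}; valid: {sorted(_VARIANT_ALIASES)}"
    )
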