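"""Independent symbolic re-derivation of the model right-hand sides.

Built with sympy directly from the model equations, term by term, as an
oracle for the numpy implementation.  Kept deliberately separate from the
package: nothing here imports from hpaxis.models.
"""

import sympy as sp

STATE_SYMS = sp.symbols(
    "COR_ex CRH ACTH_ex COR_in ACTH_in GPCR CRHR GR GRCOR2_nu "
    "mPOMC mGR TFs_in TFs_nu pmPOMC pmGR",
    positive=True,
)

PARAM_ORDER = (
    "V_in V_ex V_nu kdiff1 k1ex k2in k2ex k3in k3ex "
    "d1 d2 d3 d4 d5 d6 d7 d8 d9 d10 d11 d12 d13 d14 d15 "
    "kGRC kGRdim kCRC kGC2 K1 K3 K4 K5 K6 K7 K8 K9 "
    "v1 v2 v3 v4 v5 v6 v7 v8 ks ksb ktl1 ktl2 ktrs1 ktrs2 h"
).split()
PARAM_SYMS = sp.symbols(" ".join(PARAM_ORDER), positive=True)
P = dict(zip(PARAM_ORDER, PARAM_SYMS))
STRESS = sp.Symbol("stress", nonnegative=True)


def extended_equations():
    (COR_ex, CRH, ACTH_ex, COR_in, ACTH_in, GPCR, CRHR, GR, GRCOR2_nu,
     mPOMC, mGR, TFs_in, TFs_nu, pmPOMC, pmGR) = STATE_SYMS
    p = P
    kbar = p["V_nu"] / (2 * p["V_in"])
    R = CRHR * CRH / p["kCRC"]
    Pc = GPCR * COR_ex**2 / p["kGC2"]
    release = (
        p["k1ex"] * R * ACTH_in / (p["K4"] * (1 + Pc / p["K5"]) + R)
    )
    kappa = p["kGRC"] ** 2 * p["kGRdim"]
    Dcyt = COR_in**2 * GR**2 / kappa
    F = (COR_in * GR * (COR_in + GR) / kappa) * (
        kbar * p["k2ex"] * GRCOR2_nu - p["k2in"] * Dcyt
    )
    vie = p["V_in"] / p["V_ex"]
    vni = p["V_nu"] / p["V_in"]
    eqs = [
        vie * p["kdiff1"] * (COR_in - COR_ex)
        + p["v1"] * ACTH_ex / (p["K1"] + ACTH_ex) - p["d1"] * COR_ex,
        p["ks"] * (p["ksb"] + STRESS) / (1 + COR_ex / p["K3"]) - p["d2"] * CRH,
        vie * release - p["d3"] * ACTH_ex,
        p["kdiff1"] * (COR_ex - COR_in) - p["d4"] * COR_in + F,
        p["ktl1"] * mPOMC - p["d5"] * ACTH_in - release,
        p["v2"] - p["d6"] * GPCR,
        p["v3"] - p["d7"] * CRHR,
        p["ktl2"] * mGR + F - p["d8"] * GR,
        p["k2in"] * Dcyt - p["k2ex"] * GRCOR2_nu - p["d9"] * GRCOR2_nu,
        vni * p["ktrs1"] * pmPOMC - p["d10"] * mPOMC,
        vni * p["ktrs2"] * pmGR - p["d11"] * mGR,
        vni * p["k3ex"] * TFs_nu - p["k3in"] * TFs_in - p["d12"] * TFs_in
        + p["v4"] * R ** p["h"] / (p["K6"] ** p["h"] + R ** p["h"]),
        p["k3in"] * TFs_in - p["k3ex"] * TFs_nu - p["d13"] * TFs_nu,
        -p["ktrs1"] * pmPOMC + p["v5"] - p["d14"] * pmPOMC
        + p["v6"] * TFs_nu / (p["K7"] * (1 + GRCOR2_nu / p["K8"]) + TFs_nu),
        -p["ktrs2"] * pmGR + p["v7"]
        + p["v8"] * GRCOR2_nu / (p["K9"] + GRCOR2_nu) - p["d15"] * pmGR,
    ]
    return eqs


_LAMBDIFIED = None


def rhs_extended_oracle(state, param_values: dict, stress: float):
    """Numerical evaluation of the symbolic system.

    ``param_values`` maps parameter names (as in PARAM_ORDER) to floats.
    """
    global _LAMBDIFIED
    if _LAMBDIFIED is None:
        _LAMBDIFIED = sp.lambdify(
            (STATE_SYMS, PARAM_SYMS, STRESS), extended_equations(), "numpy"
        )
    pv = tuple(param_values[n] for n in PARAM_ORDER)
    return _LAMBDIFIED(tuple(state), pv, stress)


PARSI_STATES = sp.symbols("CRH ACTH GR COR", positive=True)
PARSI_ORDER = "kc ki1 kcd ka ki2 kad kr k kcr krd ko kod".split()
PARSI_SYMS = sp.symbols(" ".join(PARSI_ORDER), positive=True)


def parsimonious_equations():
    CRH, ACTH, GR, COR = PARSI_STATES
    q = dict(zip(PARSI_ORDER, PARSI_SYMS))
    complex_ = COR * GR
    return [
        (q["kc"] + STRESS) / (1 + COR / q["ki1"]) - q["kcd"] * CRH,
        q["ka"] * CRH / (1 + complex_ / q["ki2"]) - q["kad"] * ACTH,
        q["kr"] * complex_**2 / (q["k"] + complex_**2) + q["kcr"] - q["krd"] * GR,
        q["ko"] * ACTH - q["kod"] * COR,
    ]


_PARSI_LAMBDIFIED = None


def rhs_parsimonious_oracle(state, param_values: dict, stress: float):
    global _PARSI_LAMBDIFIED
    if _PARSI_LAMBDIFIED is None:
        _PARSI_LAMBDIFIED = sp.lambdify(
            (PARSI_STATES, PARSI_SYMS, STRESS), parsimonious_equations(), "numpy"
        )
    pv = tuple(param_values[n] for n in PARSI_ORDER)
    return _PARSI_LAMBDIFIED(tuple(state), pv, stress)
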