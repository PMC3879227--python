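"""Parameter containers for the pituitary-cell HPA-axis models.

Two models live in this package: a 15-state compartmental model of the
anterior pituitary gland cell embedded in the hormonal axis (extended
model) and the classical 4-state reference model with an intracellular
glucocorticoid receptor (parsimonious model).  Concentrations are in nM
and time is in minutes throughout; the stress input is dimensionless on
a fictive scale with basal level 0.1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Names of the 15 state variables of the extended model, in equation order.
STATE_NAMES = (
    "COR_ex",     # extracellular cortisol
    "CRH",        # corticotropin-releasing hormone (blood/medium)
    "ACTH_ex",    # extracellular ACTH
    "COR_in",     # free cytoplasmic cortisol
    "ACTH_in",    # vesicular/intracellular ACTH
    "GPCR",       # membrane glucocorticoid receptor
    "CRHR",       # membrane CRH receptor
    "GR",         # free cytoplasmic glucocorticoid receptor
    "GRCOR2_nu",  # nuclear dimerised GR-cortisol complex
    "mPOMC",      # cytoplasmic POMC mRNA
    "mGR",        # cytoplasmic GR mRNA
    "TFs_in",     # cytoplasmic CRH-related transcription factors
    "TFs_nu",     # nuclear CRH-related transcription factors
    "pmPOMC",     # nuclear (pre-)mRNA of POMC
    "pmGR",       # nuclear (pre-)mRNA of GR
)

N_STATES = len(STATE_NAMES)

#: Extracellular species that can receive a bolus dose.
EXTRACELLULAR_SPECIES = ("COR_ex", "CRH", "ACTH_ex")

PARSIMONIOUS_STATE_NAMES = ("CRH", "ACTH", "GR", "COR")


@dataclass
class ExtendedParams:
    """Rate, affinity and volume constants of the 15-state model.

    Volumes are dimensionless relative compartment sizes and are fixed
    during fitting; ``k_bar = V_nu / (2 V_in)`` is derived, never stored.
    Dissociation constants: kGRC [nM] (GR-cortisol binding), kGRdim [nM]
    (dimerisation), kCRC [nM] (CRHR-CRH), kGC2 [nM^2] (cooperative
    two-cortisol binding to the membrane receptor).
    """

    # compartment volumes (phenomenological, fixed)
    V_in: float = 1.0
    V_ex: float = 1.0
    V_nu: float = 1.0
    # transport / diffusion [1/min]
    kdiff1: float = 0.1
    k1ex: float = 1.0
    k2in: float = 0.1
    k2ex: float = 0.01
    k3in: float = 0.1
    k3ex: float = 0.05
    # degradation [1/min]
    d1: float = 0.01
    d2: float = 0.05
    d3: float = 0.01
    d4: float = 0.05
    d5: float = 0.05
    d6: float = 0.05
    d7: float = 0.05
    d8: float = 0.02
    d9: float = 0.02
    d10: float = 0.05
    d11: float = 0.05
    d12: float = 0.05
    d13: float = 0.05
    d14: float = 0.05
    d15: float = 0.05
    # dissociation constants
    kGRC: float = 10.0
    kGRdim: float = 10.0
    kCRC: float = 10.0
    kGC2: float = 100.0
    # Michaelis-Menten constants [nM]
    K1: float = 10.0
    K3: float = 10.0
    K4: float = 10.0
    K5: float = 1.0
    K6: float = 1.0
    K7: float = 1.0
    K8: float = 1.0
    K9: float = 1.0
    # limiting / production rates
    v1: float = 1.0
    v2: float = 0.05
    v3: float = 0.05
    v4: float = 0.1
    v5: float = 0.01
    v6: float = 0.1
    v7: float = 0.01
    v8: float = 0.1
    ks: float = 1.0
    ksb: float = 0.01
    ktl1: float = 0.5
    ktl2: float = 0.5
    ktrs1: float = 0.5
    ktrs2: float = 0.5
    # Hill coefficient of the TFs induction term (dimensionless, fixed)
    h: float = 2.0
    # basal stress level on the fictive scale
    stress_basal: float = 0.1

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val):
                raise ValueError(f"parameter {f.name} is not finite")
            if f.name == "stress_basal":
                if val < 0:
                    raise ValueError("stress_basal must be >= 0")
            elif f.name == "h":
                if val < 1:
                    raise ValueError("Hill coefficient h must be >= 1")
            elif val <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {val}")

    @property
    def k_bar(self) -> float:
        """Volume-ratio factor of the nuclear export flux, V_nu/(2 V_in)."""
        return self.V_nu / (2.0 * self.V_in)

    @property
    def kappa(self) -> float:
        """Effective dimer quasi-equilibrium constant kGRC^2 * kGRdim [nM^3]."""
        return self.kGRC**2 * self.kGRdim

    # --- dict / vector plumbing -------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ExtendedParams":
        return cls(**d)

    def replace(self, **kwargs: float) -> "ExtendedParams":
        return dataclasses.replace(self, **kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExtendedParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def free_vector(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = FREE_PARAM_NAMES if names is None else names
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_free_vector(
        self, q: np.ndarray, names: tuple[str, ...] | None = None
    ) -> "ExtendedParams":
        names = FREE_PARAM_NAMES if names is None else names
        if len(q) != len(names):
            raise ValueError(f"expected {len(names)} entries, got {len(q)}")
        return self.replace(**{n: float(v) for n, v in zip(names, q)})


#: The 46 free parameters of the extended model.  Of the 48 kinetic symbols
#: in the model equations, kGRdim is held fixed (it enters the dynamics only
#: through kappa = kGRC^2*kGRdim, jointly with kGRC) and the Hill exponent h
#: is fixed at 2; compartment volumes are phenomenological constants.
FREE_PARAM_NAMES: tuple[str, ...] = (
    "kdiff1", "k1ex", "k2in", "k2ex", "k3in", "k3ex",
    "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9", "d10",
    "d11", "d12", "d13", "d14", "d15",
    "kGRC", "kCRC", "kGC2",
    "K1", "K3", "K4", "K5", "K6", "K7", "K8", "K9",
    "v1", "v2", "v3", "v4", "v5", "v6", "v7", "v8",
    "ks", "ksb", "ktl1", "ktl2", "ktrs1", "ktrs2",
)

FIXED_PARAM_NAMES: tuple[str, ...] = (
    "V_in", "V_ex", "V_nu", "kGRdim", "h", "stress_basal",
)


def free_parameter_table() -> "pandas.DataFrame":  # noqa: F821
    """Tabulate every parameter symbol with its role and free/fixed status.

    The model equations contain 48 kinetic symbols besides the three
    compartment volumes.  Two of them carry no independent information:
    kGRC and kGRdim only ever appear through the combination
    kappa = kGRC^2 * kGRdim (one degree of freedom, kGRdim held fixed),
    and the Hill coefficient h is fixed at 2.  That leaves 46 free
    parameters, the length of the fit vector q.
    """
    import pandas as pd

    roles = {}
    for n in ("kdiff1", "k1ex", "k2in", "k2ex", "k3in", "k3ex"):
        roles[n] = "transport/diffusion"
    for i in range(1, 16):
        roles[f"d{i}"] = "degradation"
    for n in ("kGRC", "kGRdim", "kCRC", "kGC2"):
        roles[n] = "dissociation constant"
    for n in ("K1", "K3", "K4", "K5", "K6", "K7", "K8", "K9"):
        roles[n] = "Michaelis-Menten constant"
    for n in ("v1", "v2", "v3", "v4", "v5", "v6", "v7", "v8", "ks", "ksb"):
        roles[n] = "limiting/production rate"
    for n in ("ktl1", "ktl2"):
        roles[n] = "translation rate"
    for n in ("ktrs1", "ktrs2"):
        roles[n] = "mRNA transport rate"
    roles["h"] = "Hill coefficient"
    for n in ("V_in", "V_ex", "V_nu"):
        roles[n] = "compartment volume"
    roles["stress_basal"] = "basal stress level"

    rows = []
    for name, role in roles.items():
        if name in FREE_PARAM_NAMES:
            status = "free"
        elif name == "kGRdim":
            status = "fixed (enters only via kappa = kGRC^2*kGRdim)"
        elif name == "h":
            status = "fixed (h = 2)"
        elif name == "stress_basal":
            status = "input level, not a kinetic parameter"
        else:
            status = "fixed (phenomenological volume)"
        rows.append({"name": name, "role": role, "status": status})
    return pd.DataFrame(rows)


@dataclass
class ParsimoniousParams:
    """Rate/affinity constants of the 4-state reference model."""

    kc: float = 1.0
    ki1: float = 1.0
    kcd: float = 1.0
    ka: float = 10.0
    ki2: float = 1.0
    kad: float = 10.0
    kr: float = 4.0
    k: float = 0.5
    kcr: float = 0.05
    krd: float = 0.9
    ko: float = 1.0
    kod: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"parameter {f.name} must be finite and > 0")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParsimoniousParams":
        return cls(**d)

    def replace(self, **kwargs: float) -> "ParsimoniousParams":
        return dataclasses.replace(self, **kwargs)


PARSIMONIOUS_PARAM_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ParsimoniousParams)
)
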