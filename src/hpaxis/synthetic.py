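"""Synthetic AtT-20-like ACTH datasets and shipped parameter regimes.

The published ACTH stress-response measurements exist only as figures, so
this module generates datasets with the same structure and known ground
truth: two dose protocols on one cell culture (A: 10 nM CRH at t = 0;
B: 10 nM CRH + 100 nM cortisol at t = 0), sampled between 1 min and 1 h,
with heteroscedastic Gaussian noise and 95% confidence intervals from
replicate averaging.  The `invitro` ground-truth regime is a synthetic
parameter set tuned with this package's own tools to show the three
qualitative features of the experiment: an immediate ACTH rise under CRH
alone, a delayed but strong release around 15 min when cortisol is
co-administered, and an overall reduced ACTH level in the medium by 60
min.  It is not a reproduction of the measured data.

`make_fixture_regimes` returns the named parameter regimes used across
the analysis (hypo_switch, hyper_switch, oscillatory, invitro).  The
bifurcation regimes are cached results of the seeded discovery search;
each cache file records the generating seed and a verification summary,
and regeneration re-verifies against its regime target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .fitting import ActhDataset
from .params import ExtendedParams
from .simulate import run_dose_experiment

__all__ = [
    "GeneratorConfig",
    "generate",
    "make_fixture_regimes",
    "fixture_params",
    "DEFAULT_SAMPLE_TIMES",
    "FIXTURE_NAMES",
]

DEFAULT_SAMPLE_TIMES = (1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)

FIXTURE_NAMES = ("hypo_switch", "hyper_switch", "oscillatory", "invitro")


@dataclass
class GeneratorConfig:
    """Configuration of the two-protocol dataset generator.

    Noise: each sample is the mean of ``n_replicates`` draws with
    standard deviation ``max(sigma_abs, sigma_rel * value)``; the
    reported 95% CI half-width is ``1.96 * sd / sqrt(n)``.
    """

    params: ExtendedParams = None
    sample_times: tuple = DEFAULT_SAMPLE_TIMES
    sigma_rel: float = 0.08
    sigma_abs: float = 0.02  # nM
    n_replicates: int = 6
    seed: int = 0
    protocols: tuple = ("A", "B")

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = fixture_params("invitro")
        if self.sigma_rel < 0 or self.sigma_abs < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = np.asarray(self.sample_times, dtype=float)
        if np.any(t <= 0) or np.any(t > 60.0):
            raise ValueError("sample times must lie in (0, 60] min")


def generate(config: GeneratorConfig) -> ActhDataset:
    """Simulate both protocols at ground truth and add replicate noise."""
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times, dtype=float)
    protocols = {}
    for pid in config.protocols:
        truth = run_dose_experiment(config.params, pid, times)
        sd = np.maximum(config.sigma_abs, config.sigma_rel * truth)
        if config.sigma_rel == 0 and config.sigma_abs == 0:
            mean, ci = truth.copy(), np.zeros_like(truth)
        else:
            reps = truth[None, :] + sd[None, :] * rng.standard_normal(
                (config.n_replicates, times.size)
            )
            mean = reps.mean(axis=0)
            ci = 1.96 * sd / np.sqrt(config.n_replicates)
        protocols[pid] = {"times": times.copy(), "values": mean, "ci": ci}
    return ActhDataset(
        protocols=protocols,
        meta={
            "ground_truth": config.params.to_dict(),
            "seed": config.seed,
            "sigma_rel": config.sigma_rel,
            "sigma_abs": config.sigma_abs,
            "n_replicates": config.n_replicates,
            "synthetic": True,
        },
    )


# ---------------------------------------------------------------------------
# fixture regimes
# ---------------------------------------------------------------------------


def _fixture_path(name: str):
    return resources.files("hpaxis") / "fixtures" / f"{name}.json"


def _fixture_record(name: str) -> dict:
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid: {FIXTURE_NAMES}")
    path = _fixture_path(name)
    with resources.as_file(path) as p:
        return json.loads(Path(p).read_text())


def _fixture_params(name: str) -> ExtendedParams:
    return ExtendedParams.from_dict(_fixture_record(name)["params"])


def fixture_params(name: str) -> ExtendedParams:
    """Load a shipped named parameter regime."""
    return _fixture_params(name)


def make_fixture_regimes(seed: int | None = None, regenerate: bool = False) -> dict:
    """Named parameter regimes {hypo_switch, hyper_switch, oscillatory, invitro}.

    By default returns the shipped cached sets (each cache records the
    seed of the discovery run that produced it).  With
    ``regenerate=True`` the bifurcation regimes are re-discovered with
    their recorded seeds (or ``seed`` if given) and re-verified; a
    fixture that no longer verifies raises, naming the stale entry.
    """
    from .discovery import RegimeTarget, search_regime, verify_regime

    out = {}
    for name in FIXTURE_NAMES:
        rec = _fixture_record(name)
        params = ExtendedParams.from_dict(rec["params"])
        if name == "invitro":
            out[name] = params
            continue
        target_kind = rec["target_kind"]
        if regenerate:
            use_seed = rec["seed"] if seed is None else seed
            result = search_regime(
                RegimeTarget(kind=target_kind), seed=use_seed,
                n_starts=rec.get("n_starts", 40),
            )
            ok, _ = verify_regime(result.params, RegimeTarget(kind=target_kind))
            if not ok:
                raise RuntimeError(f"stale fixture {name!r}: regeneration failed")
            out[name] = result.params
        else:
            out[name] = params
    return out
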