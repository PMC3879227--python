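"""Two-step regularised fitting and sparsity-based structure selection.

Generates a noiseless two-protocol ACTH dataset from the invitro ground
truth with the GR autocatalytic loop silenced, then runs the two-step
fit: a Tikhonov step (p = 2) gives q_tik, a sparsity-enforcing step
(p = 0.9) started at q_tik gives q*.  Because the silenced loop leaves
no signature in the data, the sparse step drives the loop parameters
(ktrs2, v7, v8, d15, d11) toward zero while the identifiable release
and transcription parameters keep ratios near one — the relevance
ranking q*/q_tik selects the model structure the data support.  The
cellular initial states are fixed at the resting state of the culture
(the same convention the generator uses); a separate driver
(05) exercises the noisy, model-comparison setting.
Writes results/fit_relevance_ratios.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import hpaxis as h
from hpaxis.fitting import FitProblem, fit_two_step
from hpaxis.simulate import default_invitro_initial
from hpaxis.synthetic import GeneratorConfig, fixture_params, generate

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

GR_LOOP = ("ktrs2", "v7", "v8", "d15", "d11")


def main(seed: int = 1):
    truth = fixture_params("invitro")
    truth_silenced = truth.replace(v7=1e-6, v8=1e-6)
    ds = generate(GeneratorConfig(params=truth_silenced, sigma_rel=0.0,
                                  sigma_abs=0.0, seed=seed))
    ds.to_csv(OUT / "synthetic_acth.csv")

    rest = default_invitro_initial(truth_silenced)
    fixed = {n: float(v) for n, v in zip(h.STATE_NAMES, rest)
             if n not in ("COR_ex", "CRH", "ACTH_ex", "GPCR", "CRHR")}
    names = GR_LOOP + ("k1ex", "v6")
    prob = FitProblem(dataset=ds, alpha=1e-4, p=2.0, free_names=names,
                      estimated_ic=(), fixed_ic=fixed, base_params=truth,
                      n_starts=2, max_nfev=30, seed=seed)
    res = fit_two_step(prob)
    rows = [{"param": n, "q_tik": res.q_tik[n], "q_star": res.q[n],
             "ratio": res.ratios[n], "gr_loop": n in GR_LOOP}
            for n in names]
    df = pd.DataFrame(rows).sort_values("ratio")
    df.to_csv(OUT / "fit_relevance_ratios.csv", index=False)
    print("Two-step fit on noiseless synthetic data (GR loop silenced "
          "in the generator):")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    loop_max = max(res.ratios[n] for n in GR_LOOP)
    print(f"\nGR-loop ratios q*/q_tik all below {loop_max:.3g}: the sparse "
          "step identifies the silenced pathway as negligible")
    print(f"identifiable parameters keep ratios near one "
          f"(k1ex: {res.ratios['k1ex']:.3f}, v6: {res.ratios['v6']:.3f})")
    print(f"data misfit at solution: {res.data_misfit:.3g}")
    print(f"wrote {OUT / 'fit_relevance_ratios.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
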