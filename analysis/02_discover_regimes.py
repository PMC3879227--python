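"""Seeded discovery of the three qualitative regimes of the model.

Runs the eigenvalue-objective search for (a) the hypocortisolism
irreversible switch, (b) the hypercortisolism irreversible switch with
inverted branch alignment, and (c) a stable limit cycle, each within the
package's documented log-space search boxes, and verifies every result
by continuation / limit-cycle detection.  Writes the parameter sets and
a summary table under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from hpaxis.discovery import RegimeTarget, search_regime

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 1):
    rows = []
    for kind, label in (
        ("fold_bistable_hypo", "hypo_switch"),
        ("fold_bistable_hyper", "hyper_switch"),
        ("hopf_oscillatory", "oscillatory"),
    ):
        target = RegimeTarget(kind=kind, basal_stress=0.1)
        result = search_regime(target, n_starts=24, seed=seed)
        result.params.to_json(OUT / f"regime_{label}.json")
        row = {"regime": label, "seed": seed, **result.summary}
        rows.append(row)
        print(f"{label}: {result.summary}")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "discovered_regimes.csv", index=False)
    print(f"wrote {OUT / 'discovered_regimes.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
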