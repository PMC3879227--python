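# hpaxis

A compartmental kinetic model of the anterior pituitary gland cell
embedded in the hypothalamic–pituitary–adrenal (HPA) axis, with the
analysis stack built on it: stiff simulation of stress and dose
protocols, pseudo-arclength bifurcation analysis, sparsity-regularised
fitting to ACTH time courses, in-silico pathway knockouts, and sparse
inverse-bifurcation correction of an irreversible switch.

The package is for systems biologists and applied mathematicians who
study endocrine feedback: it separates **genomic** glucocorticoid
feedback (cortisol–GR homodimers acting as nuclear transcription
factors on the POMC and GR genes; minutes to hours) from **non-genomic**
feedback (a membrane glucocorticoid receptor that cooperatively binds
two cortisol molecules and inhibits ACTH vesicle release within
seconds), plus the CRH-receptor pathway that stimulates both release
and POMC transcription. Nucleus and cytoplasm are distinct
compartments; fast receptor binding and GR dimerisation are closed as
quasi-equilibria. The resulting ODE system has 15 states and 46 free
parameters,

    dx/dt = f(x, q; S),

with the dimensionless stress level `S` driving CRH production through
`ks (ksb + S) / (1 + [COR_ex]/K3)`, Michaelis–Menten and
competitive-inhibition kinetics throughout, and a shared nuclear
transport flux F coupling free cortisol and free GR to the nuclear
dimer pool. The classical 4-state model (CRH, ACTH, GR, COR with the
closure `[COR-GR] = [COR]·[GR]`) is included as the reference.

Its dynamic repertoire contains two distinct bistable switches — one
trapping the axis at *low* cortisol (hypocortisolism) and one, with
inverted branch alignment, trapping it at *elevated* cortisol
(hypercortisolism) — as well as stable limit-cycle oscillations.
A switch is *irreversible* when the return limit point LP2 of the
equilibrium branch lies below the basal stress level (0.1 on the
fictive scale): after a transient stressor the axis cannot return.

## Layout

* `src/hpaxis/` — the library: `models` (right-hand sides, knockouts),
  `simulate` (stiff integration, dose events, stress protocols),
  `bifurcation` (equilibria, Jacobians, continuation, limit points,
  Hopf points, limit cycles), `discovery` (eigenvalue-objective regime
  search), `fitting` (two-step Tikhonov → sparse estimation),
  `inverse` (fold-sensitivity correction), `synthetic` (datasets and
  shipped regimes).
* `analysis/01…06_*.py` — numbered drivers that run the full analysis
  and write tables under `results/`.
* `docs/methods.md` — model equations, closures, numerical methods,
  design choices and limitations.

## Worked example

Simulating the two cell-culture dose protocols (A: 10 nM CRH at t = 0;
B: 10 nM CRH + 100 nM cortisol) on the shipped `invitro` regime:

```
$ python analysis/01_simulate_protocols.py
Two-protocol simulation on the invitro regime
  A (CRH only):        ACTH at  2 min = 0.113 nM (immediate rise), at 60 min = 1.962 nM
  B (CRH + cortisol):  release-rate peak at 14.8 min (delayed burst), ACTH at 60 min = 0.795 nM
  final reduction: B(60)/A(60) = 0.40 (genomic feedback lowers the medium ACTH)
```

Under CRH alone, ACTH rises immediately. Co-administered cortisol
activates the membrane receptor and suppresses release; as the bolus is
absorbed the inhibition lifts and the accumulated vesicular ACTH is
released in a burst near 15 min; by 60 min the genomic feedback has
repressed POMC and the medium ACTH ends at 40% of the CRH-only level.

Discovering and verifying the dynamic regimes:

```
$ python analysis/02_discover_regimes.py --seed 1
hypo_switch:  {'kind': 'irreversible_bistable', 'orientation': 'hypo',
               'S1': 0.4689, 'S2': 0.0231}
hyper_switch: {'kind': 'irreversible_bistable', 'orientation': 'hyper',
               'S1': 0.5632, 'S2': 0.0672}
oscillatory:  {'period': 185.7, 'phase_order': ('CRH', 'ACTH_ex', 'COR_ex')}
```

Both switches have their return fold below the basal level 0.1
(irreversible); the limit cycle's hormone maxima follow the release
cascade CRH → ACTH → cortisol with a period of about three hours.
`analysis/03…06` trace the bifurcation diagrams and dysfunctional
stress responses, fit the model variants to synthetic two-protocol
data (the full model beats the membrane-receptor knockout and the
4-state reference), rank parameter relevance by the two-step sparse
fit, and correct the hypercortisolism switch.

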