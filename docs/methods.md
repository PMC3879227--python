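# Methods

## The model

`hpaxis` implements a compartmental kinetic model of the anterior
pituitary gland cell embedded in the hypothalamic–pituitary–adrenal
(HPA) axis. The axis's forward cascade — stress-driven CRH secretion,
CRH-triggered ACTH release from the pituitary, ACTH-driven cortisol
output — is closed by glucocorticoid feedback acting on two separated
time scales:

* **genomic feedback** through the intracellular glucocorticoid
  receptor GR: free cytoplasmic cortisol binds GR, the complex
  homodimerises, the dimer is imported into the nucleus where it
  represses POMC transcription (less ACTH precursor) and enhances GR
  transcription (an autocatalytic loop);
* **non-genomic feedback** through a membrane glucocorticoid receptor
  (GPCR) that cooperatively binds two extracellular cortisol molecules
  and inhibits ACTH vesicle release within seconds;
* **CRHR feedback**: extracellular CRH acts through its membrane
  receptor both non-genomically (catalysing ACTH release, in
  competition with the GPCR complex) and genomically (inducing
  transcription factors, TFs, that drive POMC expression).

The state vector has 15 concentrations (nM): extracellular cortisol,
CRH and ACTH; cytoplasmic cortisol, vesicular ACTH, the receptors GPCR,
CRHR and GR; the nuclear GR–cortisol dimer; POMC and GR mRNA
(cytoplasmic) and pre-mRNA (nuclear); and TFs in cytoplasm and nucleus.
Time is in minutes; the stress input is dimensionless on a fictive
scale with basal level 0.1. Michaelis–Menten kinetics describe the
enzymatic steps, competitive-inhibition denominators
`K (1 + I/K_I) + S` the antagonistic transcription-factor and
release controls, and a Hill factor (exponent `h = 2`) the signalling
cascade from the CRH receptor complex to TFs production.

### Quasi-equilibrium closures

Receptor–ligand binding and GR dimerisation are fast compared with
every other process, so the membrane complexes and the cytoplasmic
dimer are closed algebraically instead of receiving ODEs:

    [CRHR-CRH]    = CRHR · CRH / kCRC
    [GPCR-(COR)2] = GPCR · COR_ex^2 / kGC2      (cooperative square law)
    D_cyt         = COR_in^2 · GR^2 / kappa,    kappa = kGRC^2 · kGRdim

### The nuclear transport flux F

The net rate of change of free cytoplasmic cortisol (equally, of free
GR) due to nuclear transport of the dimer is

    F = (COR_in · GR · (COR_in + GR) / kappa)
        · (k_bar · k2ex · D_nu  −  k2in · D_cyt),     k_bar = V_nu / (2 V_in).

Derivation sketch: with the fast-binding closure, adding or removing
dimer redistributes between free and bound pools; projecting the
transport source `k_bar·k2ex·D_nu − k2in·D_cyt` onto the free species
through the equilibrium relations yields a prefactor polynomial
`COR_in·GR·(COR_in+GR)/kappa` that vanishes when either free species is
absent. The flux has units nM/min, vanishes exactly at the transport
equilibrium `k_bar·k2ex·D_nu = k2in·D_cyt`, and enters the cortisol and
GR balances with one shared value. The nuclear dimer balance is
`dD_nu/dt = k2in·D_cyt − (k2ex + d9)·D_nu`; the degradation `d9` makes
the dimer route a net drain on both free cortisol and free GR — a
mechanism that matters below.

### Parameter bookkeeping (the 46)

The equations contain 48 kinetic symbols besides the three compartment
volumes (phenomenological, fixed at 1):

| block | symbols | count |
|---|---|---|
| transport/diffusion | kdiff1, k1ex, k2in, k2ex, k3in, k3ex | 6 |
| degradation | d1 … d15 | 15 |
| dissociation constants | kGRC, kGRdim, kCRC, kGC2 | 4 |
| Michaelis–Menten constants | K1, K3 … K9 | 8 |
| limiting/production rates | v1 … v8, ks, ksb | 10 |
| translation / mRNA transport | ktl1, ktl2, ktrs1, ktrs2 | 4 |
| Hill coefficient | h | 1 |

Two of these carry no independent information: kGRC and kGRdim enter
the dynamics only through `kappa = kGRC^2 · kGRdim` (kGRdim is held
fixed), and the Hill coefficient is fixed at 2. The free-parameter
vector `q` therefore has length **46**
(`hpaxis.free_parameter_table()` prints the full reconciliation).

The 4-state reference model (CRH, ACTH, GR, COR with the closure
`[COR-GR] = COR·GR`) is implemented alongside for the model-comparison
experiments.

## Simulation

Stiff integration uses `scipy.integrate.solve_ivp` (BDF, default
rtol 1e-8 / atol 1e-10), restarting at every dose time and stress-pulse
edge. Doses are instantaneous jumps of an extracellular concentration
(bolus administration into the medium); the jump is applied after
recording the pre-dose value at the event time, except at t = 0 where
the post-dose state is the initial condition.

The two in-vitro protocols are A: 10 nM CRH at t = 0 and B: 10 nM CRH
plus 100 nM cortisol at t = 0, read out as extracellular ACTH over one
hour. In the cell-culture setting there is no hypothalamus and no
adrenal gland, so `invitro_variant` removes both the stress-driven CRH
production and the ACTH-driven cortisol production; everything cellular
is untouched. Whether medium degradation of ACTH (d3) is active remains
a parameter of the protocol (kept active by default).

## Bifurcation analysis

Equilibria are solved by damped Newton in log-concentration space
(positivity enforced; offset floor 1e-12 nM; `max|rhs| < 1e-10`).
Jacobians use complex-step differentiation (machine-precision accurate;
cross-checked against central differences). Branches are traced by
pseudo-arclength continuation in `(log x, stress)` with secant
predictors, Newton correctors and adaptive step control.

* **Limit points** are bracketed by a sign change of the stress
  component of the branch tangent (equivalent to the det-J sign change
  along arclength for folds, and insensitive to Hopf crossings) and
  sharpened by bisection to abscissa tolerance 1e-6. At a located fold
  the smallest-|Re| eigenvalue is below 1e-6.
* **Hopf points** are bracketed by a sign change of the largest real
  part over complex eigenvalue pairs, with the pair frequency reported.
* **Switch classification**: no folds → monostable; two folds with
  abscissas S1 (first met from the basal branch) and S2 (return fold) →
  bistable, irreversible iff S2 < basal stress. Orientation compares
  extracellular cortisol of the two outer branch segments at the
  mid-window stress: *hyper* when the branch reached by increasing
  stress past S1 runs at higher cortisol (inverted alignment), *hypo*
  otherwise.
* **Limit cycles** are characterised by long integration with peak
  recurrence (period = mean inter-peak interval, amplitudes over the
  final periods, phase order of the CRH/ACTH/cortisol maxima anchored
  at the final cortisol peak) rather than collocation/Floquet — enough
  for the qualitative claims made here; a decaying oscillation returns
  `sustained=False` rather than raising.

## Regime discovery and the shipped regimes

`search_regime` samples seeded Sobol points in a log-space box around a
documented anchor, ranks them by an eigenvalue objective (squared
smallest-magnitude real eigenvalue along the branch for fold targets,
squared real part of the least-damped complex pair with a frequency
floor for Hopf targets, plus hinge penalties on fold positions and
orientation), refines the best candidates by Nelder–Mead, and accepts
only candidates verified by full continuation — for fold targets this
includes requiring two distinct stable attractors at basal stress, so
an oscillatory "healthy state" never passes as a switch. Failures are
bounded-budget, seeded negative results, not proofs.

The published analysis reports no parameter values, so the anchors are
this package's own. They were found in three steps: (1) a reduced
analysis of the GR subsystem at fixed cytoplasmic cortisol c, scanning
for parameter sets whose GR balance is bistable over a window of c;
(2) random screening of hormone-cascade parameters attached to those
designs, counting coexisting equilibria along the stress axis; (3)
local tuning of fold positions. The mechanisms of the three regimes:

* **hypo_switch** — the GR autocatalytic loop (nuclear dimer → GR
  transcription → more GR → more dimer) makes the GR subsystem
  bistable; a stressor raises cortisol, flips GR to its high branch,
  and the resulting POMC repression plus dimer-mediated cortisol drain
  hold the axis at low cortisol (folds at S1 ≈ 0.47, S2 ≈ 0.023 with
  basal 0.1; cortisol drops about two-fold).
* **hyper_switch** — a double-negative loop: high cortisol drains free
  GR through dimer import and nuclear degradation (c ⊣ G) while GR
  represses cortisol production through POMC (G ⊣ c). The
  elevated-cortisol state is self-sustaining only because the
  CRH-driven genomic induction of POMC keeps ACTH production alive at
  high cortisol — which is why the search fails under the
  CRH-genomic-feedback knockout (the bounded-budget negative result).
  Folds at S1 ≈ 0.56, S2 ≈ 0.067, inverted branch alignment, five-fold
  cortisol contrast at basal.
* **oscillatory** — a relaxation-type cycle: the fast subsystem is
  bistable in the slowly varying GR mRNA, and on each fast branch the
  mRNA drifts out of that branch's existence window. Slowing the
  GR-gene-expression block (an equilibria-preserving common scaling of
  v7, v8, ktrs2, d15, d11) converts the bistable regime into a limit
  cycle (period ≈ 3 h) flanked by two genuine Hopf points; within one
  period the maxima follow the cascade CRH → ACTH → cortisol. A pure
  negative-feedback (Goodwin-type) oscillation is not reachable here
  with Hill coefficient 2: the product of stage elasticities around
  the loop (≤ 2 from the Hill stage, < 1 from every saturable stage)
  stays below the instability threshold for the loop length.
* **invitro** — tuned by feature screening to show the experiment's
  three qualitative signatures: an immediate ACTH rise under CRH alone;
  under co-administered cortisol a suppressed early release (GPCR
  inhibition) followed by a burst near 15 min as the cortisol bolus is
  absorbed and the inhibition lifts; and a reduced ACTH level at 60 min
  as the genomic feedback represses POMC. It is a synthetic regime,
  not a reproduction of the measurements.

All four are shipped as JSON fixtures with generating seeds and
verification summaries; `make_fixture_regimes(regenerate=True)`
re-discovers and re-verifies them.

## Fitting

The estimation problem minimises the squared mismatch between simulated
and measured extracellular ACTH of both protocols plus
`alpha * sum_i |q_i|^p`, over the kinetics `q` and the initial states.
The two protocols share one cellular baseline (same culture); the dosed
species are fixed by the protocol (CRH = 10 nM; COR_ex = 0 or 100 nM;
medium ACTH = 0); unknown cellular species are estimated in [0, 1e3] nM.
Residuals are divided by the 95% CI half-widths when available (flag to
disable). Optimisation runs in log-parameter space (positivity) with
`scipy.optimize.least_squares` (TRF), the penalty appended as residual
rows.

The two-step scheme: a seeded multi-start Tikhonov fit (p = 2) gives
`q_tik`; a local sparsity-enforcing fit (p = 0.9, smoothed as
`(q^2 + eps^2)^{p/2}` with an eps-continuation 1e-1 → 1e-6) started at
`q_tik` gives `q*`. The componentwise ratio `q*/q_tik` ranks model
components: for |q| < 1 the p = 0.9 penalty is orders of magnitude
stronger than the p = 2 one, so parameters the data do not constrain
collapse in step 2 while staying finite in step 1. Regularisation
weights are fixed, documented defaults per experiment (alpha = 1e-4 for
the structure-selection experiment; 1e-5 where the penalty is only a
stabiliser): at the desk-scale budgets used here a discrepancy-type
grid search added cost without changing any outcome.

## Inverse bifurcation correction

The hypercortisolism switch is corrected by solving

    min_x ||(S1(q0), S2*) − F(q0 + x)||^2 + alpha * phi(x/q0),   p = 0.9 < 1,

where F maps parameters to the two fold abscissas, S2* = basal + 0.05,
and S1 is maintained through the least-squares term (no hard
constraint). Moves are multiplicative (log-space), the penalty acts on
relative changes. Gradients use the exact saddle-node sensitivity
`dS/dq_j = − w^T f_{q_j} / (w^T f_S)` with `w` the left null vector of
the Jacobian at the fold, so one iteration costs one continuation plus
cheap directional derivatives. A damped Gauss–Newton/IRLS loop with
backtracking keeps the accepted-iterate objective monotone; smoothing
eps is reduced 1e-1 → 1e-4 on stagnation. Support is reported at the 1%
relative-change threshold; the sparse (p = 0.9) support never exceeds
the ridge (p = 2) support at the same target in the shipped
experiments.

## Synthetic data

Each sample is the mean of n replicate draws with standard deviation
`max(sigma_abs, sigma_rel * value)` (defaults 0.02 nM and 8%, n = 6;
independent Gaussian — the experimental figures show symmetric 95%
CIs, no distributional information beyond that); the reported CI
half-width is `1.96 * sd / sqrt(n)`, so CI widths scale as `1/sqrt(n)`.
Sample times default to {1, 2, 5, 10, 15, 20, 30, 45, 60} min — the
published protocol states only "1 minute to 1 hour". What passing
tests show about real data is therefore limited: the generator emulates
protocol structure, heteroscedastic replicate noise and CI reporting,
but not assay-specific error, cell-to-cell variability, or day effects.

## Numerical choices and problem sizes

* Equilibrium tolerance 1e-10 (max-norm of the rhs); fold/Hopf abscissa
  bisection tolerance 1e-6; continuation steps 0.01–0.05 arclength
  units, at most 1500 points per branch.
* Limit-cycle detection: 4000–8000 min transient + observation windows,
  prominence-gated peak detection; periods are stable to < 1% under
  horizon doubling.
* Discovery runs use 8–24 Sobol starts with 1–3 Nelder–Mead
  refinements; fitting runs use 2–4 multi-starts with 30–60
  least-squares evaluations per stage and 5–13 free parameters per
  experiment. These problem sizes are the package's desk-scale
  defaults; every driver accepts larger budgets.
* Degenerate inputs: states at the 1e-12 nM floor are treated as zero;
  integration failures inside fitting return a large finite objective
  (1e12) with a failure flag instead of raising.

## Known limitations

* Stress, and therefore the fold abscissas, live on a fictive scale;
  only their relation to the basal level 0.1 is meaningful.
* The fixture regimes are illustrative points of the model's dynamic
  repertoire, not fitted to any organism; the discovery boxes are
  local (half-width 10^0.3), so the negative knockout result is a
  statement about this box and budget.
* Limit cycles are characterised by simulation, not collocation: no
  Floquet multipliers, and narrow oscillatory windows may be missed.
* The observation model for fitting is the identity on extracellular
  ACTH; scaling/offset of a real assay would need an explicit
  observation map.
* No delay differential equations, circadian forcing, SBML I/O, or
  codimension-two bifurcation analysis.
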