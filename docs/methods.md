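# Methods

## Model

The package simulates systemic antitumor immunity triggered by localized
radiotherapy — the abscopal effect — in a mouse bearing two subcutaneous
tumors of which only the first (T1) can be irradiated.  It couples two
layers:

**PBPK scaffold.**  A whole-body compartment network of ten organs (lungs,
liver, GI tract, spleen, heart, kidneys, skin, muscle, bone, lymph nodes)
plus the two tumors, each split into a vascular and an interstitial
sub-compartment, joined by arterial and venous mixing pools in the standard
series arrangement (venous blood → lungs → arterial blood → systemic
tissues → venous blood).  Six cell populations traffic through this network
— dendritic cells (DC), pro- and anti-inflammatory macrophages (M1, M2),
regulatory T cells (Treg), effector CD8⁺ T cells (TE1), and antigen-
presenting cells (APC).  Transport is linear in cell counts: vascular
balance `Q_i (C_art − C_vasc,i)`, first-order extravasation and lymph exit,
lymph collected by the lymph-node interstitium, and the nodal efferent
returning to venous blood.  Plasma flow balance is exact by construction
(the lung flow equals the total systemic flow plus lung lymph) and is
asserted by validation.  Naive CD8⁺ T cells (TN) live only in the
lymph-node interstitium; viable and dead tumor cells (TV, TD) only in the
tumor interstitia.  State entries are absolute counts, which makes
conservation checks exact.

**QSP core.**  In each tumor interstitium, mass-action kinetics couple the
tumor to the immune system:

- intrinsic exponential growth `dTV/dt ⊃ lg_tumor · TV`;
- cytolysis `k_rc1 · [TE1] · TV / (1 + s_Treg·[Treg] + s_M2·[M2])`, which
  converts viable cells to dead cells (TV → TD);
- phagocytosis of viable cells and of debris by DC (+APC, sharing the DC
  rate constants) and M1, with matched maturation fluxes DC→APC and
  M1→APC — one phagocytic encounter removes one tumor cell and matures one
  phagocyte, so the bookkeeping balances exactly;
- first-order debris clearance `Clear_c_dead · TD` (leaves the system).

In the lymph nodes, APC drive naive-to-effector priming
`k_TN · [APC]_LN · TN`, each activated naive cell yielding `N_exp` effector
cells (aggregate clonal expansion), while the naive pool regenerates
logistically toward its baseline `TN0` at rate `k_prol_TN`.

**Radiotherapy.**  Dose fractions are instantaneous linear-quadratic
events: a tumor fraction moves `(1 − exp(−(a_c·D + b_c·D²)))·TV` into the
dead pool; a lymph-node fraction multiplies the nodal APC, TN and TE1
pools by `exp(−(a_IM·D + b_IM·D²))` (resident DC and macrophages are not
in the depleted set).  The three experimental arms are: control; 10 Gy to
T1 on day 10; the same plus 3 Gy to the draining nodes on days 10, 13, 16.
The treatment-arm switch of the two radiation-boosted parameters
(`k_TN`, `k_rc1`) follows delivered dose, so a protocol with all fractions
zeroed reproduces the control trajectory exactly.

## Parameters and units

Time is in days, volumes in mL (tumor volumes reported in mm³), cell
amounts as counts, concentrations as counts/mL against the relevant
sub-compartment volume.  Tumor sub-volumes scale with the instantaneous
tumor volume (vascular 7%, interstitial 50% of V(t)), floored at 1 mm³ so
concentrations and washout stay defined as a tumor regresses; the packed
cell volume is 1e−6 mm³ (1e6 cells per mm³), so the implant `Vi_tumor0`
maps to an initial count `Vi_tumor0 / v_cell`.

The calibrated subset comprises the tumor-intrinsic parameters
(`lg_tumor`, `Vi_tumor0`), phagocytic rate constants for viable and dead
cells (`Ac_DC`, `Ac_M1`, `Ac_dead_DC`, `Ac_dead_M1`), debris clearance
(`Clear_c_dead`), naive-pool regeneration (`k_prol_TN`), the two LQ pairs
(`a_c`, `b_c`; `a_IM`, `b_IM`), and the arm-dependent activation and
cytolysis constants (`k_TN`, `k_rc1`), stored as control/RT pairs — all
other parameters are shared across arms by construction of the type.

The shipped default values live in one versioned JSON
(`src/abscopal/data/default_parameters.json`); the murine physiology table
(organ volumes, plasma flows at standard mouse PBPK reference magnitudes,
fixed vascular/interstitial fractions of 7%/20%, lymph flows at 0.2% of
plasma flow) lives in one versioned CSV.  The exact transport-constant and
kinetic values are this package's own documented parameterization: they
were chosen so that, at defaults, the model reproduces the qualitative
experimental pattern — near-exponential control growth reaching ~2000 mm³
by day 24 from a 30 mm³ implant, strong local control of the irradiated
tumor, a clear abscopal slowing of the distant tumor, and attenuation of
that abscopal response when the draining nodes are also irradiated.

Two deliberate regime choices deserve emphasis:

- **Phagocytosis operates in its linear regime.**  The per-DC maturation
  rate `Ac_DC · [TV]` is ≈0.5/day at defaults, below the DC exit and death
  rates, so APC production responds proportionally to `Ac_DC` instead of
  saturating at the DC influx limit.  This keeps the phagocytic rate
  identifiable from growth-curve data.
- **Priming consumes the naive pool only negligibly in unirradiated
  nodes.**  The activation flux is ~1e−6/day of the pool, so TN stays
  pinned at TN0 unless nodal irradiation depletes it; effector output is
  carried by the large expansion factor instead.  Consequently the
  regeneration rate `k_prol_TN` is inert in the control and
  tumor-only-RT arms and becomes decisive exactly when the nodes are
  irradiated — the lymphoid-recovery signature the sensitivity analysis
  measures.

Immune turnover (zero-order sources into venous blood, first-order death)
sets tumor-free steady-state pools of order 1e6 cells per circulating
species.  Because the tumor-free system is linear, the pre-treatment
immune state is obtained by a direct linear solve rather than a burn-in
integration, and the implant is placed into that steady state at day 0.

## Numerics

The stiff system (161 states) is integrated with SciPy's BDF method at
rtol 1e−6 by default; the Jacobian supplies the exact constant transport
matrix plus finite-difference corrections on the ~30 columns the nonlinear
terms touch.  Integration stops at every scheduled fraction, applies the
LQ transformation, and restarts; output lands on a uniform 0.25-day grid
(all time-integral statistics are defined by the trapezoid rule on this
grid, so they are exactly reproducible).  Per-state absolute tolerances
are 1e−6 × (initial species total + 1) because counts span many orders of
magnitude.  Small solver undershoots below zero are clamped — the slack is
the larger of 1e−9 relative to the state's excursion and ten times its
absolute tolerance, which covers the benign sub-cell dips that occur while
an irradiated tumor approaches extinction; larger negatives raise an
error.  Two stiff methods at different tolerances agree on tumor volume to
well under 0.5%, which bounds the numerical error relevant to the
analyses.  Calibration objective evaluations use the cheaper LSODA /
rtol 1e−4 / 1-day-grid setting — accuracy there is limited by data noise,
not the solver — while all reported analyses use the default setting.

## Calibration

The objective is the sum of squared errors between simulated and observed
tumor volumes plus a weighted SSE on empirical growth rates (central
differences of the volume measurements, applied identically to data and to
the simulation sampled at the measurement days).  The default weight
normalizes the two terms by their control-group data variances; it is
exposed in the configuration.  One simulation per treatment arm serves
every subject curve in that arm (individual curves enter the objective,
not group means).  Optimization runs in log-parameter space with a
real-coded genetic algorithm: tournament selection, blend crossover,
Gaussian mutation with a geometrically annealed step size, and elitism;
bounds are drawn adaptively around the initial population with an
independent Uniform(0, 10%) outward expansion per parameter in log space,
so the search is never trapped at preset limits while the initial
population always remains feasible.  An optional Nelder–Mead refinement
from the GA optimum (a hybrid step in the style of population optimizers'
local-polish options) is available for the narrow curved valleys that
defeat isotropic mutation; it respects the same bounds.

Uncertainty comes from stratified bootstrap: whole subject-tumor curves
are resampled with replacement within each (group, tumor) stratum,
preserving stratum sizes exactly, and the model is refitted per replicate
with the baseline and prior replicate optima seeding the initial
population.  Ensemble statistics (mean, median, sd, 90% CI per parameter;
median/90% CI trajectory bands) summarize the replicates.

**Identifiability.**  Because effector output is linear in the priming
rate while the naive pool stays pinned, tumor-volume data constrain the
two radiation-boosted parameters within an arm only through the product
`k_TN · k_rc1`; the same antigen-flow argument links `Ac_DC` with the
downstream pair.  The desk-scale recovery exercises therefore free one
member per arm (`k_tn_rt` from the treated arm, `k_rc1_control` from the
control arm) together with `lg_tumor` and `Ac_DC`, a combination the data
identify sharply.  The full 16-scalar fit remains available; its soft
directions simply inherit wider bootstrap intervals.

## Sensitivity and correlation analyses

One-at-a-time sweeps multiply a single parameter by {10, 1.5, 1.1, 0.9,
0.5, 0.1} around each baseline parameter set, simulate the arm, and
summarize the induced dispersion of an output (tumor volume, intratumoral
TE1 count, or intratumoral APC count; absolute counts by default, per
tumor) as the time-integrated total variance

    TotVar = Σ_i (1/T) ∫₀ᵀ (V_i(t) − V̄(t))² dt,

integrated by trapezoid on the output grid over the full horizon (T = 24 d
by default, configurable).  Per-baseline values strictly above the
significance threshold (10, in squared output units — in practice this
separates structurally inert parameter/arm combinations from real effects)
are averaged into a single score per parameter; a parameter that never
crosses the threshold in any baseline reports NaN.  Heatmap tables carry
log₁₀ of the aggregate.

The correlation analysis computes, per baseline and sweep level, the
time-averaged difference of an output between two arms, then the Spearman
rank correlation of those differences against the multiplier levels
(numeric multipliers; any strictly monotone transform of the levels gives
the same ranks).  For the small sweep sizes used (n ≤ 8) the two-sided
p-value is exact, by full enumeration of the n! rank permutations with
average ranks on ties (null distributions are cached per size).  A cell is
reported only when all per-baseline correlations share one sign and at
least 70% are significant at p < 0.05; the reported value is the mean of
all per-baseline ρ (alternative: mean over the significant subset, behind
a flag).  Cells whose differences are numerically constant across levels
(< 1e−12 spread) are flagged "no effect" and reported NaN rather than an
undefined ρ.  Each cell also carries the sign of the mean inter-group
difference (+Δ/−Δ), which fixes the biological reading of the correlation
direction.

When bootstrap refits are available their optima serve as the sweep
baselines.  At desk scale the test-suite and acceptance analyses instead
use a synthetic stand-in ensemble: the shipped defaults jittered
log-normally (σ = 0.05 per fitted scalar, seeded, baseline 0 unjittered),
emulating the spread of bootstrap optima without the cost of 50 refits.

## Synthetic cohorts

The generator emulates the bilateral-flank experiment's structure: three
arms × 8 mice × 2 tumors, measurements every 2–3 days to day 24 (schedule
{0, 3, 6, 9, 10, 12, 15, 18, 21, 24}, a configuration default rather than
a claim about the original schedule).  Each mouse draws log-normal
perturbations of `lg_tumor` and `Vi_tumor0` (σ = 0.15) — biological
inter-mouse variability — and its observed volumes carry multiplicative
log-normal measurement noise (σ = 0.20, chosen once as a realistic
high-variability level for caliper measurements of subcutaneous tumors).
Noise is multiplicative so errors scale with size and volumes stay
positive.  Everything is deterministic given the seed, and a truth sidecar
records the generating parameters and per-subject draws.

What the generator does *not* emulate: cage effects, sacrifice rules,
tumor-burden-dependent dropout, digitization error structure, or any
model-misspecification gap — synthetic cohorts are realizations of the
model itself plus noise.  Recovery and coverage results on these cohorts
therefore validate the estimation machinery, not the model's adequacy for
real measurements.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the pipeline at desk scale,
as the package's own default exercise sizes: sweeps over the four focus
parameters (`Ac_DC`, `k_rc1`, `k_TN`, `k_prol_TN`) with 5 jittered
baselines; correlation tables over representative parameter subsets with
2–3 baselines; GA recovery on a noise-free two-arm cohort with the
arm-identified free quadruple; bootstrap contracts at B = 10.  The same
functions scale to the full 14-parameter, 50-replicate analysis by
changing the configuration.

## Known limitations

- The interaction kernel's closed forms (bilinear mass action, saturating
  suppression denominator, logistic naive regeneration, exponential
  intrinsic growth) are committed defaults chosen to satisfy the known
  qualitative behavior; they are isolated behind the kernel functions in
  `dynamics.py` so alternative forms can replace them without touching the
  engine.
- Radiotherapy does not act on vasculature, cytokine signalling is not
  explicit (its net effect is folded into the arm-dependent `k_TN`,
  `k_rc1`), and there are no memory T cells, checkpoint pharmacology, or
  hypoxic subregions.
- Tumor plasma flow and transport rate constants are held at their
  reference values rather than remodelling with tumor growth; only the
  sub-compartment volumes scale with V(t).
- The `k_TN`/`k_rc1` product degeneracy within an arm is structural under
  the pinned-naive-pool regime; resolving both members of a pair requires
  either immune-cell observables in the objective or substantial naive-
  pool consumption.
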