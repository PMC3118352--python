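# Methods

## Model structure

The model tracks an adult female fathead minnow as six well-mixed
compartments: gill, brain, gonad, liver, venous blood, and "other" (the
remainder of the body).  Arterial blood is not an independent compartment:
arterial concentrations equal venous ones except where gill exchange adds
water-borne chemical.  Six chemical species are followed — 17β-estradiol
(E2), testosterone (T), 17α-ethynylestradiol (EE2), 17β-trenbolone (TB),
luteinizing hormone (LH), and vitellogenin (VTG) — as free concentrations
in the five non-gill compartments (nmol/L), plus receptor and
binding-protein complexes and two dynamically produced receptor pools
(liver ER, brain AR): 48 state variables in total.

### Transport

Each perfused compartment exchanges with blood under flow-limited kinetics,
`F_j (C_art − C_j/λ_j)`, with tissue:blood partition coefficients of 1
except liver:blood = 3 for the estrogens.  Cardiac output and gill water
flow are allometric (`2.06·BW^0.75` and `10.6·BW^0.75` L/hr).  Gill uptake
applies only to chemicals with a blood:water partition coefficient (E2 and
EE2 at 300; TB calibrated, default 7.47): the net flux is
`min(FW_gil, F_car·λ)·(C_water − C_ven/λ)`, the `min` enforcing that
exchange can never exceed what either the water or the blood stream can
carry.  The same term lets endogenous E2 leave across the gills when the
water is clean.

### Binding

All ligand–receptor and ligand–SBP interactions follow mass action with
association rate `k1` (L/nmol/hr) and dissociation rate `koff = k1·Kd`
(1/hr), so printed equilibrium constants are honoured exactly at
equilibrium (Langmuir isotherm).  Receptor pools in brain and gonad (ER),
gonad and liver (AR), gonad (LH receptor) and venous blood (SBP) have
fixed totals; their free concentration is total minus bound, by
construction, so these pools can neither leak nor overfill.  Liver ER and
brain AR are dynamic pools with production and turnover (below).

### Regulation

* **LH (brain):** production = `Mag_LH (1 + sin(2πt/24))
  (1 + C_ERbd/ρ_u) / (1 + C_ARbd/ρ_d)`.  The diurnal background has period
  24 h (t = 0 at lights-on), mean `Mag_LH`, and never goes negative.
  Bound ER stimulates, bound AR represses; both regulators carry
  concentration units, hence the hyperbolic forms.
* **Brain AR:** production = `Pbg_AR · K_AR / (K_AR + C_T + C_TB)` — free
  androgens repress AR synthesis; free AR turns over at `ke_AR`.
* **T (gonad):** bound LH sets StAR (`ρ_STAR`), StAR sets deliverable
  cholesterol (`ρ_Chol`), and a Hill function (exponent `n_T`, half point
  `K_0.5 = 190 nmol/L`) of cholesterol drives the capacity
  `sc_Vmax·BW^0.75`; gonad bound ER represses as `1/(1 + C_ERbd/K_T)`.
* **E2 (gonad and brain):** Michaelis–Menten aromatization of T
  (`Km = 9.6 nmol/L`), induced in the gonad by bound LH as
  `(1 + ρ_E2·C_LHLR)`; the brain enzyme has 4.6× the specific capacity on
  its (larger) microsomal protein pool but no LH induction.  Aromatization
  debits the local free-T pool mole-for-mole.
* **VTG (liver):** Hill in bound liver ER (`K_0.5 = 1 nmol/L`, exponent
  `n_VTG`), capacity `sc_Vmax_Vtg·BW^0.75`.
* **Liver ER:** production = `Pbg_ER + k_ER·C_ERbd` (estrogen induces its
  own receptor), turnover `ke_ER`.

Elimination is first-order in the "other" compartment for all six species
(0.1 /hr; VTG 0.001 /hr; TB deliberately shares the EE2 constant), and VTG
is additionally absorbed into oocytes at 0.05 /hr of its gonadal pool —
a pure sink representing yolk deposition.

**Dynamic receptor pools turn over as whole pools.**  The elimination
constants of liver ER and brain AR apply to the free receptor *and* its
ligand-bound complexes, degrading the bound ligand with the receptor
(receptor-mediated clearance).  With free-receptor-only turnover the
auto-induced liver ER loop has no finite steady state at the shipped
parameter values — ligand accumulates indefinitely into an ever-growing
complex pool — so pool-wide turnover is the structural closure adopted
here; it is also the physiologically standard picture (internalisation and
lysosomal degradation of occupied receptor).

## Parameters

97 constants (compartment percentages, flows, receptor totals, binding
constants, partition coefficients, elimination constants) and 26 calibrated
quantities: 17 structural parameters and 9 error variances.  Shipped
defaults set every calibrated parameter to its posterior mean.  Identities
are preserved by construction: `Kd_EE2ER = Kd_E2ER/RBA_EE2_E2`,
`Kd_TBAR = Kd_TAR/RBA_TB_T`, brain aromatase scaling = 4.6 × gonad, brain
microsomal protein = gonad / 0.174, liver AR total = gonad AR total.

Choices made where the source tables leave gaps:

* **Blood-flow fractions.**  The fractions of cardiac output perfusing
  brain/gonad/liver are set to 0.02/0.05/0.03 with "other" as the
  remainder, so perfusion exactly exhausts cardiac output.  These are
  conventional small-fish PBPK magnitudes; model outputs are insensitive
  to modest changes because all tissue:blood partitions are ≈1.
* **VTG molecular weight** for nmol/L → mg/ml conversion: 1.8×10⁵ g/mol
  (a typical teleost vitellogenin dimer), configurable.
* **Plasma conversion.**  Plasma steroid = (free + SBP-bound) venous
  concentration ÷ plasma fraction (0.45), × MW/1000 → ng/ml; VTG the same
  to mg/ml.  Steroids and their carrier reside in plasma, not blood cells,
  hence the division.
* **`K_T` units**: the printed 0.016 is read as nmol/L, consistent with
  every other regulation constant in the inhibition forms.

## Simulation

The stiff system is integrated with LSODA through a compiled (numba)
right-hand side; default tolerances rtol 1e-8 / atol 1e-12 nmol/L, with a
coarse profile (1e-5/1e-9) for sampling-intensive work.  Integration
restarts at exposure-segment boundaries so concentration steps never cross
a solver step.  Components inside (−atol, 0) are clamped to zero in rate
evaluations.  The **baseline** is the 24-hour periodic orbit of the
unexposed system (the diurnal LH cycle is the only forcing), found by
integrating from a small positive seed until consecutive daily snapshots
agree to 1e-6 (relative).  The slowest mode (the liver ER pool, relaxation
time ≈ 150 h) needs ≈ 3300 h from the generic seed, so the default search
horizon is 6000 h; warm-started searches (e.g. inside MCMC) converge in a
few windows.

## Calibration

Observed plasma endpoints are lognormal with geometric mean equal to the
model prediction; log-scale residuals are normal with one variance per
(exposure group × endpoint) cell — 9 cells.  The 17 structural parameters
are updated one at a time by random-walk Metropolis, walking in log space
for positive-support priors (uniform-prior parameters walk linearly), with
the log-transform Jacobian folded into the transformed-space posterior.
The 9 variances are redrawn exactly each sweep from their conjugate
inverse-gamma posteriors `IG(shape + n/2, scale + SS/2)`; cells without
data reduce to prior draws.  Proposal scales adapt toward a 0.23–0.44
acceptance window during the burn-in half and are frozen afterwards, so
kept iterations are Markovian.  Chains are deterministic given the run
seed (per-chain streams from `SeedSequence([seed, chain])`).  During
calibration each treatment group is simulated once per candidate with the
group's median physiology (median fill-in for missing values); exact
per-fish simulation is available as an option.

Full protocol defaults: 4 chains × 20,000 iterations, keep the last
10,000, thin by 10 → 4,000 pooled draws; Gelman–Rubin
`Rhat = sqrt((n−1)/n + B/(nW))` computed per quantity from the kept halves,
acceptable in [1.0, 1.2].

### Desk-scale protocol

`scaled_recovery_protocol()` ships the reduced experiment used by the
self-tests: a 21-day TB design cut to control + 0.05 + 0.5 µg/L with
n = 4 fish per group sampled on day 21, calibrating `λ_TB,bld`,
`RBA_TB_T` and `sc_Vmax_Vtg,liv` alongside all Gibbs variances, with
4 chains × 150 sweeps on the coarse solver.  These sizes keep a full
generate-calibrate-diagnose cycle to a few minutes on one CPU while the
chains still mix well (max Rhat ≈ 1.03 in the shipped configuration).

## Synthetic data

`generate_physiology` scatters body weight, GSI and HSI lognormally around
the population medians (0.0016 kg, 11%, 3%) with a common geometric SD
defaulting to 1.3 — a typical between-fish coefficient of variation of
~25–30% — and optional per-field missingness.  `generate_study` simulates
each fish deterministically under the true parameters (fish keep their
true physiology even when the recorded value is masked) and draws
observations from the lognormal error model with the group's variance; the
shipped generating variances are the posterior-mean values per group ×
endpoint.  The published designs are bundled (21-day TB at five doses
n = 12; 48-h static TB with E2 and VTG in disjoint fish; 8-day exposure +
8-day depuration; 21-day EE2 at three concentrations n = 28).

What the generator does *not* emulate: assay-specific biases (polyclonal
vs monoclonal ELISA scale offsets), measured-vs-nominal water
concentration drift, tank effects, or any seasonal structure.  Passing
recovery tests therefore demonstrate that the calibration machinery is
self-consistent — not that the model matches any particular laboratory's
fish.

## Posterior prediction

The pooled draws are treated as a population: a study of n fish samples n
parameter sets uniformly with replacement (each draw keeping the error
variances of its own posterior iteration, preserving parameter–variance
correlation), simulates each deterministically, and draws observed
endpoints from the lognormal error model.  `coverage_report` summarises
predictions at the 5/10/25/50/75/90/95 percentiles per group × endpoint ×
time, flags whether the observed median falls in the central 95%
prediction interval, and reports median ratios; `relative_change` compares
exposed/control ratios for cross-assay comparisons.

## Known limitations

* **Equation-body reconstruction.**  The source model's differential
  equations are only available as symbol lists with units; the hyperbolic
  regulation forms here fit those lists but are not verbatim.  At the
  shipped posterior-mean parameters the reconstructed feedback loops settle
  at a baseline with plasma E2/T near 20–25 ng/ml — roughly an order above
  typical unexposed measurements — which pushes liver bound ER (~200
  nmol/L) far beyond the VTG half-saturation constant (1 nmol/L).  VTG
  therefore sits at its production ceiling: its dose-response retains the
  correct *ordering* (strictly increasing with EE2 dose; U-shaped over the
  TB dose range, minimum near 0.05 µg/L, like E2 and T) but with a
  relative amplitude of only ~1e-6, resolvable only at tight solver
  tolerance.  E2 and T show the full-amplitude U-shape.
* No seasonality or temperature dependence: the simulated fish are held
  under optimal year-round spawning conditions.
* No oocyte growth or fecundity model — VTG uptake into oocytes is a sink,
  not a developmental state.
* No GnRH state variable; androgen feedback acts directly on LH synthesis.
* No hierarchical per-fish random effects: population variability enters
  only through the posterior pool and the physiology inputs.
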