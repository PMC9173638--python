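# Methods

## The circuit model

State (molecules per cell, time in minutes): free ComR `R`, intracellular
ComS precursor `S`, extracellular XIP `Xe` (per cell-equivalent of a
well-mixed culture), intracellular mature XIP `Xi`, active complex
ComR·XIP `C`, sigma factor ComX `X`, peptidase pool `D` ("deg", PepF).

With Hill function `H(x; K, n) = xⁿ/(Kⁿ + xⁿ)` and Michaelis–Menten
degradation `v(D, x) = k_cat·D·x/(K_m + x)`:

```
dR/dt  = k_R·u_R(t) − k_on·R·Xi + k_off·C − δ_R·R
dS/dt  = k_S0 + k_S·H(C; K_S, n_S) + u_S(t) − k_exp·S − δ_S·S
dXe/dt = k_exp·S + u_Xe(t) − k_imp·Xe − δ_Xe·Xe
dXi/dt = k_imp·Xe − k_on·R·Xi + k_off·C − δ_Xi·Xi − v(D, Xi)
dC/dt  = k_on·R·Xi − k_off·C − δ_C·C
dX/dt  = k_X·H(C; K_X, n_X) − δ_X·X
dD/dt  = k_D0 + k_DX·H(X; K_D, n_D) − δ_D·D
```

`u_R` (multiplicative), `u_S` and `u_Xe` (additive) are the scenario
inputs: genetic ComR overexpression, *xip* overexpression, and an
extracellular synthetic-pheromone bolus respectively.

Assumptions worth stating plainly:

- **1:1 binding with Hill-2 transcription.** ComR and XIP associate 1:1
  into `C`; cooperativity of the dimerised complex enters through the
  transcriptional Hill exponents `n_S = n_X = n_D = 2`, not through the
  binding step. This is the simplest form consistent with an activating
  dimer and keeps binding linear in each partner.
- **Saturable degradation is the shut-off mechanism.** `v ≤ k_cat·D`
  regardless of substrate; the peptidase acts on `Xi` by default
  (`target_pool` can select the precursor or both pools). The deg
  production term always has a basal and a ComX-activated component, so
  the peptidase is both a standing locking device and a
  competence-triggered negative feedback.
- **No hard ComX ceiling.** The ~150-molecule plateau is a calibration
  outcome (`k_X/δ_X = 150`), matching the genomic ComX-box count kept as
  the reference constant `comX_box_capacity`; no saturating cap is
  imposed because the correspondence is an observation, not a mechanism.
- **Well-mixed extracellular pool.** `Xe` is molecules per cell-equivalent
  at a fixed culture density; growth dilution enters only through the δ
  terms (0.02 min⁻¹ everywhere by default, a ~35-min effective doubling).

### Units

Everything internal is molecules per cell. Conversion to nM happens only
at the presentation boundary: intracellularly via the cell volume
(1.66 fL, so 1 molecule ≈ 1 nM), culture-level via the culture density
(6·10¹¹ cells/L, so 6,000 molecules per cell-equivalent ≈ 6 nM). The
"maximum free XIP concentration" headline number uses the culture-level
conversion by default — it is the scale on which the 0.8 nM synthetic-XIP
activation threshold was measured — but both conversions are exposed and
the choice is an explicit argument.

## Calibration of the presets

The default preset is the package's own calibration against the
reference behaviour of the induced circuit: an 8.5-fold ComR
overexpression run must (i) raise total ComR toward ~7,000 molecules per
cell, (ii) bring ComX from ~zero to a ~150 molecules/cell plateau with
onset near 200 min, and (iii) produce a free intracellular XIP peak of
~6,000 molecules per cell, while the basal (uninduced) state stays off.
The shipped `default_params()` meets all of these (plateau 150, onset
~190–220 min depending on the onset definition, peak 5,908 ≈ 5.9 nM on
the culture scale).

The mechanism behind the numbers: at rest, basal peptidase (`D ≈ 9`,
capacity `k_cat·D ≈ 36 molecules/min`) outstrips pheromone import by two
orders of magnitude, pinning `Xi` near zero. Induced ComR raises the
capture rate of the trickle of pheromone into complex; once the *comS*
positive loop ignites, production (`k_S = 650/min`) dwarfs the saturated
peptidase, ComR is titrated into complex (~7,000 molecules), and the
excess pheromone accumulates as free `Xi` until only dilution removes it
— hence the ~6,000-molecule surge.

`no_deg_params()` is the counterfactual circuit without the peptidase,
**recalibrated** rather than merely `k_cat = 0`: with the deg preset's
high `k_S` and no sink the basal state would fire spontaneously. The
counterfactual reproduces the same ComX response with an ~80-fold lower
activated comS production (`k_S = 8`) and a weaker effective ComR·XIP
association (`k_on = 3·10⁻³`, `k_off = 0.3`, `K_S = 60`) — the
"low pheromone activity" regime that is the only way the circuit works
without degradation, and precisely the tension that motivates the deg
player. Its free-XIP peak is ~4 molecules per cell, a ~1,500-fold
contrast with the full model. The structural identity (deleting the deg
species ≡ zeroing `k_cat`, `k_D0`, `k_DX`) is a separate, tested
invariant.

## Scenarios, thresholds, ensembles

A bolus of amount `A` enters `Xe` as a constant influx `A/w` over an
uptake window `w` (default 15 min, start 120 min); integration is
restarted at input discontinuities so the adaptive solver cannot step
over the pulse, and the delivered mass equals the input-function integral
to quadrature accuracy. *xip* overexpression adds a constant rate to the
`S` balance from the induction time.

**Activation criterion.** A run counts as activated when ComX exceeds
50% of the calibrated full-induction plateau (75 of 150 molecules) within
the horizon. The reference analyses plot on/off without a printed cut;
half-plateau is the conventional, slope-robust choice, and the criterion
object makes the cut and the observable explicit and swappable.

**Minimal-XIP scans.** The activation boundary is bracketed by geometric
expansion (verifying the assumed monotone response), then bisected in log
space to < 1% relative width. Bolus mode reports the bolus amount;
constitutive mode bisects the production rate and reports cumulative
molecules produced up to the activation time, which makes the two routes
commensurable. The scans reproduce the expected ordering: a sharp bolus
needs ~10-fold fewer molecules than gradual production, because it
saturates the peptidase at once.

**Single-cell ensembles.** Cell-to-cell heterogeneity enters as log-normal
per-cell scale factors on the production rate of one player (ComR or
ComS); each cell runs one deterministic trajectory and the activated
fraction per induction fold is reported. Log-normal is the standard
choice for per-cell protein abundance and stands in for reporter
distributions that are not packaged here.

## Reporter model and calibration machinery

Promoter activity is the instantaneous transcription-rate term of the
fused promoter (`k_S0 + k_S·H(C)` for P_comS, `k_X·H(C)` for P_comX,
`k_R·u_R` for P_comR). Per-cell luciferase follows
`dL/dt = c·a(t) − k_dec·L` (proportionality `c` in RLU per transcription
unit, decay `k_dec = 0.05 min⁻¹`), solved exactly segment-wise for
piecewise-linear forcing; total RLU is per-cell signal times a logistic
OD600 (0.05 → 1.2, rate 0.0154 min⁻¹, ~45-min doubling), so specific
activity RLU/OD600 reads back the per-cell level.

Fitting minimises squared residuals of `log(1 + RLU/OD600)` summed over
all series — reporters span decades of signal and no weighting scheme is
given upstream, so the log loss weights them evenly. Free parameters
(default subset: `k_S`, `K_S`, `k_cat`, `K_m`; transport and binding held
fixed to avoid sloppy directions) are optimised in log space inside
bounds from 20 Latin-hypercube starts (deterministic per seed). Noise-free
self-consistency recovers an identifiable two-parameter subset to well
under 1%; that is the honest scope of the machinery — identifiability of
larger subsets depends on which reporters and conditions are supplied.

## Dose-response fitting

The four-parameter logistic inhibition model is fitted by least squares
with EC50 and Hill slope on the log scale (slope bounded to [0.3, 5], or
frozen — whether the reference analysis fitted or fixed it is not
documented, so both are supported). Zero-concentration wells enter the
residuals and pin the top plateau; replicates are fitted jointly, never
averaged, preserving the error structure; standard errors come from the
Jacobian-based covariance with the delta method for the log-scale
parameters. On synthetic data at the 11-point PepF gradient with 5%
multiplicative noise and triplicates, the median EC50 relative error is
~4–5% and the truth lies within ±3 standard errors ~95% of the time.

Apparent turnover is `(substrate/EC50)/incubation_seconds` — substrate
molecules processed per enzyme per second at the half-signal point; for
500 nM substrate, 0.2 nM EC50 and 4 h it gives the 2,500-fold
pheromone-peptidase ratio and 0.17 ≈ 0.2 s⁻¹.

## Peptide masses

Monoisotopic residue masses, free N- and C-termini, reduced cysteine,
charge +1: these conventions reproduce all three reference peaks of the
PepF digest (intact LPYFAGCL and N-terminal fragments LPYF, LPYFA).
Predicted values are kept at full precision internally; `mz_printed`
truncates (not rounds) to two decimals, the convention of chromatogram
annotations (883.4382 is printed 883.43). The complementary C-terminal
products (AGCL, GCL) are predicted but were not reported in the reference
spectra; peak matching defaults to 20 ppm (QTOF-class accuracy) with ties
broken toward the longer fragment. An independent elemental-composition
oracle (hand-summed C/H/N/O/S counts) backs the mass computation in the
tests to 10⁻⁴ Da.

## Numerical choices

- Integration: LSODA (adaptive, stiff-capable), rtol 1e-8 / atol 1e-10,
  dense output on the reporting grid, segment restarts at input
  discontinuities. Sub-tolerance negative values are clipped to zero and
  flagged on the trajectory; larger negativity raises a diagnostic naming
  the species and time. Summaries move < 0.1% under 10-fold tighter
  tolerances.
- Steady states: long-horizon relaxation from an analytic basal guess,
  polished by a root finder; non-convergence reports the residual norm.
- Bisection: geometric (log-space) midpoints; relative width < 1%.
- Randomness: numpy's PCG64 (`default_rng`) everywhere, seeds recorded in
  outputs; identical seeds give bit-identical datasets and ensemble
  fractions.
- Problem sizes: the shipped tests use ensembles of 5–10 cells, scan
  horizons of 400–600 min and 100-dataset recovery studies — sizes chosen
  so the full suite exercises every property in about a minute while the
  statistical assertions retain power.

## What the synthetic data does and does not show

The generators emulate logistic growth with promoter-driven luminescence,
sigmoid inhibition curves with replicate noise, and log-normal abundance
heterogeneity — the structural features the analysis stages rely on. They
do not emulate instrument drift, well-position effects, growth–reporter
coupling (OD is noise-free by construction), saturation of the
luminometer, or peptide-specific differences in ComR affinity that the
reporter-based degradation assay inherits. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every artefact of plate-reader data.

## Known limitations

- Deterministic ODEs only: no intrinsic-noise (Gillespie) or spatial
  modelling; the ensemble layer adds extrinsic heterogeneity only.
- The calibrated presets are point calibrations to headline behaviours,
  not posterior distributions; parameter uncertainty is not propagated
  into the circuit predictions.
- The counterfactual no-deg preset is one of several possible
  recalibrations; conclusions should rest on the structural contrast
  (bounded degradation flux vs none), which is robust, not on its exact
  parameter values.
- MS support is limited to sequence-level mass prediction and peak
  matching; no vendor-file parsing or fragmentation (b/y ion) prediction.
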