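# comrs

Deterministic modelling and assay analysis for the **ComRS competence
circuit** of *Streptococcus salivarius*, the quorum-sensing module in which
the intracellular receptor ComR, bound by the re-internalised pheromone XIP
(mature sequence `LPYFAGCL`), switches on the sigma factor ComX and with it
the late competence genes. The package is aimed at people studying
competence regulation in pyogenes/bovis/mutans/salivarius-group
streptococci who want a tested, scriptable version of three things:

1. **The circuit ODE model with a saturable pheromone-degradation player.**
   Seven species per cell (free ComR, ComS precursor, extracellular and
   intracellular XIP, the ComR·XIP complex, ComX, and the peptidase pool
   `deg`, i.e. PepF) are coupled through a positive feedback loop
   (ComR·XIP activates *comS* and *comX* with Hill kinetics, exponent 2 for
   complex dimerisation) and a negative one (ComX drives peptidase
   production; the peptidase removes intracellular XIP through a
   Michaelis–Menten flux `v = k_cat·deg·x/(K_m + x)` bounded by
   `k_cat·deg`). The bound is the point: at rest the peptidase scavenges
   every pheromone molecule (a locking device), but a sharp pheromone surge
   saturates it, so the circuit is excitable and shuts itself off.
2. **Degradation-assay mathematics.** Normalisation of reporter signals to
   the no-enzyme control, four-parameter logistic inhibition fits
   `S = b + (t − b)/(1 + ([E]/EC50)^HS)`, apparent turnover numbers,
   EC50 efficiency ratios, and the variant-screening signal-loss metric.
3. **Peptide fragment masses.** Cleavage-product enumeration for XIP and
   its variants and monoisotopic [M+H]+ m/z prediction for LC-MS peak
   assignment.

A synthetic-data layer generates every input the analysis stages read
(luciferase kinetics with logistic growth, dose-response tables, log-normal
single-cell abundance factors) with known ground truth, so the whole
pipeline is testable offline.

## Worked example

Simulate competence induction by 8.5-fold ComR overexpression with the two
calibrated presets (with and without the degradation player):

```python
import numpy as np
from comrs import default_params, no_deg_params, Scenario, simulate, \
    molecules_to_concentration

for label, p in [("deg", default_params()), ("no-deg", no_deg_params())]:
    tr = simulate(Scenario(kind="comR_overexpression", comR_fold=8.5), p,
                  horizon=600, dt=1.0)
    comX, xi = tr.species("comX"), tr.free_pheromone()
    onset = tr.time[np.argmax(comX >= 75)]
    print(f"{label}: comX plateau {comX[-1]:.0f} molecules/cell, "
          f"half-plateau at {onset:.0f} min, "
          f"free XIP peak {xi.max():.0f} molecules/cell "
          f"({molecules_to_concentration(xi.max(), p, 'extracellular'):.1f} nM)")
```

```
deg: comX plateau 150 molecules/cell, half-plateau at 222 min, free XIP peak 5908 molecules/cell (5.9 nM culture-scale)
no-deg: comX plateau 143 molecules/cell, half-plateau at 446 min, free XIP peak 4 molecules/cell (0.0 nM culture-scale)
```

Both models reach the same ComX plateau — 150 molecules per cell, the
number of ComX boxes in the genome — from roughly 200 minutes after
induction, but they disagree by three orders of magnitude on free
pheromone: with the saturable peptidase the circuit only fires after the
pheromone flood overwhelms it (peak ≈ 5,900 molecules per cell, ≈ 6 nM on
the culture scale, far above the 0.8 nM activation threshold measured for
synthetic XIP), whereas without it a handful of free molecules suffices.
That contrast is the model's argument for a degradation-based shut-off.

Fragment masses and LC-MS peak assignment from the command line:

```bash
comrs cleave --observed 539.28,610.32,883.43
```

```
fragment	span	terminus	predicted_mz
LPYFAGCL	1-8	intact	883.4382
LPYF	1-4	N-terminal	539.2864
AGCL	5-8	C-terminal	363.1697
LPYFA	1-5	N-terminal	610.3235
GCL	6-8	C-terminal	292.1326

observed_mz	fragment	predicted_mz	ppm_error
539.2800	LPYF	539.2864	-11.89
610.3200	LPYFA	610.3235	-5.78
883.4300	LPYFAGCL	883.4382	-9.32
```

The three observed peaks are the intact pheromone and the two N-terminal
products of PepF cuts after Phe4 and Ala5, all matched within 20 ppm.

Other entry points: `comrs simulate|scan|ensemble|calibrate|ec50|synth|run`
(see `comrs --help`); `comrs run --config cfg.yaml` executes a multi-stage
workflow and writes a self-describing manifest.

## Layout

- `src/comrs/model.py` — circuit ODEs, LSODA integration, unit conversion
- `src/comrs/params.py` — calibrated presets, YAML/JSON (de)serialisation
- `src/comrs/scenarios.py` — induction scenarios, activation criteria,
  bisection threshold scans, single-cell ensembles
- `src/comrs/calibration.py` — specific luciferase activity, forward
  reporter model, multi-start bounded least-squares fitting
- `src/comrs/assays.py` — dose-response normalisation, EC50 fits,
  turnover and efficiency numbers
- `src/comrs/peptides.py` — cleavage products, [M+H]+ m/z, peak matching
- `src/comrs/synth.py` — synthetic data with known ground truth
- `src/comrs/workflow.py`, `src/comrs/cli.py` — config-driven runner and CLI

See `docs/methods.md` for the model's equations, calibration rationale,
numerical choices and limitations.
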