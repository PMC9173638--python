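"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here: luciferase
kinetics (logistic growth plus promoter-driven luminescence), degradation
dose-response tables, and per-cell abundance scale factors for the
single-cell ensemble layer.  All generators are pure functions of their
arguments and a seed, using numpy's PCG64 generator
(``numpy.random.default_rng``), so every dataset is reproducible and
recovery tests know the truth that produced it.

Noise models
------------
``multiplicative_lognormal``
    signal × LN(−σ²/2, σ) with σ chosen so the coefficient of variation
    equals ``noise_cv`` (mean-one noise; plate-reader error scales with
    signal).  Default CV: 5% for dose-response, 10% for luciferase.
``additive_gaussian``
    signal + N(0, sd) with sd = ``noise_cv`` × the series maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .assays import REFERENCE_PEPF_GRADIENT_NM, DoseResponseDataset, inhibition_model
from .calibration import LuciferaseTimeSeries, Reporter, ReporterModel, simulate_reporter
from .params import CircuitParameters, default_params
from .scenarios import PopulationSample, Scenario

__all__ = [
    "SyntheticSpec",
    "gen_luciferase",
    "gen_dose_response",
    "gen_single_cell",
]

NoiseModel = Literal["multiplicative_lognormal", "additive_gaussian"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth plus noise model for one synthetic dataset."""

    params: CircuitParameters = field(default_factory=default_params)
    noise_model: NoiseModel = "multiplicative_lognormal"
    noise_cv: float = 0.1
    replicates: int = 3
    seed: int = 0
    grid_start: float = 0.0
    grid_stop: float = 720.0
    grid_step: float = 10.0  # monitoring interval, minutes

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise magnitude must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_model not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def time_grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + 0.5 * self.grid_step,
                         self.grid_step)


def _apply_noise(
    values: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.noise_cv == 0:
        return values.copy()
    if spec.noise_model == "multiplicative_lognormal":
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
        return values * noise
    sd = spec.noise_cv * float(np.max(np.abs(values))) if values.size else 0.0
    return values + rng.normal(0.0, sd, size=values.shape)


def gen_luciferase(
    spec: SyntheticSpec,
    scenario: Scenario,
    reporter: Reporter = "PcomX",
    reporter_model: ReporterModel | None = None,
) -> list[LuciferaseTimeSeries]:
    """Synthetic luciferase kinetics replicates for one reporter fusion.

    OD600 follows the reporter model's logistic growth (noise-free); RLU
    is the forward reporter model driven by the circuit simulation, with
    the spec's noise applied independently per replicate.
    """
    rm = reporter_model or ReporterModel()
    t = spec.time_grid()
    clean = simulate_reporter(
        spec.params, rm, scenario, reporter=reporter,
        horizon=float(t[-1]), dt=float(spec.grid_step),
    )
    rng = np.random.default_rng(spec.seed)
    out = []
    for r in range(spec.replicates):
        rlu = _apply_noise(clean.rlu, spec, rng)
        out.append(
            LuciferaseTimeSeries(
                time=clean.time,
                od600=clean.od600.copy(),
                rlu=np.maximum(rlu, 0.0),
                reporter=reporter,
                condition=f"{scenario.kind}/rep{r}",
            )
        )
    return out


def gen_dose_response(
    truth: dict,
    enzyme_concs: Sequence[float] = REFERENCE_PEPF_GRADIENT_NM,
    spec: SyntheticSpec | None = None,
) -> DoseResponseDataset:
    """Synthetic degradation dose-response dataset.

    ``truth`` holds the four-parameter inhibition curve parameters
    (``top``, ``bottom``, ``ec50``, ``hill_slope``); signals are the model
    values at ``enzyme_concs`` with replicate noise.  The default
    concentration list is the reference 11-point PepF gradient.
    """
    spec = spec if spec is not None else SyntheticSpec(noise_cv=0.05)
    x = np.asarray(enzyme_concs, dtype=float)
    clean = inhibition_model(
        x, truth["top"], truth["bottom"], truth["ec50"], truth["hill_slope"]
    )
    rng = np.random.default_rng(spec.seed)
    xs, ys, reps = [], [], []
    for r in range(spec.replicates):
        xs.append(x)
        ys.append(_apply_noise(clean, spec, rng))
        reps.append(np.full(x.shape, r, dtype=int))
    return DoseResponseDataset(
        enzyme_nM=np.concatenate(xs),
        signal_pct=np.concatenate(ys),
        replicate=np.concatenate(reps),
        peptide=str(truth.get("peptide", "XIP")),
    )


def gen_single_cell(
    mu: float,
    sigma: float,
    n: int,
    seed: int = 0,
    player: Literal["comR", "comS"] = "comR",
) -> PopulationSample:
    """Log-normal per-cell scale factors for one heterogeneous player.

    Draws ``n`` positive factors from LN(mu, sigma); with sigma = 0 every
    cell equals exp(mu).  Emulates the cell-to-cell spread of reporter
    distributions that seeds heterogeneity in circuit activation.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(mu, sigma, size=n))
    return PopulationSample(
        player=player,
        factors=tuple(float(f) for f in factors),
        distribution=f"lognormal(mu={mu}, sigma={sigma})",
        seed=seed,
    )
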