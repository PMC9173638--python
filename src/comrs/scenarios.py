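"""Induction scenarios, activation criteria, threshold scans and the
single-cell ensemble layer.

Three ways of switching the circuit on are encoded, mirroring how
competence is triggered experimentally:

* ``comR_overexpression`` — multiply ComR production by a fold factor from
  the induction time onward (genetic overexpression, reference fold 8.5);
* ``sxip_bolus`` — deliver a fixed quantity of synthetic pheromone into
  the extracellular pool as a constant influx over a short uptake window
  (reference: bolus at 120 min taken up within 15 min);
* ``xip_constitutive`` — add a constant intracellular pheromone production
  rate from the induction time onward (*xip* overexpression).

The threshold scans answer the question of Fig-1-style analyses: how many
pheromone molecules does each route need before the circuit activates?
Because a bolus saturates the degradation machinery at once while
constitutive production feeds it gradually, the bolus route activates with
fewer molecules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import (
    CircuitTrajectory,
    ExogenousInputs,
    IntegrationError,
    simulate,
    steady_state,
)
from .params import CircuitParameters

__all__ = [
    "Scenario",
    "ActivationCriterion",
    "PopulationSample",
    "apply_scenario",
    "is_activated",
    "min_xip_for_activation",
    "fraction_activated",
    "EnsembleResult",
]

ScenarioKind = Literal["comR_overexpression", "sxip_bolus", "xip_constitutive", "null"]

_KINDS = ("comR_overexpression", "sxip_bolus", "xip_constitutive", "null")


@dataclass(frozen=True)
class Scenario:
    """One induction scenario; only the fields of the chosen kind are used."""

    kind: ScenarioKind = "null"
    comR_fold: float = 8.5
    bolus_amount: float = 0.0  # molecules per cell-equivalent
    bolus_time: float = 120.0  # minutes
    uptake_window: float = 15.0  # minutes
    constitutive_rate: float = 0.0  # molecules/min
    induction_time: float = 0.0  # minutes, for fold / constitutive kinds

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.comR_fold < 1:
            raise ValueError("comR_fold must be >= 1")
        for name in ("bolus_amount", "bolus_time", "uptake_window",
                     "constitutive_rate", "induction_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_inputs(self, params: CircuitParameters) -> ExogenousInputs:
        if self.kind == "null":
            return ExogenousInputs()
        if self.kind == "comR_overexpression":
            fold, t0 = self.comR_fold, self.induction_time

            def factor(t: float, fold=fold, t0=t0) -> float:
                return fold if t >= t0 else 1.0

            return ExogenousInputs(comR_production_factor=factor, breakpoints=(t0,))
        if self.kind == "sxip_bolus":
            if self.uptake_window <= 0:
                raise ValueError("uptake_window must be positive for a bolus")
            rate = self.bolus_amount / self.uptake_window
            t0, t1 = self.bolus_time, self.bolus_time + self.uptake_window

            def influx(t: float, rate=rate, t0=t0, t1=t1) -> float:
                return rate if t0 <= t < t1 else 0.0

            return ExogenousInputs(xip_extra_influx=influx, breakpoints=(t0, t1))
        # xip_constitutive
        rate, t0 = self.constitutive_rate, self.induction_time

        def production(t: float, rate=rate, t0=t0) -> float:
            return rate if t >= t0 else 0.0

        return ExogenousInputs(comS_production_rate=production, breakpoints=(t0,))


def apply_scenario(scenario: Scenario, params: CircuitParameters) -> ExogenousInputs:
    """Time-dependent input functions realising a scenario."""
    return scenario.to_inputs(params)


@dataclass(frozen=True)
class ActivationCriterion:
    """Boolean activation cut on one trajectory.

    The default declares a run activated when ComX exceeds
    ``threshold_fraction`` of ``reference_level`` — half the calibrated
    full-induction ComX plateau — at any point within the horizon.
    """

    observable: Literal["comX", "promoter_comX_rate"] = "comX"
    threshold_fraction: float = 0.5
    reference_level: float = 150.0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.reference_level <= 0:
            raise ValueError("reference_level must be positive")

    @property
    def cut(self) -> float:
        return self.threshold_fraction * self.reference_level

    def evaluate(self, traj: CircuitTrajectory) -> bool:
        return bool(np.any(self.observable_series(traj) >= self.cut))

    def activation_time(self, traj: CircuitTrajectory) -> float | None:
        """First grid time at which the cut is reached, or None."""
        hits = np.nonzero(self.observable_series(traj) >= self.cut)[0]
        return float(traj.time[hits[0]]) if hits.size else None

    def observable_series(self, traj: CircuitTrajectory) -> np.ndarray:
        if self.observable == "comX":
            return traj.species("comX")
        if self.observable == "promoter_comX_rate":
            from .model import _hill  # transcription-rate term of P_comX

            C = traj.species("complex_RX")
            p = traj.params
            return np.array([p.k_X * _hill(c, p.K_X, p.n_X) for c in C])
        raise ValueError(f"unknown observable {self.observable!r}")


def is_activated(
    traj: CircuitTrajectory, criterion: ActivationCriterion | None = None
) -> bool:
    return (criterion or ActivationCriterion()).evaluate(traj)


def min_xip_for_activation(
    mode: Literal["sxip_bolus", "xip_constitutive"],
    params: CircuitParameters,
    criterion: ActivationCriterion | None = None,
    horizon: float = 600.0,
    rel_width: float = 0.01,
    lower: float = 1.0,
    upper: float = 1.0e7,
    dt: float = 2.0,
) -> float:
    """Minimal pheromone quantity (molecules) that activates the circuit.

    Bolus mode bisects over the bolus amount; constitutive mode bisects
    over the production rate and reports the cumulative molecules produced
    up to the activation time, making the two routes commensurable.  The
    activation boundary is bracketed by geometric expansion before
    bisection, which verifies the assumed monotone response.
    """
    criterion = criterion or ActivationCriterion()
    if mode not in ("sxip_bolus", "xip_constitutive"):
        raise ValueError(f"unknown mode {mode!r}")

    y0 = steady_state(params)

    def run(x: float) -> CircuitTrajectory:
        if mode == "sxip_bolus":
            sc = Scenario(kind="sxip_bolus", bolus_amount=x)
        else:
            # rate applied from t=0; x is molecules/min here
            sc = Scenario(kind="xip_constitutive", constitutive_rate=x)
        return simulate(sc, params, horizon=horizon, dt=dt, y0=y0)

    null_traj = simulate(Scenario(kind="null"), params, horizon=horizon, dt=dt, y0=y0)
    if criterion.evaluate(null_traj):
        warnings.warn(
            "system is active under the null scenario; threshold is degenerate (0)"
        )
        return 0.0

    if mode == "xip_constitutive":
        # bisect on the rate, convert to cumulative molecules at the end
        lower = lower / horizon
        upper = upper / horizon

    lo, hi = lower, lower
    activated_hi = None
    while hi <= upper:
        traj = run(hi)
        if criterion.evaluate(traj):
            activated_hi = traj
            break
        lo = hi
        hi *= 2.0
    if activated_hi is None:
        raise RuntimeError(f"not activatable at bound ({upper:g})")

    while (hi - lo) / hi > rel_width:
        mid = math.sqrt(lo * hi)
        traj = run(mid)
        if criterion.evaluate(traj):
            hi, activated_hi = mid, traj
        else:
            lo = mid

    if mode == "sxip_bolus":
        return hi
    t_act = ActivationCriterion(
        observable=criterion.observable,
        threshold_fraction=criterion.threshold_fraction,
        reference_level=criterion.reference_level,
    ).activation_time(activated_hi)
    assert t_act is not None
    return hi * t_act  # cumulative molecules produced by activation


@dataclass(frozen=True)
class PopulationSample:
    """Per-cell scale factors for one heterogeneous circuit player."""

    player: Literal["comR", "comS"]
    factors: tuple[float, ...]
    distribution: str = "lognormal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("sample is empty")
        if any(f <= 0 for f in self.factors):
            raise ValueError("scale factors must be positive")


@dataclass
class EnsembleResult:
    folds: np.ndarray
    fraction: np.ndarray
    n_cells: int
    n_failed: int = 0
    flagged: bool = False


def fraction_activated(
    sample: PopulationSample,
    params: CircuitParameters,
    comR_fold_grid: Sequence[float],
    criterion: ActivationCriterion | None = None,
    horizon: float = 600.0,
    dt: float = 2.0,
) -> EnsembleResult:
    """Fraction of cells activated at each ComR induction fold.

    Each cell runs one deterministic trajectory with its drawn scale factor
    multiplying the production rate of the heterogeneous player (ComR or
    ComS), combined multiplicatively with the induction fold for ComR.
    Cells whose integration fails are excluded and counted.
    """
    criterion = criterion or ActivationCriterion()
    folds = np.asarray(list(comR_fold_grid), dtype=float)
    frac = np.zeros_like(folds)
    n_failed = 0
    for j, fold in enumerate(folds):
        n_on = 0
        n_ok = 0
        for f in sample.factors:
            if sample.player == "comR":
                p_cell = params.replace(k_R=params.k_R * f)
            else:
                p_cell = params.replace(k_S0=params.k_S0 * f, k_S=params.k_S * f)
            sc = Scenario(kind="comR_overexpression", comR_fold=fold)
            try:
                traj = simulate(sc, p_cell, horizon=horizon, dt=dt)
            except IntegrationError:
                n_failed += 1
                continue
            n_ok += 1
            if criterion.evaluate(traj):
                n_on += 1
        frac[j] = n_on / n_ok if n_ok else float("nan")
    return EnsembleResult(
        folds=folds,
        fraction=frac,
        n_cells=len(sample.factors),
        n_failed=n_failed,
        flagged=n_failed > 0,
    )
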