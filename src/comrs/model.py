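"""Deterministic ODE model of the ComRS competence circuit.

Seven species are tracked per cell: free ComR, the intracellular ComS
precursor, extracellular XIP (per cell-equivalent of a well-mixed culture),
intracellular mature XIP, the active ComR·XIP complex, the sigma factor
ComX, and the pheromone-degrading peptidase pool (``deg``).

The wiring follows the dual-feedback architecture of the salivarius
ComRS system: the ComR·XIP complex activates transcription of *comS*
(positive loop, Hill kinetics) and of *comX*; ComX in turn drives
production of the peptidase, which removes intracellular pheromone through
a saturable Michaelis–Menten flux (negative loop).  Because the peptidase
flux is bounded by ``k_cat·deg``, a sufficiently sharp pheromone influx
overwhelms it — the behaviour that makes the circuit a locking device at
rest yet excitable under induction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import AVOGADRO, SPECIES, CircuitParameters

__all__ = [
    "CircuitState",
    "ExogenousInputs",
    "CircuitTrajectory",
    "IntegrationError",
    "derivatives",
    "simulate",
    "steady_state",
    "molecules_to_concentration",
    "concentration_to_molecules",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; names the species and time."""


@dataclass(frozen=True)
class CircuitState:
    """State vector of the circuit, molecules per cell."""

    comR_free: float = 0.0
    comS_intra: float = 0.0
    xip_extra: float = 0.0
    xip_intra: float = 0.0
    complex_RX: float = 0.0
    comX: float = 0.0
    deg: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "CircuitState":
        return cls(**{name: float(v) for name, v in zip(SPECIES, y)})

    def validate(self) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("state contains non-finite entries")
        if np.any(y < 0):
            bad = [s for s, v in zip(SPECIES, y) if v < 0]
            raise ValueError(f"negative state entries: {bad}")


def _zero(t: float) -> float:
    return 0.0


def _one(t: float) -> float:
    return 1.0


@dataclass(frozen=True)
class ExogenousInputs:
    """Time-dependent forcing applied by an induction scenario.

    ``comR_production_factor`` multiplies the ComR production rate
    (genetic overexpression); ``comS_production_rate`` is an additive
    intracellular pheromone production term (molecules/min, *xip*
    overexpression); ``xip_extra_influx`` is an additive influx into the
    extracellular pool (molecules per cell-equivalent per min, sXIP bolus).
    """

    comR_production_factor: Callable[[float], float] = _one
    comS_production_rate: Callable[[float], float] = _zero
    xip_extra_influx: Callable[[float], float] = _zero
    #: times at which an input function is discontinuous; integration is
    #: restarted there so the adaptive solver cannot step across a pulse
    breakpoints: tuple[float, ...] = ()


NULL_INPUTS = ExogenousInputs()


def _hill(x: float, K: float, n: float) -> float:
    if x <= 0.0:
        return 0.0
    xn = (x / K) ** n
    return xn / (1.0 + xn)


def derivatives(
    state: CircuitState | np.ndarray,
    params: CircuitParameters,
    t: float = 0.0,
    inputs: ExogenousInputs = NULL_INPUTS,
) -> np.ndarray:
    """Instantaneous rate vector (molecules·min⁻¹) for every species.

    With ``k_cat = 0`` the output is identical to a model with no
    degradation player acting; the deg production term always carries both
    a basal and a ComX-activated component.
    """
    if isinstance(state, CircuitState):
        state.validate()
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("state contains non-finite entries")
        if np.any(y < 0):
            bad = [s for s, v in zip(SPECIES, y) if v < 0]
            raise ValueError(f"negative state entries: {bad}")
    return _rhs(t, y, params, inputs)


def _rhs(
    t: float, y: np.ndarray, p: CircuitParameters, inputs: ExogenousInputs
) -> np.ndarray:
    R, S, Xe, Xi, C, X, D = y
    d = p.delta
    law = p.degradation

    bind = p.k_on * R * Xi
    unbind = p.k_off * C

    deg_S = law.rate(D, S) if law.target_pool in ("comS_intra", "both") else 0.0
    deg_Xi = law.rate(D, Xi) if law.target_pool in ("xip_intra", "both") else 0.0

    act_S = p.k_S * _hill(C, p.K_S, p.n_S)
    act_X = p.k_X * _hill(C, p.K_X, p.n_X)
    act_D = p.k_DX * _hill(X, p.K_D, p.n_D)

    dR = p.k_R * inputs.comR_production_factor(t) - bind + unbind - d["comR_free"] * R
    dS = (
        p.k_S0
        + act_S
        + inputs.comS_production_rate(t)
        - p.k_exp * S
        - d["comS_intra"] * S
        - deg_S
    )
    dXe = p.k_exp * S + inputs.xip_extra_influx(t) - p.k_imp * Xe - d["xip_extra"] * Xe
    dXi = p.k_imp * Xe - bind + unbind - d["xip_intra"] * Xi - deg_Xi
    dC = bind - unbind - d["complex_RX"] * C
    dX = act_X - d["comX"] * X
    dD = p.k_D0 + act_D - d["deg"] * D
    return np.array([dR, dS, dXe, dXi, dC, dX, dD])


@dataclass
class CircuitTrajectory:
    """Time grid plus per-species abundance matrix (molecules per cell)."""

    time: np.ndarray  # minutes
    values: np.ndarray  # shape (n_times, n_species), order of SPECIES
    params: CircuitParameters
    clipped: bool = False  # sub-tolerance negatives were clipped to zero

    def species(self, name: str) -> np.ndarray:
        return self.values[:, SPECIES.index(name)]

    def final_state(self) -> CircuitState:
        return CircuitState.from_array(self.values[-1])

    def free_pheromone(self) -> np.ndarray:
        """Intracellular mature XIP not bound in the ComR·XIP complex."""
        return self.species("xip_intra")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export: time_min, species, molecules_per_cell, nM.

        The nM column uses the intracellular conversion for intracellular
        species and the culture-level conversion for the extracellular pool.
        """
        rows = []
        for i, name in enumerate(SPECIES):
            compartment = "extracellular" if name == "xip_extra" else "intracellular"
            nm = molecules_to_concentration(
                self.values[:, i], self.params, compartment
            )
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.time,
                        "species": name,
                        "molecules_per_cell": self.values[:, i],
                        "nM": nm,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def simulate(
    scenario,
    params: CircuitParameters,
    horizon: float = 600.0,
    dt: float = 1.0,
    y0: CircuitState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CircuitTrajectory:
    """Integrate the circuit under an induction scenario.

    ``scenario`` is either an :class:`ExogenousInputs` or any object with a
    ``to_inputs(params)`` method (see :class:`comrs.scenarios.Scenario`).
    The initial condition defaults to the basal (null-input) steady state,
    so a null scenario yields a constant trajectory.

    Integration uses LSODA (adaptive, stiff-capable) with dense output
    sampled on the reporting grid.  Sub-tolerance negative values produced
    by the solver are clipped to zero and flagged on the trajectory.
    """
    inputs = scenario if isinstance(scenario, ExogenousInputs) else scenario.to_inputs(params)
    if y0 is None:
        y0 = steady_state(params)
    y0.validate()

    t_eval = np.arange(0.0, horizon + 0.5 * dt, dt)
    edges = [0.0]
    edges += sorted(b for b in inputs.breakpoints if 0.0 < b < horizon)
    edges.append(float(horizon))

    times: list[np.ndarray] = []
    chunks: list[np.ndarray] = []
    y_cur = y0.as_array()
    for a, b in zip(edges[:-1], edges[1:]):
        grid = t_eval[(t_eval >= a) & (t_eval <= b)]
        seg_eval = np.unique(np.concatenate([grid, [a, b]]))
        sol = solve_ivp(
            lambda t, y: _rhs(t, np.maximum(y, 0.0), params, inputs),
            (a, b),
            y_cur,
            method="LSODA",
            t_eval=seg_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            y_last = sol.y[:, -1] if sol.y.size else y_cur
            worst = SPECIES[int(np.argmax(np.abs(y_last)))]
            t_last = sol.t[-1] if sol.t.size else a
            raise IntegrationError(
                f"integration failed near t={t_last:.2f} min "
                f"(largest species: {worst}): {sol.message}"
            )
        y_cur = sol.y[:, -1]
        on_grid = np.isin(sol.t, grid)
        if b < horizon:
            on_grid &= sol.t < b  # the breakpoint belongs to the next segment
        times.append(sol.t[on_grid])
        chunks.append(sol.y.T[on_grid])
    t_out = np.concatenate(times)
    values = np.concatenate(chunks, axis=0)
    clipped = bool(np.any(values < 0))
    if clipped:
        if np.min(values) < -100 * atol:
            worst = SPECIES[int(np.argmin(np.min(values, axis=0)))]
            raise IntegrationError(
                f"trajectory went negative beyond tolerance for {worst} "
                f"(min {np.min(values):.3e})"
            )
        values = np.clip(values, 0.0, None)
    return CircuitTrajectory(time=t_out, values=values, params=params, clipped=clipped)


def steady_state(
    params: CircuitParameters,
    inputs: ExogenousInputs = NULL_INPUTS,
    tol: float = 1e-9,
) -> CircuitState:
    """Fixed point of the circuit under constant exogenous inputs.

    A coarse long-horizon integration provides the starting point, which a
    root finder then polishes; the result agrees with the endpoint of a
    very long integration.  Raises :class:`IntegrationError` with the
    residual norm if neither converges.
    """
    # crude analytic guess, then relax toward the attractor
    d = params.delta
    guess = np.array(
        [
            params.k_R * inputs.comR_production_factor(0.0) / max(d["comR_free"], 1e-12),
            params.k_S0 / max(params.k_exp + d["comS_intra"], 1e-12),
            0.0, 0.0, 0.0, 0.0,
            params.k_D0 / max(d["deg"], 1e-12),
        ]
    )
    sol = solve_ivp(
        lambda t, y: _rhs(t, np.maximum(y, 0.0), params, inputs),
        (0.0, 5000.0),
        guess,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    y_relax = np.maximum(sol.y[:, -1], 0.0)

    res = root(lambda y: _rhs(0.0, np.maximum(y, 0.0), params, inputs), y_relax, tol=1e-12)
    y_fix = np.maximum(res.x, 0.0) if res.success else y_relax
    resid = float(np.linalg.norm(_rhs(0.0, y_fix, params, inputs)))
    if resid > max(tol, 1e-6 * (1.0 + float(np.linalg.norm(y_fix)))):
        raise IntegrationError(f"steady state not converged; residual norm {resid:.3e}")
    return CircuitState.from_array(y_fix)


def molecules_to_concentration(
    n, params: CircuitParameters, compartment: str = "extracellular"
):
    """Convert molecules per cell(-equivalent) to nM.

    ``intracellular`` divides by the cell volume (Avogadro · cell_volume);
    ``extracellular`` treats the value as molecules per cell-equivalent of
    a well-mixed culture and multiplies by the culture density.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("molecule counts must be non-negative")
    if compartment == "intracellular":
        molar = n / (AVOGADRO * params.cell_volume)
    elif compartment == "extracellular":
        molar = n * params.culture_density / AVOGADRO
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    out = molar * 1e9
    return float(out) if out.ndim == 0 else out


def concentration_to_molecules(
    nM, params: CircuitParameters, compartment: str = "extracellular"
):
    """Inverse of :func:`molecules_to_concentration` (round-trip identity)."""
    nM = np.asarray(nM, dtype=float)
    if np.any(nM < 0):
        raise ValueError("concentrations must be non-negative")
    molar = nM * 1e-9
    if compartment == "intracellular":
        n = molar * AVOGADRO * params.cell_volume
    elif compartment == "extracellular":
        n = molar * AVOGADRO / params.culture_density
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    return float(n) if n.ndim == 0 else n
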