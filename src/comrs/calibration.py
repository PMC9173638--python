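"""Luciferase reporter forward model and parameter calibration.

Growth (OD600) and luciferase activity (RLU) monitored at regular
intervals are the calibration data for the circuit: promoter fusions to
*comR*, *comX* and *comS* report the instantaneous transcriptional
activity of those promoters.  The forward model maps a circuit trajectory
to a predicted time series: the promoter's transcription-rate term drives
per-cell luciferase through first-order maturation/decay kinetics, and
total light scales with biomass (RLU = OD600 × per-cell signal), so that
specific activity RLU/OD600 reads back the per-cell reporter level.

Free parameters are fitted by bounded multi-start nonlinear least squares
on log-transformed parameters, minimising squared residuals of
log(1 + specific activity) — a loss that weights reporters spanning
decades of RLU evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import CircuitTrajectory, simulate
from .params import CircuitParameters

__all__ = [
    "LuciferaseTimeSeries",
    "ReporterModel",
    "LogisticGrowth",
    "FitResult",
    "specific_activity",
    "promoter_activity",
    "simulate_reporter",
    "fit_parameters",
]

Reporter = Literal["PcomR", "PcomX", "PcomS"]
REPORTERS = ("PcomR", "PcomX", "PcomS")


@dataclass
class LuciferaseTimeSeries:
    """One well/condition of a luciferase kinetics run."""

    time: np.ndarray  # minutes, strictly increasing
    od600: np.ndarray
    rlu: np.ndarray
    reporter: Reporter = "PcomX"
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.rlu = np.asarray(self.rlu, dtype=float)
        if not (len(self.time) == len(self.od600) == len(self.rlu)):
            raise ValueError("time, od600 and rlu must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od600 <= 0):
            bad = int(np.nonzero(self.od600 <= 0)[0][0])
            raise ValueError(f"od600 must be positive (first offence at index {bad})")
        if np.any(self.rlu < 0):
            raise ValueError("rlu must be non-negative")
        if self.reporter not in REPORTERS:
            raise ValueError(f"unknown reporter {self.reporter!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "od600": self.od600,
                "rlu": self.rlu,
                "reporter": self.reporter,
                "condition": self.condition,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["LuciferaseTimeSeries"]:
        """Split a tidy table (time_min, od600, rlu, reporter, condition)."""
        out = []
        for (rep, cond), g in df.groupby(["reporter", "condition"], sort=True):
            g = g.sort_values("time_min")
            out.append(
                cls(
                    time=g["time_min"].to_numpy(float),
                    od600=g["od600"].to_numpy(float),
                    rlu=g["rlu"].to_numpy(float),
                    reporter=str(rep),
                    condition=str(cond),
                )
            )
        return out

    @classmethod
    def read_csv(cls, path: str | Path) -> list["LuciferaseTimeSeries"]:
        return cls.from_frame(pd.read_csv(path))


def specific_activity(ts: LuciferaseTimeSeries, mode: Literal["sum", "max"] = "max") -> float:
    """Specific (sum) or maximum specific (max) luciferase activity.

    RLU divided by OD600 per measurement, then summed over time or the
    maximum value taken.
    """
    ratio = ts.rlu / ts.od600
    if mode == "sum":
        return float(np.sum(ratio))
    if mode == "max":
        return float(np.max(ratio))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class LogisticGrowth:
    """Logistic OD600 growth used by the forward model."""

    od0: float = 0.05
    od_max: float = 1.2
    rate: float = 0.0154  # min^-1, ~45-min doubling

    def od(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = (self.od_max - self.od0) / self.od0
        return self.od_max / (1.0 + a * np.exp(-self.rate * t))


@dataclass(frozen=True)
class ReporterModel:
    """Maps promoter activity (molecules·min⁻¹) to luciferase signal.

    ``proportionality`` is RLU per transcription-rate unit per reporter;
    ``decay`` is the luciferase maturation/decay rate (min⁻¹).
    """

    proportionality: Mapping[str, float] = field(
        default_factory=lambda: {"PcomR": 50.0, "PcomX": 50.0, "PcomS": 50.0}
    )
    decay: float = 0.05
    growth: LogisticGrowth = field(default_factory=LogisticGrowth)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.proportionality.values()):
            raise ValueError("proportionality constants must be non-negative")
        if self.decay <= 0:
            raise ValueError("decay must be positive")


def promoter_activity(
    traj: CircuitTrajectory, reporter: Reporter, scenario=None
) -> np.ndarray:
    """Instantaneous transcription-rate term of the reporter's promoter."""
    from .model import _hill

    p = traj.params
    C = traj.species("complex_RX")
    if reporter == "PcomS":
        return p.k_S0 + p.k_S * np.array([_hill(c, p.K_S, p.n_S) for c in C])
    if reporter == "PcomX":
        return p.k_X * np.array([_hill(c, p.K_X, p.n_X) for c in C])
    if reporter == "PcomR":
        inputs = scenario.to_inputs(p) if scenario is not None else None
        factor = (
            np.array([inputs.comR_production_factor(t) for t in traj.time])
            if inputs is not None
            else np.ones_like(traj.time)
        )
        return p.k_R * factor
    raise ValueError(f"unknown reporter {reporter!r}")


def _first_order_response(t: np.ndarray, forcing: np.ndarray, k: float) -> np.ndarray:
    """Exact solution of dL/dt = f(t) - k L for piecewise-linear forcing."""
    L = np.zeros_like(forcing)
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        e = np.exp(-k * dt)
        g = (1.0 - e) / k
        slope = (forcing[i + 1] - forcing[i]) / dt
        L[i + 1] = L[i] * e + forcing[i] * g + slope * (dt - g) / k
    return L


def simulate_reporter(
    params: CircuitParameters,
    reporter_model: ReporterModel,
    scenario,
    reporter: Reporter = "PcomX",
    horizon: float = 600.0,
    dt: float = 10.0,
    condition: str = "",
) -> LuciferaseTimeSeries:
    """Forward-model a luciferase kinetics run for one reporter fusion.

    The promoter's transcription-rate term, scaled by the reporter's
    proportionality constant, drives per-cell luciferase with first-order
    decay (solved exactly segment-wise); RLU is the per-cell signal times
    the logistic OD600.
    """
    traj = simulate(scenario, params, horizon=horizon, dt=dt)
    activity = promoter_activity(traj, reporter, scenario)
    c = reporter_model.proportionality[reporter]
    per_cell = _first_order_response(traj.time, c * activity, reporter_model.decay)
    od = reporter_model.growth.od(traj.time)
    return LuciferaseTimeSeries(
        time=traj.time,
        od600=od,
        rlu=per_cell * od,
        reporter=reporter,
        condition=condition or getattr(scenario, "kind", ""),
    )


@dataclass
class FitResult:
    """Outcome of a multi-start bounded least-squares calibration."""

    values: dict[str, float]
    stderr: dict[str, float | None]
    bounds: dict[str, tuple[float, float]]
    rss: float
    converged: bool
    seed: int
    n_starts: int

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "stderr": self.stderr,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "rss": self.rss,
            "converged": self.converged,
            "seed": self.seed,
            "n_starts": self.n_starts,
        }


#: Parameter subset treated as identifiable by default; transport and
#: binding rates are held at their preset values to avoid sloppy fits.
DEFAULT_FREE = ("k_S", "K_S", "k_cat", "K_m")


def fit_parameters(
    data: Sequence[tuple[LuciferaseTimeSeries, object]],
    free: Sequence[str] = DEFAULT_FREE,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_params: CircuitParameters | None = None,
    reporter_model: ReporterModel | None = None,
    n_starts: int = 20,
    dt: float | None = None,
) -> FitResult:
    """Calibrate free circuit parameters against luciferase time courses.

    ``data`` pairs each observed series with the induction scenario it was
    recorded under.  The loss is the sum of squared residuals of
    log(1 + RLU/OD600) over all points of all series, weighting reporters
    spanning decades of signal evenly.  Free parameters are optimised in
    log space inside bounds, from ``n_starts`` Latin-hypercube starting
    points (deterministic given ``seed``).
    """
    if not data:
        raise ValueError("need at least one time series")
    base = base_params or CircuitParameters()
    rm = reporter_model or ReporterModel()
    if bounds is None:
        bounds = {}
    full_bounds: dict[str, tuple[float, float]] = {}
    for name in free:
        if name in bounds:
            full_bounds[name] = tuple(bounds[name])
        else:
            ref = _get_param(base, name)
            if ref <= 0:
                raise ValueError(
                    f"cannot derive default bounds for {name} with reference 0"
                )
            full_bounds[name] = (ref / 10.0, ref * 10.0)

    # canonical ordering makes the fit invariant to input permutation
    order = sorted(
        range(len(data)),
        key=lambda i: (data[i][0].reporter, data[i][0].condition, data[i][0].time[0]),
    )
    series = [data[i] for i in order]

    lo = np.log10([full_bounds[n][0] for n in free])
    hi = np.log10([full_bounds[n][1] for n in free])

    def residual(logx: np.ndarray) -> np.ndarray:
        p = base.replace(**{n: 10.0**v for n, v in zip(free, logx)})
        res = []
        cache: dict[tuple, LuciferaseTimeSeries] = {}
        for ts, scenario in series:
            step = dt if dt is not None else float(np.min(np.diff(ts.time)))
            key = (ts.reporter, id(scenario), float(ts.time[-1]), step)
            pred = cache.get(key)
            if pred is None:
                pred = simulate_reporter(
                    p, rm, scenario, reporter=ts.reporter,
                    horizon=float(ts.time[-1]), dt=step,
                )
                cache[key] = pred
            pred_sa = np.interp(ts.time, pred.time, pred.rlu / pred.od600)
            res.append(np.log1p(pred_sa) - np.log1p(ts.rlu / ts.od600))
        return np.concatenate(res)

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n=n_starts) * (hi - lo)

    best = None
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    rss = float(2.0 * best.cost)
    n_pts = best.fun.size
    stderr: dict[str, float | None] = {n: None for n in free}
    dof = n_pts - len(free)
    if dof > 0:
        try:
            JTJ = best.jac.T @ best.jac
            cov = np.linalg.inv(JTJ) * rss / dof
            se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for n, v_log, se in zip(free, best.x, se_log):
                stderr[n] = float(np.log(10) * 10.0**v_log * se)
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        values={n: float(10.0**v) for n, v in zip(free, best.x)},
        stderr=stderr,
        bounds=full_bounds,
        rss=rss,
        converged=bool(best.status > 0),
        seed=seed,
        n_starts=n_starts,
    )


def _get_param(params: CircuitParameters, name: str) -> float:
    if name in ("k_cat", "K_m"):
        return getattr(params.degradation, name)
    return getattr(params, name)
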