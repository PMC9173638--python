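"""Degradation-assay mathematics.

The pheromone-degradation assay incubates a fixed amount of synthetic XIP
(500 nM, 4 h, 37°C) with a gradient of PepF and reads out the remaining
active pheromone through a luciferase reporter strain.  Maximum specific
activities are normalised to the no-enzyme control and the enzyme
concentration affording half the luminescence (EC50) is extracted from a
four-parameter logistic inhibition fit

    signal = b + (t - b) / (1 + ([PepF] / EC50) ** HS)

with top ``t``, bottom ``b`` and Hill slope ``HS``.  From the EC50 the
assay yields an apparent per-enzyme turnover number, and EC50 ratios
compare degradation efficiency between peptide variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Minimizer, Parameters

__all__ = [
    "DoseResponseDataset",
    "InhibitionFit",
    "REFERENCE_PEPF_GRADIENT_NM",
    "inhibition_model",
    "normalize_to_control",
    "fit_inhibition",
    "apparent_turnover",
    "efficiency_ratio",
    "screen_signal_loss",
]

log = logging.getLogger(__name__)

#: PepF concentrations (nM) of the reference dose-response design.
REFERENCE_PEPF_GRADIENT_NM = (0.0, 0.025, 0.065, 0.16, 0.4, 1.0, 2.56, 6.4, 16.0, 40.0, 100.0)


@dataclass
class DoseResponseDataset:
    """Normalized degradation dose-response data (percent of control)."""

    enzyme_nM: np.ndarray
    signal_pct: np.ndarray
    replicate: np.ndarray | None = None
    substrate_nM: float = 500.0
    incubation_min: float = 240.0
    peptide: str = "XIP"

    def __post_init__(self) -> None:
        self.enzyme_nM = np.asarray(self.enzyme_nM, dtype=float)
        self.signal_pct = np.asarray(self.signal_pct, dtype=float)
        if self.enzyme_nM.shape != self.signal_pct.shape:
            raise ValueError("enzyme_nM and signal_pct must have equal length")
        if np.any(self.enzyme_nM < 0):
            raise ValueError("enzyme concentrations must be non-negative")
        if not np.all(np.isfinite(self.signal_pct)):
            raise ValueError("signals must be finite")
        if self.replicate is None:
            self.replicate = np.zeros_like(self.enzyme_nM, dtype=int)
        if len(np.unique(self.enzyme_nM)) < 4:
            raise ValueError("need at least 4 distinct enzyme concentrations")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enzyme_nM": self.enzyme_nM,
                "signal_pct": self.signal_pct,
                "replicate": self.replicate,
                "peptide": self.peptide,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "DoseResponseDataset":
        peptides = df["peptide"].unique() if "peptide" in df else ["XIP"]
        if len(peptides) > 1:
            raise ValueError(f"multiple peptides in table: {list(peptides)}")
        return cls(
            enzyme_nM=df["enzyme_nM"].to_numpy(float),
            signal_pct=df["signal_pct"].to_numpy(float),
            replicate=df["replicate"].to_numpy() if "replicate" in df else None,
            peptide=str(peptides[0]),
            **kwargs,
        )

    @classmethod
    def read_csv(cls, path: str | Path, **kwargs) -> "DoseResponseDataset":
        return cls.from_frame(pd.read_csv(path), **kwargs)


@dataclass(frozen=True)
class InhibitionFit:
    """Four-parameter logistic inhibition fit result."""

    top: float
    bottom: float
    ec50: float
    hill_slope: float
    se_top: float | None
    se_bottom: float | None
    se_ec50: float | None
    se_hill_slope: float | None
    rss: float
    converged: bool
    monotone_warning: bool = False

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.bottom > self.top:
            raise ValueError("bottom must not exceed top")

    def predict(self, enzyme_nM) -> np.ndarray:
        return inhibition_model(
            enzyme_nM, self.top, self.bottom, self.ec50, self.hill_slope
        )

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "ec50": self.ec50,
            "hill_slope": self.hill_slope,
            "se_top": self.se_top,
            "se_bottom": self.se_bottom,
            "se_ec50": self.se_ec50,
            "se_hill_slope": self.se_hill_slope,
            "rss": self.rss,
            "converged": self.converged,
            "monotone_warning": self.monotone_warning,
        }


def inhibition_model(enzyme_nM, top, bottom, ec50, hill_slope):
    """Four-parameter logistic inhibition curve.

    Equals ``top`` at zero enzyme and ``(top + bottom) / 2`` exactly at
    ``enzyme_nM = ec50``.
    """
    x = np.asarray(enzyme_nM, dtype=float)
    out = np.full_like(x, float(top))
    nz = x > 0
    out[nz] = bottom + (top - bottom) / (1.0 + (x[nz] / ec50) ** hill_slope)
    return float(out) if out.ndim == 0 else out


def normalize_to_control(
    raw_max_activities: Sequence[float], control_wells: Sequence[int]
) -> np.ndarray:
    """Express maximum specific activities as percent of the control mean.

    ``control_wells`` indexes the wells incubated without the peptidase.
    """
    raw = np.asarray(raw_max_activities, dtype=float)
    idx = np.asarray(control_wells, dtype=int)
    if idx.size == 0:
        raise ValueError("no control wells given")
    control_mean = float(np.mean(raw[idx]))
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return raw * 100.0 / control_mean


def fit_inhibition(
    data: DoseResponseDataset,
    fix_hill_slope: float | None = None,
    hill_bounds: tuple[float, float] = (0.3, 5.0),
) -> InhibitionFit:
    """Fit the four-parameter inhibition curve by nonlinear least squares.

    EC50 and the Hill slope are fitted on a log scale; zero-concentration
    points enter the residuals and pin the top plateau.  Replicates are
    fitted jointly, never averaged.  Standard errors come from the local
    curvature (Jacobian-based covariance).  ``fix_hill_slope`` freezes the
    slope (whether the reference analysis fitted or fixed it is not
    settled, so both are supported).
    """
    x = data.enzyme_nM
    y = data.signal_pct
    nonzero = np.unique(x[x > 0])
    if nonzero.size < 4:
        raise ValueError("need at least 4 distinct nonzero enzyme concentrations")

    # warn on overall non-monotonicity (mean signal increasing with dose)
    means = [y[x == c].mean() for c in np.concatenate([[0.0], nonzero]) if np.any(x == c)]
    increases = np.diff(means) > 0.15 * max(abs(np.max(means)), 1.0)
    monotone_warning = bool(np.any(increases))
    if monotone_warning:
        warnings.warn("dose-response not overall decreasing; fit may be unreliable")

    top0 = float(y[x == 0].mean()) if np.any(x == 0) else float(np.max(y))
    bottom0 = float(np.min(y))
    span0 = max(top0 - bottom0, 1e-6)
    # initial EC50: concentration whose mean signal is closest to half-way
    half = bottom0 + span0 / 2
    mid_idx = int(np.argmin([abs(y[x == c].mean() - half) for c in nonzero]))
    ec50_0 = float(nonzero[mid_idx])

    params = Parameters()
    params.add("top", value=top0)
    params.add("span", value=span0, min=0.0)
    params.add("bottom", expr="top - span")
    params.add("log_ec50", value=np.log(ec50_0), min=np.log(nonzero.min() / 100),
               max=np.log(nonzero.max() * 100))
    if fix_hill_slope is not None:
        params.add("log_hs", value=np.log(fix_hill_slope), vary=False)
    else:
        params.add("log_hs", value=0.0, min=np.log(hill_bounds[0]),
                   max=np.log(hill_bounds[1]))

    def residual(p):
        return (
            inhibition_model(
                x, p["top"].value, p["bottom"].value,
                np.exp(p["log_ec50"].value), np.exp(p["log_hs"].value),
            )
            - y
        )

    result = Minimizer(residual, params).minimize(method="leastsq")
    pf = result.params
    ec50 = float(np.exp(pf["log_ec50"].value))
    hs = float(np.exp(pf["log_hs"].value))

    def _se(name, scale=1.0):
        p = pf[name]
        return float(p.stderr * scale) if p.stderr is not None else None

    # delta method for the log-scale parameters
    se_ec50 = _se("log_ec50", ec50)
    se_hs = _se("log_hs", hs) if fix_hill_slope is None else None
    return InhibitionFit(
        top=float(pf["top"].value),
        bottom=float(pf["bottom"].value),
        ec50=ec50,
        hill_slope=hs,
        se_top=_se("top"),
        se_bottom=_se("bottom"),
        se_ec50=se_ec50,
        se_hill_slope=se_hs,
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        converged=bool(result.success),
        monotone_warning=monotone_warning,
    )


def apparent_turnover(ec50_nM: float, substrate_nM: float, incubation_min: float) -> float:
    """Apparent per-enzyme turnover rate (s⁻¹) at the half-signal point.

    Substrate molecules processed per enzyme per second when half the
    substrate pool is consumed by ``ec50_nM`` enzyme over the incubation:
    ``(substrate / ec50) / incubation_seconds``.
    """
    if ec50_nM <= 0 or substrate_nM <= 0 or incubation_min <= 0:
        raise ValueError("all inputs must be positive")
    return (substrate_nM / ec50_nM) / (incubation_min * 60.0)


def substrate_enzyme_ratio(ec50_nM: float, substrate_nM: float) -> float:
    """Pheromone-to-peptidase molar ratio at the half-signal point."""
    if ec50_nM <= 0 or substrate_nM <= 0:
        raise ValueError("all inputs must be positive")
    return substrate_nM / ec50_nM


def efficiency_ratio(fit_a: InhibitionFit | float, fit_b: InhibitionFit | float) -> float:
    """EC50 fold difference between two peptides (a relative to b).

    A ratio above 1 means peptide *a* needs more enzyme for half signal,
    i.e. is degraded less efficiently.
    """
    a = fit_a.ec50 if isinstance(fit_a, InhibitionFit) else float(fit_a)
    b = fit_b.ec50 if isinstance(fit_b, InhibitionFit) else float(fit_b)
    if a <= 0 or b <= 0:
        raise ValueError("EC50 values must be positive")
    return a / b


def screen_signal_loss(max_activity_without: float, max_activity_with: float) -> float:
    """Percent signal loss after pre-incubation with the peptidase.

    ``100 * (1 - with/without)``, clipped to [0, 100]; clipping is logged.
    """
    if max_activity_without <= 0:
        raise ValueError("activity without peptidase must be positive")
    loss = 100.0 * (1.0 - max_activity_with / max_activity_without)
    if loss < 0.0 or loss > 100.0:
        log.info("signal loss %.2f%% clipped to [0, 100]", loss)
        loss = min(max(loss, 0.0), 100.0)
    return loss
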