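"""Parameter sets for the ComRS competence circuit.

All internal quantities are expressed in molecules per cell and minutes;
concentrations (nM) appear only at the presentation boundary through the
conversion helpers in :mod:`comrs.model`.

Two calibrated presets are shipped:

* :func:`default_params` — the full circuit including the saturable
  pheromone-degradation player (``deg``, the PepF pool), calibrated so that
  an 8.5-fold ComR overexpression run reproduces the reference behaviour:
  ComX rising from roughly 200 min to a plateau near 150 molecules per cell,
  and a free intracellular XIP peak of ~6,000 molecules per cell.
* :func:`no_deg_params` — the same circuit with the degradation player
  removed and the activated comS production rate recalibrated so the ComX
  response is preserved while free XIP never exceeds a few molecules per
  cell.  This is the counterfactual model without the negative feedback
  loop, not merely the default preset with ``k_cat = 0``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

#: Canonical ordering of the state vector.
SPECIES = (
    "comR_free",
    "comS_intra",
    "xip_extra",
    "xip_intra",
    "complex_RX",
    "comX",
    "deg",
)

SCHEMA_VERSION = 1

TargetPool = Literal["xip_intra", "comS_intra", "both"]

#: Avogadro's number (molecules per mole).
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class DegradationLaw:
    """Michaelis–Menten law for the saturable pheromone-degradation machinery.

    The instantaneous flux is ``v(x) = k_cat * deg * x / (K_m + x)`` where
    ``deg`` is the current size of the peptidase pool.  The flux is zero at
    ``x = 0``, monotone in the substrate and bounded above by
    ``k_cat * deg`` — the saturation that lets a sharp pheromone burst
    overwhelm the machinery.
    """

    k_cat: float = 4.0  # min^-1
    K_m: float = 2.0  # molecules
    target_pool: TargetPool = "xip_intra"

    def __post_init__(self) -> None:
        if self.k_cat < 0 or self.K_m < 0:
            raise ValueError("k_cat and K_m must be non-negative")
        if self.target_pool not in ("xip_intra", "comS_intra", "both"):
            raise ValueError(f"unknown target_pool {self.target_pool!r}")

    def rate(self, deg: float, x: float) -> float:
        """Degradation flux (molecules/min) for pool size ``x``."""
        if x <= 0.0:
            return 0.0
        return self.k_cat * deg * x / (self.K_m + x)


@dataclass(frozen=True)
class CircuitParameters:
    """Rate constants and conversion factors of the deterministic circuit.

    Units: production rates in molecules·min⁻¹; Hill constants in molecules;
    first-order rates in min⁻¹; ``k_on`` in molecules⁻¹·min⁻¹;
    ``cell_volume`` in litres; ``culture_density`` in cells per litre.
    """

    # production
    k_R: float = 16.4
    k_S0: float = 0.1
    k_S: float = 650.0
    k_X: float = 3.0
    k_D0: float = 0.18
    k_DX: float = 2.0
    # Hill constants / exponents (activation by the ComR·XIP complex, and of
    # deg by ComX); exponent 2 reflects dimerization of the active complex
    K_S: float = 25.0
    K_X: float = 25.0
    K_D: float = 75.0
    n_S: float = 2.0
    n_X: float = 2.0
    n_D: float = 2.0
    # ComR·XIP binding
    k_on: float = 1.0e-3
    k_off: float = 0.1
    # transport (export of the ComS precursor, re-import of mature XIP)
    k_exp: float = 0.1
    k_imp: float = 0.2
    # saturable degradation (PepF pool acting on intracellular pheromone)
    degradation: DegradationLaw = field(default_factory=DegradationLaw)
    # first-order decay / growth dilution per species
    delta: dict[str, float] = field(
        default_factory=lambda: {name: 0.02 for name in SPECIES}
    )
    # reference constant only: predicted number of ComX boxes in the genome
    comX_box_capacity: float = 150.0
    # conversion factors
    cell_volume: float = 1.66e-15  # L; 1 molecule per cell ≈ 1 nM intracellular
    culture_density: float = 6.0e11  # cells per litre of culture

    def __post_init__(self) -> None:
        for name in (
            "k_R", "k_S0", "k_S", "k_X", "k_D0", "k_DX",
            "K_S", "K_X", "K_D", "k_on", "k_off", "k_exp", "k_imp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_S", "n_X", "n_D"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.comX_box_capacity <= 0:
            raise ValueError("comX_box_capacity must be positive")
        if self.cell_volume <= 0 or self.culture_density <= 0:
            raise ValueError("conversion factors must be positive")
        missing = set(SPECIES) - set(self.delta)
        if missing:
            raise ValueError(f"delta missing species: {sorted(missing)}")
        if any(v < 0 for v in self.delta.values()):
            raise ValueError("delta rates must be non-negative")

    # -- serialisation -----------------------------------------------------

    def replace(self, **changes) -> "CircuitParameters":
        """Return a copy with the given fields replaced.

        Degradation sub-fields may be addressed as ``k_cat``, ``K_m`` and
        ``target_pool``.
        """
        deg_changes = {
            k: changes.pop(k) for k in ("k_cat", "K_m", "target_pool")
            if k in changes
        }
        if deg_changes:
            changes["degradation"] = dataclasses.replace(
                self.degradation, **deg_changes
            )
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParameters":
        d = dict(d)
        d.pop("schema_version", None)
        if "degradation" in d and isinstance(d["degradation"], dict):
            d["degradation"] = DegradationLaw(**d["degradation"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CircuitParameters":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(doc)


def default_params() -> CircuitParameters:
    """Calibrated circuit including the saturable degradation player."""
    return CircuitParameters()


def no_deg_params() -> CircuitParameters:
    """Calibrated counterfactual circuit without the degradation player.

    The deg pool is removed (all its production and catalysis set to zero)
    and the activated comS production rate is recalibrated downward so the
    ComX response matches the full model; without scavenging by the
    peptidase a far smaller pheromone flux sustains the positive loop.

    The binding constants are also recalibrated: without degradation the
    model only reproduces the observed off/on behaviour in a low-pheromone-
    activity regime (different effective ComR·XIP association), which is
    precisely the tension that motivated introducing the degradation player.
    """
    return CircuitParameters().replace(
        k_D0=0.0, k_DX=0.0, k_cat=0.0,
        k_S=8.0, K_S=60.0, k_on=3.0e-3, k_off=0.3,
    )
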