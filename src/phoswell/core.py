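"""Domain types and unit helpers shared by every stage of the pipeline.

Canonical internal units
------------------------
concentration  mM (= mmol/L = nmol/µL)
volume         µL (converted to mL only inside permeability math)
time           s
area           cm²
permeability   cm/s
amount         nmol (mM × µL)

The default Transwell geometry is a 24-well polyester insert: 200 µL apical,
1000 µL basolateral, 0.33 cm² membrane, 0.4 µm pores.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ATOMIC_MASS_P",
    "ATOMIC_MASS_O",
    "TranswellGeometry",
    "Layout",
    "Inhibitor",
    "Condition",
    "ConcentrationSeries",
    "SamplingPlan",
    "phosphate_molar_mass",
    "convert_phosphorus_conc",
    "phosphorus_mmol_l_to_mg_dl",
    "amount_nmol",
]

# Fixed atomic masses (g/mol) so the conversion helpers are reproducible.
ATOMIC_MASS_P = 30.974
ATOMIC_MASS_O = 15.999


def phosphate_molar_mass() -> float:
    """Molar mass of the orthophosphate ion PO4³⁻ in g/mol (≈ 95)."""
    return ATOMIC_MASS_P + 4.0 * ATOMIC_MASS_O


def convert_phosphorus_conc(value_mg_dl: float) -> float:
    """Convert an elemental-phosphorus concentration from mg/dL to mmol/L.

    Clinical laboratories report serum phosphate as elemental phosphorus, so
    the divisor is the atomic mass of P, not the phosphate ion mass.
    The hyperphosphatemia cut-off 4.5 mg/dL maps to 1.45 mmol/L (commonly
    rounded to 1.46 in the clinical literature).
    """
    if value_mg_dl < 0:
        raise ValueError(f"concentration must be non-negative, got {value_mg_dl}")
    return value_mg_dl * 10.0 / ATOMIC_MASS_P


def phosphorus_mmol_l_to_mg_dl(value_mmol_l: float) -> float:
    """Inverse of :func:`convert_phosphorus_conc`."""
    if value_mmol_l < 0:
        raise ValueError(f"concentration must be non-negative, got {value_mmol_l}")
    return value_mmol_l * ATOMIC_MASS_P / 10.0


def amount_nmol(conc_mm: float | np.ndarray, volume_ul: float) -> float | np.ndarray:
    """Amount of substance in nmol for a concentration (mM) in a volume (µL)."""
    return conc_mm * volume_ul


@dataclass(frozen=True)
class TranswellGeometry:
    """Compartment volumes, membrane area and pore size of one insert."""

    apical_volume_ul: float = 200.0
    basolateral_volume_ul: float = 1000.0
    membrane_area_cm2: float = 0.33
    pore_size_um: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "apical_volume_ul",
            "basolateral_volume_ul",
            "membrane_area_cm2",
            "pore_size_um",
        ):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")

    @property
    def apical_volume_ml(self) -> float:
        return self.apical_volume_ul / 1000.0

    @property
    def basolateral_volume_ml(self) -> float:
        return self.basolateral_volume_ul / 1000.0

    @property
    def total_volume_ul(self) -> float:
        return self.apical_volume_ul + self.basolateral_volume_ul

    def to_dict(self) -> dict[str, float]:
        return {
            "apical_volume_ul": self.apical_volume_ul,
            "basolateral_volume_ul": self.basolateral_volume_ul,
            "membrane_area_cm2": self.membrane_area_cm2,
            "pore_size_um": self.pore_size_um,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "TranswellGeometry":
        known = {
            k: float(v)
            for k, v in d.items()
            if k in ("apical_volume_ul", "basolateral_volume_ul", "membrane_area_cm2", "pore_size_um")
        }
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown geometry fields: {sorted(unknown)}")
        return cls(**known)


DEFAULT_GEOMETRY = TranswellGeometry()


class Layout(str, enum.Enum):
    """Cell-model layout on the insert."""

    BLANK = "blank"
    MESO_APICAL = "meso_apical"
    MESO_BASOLATERAL = "meso_basolateral"
    ENDO_APICAL = "endo_apical"
    COCULTURED = "cocultured"

    @property
    def n_cell_layers(self) -> int:
        if self is Layout.BLANK:
            return 0
        if self is Layout.COCULTURED:
            return 2
        return 1


class Inhibitor(str, enum.Enum):
    """Pathway blockers used in the assay.

    PFA (foscarnet) competitively inhibits SLC20/SLC34 sodium–phosphate
    cotransporters (transcellular route); Tenapanor inhibits NHE3 and
    indirectly tightens the paracellular route.
    """

    PFA = "PFA"
    TENAPANOR = "Tenapanor"


#: Doses used throughout the assay: PFA in mM, Tenapanor in µM.
DEFAULT_INHIBITOR_DOSES: dict[Inhibitor, float] = {
    Inhibitor.PFA: 1.0,
    Inhibitor.TENAPANOR: 1.0,
}


def normalize_inhibitors(inhibitors: Iterable[Inhibitor | str]) -> frozenset[Inhibitor]:
    """Coerce inhibitor names to :class:`Inhibitor`, rejecting unknown ones."""
    out = set()
    for i in inhibitors:
        if isinstance(i, Inhibitor):
            out.add(i)
            continue
        try:
            out.add(Inhibitor(i))
        except ValueError:
            matches = [m for m in Inhibitor if m.value.lower() == str(i).lower()]
            if not matches:
                raise ValueError(f"unknown inhibitor {i!r}; known: {[m.value for m in Inhibitor]}") from None
            out.add(matches[0])
    return frozenset(out)


@dataclass(frozen=True)
class Condition:
    """One experimental condition: layout, phosphate dosing, inhibitor set."""

    layout: Layout = Layout.BLANK
    apical_phosphate_mm: float = 1.0
    basolateral_phosphate_mm: float = 0.1
    inhibitors: frozenset[Inhibitor] = frozenset()
    inhibitor_doses: Mapping[Inhibitor, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "layout", Layout(self.layout))
        object.__setattr__(self, "inhibitors", normalize_inhibitors(self.inhibitors))
        if self.apical_phosphate_mm < 0 or self.basolateral_phosphate_mm < 0:
            raise ValueError("phosphate concentrations must be non-negative")
        doses = dict(self.inhibitor_doses)
        extra = set(doses) - set(self.inhibitors)
        if extra:
            raise ValueError(f"doses given for absent inhibitors: {sorted(i.value for i in extra)}")
        for i in self.inhibitors:
            doses.setdefault(i, DEFAULT_INHIBITOR_DOSES[i])
        object.__setattr__(self, "inhibitor_doses", doses)
        if not self.name:
            label = self.layout.value
            if self.inhibitors:
                label += "+" + "+".join(sorted(i.value for i in self.inhibitors))
            object.__setattr__(self, "name", label)

    @property
    def condition_id(self) -> str:
        return self.name


@dataclass(frozen=True)
class SamplingPlan:
    """Volumes withdrawn from each compartment at each sampling time.

    ``replace_same``  — the withdrawn aliquot volume is replaced at the sampled
    concentration (net mass change zero; trajectories unaffected).
    ``replace_blank`` — replaced with phosphate-free medium: the compartment is
    diluted by (V−v)/V at each sampling and the withdrawn amount is tracked.
    """

    withdrawal_volume_ul: float = 0.0
    mode: str = "replace_same"

    def __post_init__(self) -> None:
        if self.withdrawal_volume_ul < 0:
            raise ValueError("withdrawal volume must be non-negative")
        if self.mode not in ("replace_same", "replace_blank"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


@dataclass
class ConcentrationSeries:
    """Timed apical + basolateral concentration measurements for one well."""

    condition: Condition
    replicate_id: str
    times_s: np.ndarray
    apical_mm: np.ndarray
    basolateral_mm: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.apical_mm = np.asarray(self.apical_mm, dtype=float)
        self.basolateral_mm = np.asarray(self.basolateral_mm, dtype=float)
        n = len(self.times_s)
        if len(self.apical_mm) != n or len(self.basolateral_mm) != n:
            raise ValueError("times, apical and basolateral must have equal length")
        if n == 0:
            raise ValueError("series must contain at least one time point")
        if self.times_s[0] != 0:
            raise ValueError("series must start at t = 0")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.apical_mm < 0) or np.any(self.basolateral_mm < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def c_a0(self) -> float:
        """Initial (donor) apical concentration, mM."""
        return float(self.apical_mm[0])

    @property
    def c_b0(self) -> float:
        """Initial basolateral (receiver) concentration, mM."""
        return float(self.basolateral_mm[0])

    def to_frame(self):
        """Long-format DataFrame with the on-disk CSV columns."""
        import pandas as pd

        n = len(self)
        rows = {
            "condition_id": [self.condition.condition_id] * (2 * n),
            "layout": [self.condition.layout.value] * (2 * n),
            "replicate": [self.replicate_id] * (2 * n),
            "time_s": np.concatenate([self.times_s, self.times_s]),
            "compartment": ["apical"] * n + ["basolateral"] * n,
            "conc_mM": np.concatenate([self.apical_mm, self.basolateral_mm]),
        }
        return pd.DataFrame(rows)
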