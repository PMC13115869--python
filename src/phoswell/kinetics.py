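"""Forward model: two-compartment diffusion across a composite membrane.

The insert is modelled as a filter in series with zero, one or two cell
layers.  Within a cell layer the transcellular (carrier-mediated) and
paracellular (tight-junction) routes conduct in parallel, so their
permeabilities add; the filter and the layers are traversed sequentially, so
their resistances (1/P) add.  Inhibitors act multiplicatively on their
pathway: PFA scales the transcellular permeability by (1 − e_pfa), Tenapanor
the paracellular one by (1 − e_tena).

With a constant overall permeability P (cm/s), membrane area A (cm²) and
compartment volumes V_a, V_b (mL), both well-mixed compartments relax
exponentially toward the mass-balance equilibrium
C_eq = (C_a0·V_a + C_b0·V_b)/(V_a + V_b) with rate constant

    k = P·A·(1/V_a + 1/V_b)            [1/s]

There is no active (uphill) flux term: with no concentration gradient the
concentrations stay put.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    DEFAULT_GEOMETRY,
    ConcentrationSeries,
    Condition,
    Inhibitor,
    Layout,
    TranswellGeometry,
    normalize_inhibitors,
)

__all__ = [
    "PermeabilityModel",
    "cell_layer_permeability",
    "compose_series",
    "overall_papp",
    "equilibration_rate_constant",
    "expected_equilibrium_conc",
    "closed_form_concentrations",
    "simulate_ode",
]


@dataclass(frozen=True)
class PermeabilityModel:
    """Pathway permeabilities (cm/s) and inhibitor efficacies of one insert.

    ``layers`` counts identical cell layers composed in series with the
    filter (0 = blank insert, 2 = co-culture of two such layers).  The
    optional ``leak_rate`` (1/s) adds first-order cellular consumption to the
    ODE simulator; it is off by default because the no-gradient control showed
    unchanged concentrations.
    """

    p_filter: float
    p_trans: float = 0.0
    p_para: float = 0.0
    efficacy_pfa: float = 0.0
    efficacy_tena: float = 0.0
    layers: int = 1
    leak_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_filter", "p_trans", "p_para"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.p_filter <= 0:
            raise ValueError("p_filter must be strictly positive")
        for name in ("efficacy_pfa", "efficacy_tena"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.layers not in (0, 1, 2):
            raise ValueError("layers must be 0, 1 or 2")
        if self.leak_rate < 0:
            raise ValueError("leak_rate must be non-negative")


def cell_layer_permeability(
    model: PermeabilityModel, inhibitors: Iterable[Inhibitor | str] = ()
) -> float:
    """Permeability of one cell layer (cm/s): parallel pathways under inhibition."""
    inh = normalize_inhibitors(inhibitors)
    p_t = model.p_trans * (1.0 - model.efficacy_pfa * (Inhibitor.PFA in inh))
    p_p = model.p_para * (1.0 - model.efficacy_tena * (Inhibitor.TENAPANOR in inh))
    return p_t + p_p


def compose_series(p_filter: float, layer_permeabilities: Sequence[float]) -> float:
    """Overall permeability of a filter plus cell layers traversed in series.

    Resistances add: 1/P = 1/p_filter + Σ 1/p_layer.  A fully blocked layer
    (zero permeability) blocks the composite, giving 0 rather than an error.
    """
    if p_filter <= 0:
        raise ValueError("p_filter must be strictly positive")
    if any(p < 0 for p in layer_permeabilities):
        raise ValueError("layer permeabilities must be non-negative")
    if any(p == 0 for p in layer_permeabilities):
        return 0.0
    return 1.0 / (1.0 / p_filter + sum(1.0 / p for p in layer_permeabilities))


def overall_papp(
    model: PermeabilityModel, inhibitors: Iterable[Inhibitor | str] = ()
) -> float:
    """Overall apparent permeability (cm/s) of the modelled insert.

    Blank inserts (``layers == 0``) return the filter permeability; otherwise
    the filter and ``layers`` identical cell layers compose in series, which
    can only reduce the permeability below ``p_filter``.
    """
    if model.layers == 0:
        return model.p_filter
    p_layer = cell_layer_permeability(model, inhibitors)
    return compose_series(model.p_filter, [p_layer] * model.layers)


def equilibration_rate_constant(papp: float, geom: TranswellGeometry = DEFAULT_GEOMETRY) -> float:
    """Rate constant k = Papp·A·(1/V_a + 1/V_b) in 1/s (volumes in mL)."""
    return papp * geom.membrane_area_cm2 * (
        1.0 / geom.apical_volume_ml + 1.0 / geom.basolateral_volume_ml
    )


def expected_equilibrium_conc(
    c_a0: float, c_b0: float, geom: TranswellGeometry = DEFAULT_GEOMETRY
) -> float:
    """Volume-weighted mass-balance equilibrium concentration (mM)."""
    return (c_a0 * geom.apical_volume_ul + c_b0 * geom.basolateral_volume_ul) / geom.total_volume_ul


def closed_form_concentrations(
    papp: float,
    geom: TranswellGeometry,
    c_a0: float,
    c_b0: float,
    t: float | np.ndarray,
):
    """Exact concentrations (C_a(t), C_b(t)) in mM at time(s) t (s).

    C_b(t) = C_eq + (C_b0 − C_eq)·exp(−k·t); C_a(t) follows from mass
    conservation.  Both tend to C_eq as t → ∞.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if papp < 0:
        raise ValueError("papp must be non-negative")
    c_eq = expected_equilibrium_conc(c_a0, c_b0, geom)
    k = equilibration_rate_constant(papp, geom)
    decay = np.exp(-k * t)
    c_b = c_eq + (c_b0 - c_eq) * decay
    c_a = c_eq + (c_a0 - c_eq) * decay
    if c_a.ndim == 0:
        return float(c_a), float(c_b)
    return c_a, c_b


def simulate_ode(
    papp: float,
    geom: TranswellGeometry,
    c_a0: float,
    c_b0: float,
    times: Sequence[float],
    condition: Condition | None = None,
    replicate_id: str = "ode",
    leak_rate: float = 0.0,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> ConcentrationSeries:
    """Numerically integrate the two-compartment ODE system.

    dC_a/dt = −P·A·(C_a − C_b)/V_a,  dC_b/dt = P·A·(C_a − C_b)/V_b
    (plus an optional first-order leak −λ·C in each compartment).  With
    ``leak_rate = 0`` the trajectory agrees with the closed form; the solver
    preserves the linear mass invariant to round-off.
    """
    times = np.asarray(times, dtype=float)
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    a_over_va = papp * geom.membrane_area_cm2 / geom.apical_volume_ml
    a_over_vb = papp * geom.membrane_area_cm2 / geom.basolateral_volume_ml

    def rhs(_t, y):
        grad = y[0] - y[1]
        return [-a_over_va * grad - leak_rate * y[0], a_over_vb * grad - leak_rate * y[1]]

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        [c_a0, c_b0],
        t_eval=times,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed (papp={papp:g}, c_a0={c_a0:g}, c_b0={c_b0:g}): {sol.message}"
        )
    if condition is None:
        condition = Condition(
            layout=Layout.BLANK, apical_phosphate_mm=c_a0, basolateral_phosphate_mm=c_b0
        )
    return ConcentrationSeries(
        condition=condition,
        replicate_id=replicate_id,
        times_s=times,
        apical_mm=np.clip(sol.y[0], 0.0, None),
        basolateral_mm=np.clip(sol.y[1], 0.0, None),
    )
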