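"""Inverse computations: equilibrium, percent transport, Papp, TER, QC.

The central object is :class:`PhosphateTransportModel`, a one-well kinetic
model whose :meth:`~PhosphateTransportModel.fit` returns a
:class:`TransportFitResults` carrying the Papp estimate, its standard error,
residual diagnostics and QC flags.  Two estimation methods are provided:

``nonsink``
    Least-squares fit of the exponential relaxation closed form in the single
    parameter Papp, using both compartments.  This is the recommended default
    because the assay starts with a non-zero receiver concentration
    (0.1 mM basolateral) and runs far from sink conditions.
``sink``
    The classical Papp = (dQ/dt)/(A·C0) slope estimator: least-squares slope
    of receiver amount versus time over a reporting interval (default 0–8 h),
    divided by membrane area × initial donor concentration.  It systematically
    underestimates permeability once the receiver concentration becomes
    appreciable, so a sink-condition check is attached to the result.

Module-level functions (``papp_nonsink_fit``, ``papp_sink_slope``,
``percent_transport``, ...) are thin wrappers over the model objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    DEFAULT_GEOMETRY,
    ConcentrationSeries,
    SamplingPlan,
    TranswellGeometry,
)
from .kinetics import (
    closed_form_concentrations,
    equilibration_rate_constant,
    expected_equilibrium_conc,
)

__all__ = [
    "QCWarning",
    "UndefinedTransportError",
    "expected_equilibrium",
    "expected_transport",
    "percent_transport",
    "papp_from_percent_equilibrium",
    "PhosphateTransportModel",
    "TransportFitResults",
    "papp_sink_slope",
    "papp_nonsink_fit",
    "inhibitor_effect_ratio",
    "headline_ratio",
    "ter_normalize",
    "mass_recovery",
    "TransportSummary",
    "summarize_transport",
    "fit_wells",
    "summarize_study",
    "PathwayDecomposition",
    "decompose_pathways",
]

DEFAULT_REPORTING_INTERVAL_S = (0.0, 8 * 3600.0)
SINK_TOLERANCE = 0.10  # warn when receiver exceeds 10% of donor concentration


class QCWarning(UserWarning):
    """Quality-control warning attached to an estimate."""


class UndefinedTransportError(ValueError):
    """Raised when percent transport is undefined (no concentration gradient)."""


def expected_equilibrium(
    c_a0: float, c_b0: float, geom: TranswellGeometry = DEFAULT_GEOMETRY
) -> float:
    """Mass-balance equilibrium concentration (C_a0·V_a + C_b0·V_b)/(V_a+V_b)."""
    return expected_equilibrium_conc(c_a0, c_b0, geom)


def expected_transport(
    c_a0: float, c_b0: float, geom: TranswellGeometry = DEFAULT_GEOMETRY, side: str = "basolateral"
) -> float:
    """Expected concentration change on one side: the delta to equilibrium (mM)."""
    c_eq = expected_equilibrium(c_a0, c_b0, geom)
    if side == "basolateral":
        return c_eq - c_b0
    if side == "apical":
        return c_a0 - c_eq
    raise ValueError(f"side must be 'apical' or 'basolateral', got {side!r}")


def percent_transport(
    series: ConcentrationSeries,
    side: str = "basolateral",
    geom: TranswellGeometry = DEFAULT_GEOMETRY,
) -> np.ndarray:
    """Percent of the expected equilibrium reached at each sampling time.

    basolateral: 100·(C_b(t) − C_b0)/(C_eq − C_b0);
    apical:      100·(C_a0 − C_a(t))/(C_a0 − C_eq).
    """
    delta = expected_transport(series.c_a0, series.c_b0, geom, side)
    if delta == 0:
        raise UndefinedTransportError(
            "percent transport undefined: initial apical and basolateral "
            "concentrations are equal, expected transport is zero"
        )
    if side == "basolateral":
        return (series.basolateral_mm - series.c_b0) / delta * 100.0
    return (series.c_a0 - series.apical_mm) / delta * 100.0


def papp_from_percent_equilibrium(
    percent: float, t_s: float, geom: TranswellGeometry = DEFAULT_GEOMETRY
) -> float:
    """Invert a percent-of-equilibrium reading at time t into a Papp (cm/s).

    percent/100 = 1 − exp(−k·t) with k = Papp·A·(1/V_a + 1/V_b).
    """
    if not (0.0 <= percent < 100.0):
        raise ValueError("percent must lie in [0, 100)")
    if t_s <= 0:
        raise ValueError("time must be positive")
    k = -np.log(1.0 - percent / 100.0) / t_s
    return k / (geom.membrane_area_cm2 * (1.0 / geom.apical_volume_ml + 1.0 / geom.basolateral_volume_ml))


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class PhosphateTransportModel:
    """Two-compartment kinetic model of one Transwell well.

    Parameters
    ----------
    series : ConcentrationSeries
        Timed apical and basolateral concentration measurements.
    geometry : TranswellGeometry, optional
        Insert geometry; defaults to the 200 µL / 1000 µL / 0.33 cm² insert.

    Examples
    --------
    >>> model = PhosphateTransportModel(series)
    >>> res = model.fit()                       # non-sink closed-form fit
    >>> res.papp, res.papp_se
    >>> print(res.summary())
    """

    def __init__(self, series: ConcentrationSeries, geometry: TranswellGeometry = DEFAULT_GEOMETRY):
        self.series = series
        self.geometry = geometry

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        condition_id: str | None = None,
        replicate: str | None = None,
        geometry: TranswellGeometry = DEFAULT_GEOMETRY,
    ) -> "PhosphateTransportModel":
        """Build a model for one well out of a long-format assay DataFrame."""
        from .io import series_from_frame

        sub = df
        if condition_id is not None:
            sub = sub[sub["condition_id"] == condition_id]
        if replicate is not None:
            sub = sub[sub["replicate"].astype(str) == str(replicate)]
        all_series = series_from_frame(sub)
        if len(all_series) != 1:
            raise ValueError(
                f"expected exactly one well after selection, found {len(all_series)}; "
                "pass condition_id/replicate to disambiguate"
            )
        return cls(all_series[0], geometry)

    # -- estimation ---------------------------------------------------------

    def fit(
        self,
        method: str = "nonsink",
        interval_s: tuple[float, float] | None = None,
    ) -> "TransportFitResults":
        if method == "nonsink":
            return self._fit_nonsink()
        if method == "sink":
            return self._fit_sink(interval_s or DEFAULT_REPORTING_INTERVAL_S)
        raise ValueError(f"unknown method {method!r}; use 'nonsink' or 'sink'")

    def _initial_guess(self) -> float:
        s, g = self.series, self.geometry
        try:
            pct = float(percent_transport(s, "basolateral", g)[-1])
        except UndefinedTransportError:
            return 1e-6
        pct = min(max(pct, 0.1), 99.9)
        return papp_from_percent_equilibrium(pct, float(s.times_s[-1]), g)

    def _fit_nonsink(self) -> "TransportFitResults":
        s, g = self.series, self.geometry
        if len(s) < 3:
            raise ValueError("non-sink fit needs at least 3 time points")
        obs = np.concatenate([s.apical_mm, s.basolateral_mm])

        def resid(p):
            c_a, c_b = closed_form_concentrations(p[0], g, s.c_a0, s.c_b0, s.times_s)
            return np.concatenate([c_a, c_b]) - obs

        x0 = max(self._initial_guess(), 1e-12)
        sol = least_squares(
            resid,
            x0=[x0],
            bounds=([0.0], [np.inf]),
            x_scale=[max(x0, 1e-8)],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        if not sol.success:
            raise RuntimeError(
                f"non-sink fit did not converge for well {s.replicate_id!r} "
                f"(cost={sol.cost:.3g}, message={sol.message!r})"
            )
        papp = float(sol.x[0])
        r = sol.fun
        dof = len(r) - 1
        jtj = float((sol.jac.T @ sol.jac).item())
        if dof > 0 and jtj > 0:
            s2 = float(r @ r) / dof
            papp_se = float(np.sqrt(s2 / jtj))
        else:
            papp_se = np.nan
        flags: list[str] = []
        if np.sqrt(np.mean(r**2)) > 0.25 * max(s.c_a0, 1e-12):
            flags.append("poor_fit")
        return TransportFitResults(
            model=self, papp=papp, papp_se=papp_se, method="nonsink", resid=r, qc_flags=flags
        )

    def _fit_sink(self, interval_s: tuple[float, float]) -> "TransportFitResults":
        s, g = self.series, self.geometry
        t0, t1 = interval_s
        mask = (s.times_s >= t0) & (s.times_s <= t1)
        if mask.sum() < 2:
            raise ValueError(f"need at least 2 samples in interval {interval_s}, found {mask.sum()}")
        t = s.times_s[mask]
        # receiver amount in nmol; donor concentration in nmol/cm^3 = mM * 1000
        q_nmol = s.basolateral_mm[mask] * g.basolateral_volume_ul
        flags: list[str] = []
        if np.any(s.basolateral_mm[mask] > SINK_TOLERANCE * np.maximum(s.apical_mm[mask], 1e-300)):
            flags.append("sink_violation")
            warnings.warn(
                "receiver concentration exceeds 10% of donor within the reporting "
                "interval; sink-slope Papp will be biased low — prefer method='nonsink'",
                QCWarning,
                stacklevel=3,
            )
        denom_t = t - t.mean()
        ss_t = float(denom_t @ denom_t)
        if ss_t == 0:
            raise ValueError("degenerate time grid in reporting interval")
        slope = float(denom_t @ (q_nmol - q_nmol.mean()) / ss_t)  # nmol/s
        c0_nmol_cm3 = s.c_a0 * 1000.0
        if c0_nmol_cm3 <= 0:
            raise ValueError("initial donor concentration must be positive for the sink estimator")
        papp = slope / (g.membrane_area_cm2 * c0_nmol_cm3)
        if papp < 0:
            flags.append("negative_slope")
            papp = 0.0
        if np.allclose(q_nmol, q_nmol[0]):
            flags.append("flat_series")
        fitted = q_nmol.mean() + slope * denom_t
        r = q_nmol - fitted
        if len(t) > 2:
            se_slope = float(np.sqrt((r @ r) / (len(t) - 2) / ss_t))
            papp_se = se_slope / (g.membrane_area_cm2 * c0_nmol_cm3)
        else:
            papp_se = np.nan
        return TransportFitResults(
            model=self,
            papp=papp,
            papp_se=papp_se,
            method="sink",
            resid=r,
            qc_flags=flags,
            interval_s=(float(t0), float(t1)),
        )


@dataclass
class TransportFitResults:
    """Papp estimate for one well, with uncertainty and diagnostics."""

    model: PhosphateTransportModel
    papp: float
    papp_se: float
    method: str
    resid: np.ndarray
    qc_flags: list[str] = field(default_factory=list)
    interval_s: tuple[float, float] | None = None

    @property
    def nobs(self) -> int:
        return len(self.resid)

    @property
    def rate_constant(self) -> float:
        """Equilibration rate constant k implied by the estimate, 1/s."""
        return equilibration_rate_constant(self.papp, self.model.geometry)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation confidence interval for Papp."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (self.papp - z * self.papp_se, self.papp + z * self.papp_se)

    def predict(self, times_s: Sequence[float]) -> pd.DataFrame:
        """Closed-form concentrations at ``times_s`` under the fitted Papp."""
        s, g = self.model.series, self.model.geometry
        c_a, c_b = closed_form_concentrations(self.papp, g, s.c_a0, s.c_b0, np.asarray(times_s, float))
        return pd.DataFrame({"time_s": times_s, "apical_mM": c_a, "basolateral_mM": c_b})

    def plot_fit(self, ax=None):
        """Observed points and fitted trajectories for both compartments."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        grid = np.linspace(0, s.times_s[-1], 200)
        pred = self.predict(grid)
        ax.plot(grid / 3600, pred["apical_mM"], "-", color="C0", label="apical (fit)")
        ax.plot(grid / 3600, pred["basolateral_mM"], "-", color="C1", label="basolateral (fit)")
        ax.plot(s.times_s / 3600, s.apical_mm, "o", color="C0", label="apical")
        ax.plot(s.times_s / 3600, s.basolateral_mm, "s", color="C1", label="basolateral")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("phosphate (mM)")
        ax.set_title(f"Papp = {self.papp:.3g} cm/s ({self.method})")
        ax.legend()
        return ax

    def summary(self) -> str:
        s = self.model.series
        lo, hi = self.conf_int() if np.isfinite(self.papp_se) else (np.nan, np.nan)
        lines = [
            "Phosphate transport fit",
            "=" * 52,
            f"well:            {s.condition.condition_id} / {s.replicate_id}",
            f"method:          {self.method}"
            + (f" (interval {self.interval_s[0]/3600:g}-{self.interval_s[1]/3600:g} h)" if self.interval_s else ""),
            f"n observations:  {self.nobs}",
            f"Papp:            {self.papp:.4g} cm/s",
            f"std err:         {self.papp_se:.3g} cm/s",
            f"95% CI:          [{lo:.4g}, {hi:.4g}] cm/s",
            f"rate constant k: {self.rate_constant:.4g} 1/s",
            f"RMS residual:    {np.sqrt(np.mean(self.resid**2)):.3g}",
            f"QC flags:        {', '.join(self.qc_flags) if self.qc_flags else 'none'}",
        ]
        return "\n".join(lines)


def papp_sink_slope(
    series: ConcentrationSeries,
    geom: TranswellGeometry = DEFAULT_GEOMETRY,
    interval_s: tuple[float, float] = DEFAULT_REPORTING_INTERVAL_S,
) -> float:
    """Sink-assumption Papp (cm/s): slope of receiver amount / (A·C0)."""
    return PhosphateTransportModel(series, geom).fit(method="sink", interval_s=interval_s).papp


def papp_nonsink_fit(
    series: ConcentrationSeries, geom: TranswellGeometry = DEFAULT_GEOMETRY
) -> float:
    """Non-sink Papp (cm/s): closed-form least-squares fit; inverse of the simulator."""
    return PhosphateTransportModel(series, geom).fit(method="nonsink").papp


# ---------------------------------------------------------------------------
# Inhibitor ratios, TER, recovery
# ---------------------------------------------------------------------------


def inhibitor_effect_ratio(papp_treated_mean: float, papp_control_mean: float) -> float:
    """Residual transport under inhibition, as % of control (100 = no effect)."""
    if papp_control_mean <= 0:
        raise ValueError("control Papp must be strictly positive")
    return 100.0 * papp_treated_mean / papp_control_mean


def headline_ratio(percent: float) -> float:
    """Round a percent ratio to the nearest 5% for headline reporting."""
    return 5.0 * round(percent / 5.0)


def ter_normalize(raw_ter_ohm: float, blank_ter_ohm: float, area_cm2: float = 0.33) -> float:
    """Blank-corrected, area-normalized transepithelial resistance (Ω·cm²).

    A raw reading below the blank yields a negative value; it is flagged via
    :class:`QCWarning` and returned as-is for the audit trail, never clamped.
    """
    corrected = (raw_ter_ohm - blank_ter_ohm) * area_cm2
    if raw_ter_ohm < blank_ter_ohm:
        warnings.warn(
            f"raw TER {raw_ter_ohm:g} Ω below blank {blank_ter_ohm:g} Ω; "
            "corrected value is negative and flagged, not clamped",
            QCWarning,
            stacklevel=2,
        )
    return corrected


def mass_recovery(
    series: ConcentrationSeries,
    geom: TranswellGeometry = DEFAULT_GEOMETRY,
    plan: SamplingPlan | None = None,
) -> np.ndarray:
    """Fraction of the initial phosphate amount accounted for at each time.

    recovery(t) = (amount now in both compartments + net amount withdrawn so
    far) / initial amount.  Under ``replace_same`` sampling the net withdrawn
    amount is zero; under ``replace_blank`` the withdrawn aliquots
    (concentration at sampling × withdrawn volume, both compartments) are
    added back in the bookkeeping.  Values should be 1.0 ± tolerance; a
    shortfall signals spillage, adsorption or cellular uptake.
    """
    v_a, v_b = geom.apical_volume_ul, geom.basolateral_volume_ul
    m0 = series.c_a0 * v_a + series.c_b0 * v_b
    if m0 <= 0:
        raise ValueError("initial amount must be positive")
    current = series.apical_mm * v_a + series.basolateral_mm * v_b
    if plan is None or plan.mode == "replace_same" or plan.withdrawal_volume_ul == 0:
        return current / m0
    # replace_blank: withdrawals at every t > 0, at the recorded concentration
    v_w = plan.withdrawal_volume_ul
    withdrawn_per_time = (series.apical_mm + series.basolateral_mm) * v_w
    withdrawn_per_time[series.times_s == 0] = 0.0
    cum_before = np.concatenate([[0.0], np.cumsum(withdrawn_per_time)[:-1]])
    return (current + cum_before) / m0


# ---------------------------------------------------------------------------
# Per-well summaries and study aggregation
# ---------------------------------------------------------------------------


@dataclass
class TransportSummary:
    """Per-well transport summary: equilibrium, percent transport, Papp, QC."""

    condition_id: str
    replicate_id: str
    expected_equilibrium_mm: float
    percent_transport_apical: np.ndarray
    percent_transport_basolateral: np.ndarray
    papp: float
    papp_se: float
    papp_method: str
    recovery: np.ndarray
    qc_flags: list[str]
    times_s: np.ndarray

    def to_row(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "replicate": self.replicate_id,
            "expected_equilibrium_mM": self.expected_equilibrium_mm,
            "pct_transport_basolateral_final": float(self.percent_transport_basolateral[-1]),
            "pct_transport_apical_final": float(self.percent_transport_apical[-1]),
            "papp_cm_s": self.papp,
            "papp_se_cm_s": self.papp_se,
            "papp_method": self.papp_method,
            "recovery_final": float(self.recovery[-1]),
            "qc_flags": ";".join(self.qc_flags),
        }


def summarize_transport(
    series: ConcentrationSeries,
    geom: TranswellGeometry = DEFAULT_GEOMETRY,
    method: str = "nonsink",
    interval_s: tuple[float, float] | None = None,
    plan: SamplingPlan | None = None,
    recovery_tolerance: float = 0.05,
) -> TransportSummary:
    """Run the full per-well analysis and collect it into a TransportSummary."""
    res = PhosphateTransportModel(series, geom).fit(method=method, interval_s=interval_s)
    rec = mass_recovery(series, geom, plan)
    flags = list(res.qc_flags)
    if np.any(np.abs(rec - 1.0) > recovery_tolerance):
        flags.append("recovery_out_of_band")
    return TransportSummary(
        condition_id=series.condition.condition_id,
        replicate_id=series.replicate_id,
        expected_equilibrium_mm=expected_equilibrium(series.c_a0, series.c_b0, geom),
        percent_transport_apical=percent_transport(series, "apical", geom),
        percent_transport_basolateral=percent_transport(series, "basolateral", geom),
        papp=res.papp,
        papp_se=res.papp_se,
        papp_method=method,
        recovery=rec,
        qc_flags=flags,
        times_s=series.times_s,
    )


def fit_wells(
    series_list: Iterable[ConcentrationSeries],
    geom: TranswellGeometry = DEFAULT_GEOMETRY,
    method: str = "nonsink",
    interval_s: tuple[float, float] | None = None,
    plan: SamplingPlan | None = None,
) -> pd.DataFrame:
    """Per-well Papp estimates and QC for a whole study, one row per well."""
    rows = [
        summarize_transport(s, geom, method=method, interval_s=interval_s, plan=plan).to_row()
        for s in series_list
    ]
    return pd.DataFrame(rows)


def summarize_study(well_estimates: pd.DataFrame) -> pd.DataFrame:
    """Condition-level mean ± SD of the per-well Papp estimates."""
    g = well_estimates.groupby("condition_id")["papp_cm_s"]
    out = g.agg(papp_mean="mean", papp_sd="std", n_wells="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# Pathway decomposition from inhibitor arms
# ---------------------------------------------------------------------------


@dataclass
class PathwayDecomposition:
    """Transcellular/paracellular split estimated from the inhibitor arms.

    Built from condition-mean Papp of three arms (no inhibitor, PFA alone,
    PFA + Tenapanor).  When the blank-filter permeability is supplied, the
    overall values are first converted to cell-layer permeabilities by
    removing the filter's series resistance, so the pathway estimates are on
    the cell-layer scale; otherwise they are differences of overall Papp and
    underestimate the layer-scale pathways.  With the default unit efficacies
    the estimates read as the inhibitor-sensitive components.
    """

    p_trans: float
    p_para: float
    p_insensitive: float
    ratio_pfa_pct: float
    ratio_both_pct: float
    headline_pfa_pct: float
    headline_both_pct: float
    scale: str
    qc_flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Pathway decomposition (" + self.scale + " scale)",
            "=" * 52,
            f"transcellular (PFA-sensitive):   {self.p_trans:.4g} cm/s",
            f"paracellular (Tenapanor-sens.):  {self.p_para:.4g} cm/s",
            f"inhibitor-insensitive residual:  {self.p_insensitive:.4g} cm/s",
            f"Papp ratio, PFA vs control:      {self.ratio_pfa_pct:.1f}% (headline {self.headline_pfa_pct:.0f}%)",
            f"Papp ratio, PFA+Tenapanor:       {self.ratio_both_pct:.1f}% (headline {self.headline_both_pct:.0f}%)",
            f"QC flags: {', '.join(self.qc_flags) if self.qc_flags else 'none'}",
        ]
        return "\n".join(lines)


def _layer_from_overall(papp: float, p_filter: float) -> float:
    inv = 1.0 / papp - 1.0 / p_filter
    if inv <= 0:
        raise ValueError(
            f"overall Papp {papp:g} is not below the filter permeability {p_filter:g}; "
            "cannot remove the filter resistance"
        )
    return 1.0 / inv


def decompose_pathways(
    papp_control: float,
    papp_pfa: float,
    papp_both: float,
    p_filter: float | None = None,
    efficacy_pfa: float = 1.0,
    efficacy_tena: float = 1.0,
) -> PathwayDecomposition:
    """Estimate transcellular and paracellular components from inhibitor arms.

    Uses the parallel-pathway identities on the cell-layer permeability L:
    L_control − L_pfa = e_pfa·p_trans and L_pfa − L_both = e_tena·p_para.
    The residual L_both-derived permeability is the inhibitor-insensitive
    component.  Single-layer inversion; for a two-layer co-culture the result
    is an effective single-layer equivalent.
    """
    for name, v in (("papp_control", papp_control), ("papp_pfa", papp_pfa), ("papp_both", papp_both)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    for name, e in (("efficacy_pfa", efficacy_pfa), ("efficacy_tena", efficacy_tena)):
        if not (0 < e <= 1):
            raise ValueError(f"{name} must lie in (0, 1]")
    flags: list[str] = []
    if p_filter is not None:
        scale = "cell-layer"
        l_control = _layer_from_overall(papp_control, p_filter)
        l_pfa = _layer_from_overall(papp_pfa, p_filter)
        l_both = _layer_from_overall(papp_both, p_filter)
    else:
        scale = "overall"
        l_control, l_pfa, l_both = papp_control, papp_pfa, papp_both
    p_trans = (l_control - l_pfa) / efficacy_pfa
    p_para = (l_pfa - l_both) / efficacy_tena
    if p_trans < 0:
        flags.append("negative_transcellular_estimate")
    if p_para < 0:
        flags.append("negative_paracellular_estimate")
    p_insensitive = l_both - (1 - efficacy_pfa) * p_trans - (1 - efficacy_tena) * p_para
    ratio_pfa = inhibitor_effect_ratio(papp_pfa, papp_control)
    ratio_both = inhibitor_effect_ratio(papp_both, papp_control)
    return PathwayDecomposition(
        p_trans=p_trans,
        p_para=p_para,
        p_insensitive=p_insensitive,
        ratio_pfa_pct=ratio_pfa,
        ratio_both_pct=ratio_both,
        headline_pfa_pct=headline_ratio(ratio_pfa),
        headline_both_pct=headline_ratio(ratio_both),
        scale=scale,
        qc_flags=flags,
    )
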