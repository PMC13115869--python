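"""Synthetic assay datasets and count matrices.

Time-series generator: each well follows the exponential closed form under
its condition's composed overall permeability, sampled at 0/4/8/12 h, with
heteroscedastic Gaussian measurement noise (σ = noise_sd·C + 0.005 mM floor,
mimicking a clinical analyzer's proportional CV with an additive detection
floor).  Negative draws are clamped at zero and counted.  A single master
seed drives per-well substreams, so the same seed always reproduces the same
study.

The "paper-like" preset encodes the study conditions: a blank filter at
1.8e-5 cm/s; a leaky, mostly paracellular endothelial (HUVEC) layer; a
tighter mesothelial (MeT-5A) layer with equal transcellular/paracellular
shares giving an overall Papp of 7.75e-6 cm/s; and a co-culture stacking
both layers on one filter (overall ≈ 0.90 × the mesothelial value).
Inhibitor efficacies are 0.2 (PFA, transcellular) and 0.15 (Tenapanor,
paracellular).

Count-matrix generator: negative-binomial raw counts over the ten-gene
sodium–phosphate transporter panel, with mean profiles chosen so the
detection calls reproduce the qualitative expression pattern of the four
cell lines (SLC20A1/SLC20A2/XPR1 high everywhere, SLC34A2 HPMC-only,
SLC34A3 MeT-5A-only) or of the patient arteriole groups (SLC20A1 two-fold
up in low-GDP PD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_GEOMETRY,
    ConcentrationSeries,
    Condition,
    Inhibitor,
    Layout,
    SamplingPlan,
    TranswellGeometry,
)
from .kinetics import (
    PermeabilityModel,
    cell_layer_permeability,
    closed_form_concentrations,
    compose_series,
)

__all__ = [
    "StudyArm",
    "StudyDesign",
    "SyntheticStudy",
    "paper_like_design",
    "generate_timeseries",
    "CountConfig",
    "cell_line_count_config",
    "arteriole_count_config",
    "generate_count_matrix",
]

DEFAULT_SAMPLE_TIMES_S = (0.0, 4 * 3600.0, 8 * 3600.0, 12 * 3600.0)
NOISE_FLOOR_MM = 0.005

#: Preset ground truth (cm/s): filter and per-layer pathway permeabilities.
PRESET_P_FILTER = 1.8e-5
PRESET_MESO_LAYER = PermeabilityModel(
    p_filter=PRESET_P_FILTER, p_trans=6.8e-6, p_para=6.8e-6,
    efficacy_pfa=0.2, efficacy_tena=0.15, layers=1,
)
PRESET_ENDO_LAYER = PermeabilityModel(
    p_filter=PRESET_P_FILTER, p_trans=5.0e-6, p_para=6.5e-5,
    efficacy_pfa=0.2, efficacy_tena=0.15, layers=1,
)


@dataclass(frozen=True)
class StudyArm:
    """One condition plus its ground-truth membrane composition.

    ``layer_models`` lists the cell layers stacked on the filter (empty for a
    blank insert); the co-culture carries two different layer models.
    """

    condition: Condition
    layer_models: tuple[PermeabilityModel, ...] = ()
    p_filter: float = PRESET_P_FILTER

    def true_papp(self) -> float:
        """Overall permeability of this arm with its inhibitors applied."""
        inh = self.condition.inhibitors
        layers = [cell_layer_permeability(m, inh) for m in self.layer_models]
        if not layers:
            return self.p_filter
        return compose_series(self.p_filter, layers)


@dataclass
class StudyDesign:
    """Full synthetic-study specification; the generator's single input."""

    arms: list[StudyArm]
    replicates: int = 6
    sample_times_s: tuple[float, ...] = DEFAULT_SAMPLE_TIMES_S
    noise_sd: float = 0.02
    noise_floor_mm: float = NOISE_FLOOR_MM
    sampling: SamplingPlan = field(default_factory=SamplingPlan)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0 or self.noise_floor_mm < 0:
            raise ValueError("noise parameters must be non-negative")
        t = np.asarray(self.sample_times_s, float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must start at 0 and increase strictly")


def _layers_for(layout: Layout) -> tuple[PermeabilityModel, ...]:
    return {
        Layout.BLANK: (),
        Layout.MESO_APICAL: (PRESET_MESO_LAYER,),
        Layout.MESO_BASOLATERAL: (PRESET_MESO_LAYER,),
        Layout.ENDO_APICAL: (PRESET_ENDO_LAYER,),
        Layout.COCULTURED: (PRESET_ENDO_LAYER, PRESET_MESO_LAYER),
    }[layout]


def paper_like_design(
    replicates: int = 6,
    noise_sd: float = 0.02,
    seed: int = 0,
    apical_phosphate_mm: float = 1.0,
    basolateral_phosphate_mm: float = 0.1,
    include_inhibitor_arms: bool = True,
    layouts: Sequence[Layout] | None = None,
) -> StudyDesign:
    """Study design mirroring the published assay conditions.

    Base arms cover the blank filter and the four cell models at 1 mM apical /
    0.1 mM basolateral phosphate; inhibitor arms add PFA and PFA+Tenapanor to
    the mesothelial and co-culture models.
    """
    if layouts is None:
        layouts = (
            Layout.BLANK,
            Layout.ENDO_APICAL,
            Layout.MESO_APICAL,
            Layout.MESO_BASOLATERAL,
            Layout.COCULTURED,
        )
    arms = [
        StudyArm(
            Condition(
                layout=lay,
                apical_phosphate_mm=apical_phosphate_mm,
                basolateral_phosphate_mm=basolateral_phosphate_mm,
            ),
            _layers_for(lay),
        )
        for lay in layouts
    ]
    if include_inhibitor_arms:
        for lay in (Layout.MESO_BASOLATERAL, Layout.COCULTURED):
            if lay not in layouts:
                continue
            for inh in ({Inhibitor.PFA}, {Inhibitor.PFA, Inhibitor.TENAPANOR}):
                arms.append(
                    StudyArm(
                        Condition(
                            layout=lay,
                            apical_phosphate_mm=apical_phosphate_mm,
                            basolateral_phosphate_mm=basolateral_phosphate_mm,
                            inhibitors=frozenset(inh),
                        ),
                        _layers_for(lay),
                    )
                )
    return StudyDesign(arms=arms, replicates=replicates, noise_sd=noise_sd, seed=seed)


@dataclass
class SyntheticStudy:
    """Generated series plus the ground truth they were drawn from."""

    series: list[ConcentrationSeries]
    truth: pd.DataFrame  # condition_id, layout, inhibitors, true_papp_cm_s
    design: StudyDesign
    clamp_count: int = 0

    def truth_papp(self, condition_id: str) -> float:
        row = self.truth[self.truth["condition_id"] == condition_id]
        if len(row) != 1:
            raise KeyError(f"no unique truth row for {condition_id!r}")
        return float(row["true_papp_cm_s"].iloc[0])


def _noiseless_trajectory(
    papp: float,
    geom: TranswellGeometry,
    c_a0: float,
    c_b0: float,
    times: np.ndarray,
    plan: SamplingPlan,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form trajectory, piecewise-diluted when sampling replaces with blank medium."""
    if plan.mode != "replace_blank" or plan.withdrawal_volume_ul == 0:
        return closed_form_concentrations(papp, geom, c_a0, c_b0, times)
    v_w = plan.withdrawal_volume_ul
    f_a = (geom.apical_volume_ul - v_w) / geom.apical_volume_ul
    f_b = (geom.basolateral_volume_ul - v_w) / geom.basolateral_volume_ul
    if f_a <= 0 or f_b <= 0:
        raise ValueError("withdrawal volume exceeds a compartment volume")
    c_a = np.empty_like(times)
    c_b = np.empty_like(times)
    cur_a, cur_b, t_prev = c_a0, c_b0, 0.0
    for i, t in enumerate(times):
        a, b = closed_form_concentrations(papp, geom, cur_a, cur_b, t - t_prev)
        c_a[i], c_b[i] = a, b  # recorded = pre-withdrawal concentration
        if t > 0:
            cur_a, cur_b, t_prev = a * f_a, b * f_b, t
        else:
            cur_a, cur_b = a, b
    return c_a, c_b


def generate_timeseries(
    design: StudyDesign, geom: TranswellGeometry = DEFAULT_GEOMETRY
) -> SyntheticStudy:
    """Simulate every well of the design; deterministic for a given seed."""
    root = np.random.SeedSequence(design.seed)
    streams = root.spawn(len(design.arms) * design.replicates)
    times = np.asarray(design.sample_times_s, float)
    series: list[ConcentrationSeries] = []
    truth_rows = []
    clamped = 0
    for a_idx, arm in enumerate(design.arms):
        papp = arm.true_papp()
        cond = arm.condition
        truth_rows.append(
            {
                "condition_id": cond.condition_id,
                "layout": cond.layout.value,
                "inhibitors": "+".join(sorted(i.value for i in cond.inhibitors)),
                "true_papp_cm_s": papp,
            }
        )
        c_a_clean, c_b_clean = _noiseless_trajectory(
            papp, geom, cond.apical_phosphate_mm, cond.basolateral_phosphate_mm, times, design.sampling
        )
        for r in range(design.replicates):
            rng = np.random.default_rng(streams[a_idx * design.replicates + r])
            if design.noise_sd > 0 or design.noise_floor_mm > 0:
                sd_a = design.noise_sd * c_a_clean + design.noise_floor_mm
                sd_b = design.noise_sd * c_b_clean + design.noise_floor_mm
                c_a = c_a_clean + rng.normal(0.0, 1.0, size=len(times)) * sd_a
                c_b = c_b_clean + rng.normal(0.0, 1.0, size=len(times)) * sd_b
            else:
                c_a, c_b = c_a_clean.copy(), c_b_clean.copy()
            clamped += int(np.sum(c_a < 0) + np.sum(c_b < 0))
            series.append(
                ConcentrationSeries(
                    condition=cond,
                    replicate_id=f"w{r + 1}",
                    times_s=times,
                    apical_mm=np.clip(c_a, 0.0, None),
                    basolateral_mm=np.clip(c_b, 0.0, None),
                )
            )
    return SyntheticStudy(
        series=series, truth=pd.DataFrame(truth_rows), design=design, clamp_count=clamped
    )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountConfig:
    """Negative-binomial count model: per-gene, per-group mean raw counts."""

    means: Mapping[str, Mapping[str, float]]  # gene -> group -> mean count
    group_sizes: Mapping[str, int]
    dispersion: float = 0.1
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValueError("zero_inflation must lie in [0, 1)")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have at least one sample")


CELL_LINE_GROUPS = ("HPMC", "MeT-5A", "HUVEC", "HCMEC")
ARTERIOLE_GROUPS = ("NKF", "CKD5", "low-GDP PD", "high-GDP PD")
_PANEL_SYMBOLS = (
    "SLC20A1", "SLC20A2", "SLC34A1", "SLC34A2", "SLC34A3",
    "SLC17A1", "SLC17A2", "SLC17A3", "SLC17A4", "XPR1",
)


def cell_line_count_config(dispersion: float = 0.1, replicates: int = 3) -> CountConfig:
    """Means reproducing the four-cell-line detection pattern at threshold 100."""
    base_low = 15.0
    means: dict[str, dict[str, float]] = {g: {ct: base_low for ct in CELL_LINE_GROUPS} for g in _PANEL_SYMBOLS}
    for g in ("SLC20A1", "SLC20A2", "XPR1"):
        means[g] = {ct: 2000.0 for ct in CELL_LINE_GROUPS}
    means["SLC34A2"]["HPMC"] = 400.0
    means["SLC34A3"]["MeT-5A"] = 300.0
    return CountConfig(
        means=means,
        group_sizes={ct: replicates for ct in CELL_LINE_GROUPS},
        dispersion=dispersion,
    )


def arteriole_count_config(dispersion: float = 0.1) -> CountConfig:
    """Patient-arteriole means: five detected transporters, SLC20A1 2× in low-GDP PD."""
    means: dict[str, dict[str, float]] = {g: {gr: 20.0 for gr in ARTERIOLE_GROUPS} for g in _PANEL_SYMBOLS}
    for g in ("SLC20A2", "SLC34A1", "SLC17A1", "XPR1"):
        means[g] = {gr: 800.0 for gr in ARTERIOLE_GROUPS}
    means["SLC20A1"] = {"NKF": 1000.0, "CKD5": 1000.0, "low-GDP PD": 2000.0, "high-GDP PD": 1300.0}
    # cohort sizes: 8 NKF-like controls, 8 CKD5, 5 low-GDP, 6 high-GDP
    return CountConfig(
        means=means,
        group_sizes={"NKF": 8, "CKD5": 8, "low-GDP PD": 5, "high-GDP PD": 6},
        dispersion=dispersion,
    )


def generate_count_matrix(
    config: CountConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a genes × samples raw-count matrix and its sample metadata.

    Counts are negative binomial with var = µ + dispersion·µ²; dispersion 0
    degenerates to the configured means exactly.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = list(config.means)
    sample_names: list[str] = []
    groups: list[str] = []
    for grp, n in config.group_sizes.items():
        for i in range(n):
            sample_names.append(f"{grp}_{i + 1}")
            groups.append(grp)
    data = np.zeros((len(genes), len(sample_names)), dtype=np.int64)
    for gi, gene in enumerate(genes):
        for si, (name, grp) in enumerate(zip(sample_names, groups)):
            mu = float(config.means[gene].get(grp, 0.0))
            if mu <= 0:
                data[gi, si] = 0
                continue
            if config.dispersion == 0:
                c = int(round(mu))
            else:
                n_param = 1.0 / config.dispersion
                p_param = n_param / (n_param + mu)
                c = int(rng.negative_binomial(n_param, p_param))
            if config.zero_inflation > 0 and rng.random() < config.zero_inflation:
                c = 0
            data[gi, si] = c
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=sample_names)
    metadata = pd.DataFrame({"sample": sample_names, "group": groups}).set_index("sample")
    return counts, metadata
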