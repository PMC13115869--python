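"""File I/O and configuration: long-format assay CSV, count tables, YAML.

The assay interchange format is a UTF-8 long-format CSV with header
``condition_id,layout,replicate,time_s,compartment,conc_mM`` ('.' decimal
separator).  Readers validate every row and report malformed ones with their
CSV line number; rows are never silently dropped.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    ConcentrationSeries,
    Condition,
    Inhibitor,
    Layout,
    SamplingPlan,
    TranswellGeometry,
)
from .kinetics import PermeabilityModel

__all__ = [
    "SERIES_COLUMNS",
    "frame_from_series",
    "series_from_frame",
    "write_series_csv",
    "read_series_csv",
    "write_counts",
    "read_counts",
    "load_config",
    "geometry_from_config",
    "permeability_model_from_config",
    "design_from_config",
    "write_resolved_config",
    "papp_unit_scale",
]

SERIES_COLUMNS = ["condition_id", "layout", "replicate", "time_s", "compartment", "conc_mM"]
_COMPARTMENTS = {"apical", "basolateral"}


def frame_from_series(series_list: Iterable[ConcentrationSeries]) -> pd.DataFrame:
    frames = [s.to_frame() for s in series_list]
    if not frames:
        return pd.DataFrame(columns=SERIES_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SERIES_COLUMNS]


def _condition_from_id(condition_id: str, layout: Layout, c_a0: float, c_b0: float) -> Condition:
    """Reconstruct a Condition from its id string and the baseline row."""
    inhibitors: set[Inhibitor] = set()
    for token in str(condition_id).split("+")[1:]:
        try:
            inhibitors.add(Inhibitor(token))
        except ValueError:
            matches = [m for m in Inhibitor if m.value.lower() == token.lower()]
            if matches:
                inhibitors.add(matches[0])
    return Condition(
        layout=layout,
        apical_phosphate_mm=c_a0,
        basolateral_phosphate_mm=c_b0,
        inhibitors=frozenset(inhibitors),
        name=str(condition_id),
    )


def series_from_frame(df: pd.DataFrame) -> list[ConcentrationSeries]:
    """Assemble one ConcentrationSeries per (condition_id, replicate) well."""
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["compartment"] not in _COMPARTMENTS:
            errors.append(f"line {line}: invalid compartment {row['compartment']!r}")
        try:
            Layout(row["layout"])
        except ValueError:
            errors.append(f"line {line}: invalid layout {row['layout']!r}")
        try:
            t = float(row["time_s"])
            if t < 0:
                errors.append(f"line {line}: negative time {t}")
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric time_s {row['time_s']!r}")
        try:
            c = float(row["conc_mM"])
            if c < 0 or not np.isfinite(c):
                errors.append(f"line {line}: invalid concentration {row['conc_mM']!r}")
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric conc_mM {row['conc_mM']!r}")
    if errors:
        shown = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise ValueError(f"malformed assay rows:\n{shown}{more}")

    out: list[ConcentrationSeries] = []
    for (cid, rep), well in df.groupby(["condition_id", "replicate"], sort=False):
        layouts = well["layout"].unique()
        if len(layouts) != 1:
            raise ValueError(f"well ({cid!r}, {rep!r}) mixes layouts {list(layouts)}")
        pivot = well.pivot_table(index="time_s", columns="compartment", values="conc_mM")
        if pivot.isna().any().any() or set(pivot.columns) != _COMPARTMENTS:
            raise ValueError(
                f"well ({cid!r}, {rep!r}) lacks paired apical/basolateral samples at some times"
            )
        pivot = pivot.sort_index()
        times = pivot.index.to_numpy(dtype=float)
        apical = pivot["apical"].to_numpy(dtype=float)
        baso = pivot["basolateral"].to_numpy(dtype=float)
        cond = _condition_from_id(cid, Layout(layouts[0]), float(apical[0]), float(baso[0]))
        out.append(
            ConcentrationSeries(
                condition=cond,
                replicate_id=str(rep),
                times_s=times,
                apical_mm=apical,
                basolateral_mm=baso,
            )
        )
    return out


def write_series_csv(series_list: Iterable[ConcentrationSeries], path: str | Path) -> None:
    frame_from_series(series_list).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> list[ConcentrationSeries]:
    # round_trip parsing keeps writer → reader bit-identical for valid files
    df = pd.read_csv(path, float_precision="round_trip")
    return series_from_frame(df)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def write_counts(
    counts: pd.DataFrame, metadata: pd.DataFrame, path: str | Path, metadata_path: str | Path
) -> None:
    """Write genes × samples counts (TSV for .tsv, else CSV) plus sample metadata."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    counts.to_csv(path, sep=sep)
    metadata.to_csv(metadata_path)


def read_counts(path: str | Path, metadata_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    sep = "\t" if str(path).endswith(".tsv") else ","
    counts = pd.read_csv(path, sep=sep, index_col=0)
    metadata = pd.read_csv(metadata_path, index_col=0)
    if "group" not in metadata.columns:
        raise ValueError(f"{metadata_path}: metadata must contain a 'group' column")
    bad = counts.columns[~counts.columns.isin(metadata.index)]
    if len(bad):
        raise ValueError(f"samples without metadata: {list(bad)}")
    return counts, metadata


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return cfg


def geometry_from_config(cfg: Mapping | None) -> TranswellGeometry:
    """`geometry:` block; omitted fields take the standard insert defaults."""
    block = (cfg or {}).get("geometry", {}) if cfg else {}
    return TranswellGeometry.from_dict(block or {})


def permeability_model_from_config(block: Mapping) -> PermeabilityModel:
    known = {
        "p_filter", "p_trans", "p_para", "efficacy_pfa", "efficacy_tena", "layers", "leak_rate",
    }
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown model fields: {sorted(unknown)}")
    return PermeabilityModel(**{k: v for k, v in block.items()})


def design_from_config(cfg: Mapping):
    """Build a StudyDesign from a `design:` config block.

    Either ``preset: paper_like`` (with optional replicates / noise_sd / seed
    overrides) or an explicit ``arms:`` list, each arm giving layout,
    phosphate doses, inhibitors and a `model:` block.
    """
    from .synthetic import StudyArm, StudyDesign, paper_like_design

    block = dict(cfg.get("design", cfg))
    if block.get("preset") == "paper_like":
        kwargs = {
            k: block[k]
            for k in ("replicates", "noise_sd", "seed", "include_inhibitor_arms")
            if k in block
        }
        return paper_like_design(**kwargs)
    arms = []
    for a in block.get("arms", []):
        model = permeability_model_from_config(a.get("model", {}))
        cond = Condition(
            layout=Layout(a["layout"]),
            apical_phosphate_mm=float(a.get("apical_phosphate_mm", 1.0)),
            basolateral_phosphate_mm=float(a.get("basolateral_phosphate_mm", 0.1)),
            inhibitors=frozenset(a.get("inhibitors", ())),
            name=a.get("name", ""),
        )
        arms.append(StudyArm(cond, (model,) * model.layers, p_filter=model.p_filter))
    if not arms:
        raise ValueError("design config needs either preset: paper_like or a non-empty arms list")
    kwargs = {}
    for k in ("replicates", "noise_sd", "noise_floor_mm", "seed"):
        if k in block:
            kwargs[k] = block[k]
    if "sample_times_s" in block:
        kwargs["sample_times_s"] = tuple(float(t) for t in block["sample_times_s"])
    if "withdrawal_volume_ul" in block or "sampling_mode" in block:
        kwargs["sampling"] = SamplingPlan(
            withdrawal_volume_ul=float(block.get("withdrawal_volume_ul", 0.0)),
            mode=block.get("sampling_mode", "replace_same"),
        )
    return StudyDesign(arms=arms, **kwargs)


def write_resolved_config(path: str | Path, resolved: Mapping) -> None:
    """Provenance record: the fully resolved configuration of a run, as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


_UNIT_RE = re.compile(r"^\s*(?:[x×]?\s*10\^?\s*(-?\d+)|1e(-?\d+))?\s*cm/s\s*$", re.IGNORECASE)


def papp_unit_scale(unit: str) -> float:
    """Scale factor turning a printed Papp column into cm/s.

    Accepts "cm/s", "1e-6 cm/s", "x10^-6 cm/s" and the like.  A positive
    exponent (e.g. "x10^6 cm/s") is physically implausible for a
    permeability printed as a small multiple, so it is interpreted as the
    corresponding negative exponent with a warning.
    """
    m = _UNIT_RE.match(unit)
    if not m:
        raise ValueError(f"unrecognized Papp unit {unit!r}")
    exp_str = m.group(1) or m.group(2)
    if exp_str is None:
        return 1.0
    exp = int(exp_str)
    if exp > 0:
        warnings.warn(
            f"Papp unit {unit!r} has a positive exponent; interpreting as 10^{-exp} cm/s",
            stacklevel=2,
        )
        exp = -exp
    return 10.0**exp
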