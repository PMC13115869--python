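"""Transporter-panel detection filtering and group fold-change tables.

Ten known phosphate transporters are screened: the type III sodium–phosphate
cotransporters SLC20A1 (PiT-1) and SLC20A2 (PiT-2), the type II family
SLC34A1–3, the type I family SLC17A1–4, and the sole known phosphate efflux
transporter XPR1 (SLC53A1).  A gene counts as detected in a sample group when
its mean raw count reaches the detection threshold (default 100, boundary
inclusive — transcripts *below* 100 are excluded as background noise).

Fold changes are ratios of group mean raw counts against a reference group,
restricted to detected genes.  No library-size normalization is applied by
default (the raw-count presentation); pass ``size_factors`` to enable it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PanelGene",
    "TransporterPanel",
    "PHOSPHATE_TRANSPORTER_PANEL",
    "CountMatrix",
    "filter_detected",
    "fold_change_table",
]

DETECTION_THRESHOLD = 100.0


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    entrez_id: int
    gene_name: str
    aliases: tuple[str, ...]


class TransporterPanel:
    """An ordered gene panel with alias → symbol resolution."""

    def __init__(self, genes: list[PanelGene]):
        symbols = [g.symbol for g in genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("panel symbols must be unique")
        self.genes = list(genes)
        self._alias_map: dict[str, str] = {}
        for g in genes:
            self._alias_map[g.symbol.upper()] = g.symbol
            for a in g.aliases:
                self._alias_map.setdefault(a.upper(), g.symbol)

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def resolve(self, name: str) -> str | None:
        """Canonical symbol for a gene name or alias; None if not on the panel."""
        return self._alias_map.get(str(name).upper())

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


#: The ten-gene sodium-phosphate transporter panel used throughout.
PHOSPHATE_TRANSPORTER_PANEL = TransporterPanel(
    [
        PanelGene("SLC20A1", 6574, "Solute Carrier Family 20 Member 1", ("GLVR1", "Glvr-1", "PIT1", "PiT-1")),
        PanelGene("SLC20A2", 6575, "Solute Carrier Family 20 Member 2", ("PiT-2", "PIT2", "GLVR2", "Glvr-2", "Ram-1")),
        PanelGene("SLC34A1", 6569, "Solute Carrier Family 34 Member 1", ("FRTS2", "HCINF2", "NAPI-3", "NPHLOP1", "NPT2")),
        PanelGene("SLC34A2", 10568, "Solute Carrier Family 34 Member 2", ("NAPI-3B", "NAPI-IIb", "NPTIIb", "NaPi2b", "PULAM")),
        PanelGene("SLC34A3", 142680, "Solute Carrier Family 34 Member 3", ("HHRH", "NPT2C", "NPTIIc")),
        PanelGene("SLC17A1", 6568, "Solute Carrier Family 17 Member 1", ("NPT1", "NAPI-1")),
        PanelGene("SLC17A2", 10246, "Solute Carrier Family 17 Member 2", ("NPT3",)),
        PanelGene("SLC17A3", 10786, "Solute Carrier Family 17 Member 3", ("GOUT4", "NPT4", "UAQTL4")),
        PanelGene("SLC17A4", 10050, "Solute Carrier Family 17 Member 4", ("KIAA2138",)),
        PanelGene("XPR1", 9213, "Xenotropic And Polytropic Retrovirus Receptor 1", ("SLC53A1", "SYG1", "X3", "IBGC6")),
    ]
)


@dataclass
class CountMatrix:
    """Raw counts (genes × samples) with a sample → group assignment."""

    counts: pd.DataFrame
    sample_groups: pd.Series  # indexed by sample name

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c.values, np.round(c.values)):
            raise ValueError("counts must be integral raw counts")
        missing = set(c.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"samples without group metadata: {sorted(missing)}")
        self.sample_groups = self.sample_groups.loc[list(c.columns)]

    @classmethod
    def from_frames(cls, counts: pd.DataFrame, metadata: pd.DataFrame) -> "CountMatrix":
        """Build from a counts frame and a metadata frame with a 'group' column."""
        if "group" not in metadata.columns:
            raise ValueError("metadata must contain a 'group' column")
        return cls(counts=counts, sample_groups=metadata["group"])

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.sample_groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_means(self) -> pd.DataFrame:
        """Mean raw count per gene per group (genes × groups)."""
        out = {}
        for g in self.groups:
            samples = self.sample_groups.index[self.sample_groups == g]
            if len(samples) == 0:
                raise ValueError(f"group {g!r} has no samples")
            out[g] = self.counts[list(samples)].mean(axis=1)
        return pd.DataFrame(out)


def _resolve_to_panel(matrix: CountMatrix, panel: TransporterPanel) -> CountMatrix:
    """Rename alias rows to canonical symbols; merge duplicates by summing."""
    mapped = {}
    for name in matrix.counts.index:
        sym = panel.resolve(name)
        mapped[name] = sym if sym is not None else name
    renamed = matrix.counts.rename(index=mapped)
    if renamed.index.duplicated().any():
        dupes = sorted(set(renamed.index[renamed.index.duplicated()]))
        logger.info("merging alias rows by summation for: %s", ", ".join(dupes))
        renamed = renamed.groupby(level=0, sort=False).sum()
    return CountMatrix(counts=renamed, sample_groups=matrix.sample_groups)


def filter_detected(
    matrix: CountMatrix,
    threshold: float = DETECTION_THRESHOLD,
    panel: TransporterPanel | None = PHOSPHATE_TRANSPORTER_PANEL,
) -> pd.DataFrame:
    """Detection table (genes × groups, boolean): group mean raw count ≥ threshold.

    Gene names are resolved through the panel alias map first (PiT-1 →
    SLC20A1, SLC53A1 → XPR1, ...).  The boundary is inclusive: a mean of
    exactly ``threshold`` is detected.
    """
    if threshold <= 0:
        raise ValueError("threshold must be strictly positive")
    if panel is not None:
        matrix = _resolve_to_panel(matrix, panel)
    means = matrix.group_means()
    return means >= threshold


def fold_change_table(
    matrix: CountMatrix,
    reference_group: str,
    threshold: float = DETECTION_THRESHOLD,
    panel: TransporterPanel | None = PHOSPHATE_TRANSPORTER_PANEL,
    restrict_to_detected: bool = True,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Fold change of group mean counts vs a reference group (genes × groups).

    Restricted to genes detected in at least one group (unless
    ``restrict_to_detected=False``).  Genes whose reference mean is zero are
    omitted with a log entry rather than producing infinities.  Optional
    ``size_factors`` (per sample) divide the counts before averaging; off by
    default to mirror a raw-count presentation.
    """
    if panel is not None:
        matrix = _resolve_to_panel(matrix, panel)
    if reference_group not in matrix.groups:
        raise ValueError(f"reference group {reference_group!r} not among {matrix.groups}")
    counts = matrix.counts
    if size_factors is not None:
        counts = counts / size_factors.loc[list(counts.columns)]
        means = pd.DataFrame(
            {
                g: counts[list(matrix.sample_groups.index[matrix.sample_groups == g])].mean(axis=1)
                for g in matrix.groups
            }
        )
    else:
        means = matrix.group_means()
    if restrict_to_detected:
        detected_any = (means >= threshold).any(axis=1)
        means = means.loc[detected_any]
    ref = means[reference_group]
    zero_ref = ref == 0
    if zero_ref.any():
        logger.warning(
            "omitting genes with zero reference mean in %r: %s",
            reference_group,
            ", ".join(means.index[zero_ref]),
        )
        means = means.loc[~zero_ref]
        ref = ref.loc[~zero_ref]
    return means.div(ref, axis=0)
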