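"""Stand-level competition metrics: basal area by species class, relative height.

Competitors are assessed on small fixed-area plots (1.78 m radius, 0.001 ha)
centered on each subject tree; plots are pooled to estimate transect-level
stand basal area,

    BA = π · Σ (DBH/2000)² / (0.001 ha · n_plots),   DBH in mm,

split into three functional classes — deciduous (trembling aspen, white/paper
birch, balsam poplar), pine (lodgepole or jack pine) and spruce (white
spruce).  Relative height — the asymmetric-competition / social-status proxy —
is each subject tree's height divided by the tallest subject in its transect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLOT_AREA_HA = 0.001

#: species name → functional class; extensible through config
SPECIES_CLASSES = {
    "trembling aspen": "deciduous",
    "aspen": "deciduous",
    "white birch": "deciduous",
    "paper birch": "deciduous",
    "balsam poplar": "deciduous",
    "lodgepole pine": "pine",
    "jack pine": "pine",
    "pine": "pine",
    "white spruce": "spruce",
    "spruce": "spruce",
    "deciduous": "deciduous",
}

CLASS_COLUMNS = {"deciduous": "decba", "pine": "pinba", "spruce": "sprba"}


class CompetitionError(ValueError):
    pass


@dataclass
class CompetitionPlot:
    """Competitors (dbh mm, species class) around one subject tree."""

    subject_tree_id: str
    competitors: list[tuple[float, str]] = field(default_factory=list)
    plot_area: float = PLOT_AREA_HA

    def __post_init__(self):
        for dbh, _ in self.competitors:
            if dbh <= 0:
                raise CompetitionError(f"plot {self.subject_tree_id}: non-positive DBH")


def classify_species(species: str, mapping: dict[str, str] | None = None) -> str:
    mapping = mapping or SPECIES_CLASSES
    key = species.strip().lower()
    if key not in mapping:
        raise CompetitionError(f"unknown species {species!r}; extend the class mapping")
    return mapping[key]


def stand_basal_area(plots: list[CompetitionPlot]) -> dict[str, float]:
    """Pooled per-class and total basal area (m² ha⁻¹) over all plots.

    Per-class sums are taken before division by the pooled plot area, so
    ``total_ba == decba + pinba + sprba`` exactly.
    """
    if not plots:
        raise CompetitionError("no competition plots supplied")
    area = sum(p.plot_area for p in plots)
    sums = {cls: 0.0 for cls in CLASS_COLUMNS}
    for p in plots:
        for dbh, cls in p.competitors:
            if cls not in sums:
                cls = classify_species(cls)
            sums[cls] += np.pi * (dbh / 2000.0) ** 2
    out = {CLASS_COLUMNS[cls]: s / area for cls, s in sums.items()}
    out["total_ba"] = sum(out.values())
    return out


def relative_height(heights) -> np.ndarray:
    """h_i / max(h) within a transect; ties at the maximum all map to 1."""
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise CompetitionError("no heights supplied")
    if np.any(h <= 0):
        raise CompetitionError("heights must be positive")
    return h / h.max()


def competition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Transect-level summary from a long competitor table.

    ``table`` columns: transect_id, subject_tree_id, competitor_dbh_mm,
    species (empty competitor rows may carry NaN dbh).  Returns one row per
    transect with decba/pinba/sprba/total_ba.
    """
    rows = []
    for transect, grp in table.groupby("transect_id"):
        plots = []
        for subject, pgrp in grp.groupby("subject_tree_id"):
            comp = [
                (float(d), classify_species(str(s)))
                for d, s in zip(pgrp["competitor_dbh_mm"], pgrp["species"])
                if pd.notna(d)
            ]
            plots.append(CompetitionPlot(subject_tree_id=str(subject), competitors=comp))
        rows.append({"transect_id": transect, **stand_basal_area(plots)})
    return pd.DataFrame(rows)


def relative_height_table(heights: pd.DataFrame) -> pd.DataFrame:
    """Per-subject relative height from columns transect_id, tree_id, height_m."""
    out = heights.copy()
    out["relative_height"] = out.groupby("transect_id")["height_m"].transform(
        lambda h: relative_height(h.to_numpy())
    )
    return out
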