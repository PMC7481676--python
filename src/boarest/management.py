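"""Up-scaling densities to grid cells and management units; catch-effort model.

Habitat coefficients estimated at camera sites predict density in every 1 km^2
grid cell from that cell's landscape PC scores (same log-linear model).  A
management unit's density is the forest-area-weighted mean of its cells'
densities — the species occupies forested habitat, so forested area is the
natural weight.  Harvest records then identify trap catchability through a
catch-effort relation: the expected monthly catch in a unit is

    lambda = catchability * n_traps * density,

with the observed catch Poisson(lambda).  Catchability is parameterized per
(month, trap type), shared across units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rest import linear_predictor

__all__ = [
    "TRAP_TYPES",
    "GridCell",
    "UnitDensity",
    "cell_density",
    "unit_density",
    "unit_densities",
    "expected_catch",
]

TRAP_TYPES = ["box", "snare"]


@dataclass
class GridCell:
    cell_id: str
    unit_id: str
    pc_scores: np.ndarray
    forest_area_km2: float

    def __post_init__(self) -> None:
        self.pc_scores = np.asarray(self.pc_scores, dtype=float)
        if self.forest_area_km2 < 0:
            raise ValueError("forest_area_km2 must be non-negative")


@dataclass
class UnitDensity:
    unit_id: str
    month: str
    density_km2: float


def cell_density(alpha: np.ndarray, pc_scores: np.ndarray) -> float | np.ndarray:
    """Density (animals per km^2) in cells with the given PC scores.

    Shares the log-linear predictor of the camera-site model:
    D_c = exp(alpha_0 + sum_e alpha_e * PC_{e,c}).
    """
    scores = np.asarray(pc_scores, dtype=float)
    if scores.size == 0 or np.any(~np.isfinite(scores)):
        raise ValueError("cell PC scores are missing or non-finite")
    d = np.exp(linear_predictor(alpha, scores))
    return d if d.size > 1 else float(d[0])


def unit_density(
    cell_densities: np.ndarray, forest_areas_km2: np.ndarray, unit_id: str = "", month: str = ""
) -> UnitDensity:
    """Forest-area-weighted mean density of one unit's cells."""
    d = np.asarray(cell_densities, dtype=float)
    w = np.asarray(forest_areas_km2, dtype=float)
    if d.shape != w.shape or d.size == 0:
        raise ValueError("cell densities and forest areas must be equal-length, non-empty")
    if np.any(w < 0):
        raise ValueError("forest areas must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"unit {unit_id!r} has no forested area; its density is undefined under the model"
        )
    return UnitDensity(unit_id=unit_id, month=month, density_km2=float((w * d).sum() / total))


def unit_densities(
    alpha: np.ndarray, cells: pd.DataFrame, month: str = ""
) -> pd.Series:
    """Per-unit forest-weighted densities from a cell table.

    ``cells`` needs columns unit_id, forest_area_km2 and PC1..PCk.
    """
    pc_cols = [c for c in cells.columns if c.startswith("PC")]
    d = np.exp(linear_predictor(alpha, cells[pc_cols].to_numpy()))
    num = (
        pd.Series(d * cells["forest_area_km2"].to_numpy(), index=cells["unit_id"])
        .groupby(level=0)
        .sum()
    )
    den = cells.groupby("unit_id")["forest_area_km2"].sum()
    if (den <= 0).any():
        bad = den.index[den <= 0].tolist()
        raise ValueError(f"units with no forested area: {bad}")
    out = num / den
    out.name = month or "density_km2"
    return out


def expected_catch(catchability: float, n_traps: float, density_km2: float) -> float:
    """Poisson mean of the monthly catch: catchability * traps * density."""
    if n_traps < 0:
        raise ValueError("n_traps must be non-negative")
    if density_km2 < 0:
        raise ValueError("density must be non-negative")
    if not 0 <= catchability <= 1:
        raise ValueError("catchability must lie in [0, 1]")
    return float(catchability) * float(n_traps) * float(density_km2)
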