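"""Population-level aggregation of assignment surfaces.

Individual surfaces are summed — optionally weighted by clutch size
(eggs) or by emergents — into annual and overall importance indices.
The cell-wise sums are probability-weighted evidence indices, not
turtle counts (several cells can score 1 on one surface). Hotspot ×
year contribution tables are built by summing an index over the cells
whose centers fall inside each hotspot polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .assignment import AssignmentSurface
from .errors import EmptyCohortError, EmptyHotspotError, ValidationError
from .grid import GridSpec, Raster
from .samples import HotspotSet

logger = logging.getLogger(__name__)

Weighting = Literal["count", "eggs", "emergents"]
Normalize = Literal["by_n", "by_hotspot_total", "none"]


@dataclass(frozen=True)
class ImportanceIndex:
    """Cell-wise (weighted) sum of assignment surfaces for a cohort."""

    raster: Raster
    year: int | str  # a season, or "overall"
    weighting: str
    n: int
    total_weight: float


def _select(surfaces: Sequence[AssignmentSurface], year: int | None):
    sel = [s for s in surfaces if year is None or s.year == year]
    if not sel:
        raise EmptyCohortError(f"no surfaces for year {year!r}")
    grid = sel[0].raster.grid
    for s in sel[1:]:
        if not s.raster.grid.same_geometry(grid):
            raise ValidationError("surfaces do not share a grid")
    return sel, grid


def foraging_index(
    surfaces: Sequence[AssignmentSurface], year: int | None = None
) -> ImportanceIndex:
    """Sum the rescaled assignment surfaces of a cohort cell-wise.

    The result is the probable number of females that used each cell
    (an evidence index), bounded by the cohort size at every cell.
    """
    sel, grid = _select(surfaces, year)
    total = np.zeros(grid.shape)
    for s in sel:
        total += np.nan_to_num(s.raster.values)
    vals = np.where(grid.mask, total, np.nan)
    return ImportanceIndex(
        Raster(grid, vals), year if year is not None else "overall",
        "count", len(sel), float(len(sel)),
    )


def weighted_index(
    surfaces: Sequence[AssignmentSurface],
    weights: Mapping[str, float],
    year: int | None = None,
    weighting: Weighting = "eggs",
) -> ImportanceIndex:
    """Cell-wise Σᵢ wᵢ·surfaceᵢ with per-individual reproductive weights.

    Individuals without a recorded weight (nest not marked/excavated)
    are excluded with a logged count, mirroring the nest-fate subset.
    """
    sel, grid = _select(surfaces, year)
    missing = [s.id for s in sel if s.id not in weights or weights[s.id] is None]
    if missing:
        logger.warning(
            "excluding %d individual(s) without %s weights", len(missing), weighting
        )
        sel = [s for s in sel if s.id not in set(missing)]
    if not sel:
        raise EmptyCohortError("no individuals with recorded weights")
    total = np.zeros(grid.shape)
    wsum = 0.0
    for s in sel:
        w = float(weights[s.id])
        if w < 0:
            raise ValidationError(f"{s.id}: negative weight")
        total += w * np.nan_to_num(s.raster.values)
        wsum += w
    vals = np.where(grid.mask, total, np.nan)
    return ImportanceIndex(
        Raster(grid, vals), year if year is not None else "overall",
        weighting, len(sel), wsum,
    )


def emergence_rate_surface(
    egg_index: ImportanceIndex, emergent_index: ImportanceIndex
) -> Raster:
    """Probability-weighted mean emergence rate per cell.

    Ratio of the emergent-weighted to the egg-weighted index; cells with
    zero egg evidence are no-data. Values lie within the contributing
    nests' min/max emergence rates.
    """
    if not egg_index.raster.grid.same_geometry(emergent_index.raster.grid):
        raise ValidationError("indices do not share a grid")
    if egg_index.year != emergent_index.year or egg_index.n != emergent_index.n:
        raise ValidationError("egg and emergent indices must describe the same cohort")
    eggs = egg_index.raster.values
    emer = emergent_index.raster.values
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(eggs > 0, emer / eggs, np.nan)
    return Raster(egg_index.raster.grid, rate)


def hotspot_cell_masks(hotspots: HotspotSet, grid: GridSpec) -> dict[str, np.ndarray]:
    """Boolean membership raster per hotspot (cell-center-in-polygon)."""
    lon, lat = grid.center_grids()
    masks = {}
    for name, poly in hotspots:
        inside = shapely.contains_xy(poly, lon.ravel(), lat.ravel()).reshape(grid.shape)
        inside &= grid.mask
        if not inside.any():
            raise EmptyHotspotError(f"hotspot {name} covers no usable cell centers")
        masks[name] = inside
    return masks


@dataclass(frozen=True)
class ContributionTable:
    """Hotspot × year matrix of importance (or emergence-rate) values."""

    data: pd.DataFrame  # rows = hotspots (fixed order), columns = years
    metric: str
    normalize: str
    n_per_year: dict

    def overall(self) -> pd.Series:
        """Mean across the annual columns, per hotspot."""
        return self.data.mean(axis=1)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metric: {self.metric}\n# normalize: {self.normalize}\n")
            fh.write(
                "# n_per_year: "
                + ", ".join(f"{y}={n}" for y, n in self.n_per_year.items())
                + "\n"
            )
            self.data.to_csv(fh, index_label="hotspot")

    @staticmethod
    def read_csv(path) -> "ContributionTable":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("# "):
                key, _, val = ln[2:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body.append(ln)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)), index_col="hotspot")
        df.columns = [int(c) if c.isdigit() else c for c in df.columns]
        n_per_year = {}
        for item in meta.get("n_per_year", "").split(","):
            if "=" in item:
                y, n = item.split("=")
                n_per_year[int(y)] = int(n)
        return ContributionTable(
            df, meta.get("metric", ""), meta.get("normalize", ""), n_per_year
        )


def hotspot_table(
    indices: Mapping[int, ImportanceIndex],
    hotspots: HotspotSet,
    normalize: Normalize = "by_n",
    metric: str = "female_index",
) -> ContributionTable:
    """Sum each year's index over every hotspot's cells.

    ``by_n`` divides each year column by that year's cohort size (the
    per-female contribution); ``by_hotspot_total`` rescales each column
    to sum to 1 across hotspots; ``none`` leaves raw sums.
    """
    years = sorted(indices)
    if not years:
        raise EmptyCohortError("no annual indices supplied")
    grid = indices[years[0]].raster.grid
    hotspots.validate_within(grid)
    masks = hotspot_cell_masks(hotspots, grid)
    mat = np.zeros((len(hotspots), len(years)))
    for j, year in enumerate(years):
        vals = np.nan_to_num(indices[year].raster.values)
        for i, name in enumerate(hotspots.names):
            mat[i, j] = vals[masks[name]].sum()
    if normalize == "by_n":
        mat = mat / np.array([indices[y].n for y in years], float)[None, :]
    elif normalize == "by_hotspot_total":
        col = mat.sum(axis=0)
        if np.any(col <= 0):
            raise ValidationError("a year column sums to zero; cannot normalize")
        mat = mat / col[None, :]
    elif normalize != "none":
        raise ValidationError(f"unknown normalization {normalize!r}")
    df = pd.DataFrame(mat, index=list(hotspots.names), columns=years)
    return ContributionTable(
        df, metric, normalize, {y: indices[y].n for y in years}
    )


def emergence_rate_table(
    egg_indices: Mapping[int, ImportanceIndex],
    emergent_indices: Mapping[int, ImportanceIndex],
    hotspots: HotspotSet,
) -> ContributionTable:
    """Hotspot × year probability-weighted mean emergence rates.

    Per hotspot-year: (Σ emergent index over hotspot cells) /
    (Σ egg index over hotspot cells) — a weighted mean of per-nest
    emergence success, so every entry lies in [0, 1].
    """
    years = sorted(egg_indices)
    if sorted(emergent_indices) != years:
        raise ValidationError("egg and emergent indices cover different years")
    grid = egg_indices[years[0]].raster.grid
    masks = hotspot_cell_masks(hotspots, grid)
    mat = np.zeros((len(hotspots), len(years)))
    for j, year in enumerate(years):
        eggs = np.nan_to_num(egg_indices[year].raster.values)
        emer = np.nan_to_num(emergent_indices[year].raster.values)
        for i, name in enumerate(hotspots.names):
            denom = eggs[masks[name]].sum()
            if denom <= 0:
                raise ValidationError(f"hotspot {name}, year {year}: zero egg evidence")
            mat[i, j] = emer[masks[name]].sum() / denom
    df = pd.DataFrame(mat, index=list(hotspots.names), columns=years)
    return ContributionTable(
        df, "emergence_rate", "none", {y: egg_indices[y].n for y in years}
    )
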