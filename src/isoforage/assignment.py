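"""Bivariate-normal assignment of individuals to grid cells.

Each grid cell carries a bivariate normal model for (δ¹³C, δ¹⁵N): the
mean vector comes from the two isoscapes, the covariance combines (i)
the pooled among-turtle tissue covariance estimated at the six broad
calibration areas and (ii) the squared kriging standard error of the
cell (the two variance sources are summed, i.e. assumed independent;
the kriging model supplies no cross-element covariance, so the
off-diagonal is the tissue covariance alone).

A turtle's assignment surface is the density of her observed tissue
values under every cell's model, rescaled by the surface maximum so
values lie in [0, 1] with 1 at the most probable foraging cell(s).
Densities are computed in log space and exponentiated after subtracting
the maximum, so distant cells cannot underflow the normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .grid import GridSpec, Raster
from .isoscape import Isoscape
from .samples import AREAS, CalibrationSample, IsotopeSample

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TissueCov:
    """Pooled among-turtle isotope covariance.

    Per-area sample variances and correlations are averaged (unweighted)
    across foraging areas; the pooled covariance is re-implied from the
    mean correlation and mean variances, c̄ = r̄·√(v̄C·v̄N), because
    correlations — not raw covariances — are what get averaged.
    """

    var_c: float
    var_n: float
    corr: float
    per_area: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.var_c <= 0 or self.var_n <= 0:
            raise ValidationError("tissue variances must be positive")
        if not -1.0 <= self.corr <= 1.0:
            raise ValidationError("correlation must lie in [-1, 1]")

    @property
    def cov(self) -> float:
        return self.corr * np.sqrt(self.var_c * self.var_n)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.var_c, self.cov], [self.cov, self.var_n]])


def pooled_tissue_covariance(
    calibration: Sequence[CalibrationSample],
    min_per_area: int = 3,
    weighted: bool = False,
) -> TissueCov:
    """Average per-area isotope variances and correlations.

    Every area present in the data needs at least ``min_per_area``
    animals. ``weighted=True`` weights areas by sample size instead of
    the default unweighted mean.
    """
    groups: dict[str, list[CalibrationSample]] = {}
    for s in calibration:
        groups.setdefault(s.area, []).append(s)
    if not groups:
        raise ValidationError("no calibration samples")
    per_area = {}
    for area in sorted(groups, key=AREAS.index):
        ss = groups[area]
        if len(ss) < min_per_area:
            raise ValidationError(
                f"area {area}: only {len(ss)} sample(s), need >= {min_per_area}"
            )
        c = np.array([s.d13C for s in ss])
        n = np.array([s.d15N for s in ss])
        vc, vn = c.var(ddof=1), n.var(ddof=1)
        r = float(np.corrcoef(c, n)[0, 1]) if vc > 0 and vn > 0 else 0.0
        per_area[area] = {"var_c": float(vc), "var_n": float(vn), "corr": r, "n": len(ss)}
    w = np.array([g["n"] for g in per_area.values()], float) if weighted else np.ones(len(per_area))
    w = w / w.sum()
    var_c = float(np.sum(w * [g["var_c"] for g in per_area.values()]))
    var_n = float(np.sum(w * [g["var_n"] for g in per_area.values()]))
    corr = float(np.sum(w * [g["corr"] for g in per_area.values()]))
    return TissueCov(var_c, var_n, corr, per_area)


@dataclass(frozen=True)
class CovField:
    """Per-cell 2×2 covariance: tissue variance + squared kriging se.

    Stored as three rasters-worth of arrays (vc, vn, cov) on a shared
    grid; the off-diagonal is constant across cells.
    """

    grid: GridSpec
    vc: np.ndarray
    vn: np.ndarray
    cov: float

    def det(self) -> np.ndarray:
        return self.vc * self.vn - self.cov**2


def build_cov_field(
    tissue: TissueCov, iso_c: Isoscape, iso_n: Isoscape, ridge: float = 1e-8
) -> CovField:
    """Assemble the per-cell covariance field from tissue + kriging error.

    Kriging variances add to the tissue variances on the diagonal; the
    off-diagonal is the tissue covariance. Any cell whose matrix is not
    positive definite (cannot happen while |r̄| < 1, since kriging only
    inflates the diagonal) gets a diagonal ridge and a warning.
    """
    if not iso_c.grid.same_geometry(iso_n.grid):
        raise ConfigurationError("isoscapes must share the grid")
    grid = iso_c.grid
    vc = tissue.var_c + np.square(iso_c.se.values)
    vn = tissue.var_n + np.square(iso_n.se.values)
    cov = tissue.cov
    det = vc * vn - cov**2
    bad = grid.mask & ~(det > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} cell(s) not positive definite; applying ridge {ridge}",
            stacklevel=2,
        )
        vc = np.where(bad, vc + ridge, vc)
        vn = np.where(bad, vn + ridge, vn)
    return CovField(grid, vc, vn, cov)


def bivariate_density(
    x: tuple[float, float], mu: tuple[float, float], sigma: np.ndarray
) -> float:
    """Bivariate normal density at a point (scalar convenience form)."""
    sigma = np.asarray(sigma, float)
    det = np.linalg.det(sigma)
    if det <= 0:
        raise ValidationError("sigma must be positive definite")
    d = np.asarray(x, float) - np.asarray(mu, float)
    quad = d @ np.linalg.solve(sigma, d)
    return float(np.exp(-LOG2PI - 0.5 * np.log(det) - 0.5 * quad))


@dataclass(frozen=True)
class AssignmentSurface:
    """Normalized posterior surface for one individual (max = 1)."""

    id: str
    year: int
    raster: Raster

    def __post_init__(self) -> None:
        v = self.raster.masked_values()
        if not np.isclose(v.max(), 1.0):
            raise ValidationError(f"{self.id}: surface maximum is {v.max()}, not 1")
        if v.min() < 0:
            raise ValidationError(f"{self.id}: negative surface values")


def _log_density_cells(
    d13c: np.ndarray,
    d15n: np.ndarray,
    iso_c: Isoscape,
    iso_n: Isoscape,
    cov: CovField,
) -> np.ndarray:
    """Log bivariate-normal density of each sample (rows) at every
    masked-in cell (columns)."""
    sel = cov.grid.mask
    mu_c = iso_c.mean.values[sel]
    mu_n = iso_n.mean.values[sel]
    vc, vn, c = cov.vc[sel], cov.vn[sel], cov.cov
    det = vc * vn - c**2
    # analytic 2x2 inverse per cell
    ic, in_, ix = vn / det, vc / det, -c / det
    dc = d13c[:, None] - mu_c[None, :]
    dn = d15n[:, None] - mu_n[None, :]
    quad = ic * dc**2 + 2.0 * ix * dc * dn + in_ * dn**2
    return -LOG2PI - 0.5 * np.log(det)[None, :] - 0.5 * quad


def assignment_surfaces(
    samples: Sequence[IsotopeSample],
    iso_c: Isoscape,
    iso_n: Isoscape,
    cov: CovField,
) -> list[AssignmentSurface]:
    """Normalized assignment surfaces for a batch of individuals.

    Samples must be in the epidermis currency. The per-cell log density
    is normalized by subtracting the row maximum before exponentiating.
    """
    non_epi = [s.id for s in samples if s.tissue != "epidermis"]
    if non_epi:
        raise ConfigurationError(f"samples not in epidermis currency: {non_epi[:5]}")
    if not (iso_c.grid.same_geometry(iso_n.grid) and iso_c.grid.same_geometry(cov.grid)):
        raise ConfigurationError("isoscapes and covariance field must share the grid")
    grid = cov.grid
    d13c = np.array([s.d13C for s in samples])
    d15n = np.array([s.d15N for s in samples])
    logd = _log_density_cells(d13c, d15n, iso_c, iso_n, cov)
    norm = np.exp(logd - logd.max(axis=1, keepdims=True))
    out = []
    for i, s in enumerate(samples):
        vals = np.full(grid.shape, np.nan)
        vals[grid.mask] = norm[i]
        out.append(AssignmentSurface(s.id, s.year, Raster(grid, vals)))
    return out


def assignment_surface(
    sample: IsotopeSample, iso_c: Isoscape, iso_n: Isoscape, cov: CovField
) -> AssignmentSurface:
    """Single-individual convenience wrapper around assignment_surfaces."""
    return assignment_surfaces([sample], iso_c, iso_n, cov)[0]


@dataclass(frozen=True)
class CalibrationValidation:
    """Surface values at the true cells of known-origin animals."""

    values: dict  # id -> surface value at the known cell
    median: float
    q1: float


def validate_calibration(
    surfaces: Sequence[AssignmentSurface],
    calibration: Sequence[CalibrationSample],
    snap_cells: int = 1,
) -> CalibrationValidation:
    """Evaluate each calibration animal's surface at its known location.

    Locations on masked-out cells are snapped to the nearest masked-in
    cell within ``snap_cells`` (coastal captures often fall on land
    pixels); farther than that is an error.
    """
    by_id = {s.id: s for s in surfaces}
    values = {}
    for cal in calibration:
        surf = by_id.get(cal.id)
        if surf is None:
            raise ValidationError(f"no surface for calibration animal {cal.id}")
        grid = surf.raster.grid
        row, col = grid.cell_of(cal.lon, cal.lat)
        if not grid.mask[row, col]:
            row, col = _snap(grid, row, col, snap_cells, cal.id)
        values[cal.id] = float(surf.raster.values[row, col])
    arr = np.array(list(values.values()))
    return CalibrationValidation(
        values, float(np.median(arr)), float(np.percentile(arr, 25))
    )


def _snap(grid: GridSpec, row: int, col: int, snap_cells: int, sid: str) -> tuple[int, int]:
    best = None
    for dr in range(-snap_cells, snap_cells + 1):
        for dc in range(-snap_cells, snap_cells + 1):
            r, c = row + dr, col + dc
            if 0 <= r < grid.nrows and 0 <= c < grid.ncols and grid.mask[r, c]:
                dist = dr * dr + dc * dc
                if best is None or dist < best[0]:
                    best = (dist, r, c)
    if best is None:
        raise ValidationError(
            f"{sid}: known location falls on a masked cell with no ocean "
            f"neighbor within {snap_cells} cell(s)"
        )
    return best[1], best[2]
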