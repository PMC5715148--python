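"""Isoscape fitting: variogram estimation and ordinary kriging.

An isoscape is a spatially continuous surface of predicted tissue
isotope values with a per-cell prediction standard error. The original
workflow used ArcGIS's proprietary empirical Bayesian kriging; here the
surface is fit by ordinary kriging with a weighted-least-squares
variogram, which supplies the same two ingredients the assignment model
needs — a mean raster and an error raster — from open, testable code.

Distances are great-circle separations expressed in degrees of arc (the
study spans ~30° of latitude, so planar distances would distort the
northern pairs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, DegenerateFieldError, SingularKrigingError
from .grid import GridSpec, Raster, great_circle_deg, pairwise_great_circle_deg
from .samples import CalibrationSample

logger = logging.getLogger(__name__)

VariogramFamily = Literal["exponential", "spherical", "gaussian"]


@dataclass(frozen=True)
class Variogram:
    """Semivariogram model γ(h) = nugget + psill·f(h/range).

    ``range_`` is the scale parameter of the family (not the 95%
    "practical" range): for the exponential family the correlation falls
    to e⁻¹ at h = range_.
    """

    family: str
    nugget: float
    psill: float
    range_: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ConfigurationError("variogram requires nugget, psill >= 0, range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.family == "exponential":
            g = 1.0 - np.exp(-h / r)
        elif self.family == "gaussian":
            g = 1.0 - np.exp(-((h / r) ** 2))
        elif self.family == "spherical":
            hr = np.minimum(h / r, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        else:
            raise ConfigurationError(f"unknown variogram family {self.family!r}")
        out = self.nugget + self.psill * g
        return np.where(h == 0.0, 0.0, out)  # γ(0) = 0 by definition

    @property
    def sill(self) -> float:
        return self.nugget + self.psill


@dataclass(frozen=True)
class Isoscape:
    """Mean and standard-error rasters for one element (C or N)."""

    element: str
    mean: Raster
    se: Raster
    variogram: Variogram

    def __post_init__(self) -> None:
        if self.element not in ("C", "N"):
            raise ConfigurationError("element must be 'C' or 'N'")
        if not self.mean.grid.same_geometry(self.se.grid):
            raise ConfigurationError("mean and se rasters must share the grid")
        se_vals = self.se.masked_values()
        if np.any(se_vals < 0):
            raise ConfigurationError("standard errors must be non-negative")

    @property
    def grid(self) -> GridSpec:
        return self.mean.grid


def empirical_variogram(
    lons: np.ndarray,
    lats: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_dist: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned method-of-moments semivariogram.

    Returns (bin centers h, γ̂(h), pair counts). ``max_dist`` defaults to
    half the maximum pairwise separation.
    """
    d = pairwise_great_circle_deg(np.asarray(lons, float), np.asarray(lats, float))
    iu = np.triu_indices(len(lons), k=1)
    h = d[iu]
    sq = 0.5 * (np.asarray(values, float)[iu[0]] - np.asarray(values, float)[iu[1]]) ** 2
    if max_dist is None:
        max_dist = 0.5 * h.max()
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    idx = np.digitize(h, edges) - 1
    keep = (idx >= 0) & (idx < n_bins)
    centers, gamma, counts = [], [], []
    for b in range(n_bins):
        sel = keep & (idx == b)
        n = int(sel.sum())
        if n == 0:
            continue
        centers.append(h[sel].mean())
        gamma.append(sq[sel].mean())
        counts.append(n)
    return np.array(centers), np.array(gamma), np.array(counts)


def fit_variogram(
    points: Sequence[tuple[float, float, float]],
    family: VariogramFamily = "exponential",
    n_bins: int = 15,
) -> Variogram:
    """Fit a variogram to scattered observations by weighted least squares.

    Uses Cressie's weights N(h)/γ(h)², which emphasize the short lags
    that determine the range. Raises :class:`DegenerateFieldError` when
    all values are identical (a pure-nugget fallback must then be
    chosen deliberately).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 10:
        raise ConfigurationError(f"need >= 10 points to fit a variogram, got {len(pts)}")
    lons, lats, values = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.ptp(values) == 0.0:
        raise DegenerateFieldError(
            "all values identical; fit a pure-nugget model explicitly if intended"
        )
    h, gamma, counts = empirical_variogram(lons, lats, values, n_bins=n_bins)
    var = values.var(ddof=1)
    hmax = h.max()

    def resid(theta):
        nugget, psill, rng = theta
        model = Variogram(family, max(nugget, 0.0), max(psill, 0.0), max(rng, 1e-6))
        gm = np.maximum(model(h), 1e-12)
        return np.sqrt(counts) * (gamma / gm - 1.0)

    x0 = np.array([0.1 * var, var, hmax / 3.0])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-6], [5.0 * var, 10.0 * var, 10.0 * hmax]),
    )
    nugget, psill, rng = sol.x
    if psill <= 1e-12 * var:
        warnings.warn("variogram fit collapsed to pure nugget", stacklevel=2)
    return Variogram(family, float(nugget), float(psill), float(rng))


def _dedupe(
    lons: np.ndarray, lats: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates (kriging systems are
    singular otherwise)."""
    coords = np.round(np.column_stack([lons, lats]), 9)
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return lons, lats, values
    logger.info("averaging %d duplicate coordinate(s)", len(coords) - len(uniq))
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(counts, inv, 1.0)
    return uniq[:, 0], uniq[:, 1], sums / counts


def krige_points(
    lons: np.ndarray,
    lats: np.ndarray,
    values: np.ndarray,
    variogram: Variogram,
    pred_lons: np.ndarray,
    pred_lats: np.ndarray,
    dedupe: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging prediction and variance at arbitrary points.

    Solves the dual system [Γ 1; 1ᵀ 0][λ; μ] = [γ₀; 1] per prediction
    point (batched); prediction = λᵀz, variance = λᵀγ₀ + μ. The
    unbiasedness constraint (weights summing to 1) is asserted.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    values = np.asarray(values, float)
    if dedupe:
        lons, lats, values = _dedupe(lons, lats, values)
    n = len(lons)
    gamma_dd = variogram(pairwise_great_circle_deg(lons, lats))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_dd
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    gamma_0 = variogram(
        great_circle_deg(
            lons[:, None], lats[:, None], np.asarray(pred_lons)[None, :], np.asarray(pred_lats)[None, :]
        )
    )
    b = np.vstack([gamma_0, np.ones(gamma_0.shape[1])])
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise SingularKrigingError(
            "singular kriging system (duplicate coordinates?)"
        ) from exc
    weights, mu = sol[:n, :], sol[n, :]
    wsum = weights.sum(axis=0)
    if not np.allclose(wsum, 1.0, atol=1e-6):
        raise SingularKrigingError(
            f"kriging weights do not sum to 1 (max deviation {np.abs(wsum - 1).max():.2e})"
        )
    pred = weights.T @ values
    var = np.einsum("ij,ij->j", weights, gamma_0) + mu
    return pred, np.maximum(var, 0.0)


def krige_surface(
    calibration: Sequence[CalibrationSample],
    grid: GridSpec,
    element: Literal["C", "N"],
    family: VariogramFamily = "exponential",
    variogram: Variogram | None = None,
) -> Isoscape:
    """Fit an isoscape for one element from known-origin animals.

    Calibration samples must already be in the epidermis currency.
    Duplicate capture coordinates are averaged before fitting.
    """
    attr = "d13C" if element == "C" else "d15N"
    non_epi = [s.id for s in calibration if s.tissue != "epidermis"]
    if non_epi:
        raise ConfigurationError(
            f"calibration samples not in epidermis currency: {non_epi[:5]}..."
        )
    inside = [s for s in calibration if grid.contains(s.lon, s.lat)]
    if len(inside) < 10:
        raise ConfigurationError(
            f"need >= 10 calibration points inside the grid, got {len(inside)}"
        )
    lons = np.array([s.lon for s in inside])
    lats = np.array([s.lat for s in inside])
    values = np.array([getattr(s, attr) for s in inside])
    lons, lats, values = _dedupe(lons, lats, values)
    if variogram is None:
        variogram = fit_variogram(list(zip(lons, lats, values)), family=family)
    logger.info(
        "element %s: variogram %s nugget=%.3g psill=%.3g range=%.3g, n=%d",
        element, variogram.family, variogram.nugget, variogram.psill,
        variogram.range_, len(values),
    )
    lon_c, lat_c = grid.center_grids()
    sel = grid.mask
    pred, var = krige_points(
        lons, lats, values, variogram, lon_c[sel], lat_c[sel], dedupe=False
    )
    mean = np.full(grid.shape, np.nan)
    se = np.full(grid.shape, np.nan)
    mean[sel] = pred
    se[sel] = np.sqrt(var)
    return Isoscape(element, Raster(grid, mean), Raster(grid, se), variogram)
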