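"""Synthetic study generator with known ground truth.

Emulates the structure of the field study: two smooth tissue-isotope
surfaces over a Northwest-Atlantic-like shelf grid, six broad
calibration areas with known-origin animals, and nine nesting seasons
(2007–2015) of unknown females drawn from seven foraging hotspots whose
mixture weights vary by year. Each female carries bivariate tissue
noise around the true isoscape value at her (latent) foraging site;
a per-year subset of nests has clutch size and hatch/emergence counts.

Truth surfaces are linear latitude/longitude trends plus a smooth
Gaussian-process anomaly; the two elements are given distinct trend
directions (δ¹³C mostly latitudinal, δ¹⁵N with a west–east component)
so that dual-isotope assignment is geographically informative in both
axes, as in real marine isoscapes.

The latent hotspot labels and true parameters are written to a sidecar
that the analysis pipeline never reads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import RectBivariateSpline
from shapely.geometry import box

from .errors import ConfigurationError
from .grid import GridSpec, Raster
from .samples import (
    AREAS,
    HOTSPOT_NAMES,
    CalibrationSample,
    HotspotSet,
    IsotopeSample,
    write_hotspots,
    write_samples,
)

YEARS: tuple[int, ...] = tuple(range(2007, 2016))

#: Females sampled per season and nests with recorded fate per season.
COHORT_SIZES: dict[int, int] = dict(
    zip(YEARS, (63, 71, 58, 70, 73, 103, 98, 73, 140))
)
NEST_COUNTS: dict[int, int] = dict(
    zip(YEARS, (56, 47, 33, 52, 50, 55, 83, 73, 64))
)

#: Known-origin animals per broad foraging area (totals 227).
CALIBRATION_SIZES: dict[str, int] = {
    "CAN": 25, "MAB": 45, "SAB": 50, "SNWA": 40, "FLKeys": 35, "SWFL": 32,
}

#: lon/lat boxes for the six broad calibration areas.
CALIBRATION_BOXES: dict[str, tuple[float, float, float, float]] = {
    "CAN": (-66.0, 41.0, -60.5, 45.5),
    "MAB": (-75.0, 36.5, -70.0, 41.0),
    "SAB": (-81.0, 28.5, -75.5, 36.0),
    "SNWA": (-79.5, 22.0, -70.0, 27.5),
    "FLKeys": (-83.0, 23.5, -80.0, 25.5),
    "SWFL": (-85.0, 25.0, -82.0, 28.5),
}

#: lon/lat boxes for the seven foraging hotspots (fixed order).
HOTSPOT_BOXES: dict[str, tuple[float, float, float, float]] = {
    "N_Hatteras": (-75.5, 35.5, -71.5, 38.5),
    "S_Hatteras": (-77.5, 32.5, -73.5, 35.0),
    "SC_GA": (-80.5, 30.5, -77.0, 32.5),
    "E_FL": (-80.5, 27.0, -77.5, 30.0),
    "Bahamas": (-79.5, 22.5, -76.5, 25.0),
    "FL_Keys": (-83.0, 23.5, -80.5, 25.5),
    "W_FL": (-85.5, 25.5, -82.5, 28.5),
}

#: Year-varying hotspot mixture weights. Southern hotspots (Bahamas,
#: FL Keys) pulse in 2007/2014, northern (the Hatteras pair) in
#: 2009/2012, and the hotspot adjacent to the rookery (E FL) stays
#: high and stable (~0.30) throughout.
_SOUTH = (0.04, 0.05, 0.06, 0.30, 0.24, 0.20, 0.11)
_NORTH = (0.15, 0.17, 0.10, 0.28, 0.09, 0.08, 0.13)
_BASE = (0.08, 0.10, 0.08, 0.31, 0.16, 0.14, 0.13)
MIXTURES: dict[int, tuple[float, ...]] = {
    2007: _SOUTH, 2008: _BASE, 2009: _NORTH, 2010: _BASE, 2011: _BASE,
    2012: _NORTH, 2013: _BASE, 2014: _SOUTH, 2015: _BASE,
}

#: Per-hotspot emergence probability: lower at high latitude, highest
#: in the southern hotspots.
EMERGENCE_P: dict[str, float] = {
    "N_Hatteras": 0.55, "S_Hatteras": 0.60, "SC_GA": 0.65, "E_FL": 0.70,
    "Bahamas": 0.80, "FL_Keys": 0.78, "W_FL": 0.72,
}


@dataclass(frozen=True)
class FieldParams:
    """Trend + anomaly parameters for one element's truth surface."""

    base: float             # value at (lat_ref, lon_ref), per mil
    lat_gradient: float     # per-mil per degree latitude
    lon_gradient: float     # per-mil per degree longitude
    anomaly_amplitude: float  # SD of the smooth GP anomaly, per mil
    anomaly_scale: float    # GP correlation length, degrees
    lat_ref: float = 18.0
    lon_ref: float = -98.0


@dataclass
class Scenario:
    """Everything needed to generate one synthetic study, seed included."""

    seed: int = 0
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(-98.0, -60.0, 18.0, 46.0, 0.5)
    )
    field_c: FieldParams = field(
        default_factory=lambda: FieldParams(-9.5, -0.35, -0.03, 0.6, 6.0)
    )
    field_n: FieldParams = field(
        default_factory=lambda: FieldParams(4.5, 0.06, 0.28, 0.6, 6.0)
    )
    calibration_sizes: dict = field(default_factory=lambda: dict(CALIBRATION_SIZES))
    calibration_boxes: dict = field(default_factory=lambda: dict(CALIBRATION_BOXES))
    hotspot_boxes: dict = field(default_factory=lambda: dict(HOTSPOT_BOXES))
    years: tuple = YEARS
    mixtures: dict = field(default_factory=lambda: dict(MIXTURES))
    cohort_sizes: dict = field(default_factory=lambda: dict(COHORT_SIZES))
    nest_counts: dict = field(default_factory=lambda: dict(NEST_COUNTS))
    # among-turtle tissue (co)variance around the local isoscape value
    tissue_var_c: float = 0.30
    tissue_var_n: float = 0.25
    tissue_corr: float = 0.2
    clutch_mean: float = 113.0
    clutch_sd: float = 20.0
    emergence_p: dict = field(default_factory=lambda: dict(EMERGENCE_P))
    # small fractions of hatched young found dead/alive in the nest
    dead_in_nest_p: float = 0.007
    live_in_nest_p: float = 0.003

    def __post_init__(self) -> None:
        for year in self.years:
            w = np.asarray(self.mixtures[year], dtype=float)
            if len(w) != len(HOTSPOT_NAMES) or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"mixture weights for {year} must be {len(HOTSPOT_NAMES)} "
                    "values summing to 1"
                )
            if year not in self.cohort_sizes or year not in self.nest_counts:
                raise ConfigurationError(f"no cohort/nest size for year {year}")
            if self.nest_counts[year] > self.cohort_sizes[year]:
                raise ConfigurationError(f"{year}: more nests than females")
        for name, p in self.emergence_p.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"emergence probability for {name} not in [0,1]")
        for label, boxes in (
            ("calibration area", self.calibration_boxes),
            ("hotspot", self.hotspot_boxes),
        ):
            for name, (x0, y0, x1, y1) in boxes.items():
                if not (self.grid.contains(x0, y0) and self.grid.contains(x1, y1)):
                    raise ConfigurationError(f"{label} {name} outside the grid")

    def hotspots(self) -> HotspotSet:
        return HotspotSet(
            HOTSPOT_NAMES,
            tuple(box(*self.hotspot_boxes[n]) for n in HOTSPOT_NAMES),
        )

    @property
    def tissue_cov(self) -> np.ndarray:
        c = self.tissue_corr * np.sqrt(self.tissue_var_c * self.tissue_var_n)
        return np.array([[self.tissue_var_c, c], [c, self.tissue_var_n]])

    # -- YAML round trip --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        g = self.grid
        d["grid"] = {
            "lon_min": g.lon_min, "lon_max": g.lon_max,
            "lat_min": g.lat_min, "lat_max": g.lat_max,
            "cell_size": g.cell_size, "crs": g.crs,
        }
        d = _tuples_to_lists(d)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path: str | Path) -> "Scenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["grid"] = GridSpec(**d["grid"])
        d["field_c"] = FieldParams(**d["field_c"])
        d["field_n"] = FieldParams(**d["field_n"])
        d["years"] = tuple(d["years"])
        for key in ("calibration_boxes", "hotspot_boxes"):
            d[key] = {k: tuple(v) for k, v in d[key].items()}
        d["mixtures"] = {int(k): tuple(v) for k, v in d["mixtures"].items()}
        d["cohort_sizes"] = {int(k): int(v) for k, v in d["cohort_sizes"].items()}
        d["nest_counts"] = {int(k): int(v) for k, v in d["nest_counts"].items()}
        return Scenario(**d)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


class TruthFields:
    """Continuous true isotope surfaces, evaluable at any lon/lat."""

    def __init__(self, scenario: Scenario, rng: np.random.Generator):
        self.scenario = scenario
        self._params = {"C": scenario.field_c, "N": scenario.field_n}
        self._splines = {
            el: self._anomaly_spline(p, rng) for el, p in self._params.items()
        }

    def _anomaly_spline(self, p: FieldParams, rng: np.random.Generator):
        """Smooth GP anomaly: exact draw on a coarse knot lattice
        (squared-exponential covariance), bicubic spline in between."""
        if p.anomaly_amplitude == 0.0:
            return None
        g = self.scenario.grid
        step = max(p.anomaly_scale / 2.0, g.cell_size)
        lons = np.arange(g.lon_min, g.lon_max + step, step)
        lats = np.arange(g.lat_min, g.lat_max + step, step)
        xx, yy = np.meshgrid(lons, lats, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        cov = p.anomaly_amplitude**2 * np.exp(-0.5 * d2 / p.anomaly_scale**2)
        cov[np.diag_indices_from(cov)] += 1e-10
        z = np.linalg.cholesky(cov) @ rng.standard_normal(len(pts))
        return RectBivariateSpline(lons, lats, z.reshape(len(lons), len(lats)))

    def value(self, element: str, lon, lat) -> np.ndarray:
        p = self._params[element]
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        v = (
            p.base
            + p.lat_gradient * (lat - p.lat_ref)
            + p.lon_gradient * (lon - p.lon_ref)
        )
        sp = self._splines[element]
        if sp is not None:
            v = v + sp(lon.ravel(), lat.ravel(), grid=False).reshape(lon.shape)
        return v

    def raster(self, element: str) -> Raster:
        g = self.scenario.grid
        lon, lat = g.center_grids()
        return Raster(g, self.value(element, lon, lat))


def make_truth_fields(scenario: Scenario) -> TruthFields:
    """Deterministic truth surfaces for the scenario's seed."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    return TruthFields(scenario, rng)


def _noisy_tissue(
    truth: TruthFields, lons: np.ndarray, lats: np.ndarray, scenario: Scenario,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    mu = np.column_stack(
        [truth.value("C", lons, lats), truth.value("N", lons, lats)]
    )
    chol = np.linalg.cholesky(scenario.tissue_cov)
    eps = rng.standard_normal((len(lons), 2)) @ chol.T
    vals = mu + eps
    return vals[:, 0], vals[:, 1]


def sample_calibration(
    scenario: Scenario, truth: TruthFields | None = None
) -> list[CalibrationSample]:
    """Known-origin animals: uniform locations within each area box,
    tissue = truth + bivariate noise."""
    if truth is None:
        truth = make_truth_fields(scenario)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    out: list[CalibrationSample] = []
    for area in AREAS:
        n = scenario.calibration_sizes[area]
        x0, y0, x1, y1 = scenario.calibration_boxes[area]
        lons = rng.uniform(x0, x1, n)
        lats = rng.uniform(y0, y1, n)
        d13c, d15n = _noisy_tissue(truth, lons, lats, scenario, rng)
        for i in range(n):
            out.append(
                CalibrationSample(
                    id=f"cal-{area}-{i:03d}", year=scenario.years[0],
                    tissue="epidermis", d13C=float(d13c[i]), d15N=float(d15n[i]),
                    lon=float(lons[i]), lat=float(lats[i]), area=area,
                )
            )
    return out


def sample_cohort(
    scenario: Scenario, year: int, truth: TruthFields | None = None
) -> tuple[list[IsotopeSample], dict[str, str]]:
    """One nesting season's unknown females.

    Each female draws a latent hotspot from the year's mixture, a
    uniform location in it, noisy tissue values, and — for the year's
    nest-fate quota — a clutch size (truncated normal), hatched count
    (binomial at the hotspot's emergence probability) and small
    dead/live-in-nest counts. Returns (samples, latent hotspot per id);
    the latent labels are ground truth only and never feed the pipeline.
    """
    if year not in scenario.years:
        raise ConfigurationError(f"year {year} not in scenario")
    if truth is None:
        truth = make_truth_fields(scenario)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3, year]))
    n = scenario.cohort_sizes[year]
    weights = np.asarray(scenario.mixtures[year], float)
    hot_idx = rng.choice(len(HOTSPOT_NAMES), size=n, p=weights)
    lons = np.empty(n)
    lats = np.empty(n)
    for i, h in enumerate(hot_idx):
        x0, y0, x1, y1 = scenario.hotspot_boxes[HOTSPOT_NAMES[h]]
        lons[i] = rng.uniform(x0, x1)
        lats[i] = rng.uniform(y0, y1)
    d13c, d15n = _noisy_tissue(truth, lons, lats, scenario, rng)
    with_fate = set(
        rng.choice(n, size=scenario.nest_counts[year], replace=False).tolist()
    )
    samples: list[IsotopeSample] = []
    latent: dict[str, str] = {}
    for i in range(n):
        sid = f"f{year}-{i:03d}"
        hotspot = HOTSPOT_NAMES[hot_idx[i]]
        latent[sid] = hotspot
        clutch = hatched = dead = live = None
        if i in with_fate:
            clutch = max(1, round(rng.normal(scenario.clutch_mean, scenario.clutch_sd)))
            hatched = int(rng.binomial(clutch, scenario.emergence_p[hotspot]))
            dead = int(rng.binomial(hatched, scenario.dead_in_nest_p))
            live = int(rng.binomial(hatched - dead, scenario.live_in_nest_p))
        samples.append(
            IsotopeSample(
                id=sid, year=year, tissue="epidermis",
                d13C=float(d13c[i]), d15N=float(d15n[i]),
                clutch_size=clutch, hatched=hatched,
                dead_in_nest=dead, live_in_nest=live,
            )
        )
    return samples, latent


@dataclass
class SyntheticStudy:
    """A full generated study plus its ground truth."""

    scenario: Scenario
    truth: TruthFields
    calibration: list[CalibrationSample]
    cohorts: dict[int, list[IsotopeSample]]
    latent_hotspots: dict[str, str]

    @property
    def assignment_samples(self) -> list[IsotopeSample]:
        return [s for year in sorted(self.cohorts) for s in self.cohorts[year]]

    def hotspots(self) -> HotspotSet:
        return self.scenario.hotspots()


def generate_study(scenario: Scenario, out_dir: str | Path | None = None) -> SyntheticStudy:
    """Generate calibration + all cohorts; optionally write the input
    files (CSV/GeoJSON) and a truth/ sidecar the pipeline never reads."""
    truth = make_truth_fields(scenario)
    calibration = sample_calibration(scenario, truth)
    cohorts: dict[int, list[IsotopeSample]] = {}
    latent: dict[str, str] = {}
    for year in scenario.years:
        samples, lat_y = sample_cohort(scenario, year, truth)
        cohorts[year] = samples
        latent.update(lat_y)
    study = SyntheticStudy(scenario, truth, calibration, cohorts, latent)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_samples(calibration, out / "calibration.csv")
        for year, samples in cohorts.items():
            write_samples(samples, out / f"cohort_{year}.csv")
        write_hotspots(study.hotspots(), out / "hotspots.geojson")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        truth.raster("C").write_ascii(truth_dir / "true_d13C.asc")
        truth.raster("N").write_ascii(truth_dir / "true_d15N.asc")
        with open(truth_dir / "latent_hotspots.json", "w") as fh:
            json.dump(latent, fh, indent=0, sort_keys=True)
    return study
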