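"""Sample tables, tissue conversion, nest arithmetic, and hotspot polygons.

The unit of analysis is one nesting female: her tissue δ¹³C/δ¹⁵N values
(per mil), the nesting year, and — for the subset of females whose nest
was marked and excavated — clutch size and hatchling counts. Calibration
animals additionally carry a known foraging location and one of six broad
foraging-area labels.

All isotope values entering the assignment model must be in a common
tissue currency (epidermis); red-blood-cell and unhatched-egg values are
mapped onto epidermis equivalents with linear regressions supplied via
config (the coefficients come from prior calibration work and are inputs
here, not estimates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, SchemaError, ValidationError
from .grid import GridSpec

Tissue = Literal["epidermis", "red_blood_cells", "unhatched_egg"]
TISSUES: tuple[str, ...] = ("epidermis", "red_blood_cells", "unhatched_egg")

#: The six broad foraging areas with known-origin calibration animals:
#: Canada, Mid-Atlantic Bight, South Atlantic Bight, Subtropical NW
#: Atlantic, Florida Keys, Southwest Florida.
AREAS: tuple[str, ...] = ("CAN", "MAB", "SAB", "SNWA", "FLKeys", "SWFL")

#: Fixed hotspot order used in every table and figure.
HOTSPOT_NAMES: tuple[str, ...] = (
    "N_Hatteras",
    "S_Hatteras",
    "SC_GA",
    "E_FL",
    "Bahamas",
    "FL_Keys",
    "W_FL",
)


@dataclass(frozen=True)
class IsotopeSample:
    """One female's tissue isotope values plus optional nest data."""

    id: str
    year: int
    tissue: str
    d13C: float
    d15N: float
    clutch_size: int | None = None
    hatched: int | None = None
    dead_in_nest: int | None = None
    live_in_nest: int | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"{self.id}: unknown tissue {self.tissue!r}")
        for name in ("d13C", "d15N"):
            v = getattr(self, name)
            if abs(v) > 100:
                raise ValidationError(
                    f"{self.id}: {name} = {v} outside plausible per-mil range"
                )
        for name in ("clutch_size", "hatched", "dead_in_nest", "live_in_nest"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.id}: {name} must be non-negative")
        if (
            self.hatched is not None
            and self.clutch_size is not None
            and self.hatched > self.clutch_size
        ):
            raise ValidationError(f"{self.id}: hatched > clutch_size")
        if self.hatched is not None:
            dead = self.dead_in_nest or 0
            live = self.live_in_nest or 0
            if dead + live > self.hatched:
                raise ValidationError(
                    f"{self.id}: dead_in_nest + live_in_nest > hatched"
                )

    @property
    def has_nest_fate(self) -> bool:
        return self.clutch_size is not None and self.hatched is not None


@dataclass(frozen=True)
class CalibrationSample(IsotopeSample):
    """Known-origin animal: adds foraging location and area label."""

    lon: float = 0.0
    lat: float = 0.0
    area: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.area not in AREAS:
            raise ValidationError(
                f"{self.id}: area {self.area!r} not one of {AREAS}"
            )


_BASE_COLS = ["id", "year", "tissue", "d13C", "d15N"]
_NEST_COLS = ["clutch_size", "hatched", "dead_in_nest", "live_in_nest"]
_CAL_COLS = ["lon", "lat", "area"]


def read_samples(
    path: str | Path, role: Literal["calibration", "assignment"]
) -> list[IsotopeSample]:
    """Read and validate a sample table (comma-separated, UTF-8, header row).

    Missing reproductive fields are empty cells. Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    for duplicate ids or out-of-range values.
    """
    if role not in ("calibration", "assignment"):
        raise ConfigurationError(f"unknown role {role!r}")
    df = pd.read_csv(path)
    required = _BASE_COLS + (_CAL_COLS if role == "calibration" else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dup = df["id"][df["id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate id(s) {dup}")

    def _opt_int(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return int(row[col])

    out: list[IsotopeSample] = []
    for _, row in df.iterrows():
        kwargs = dict(
            id=str(row["id"]),
            year=int(row["year"]),
            tissue=str(row["tissue"]),
            d13C=float(row["d13C"]),
            d15N=float(row["d15N"]),
            clutch_size=_opt_int(row, "clutch_size"),
            hatched=_opt_int(row, "hatched"),
            dead_in_nest=_opt_int(row, "dead_in_nest"),
            live_in_nest=_opt_int(row, "live_in_nest"),
        )
        if role == "calibration":
            out.append(
                CalibrationSample(
                    lon=float(row["lon"]), lat=float(row["lat"]), area=str(row["area"]), **kwargs
                )
            )
        else:
            out.append(IsotopeSample(**kwargs))
    return out


def write_samples(samples: Sequence[IsotopeSample], path: str | Path) -> None:
    """Write a sample table; round-trips bit-exactly through read_samples."""
    rows = []
    calibration = samples and isinstance(samples[0], CalibrationSample)
    for s in samples:
        row = {c: getattr(s, c) for c in _BASE_COLS + _NEST_COLS}
        if calibration:
            row.update({c: getattr(s, c) for c in _CAL_COLS})
        rows.append(row)
    cols = _BASE_COLS + (_CAL_COLS if calibration else []) + _NEST_COLS
    df = pd.DataFrame(rows, columns=cols)
    for c in _NEST_COLS:
        df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tissue conversion


@dataclass(frozen=True)
class ConversionModel:
    """Linear maps tissue → epidermis equivalent, per element.

    ``coeffs[tissue] = ((slope_C, intercept_C), (slope_N, intercept_N))``.
    Epidermis always maps to identity.
    """

    coeffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {"epidermis": ((1.0, 0.0), (1.0, 0.0))}
        merged.update(self.coeffs)
        sc, ic = merged["epidermis"][0]
        sn, in_ = merged["epidermis"][1]
        if (sc, ic, sn, in_) != (1.0, 0.0, 1.0, 0.0):
            raise ConfigurationError("epidermis must map to identity")
        object.__setattr__(self, "coeffs", merged)

    @staticmethod
    def from_dict(d: dict) -> "ConversionModel":
        coeffs = {
            t: (
                (float(v["d13C"]["slope"]), float(v["d13C"]["intercept"])),
                (float(v["d15N"]["slope"]), float(v["d15N"]["intercept"])),
            )
            for t, v in d.items()
        }
        return ConversionModel(coeffs)

    @staticmethod
    def from_yaml(path: str | Path) -> "ConversionModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return ConversionModel.from_dict(d.get("tissue_conversion", d))


def to_epidermis(sample: IsotopeSample, model: ConversionModel) -> IsotopeSample:
    """Map a sample's isotope values to the epidermis currency.

    Identity on epidermis samples; other fields are untouched.
    """
    if sample.tissue == "epidermis":
        return sample
    if sample.tissue not in model.coeffs:
        raise ConfigurationError(
            f"no conversion coefficients for tissue {sample.tissue!r}"
        )
    (sc, ic), (sn, in_) = model.coeffs[sample.tissue]
    return replace(
        sample,
        tissue="epidermis",
        d13C=sc * sample.d13C + ic,
        d15N=sn * sample.d15N + in_,
    )


# ---------------------------------------------------------------------------
# nest arithmetic


def compute_emergents(hatched: int, dead_in_nest: int, live_in_nest: int) -> int:
    """Hatchlings that emerged from the nest.

    hatched eggs minus dead and live hatchlings found at excavation.
    """
    for name, v in (
        ("hatched", hatched),
        ("dead_in_nest", dead_in_nest),
        ("live_in_nest", live_in_nest),
    ):
        if v < 0:
            raise ValidationError(f"{name} must be non-negative")
    if dead_in_nest + live_in_nest > hatched:
        raise ValidationError("dead_in_nest + live_in_nest exceeds hatched")
    return hatched - (dead_in_nest + live_in_nest)


def emergence_success(emergents: int, clutch_size: int) -> float:
    """Per-nest emergence success: emergents / clutch size, in [0, 1]."""
    if clutch_size <= 0:
        raise ValidationError("clutch_size must be positive for a rate")
    if emergents < 0 or emergents > clutch_size:
        raise ValidationError("emergents must lie in [0, clutch_size]")
    return emergents / clutch_size


def sample_emergents(sample: IsotopeSample) -> int:
    if sample.hatched is None:
        raise ValidationError(f"{sample.id}: no nest-fate record")
    return compute_emergents(
        sample.hatched, sample.dead_in_nest or 0, sample.live_in_nest or 0
    )


# ---------------------------------------------------------------------------
# hotspots


@dataclass(frozen=True)
class HotspotSet:
    """The seven foraging hotspots as named polygons, in fixed order."""

    names: tuple[str, ...]
    polygons: tuple[BaseGeometry, ...]
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValidationError("hotspot names must be unique")
        if len(self.names) != len(self.polygons):
            raise ValidationError("names and polygons must pair up")
        for name, poly in zip(self.names, self.polygons):
            if not poly.is_valid:
                raise ValidationError(f"hotspot {name}: invalid polygon")

    def __iter__(self):
        return iter(zip(self.names, self.polygons))

    def __len__(self) -> int:
        return len(self.names)

    def validate_within(self, grid: GridSpec) -> None:
        for name, poly in self:
            minx, miny, maxx, maxy = poly.bounds
            if not (
                grid.lon_min <= minx
                and maxx <= grid.lon_max
                and grid.lat_min <= miny
                and maxy <= grid.lat_max
            ):
                raise ValidationError(f"hotspot {name} extends outside the grid")


def read_hotspots(path: str | Path, crs: str = "EPSG:4326") -> HotspotSet:
    """Read a GeoJSON FeatureCollection with a "name" property per feature."""
    with open(path) as fh:
        gj = json.load(fh)
    names, polys = [], []
    for feat in gj["features"]:
        names.append(feat["properties"]["name"])
        polys.append(shape(feat["geometry"]))
    return HotspotSet(tuple(names), tuple(polys), crs=crs)


def write_hotspots(hotspots: HotspotSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(poly),
        }
        for name, poly in hotspots
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
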