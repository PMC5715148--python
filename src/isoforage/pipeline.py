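"""End-to-end orchestration: simulate/ingest → isoscapes → covariance
field → assignment → validation → summaries → rank tests.

`run_study` is the single entry point the CLI and the reproduction
script call; it returns every intermediate product so tests can inspect
them, and optionally writes the artifact tree with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .assignment import (
    AssignmentSurface,
    CalibrationValidation,
    CovField,
    TissueCov,
    assignment_surfaces,
    build_cov_field,
    pooled_tissue_covariance,
    validate_calibration,
)
from .isoscape import Isoscape, krige_surface
from .ranktests import FriedmanResult, PosthocResult, conover_pairwise, friedman
from .samples import (
    CalibrationSample,
    ConversionModel,
    HotspotSet,
    IsotopeSample,
    sample_emergents,
    to_epidermis,
)
from .simulate import Scenario, SyntheticStudy, generate_study
from .summaries import (
    ContributionTable,
    ImportanceIndex,
    emergence_rate_table,
    foraging_index,
    hotspot_table,
    weighted_index,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyResults:
    """All pipeline products for one study run."""

    iso_c: Isoscape
    iso_n: Isoscape
    tissue_cov: TissueCov
    cov_field: CovField
    calibration_surfaces: list[AssignmentSurface]
    validation: CalibrationValidation
    surfaces: list[AssignmentSurface]
    count_indices: dict[int, ImportanceIndex]
    egg_indices: dict[int, ImportanceIndex]
    emergent_indices: dict[int, ImportanceIndex]
    female_table: ContributionTable          # by_n hotspot sums
    female_table_prop: ContributionTable     # by_hotspot_total proportions
    emergence_table: ContributionTable
    friedman_female: FriedmanResult
    conover_female: PosthocResult
    friedman_emergence: FriedmanResult
    conover_emergence: PosthocResult


def analyze_study(
    calibration: Sequence[CalibrationSample],
    cohorts: dict[int, Sequence[IsotopeSample]],
    hotspots: HotspotSet,
    grid,
    conversion: ConversionModel | None = None,
    alpha: float = 0.05,
) -> StudyResults:
    """Run the full analysis on ingested (or simulated) sample tables."""
    conversion = conversion or ConversionModel()
    calibration = [to_epidermis(s, conversion) for s in calibration]
    cohorts = {
        y: [to_epidermis(s, conversion) for s in ss] for y, ss in cohorts.items()
    }
    t0 = time.time()
    iso_c = krige_surface(calibration, grid, "C")
    iso_n = krige_surface(calibration, grid, "N")
    logger.info("isoscapes fit in %.1fs", time.time() - t0)

    tissue = pooled_tissue_covariance(calibration)
    cov = build_cov_field(tissue, iso_c, iso_n)

    cal_surfaces = assignment_surfaces(calibration, iso_c, iso_n, cov)
    validation = validate_calibration(cal_surfaces, calibration)
    logger.info(
        "calibration validation: median=%.3f q1=%.3f over %d animals",
        validation.median, validation.q1, len(calibration),
    )

    surfaces: list[AssignmentSurface] = []
    for year in sorted(cohorts):
        surfaces.extend(assignment_surfaces(cohorts[year], iso_c, iso_n, cov))
    logger.info("built %d assignment surfaces", len(surfaces))

    egg_weights = {
        s.id: float(s.clutch_size)
        for ss in cohorts.values() for s in ss if s.clutch_size is not None
    }
    emergent_weights = {
        s.id: float(sample_emergents(s))
        for ss in cohorts.values() for s in ss if s.has_nest_fate
    }
    years = sorted(cohorts)
    count_idx = {y: foraging_index(surfaces, y) for y in years}
    egg_idx = {y: weighted_index(surfaces, egg_weights, y, "eggs") for y in years}
    emer_idx = {
        y: weighted_index(surfaces, emergent_weights, y, "emergents") for y in years
    }

    female_table = hotspot_table(count_idx, hotspots, normalize="by_n")
    female_prop = hotspot_table(count_idx, hotspots, normalize="by_hotspot_total")
    emergence = emergence_rate_table(egg_idx, emer_idx, hotspots)

    return StudyResults(
        iso_c=iso_c, iso_n=iso_n, tissue_cov=tissue, cov_field=cov,
        calibration_surfaces=cal_surfaces, validation=validation,
        surfaces=surfaces, count_indices=count_idx, egg_indices=egg_idx,
        emergent_indices=emer_idx, female_table=female_table,
        female_table_prop=female_prop, emergence_table=emergence,
        friedman_female=friedman(female_table),
        conover_female=conover_pairwise(female_table, alpha=alpha),
        friedman_emergence=friedman(emergence),
        conover_emergence=conover_pairwise(emergence, alpha=alpha),
    )


def run_study(
    scenario: Scenario, out_dir: str | Path | None = None
) -> tuple[SyntheticStudy, StudyResults]:
    """Simulate a study from the scenario and analyze it end to end."""
    data_dir = Path(out_dir) / "data" if out_dir is not None else None
    study = generate_study(scenario, data_dir)
    results = analyze_study(
        study.calibration,
        {y: list(ss) for y, ss in study.cohorts.items()},
        study.hotspots(),
        scenario.grid,
    )
    if out_dir is not None:
        write_outputs(results, Path(out_dir), scenario)
    return study, results


def write_outputs(results: StudyResults, out: Path, scenario: Scenario) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results.iso_c.mean.write_ascii(out / "isoscape_C_mean.asc")
    results.iso_c.se.write_ascii(out / "isoscape_C_se.asc")
    results.iso_n.mean.write_ascii(out / "isoscape_N_mean.asc")
    results.iso_n.se.write_ascii(out / "isoscape_N_se.asc")
    results.female_table.to_csv(out / "female_index_by_n.csv")
    results.female_table_prop.to_csv(out / "female_index_proportions.csv")
    results.emergence_table.to_csv(out / "emergence_rates.csv")
    tests = {
        "female_index": _test_json(results.friedman_female, results.conover_female),
        "emergence_rate": _test_json(
            results.friedman_emergence, results.conover_emergence
        ),
        "calibration_validation": {
            "median": results.validation.median,
            "q1": results.validation.q1,
            "n": len(results.validation.values),
        },
    }
    with open(out / "rank_tests.json", "w") as fh:
        json.dump(tests, fh, indent=1)
    write_manifest(out, scenario)


def _test_json(fr: FriedmanResult, ph: PosthocResult) -> dict:
    return {
        "friedman": {"statistic": fr.statistic, "df": fr.df, "p": fr.pvalue},
        "conover": {
            "treatments": ph.treatments,
            "adjusted_p": np.round(ph.adjusted_p, 6).tolist(),
            "letters": ph.letters,
            "alpha": ph.alpha,
        },
    }


def write_manifest(out: Path, scenario: Scenario) -> None:
    """Provenance stamp: config hash, seed, input checksums, version.

    Reruns with identical inputs differ only in the timestamp.
    """
    scenario_yaml = out / "scenario.yaml"
    scenario.to_yaml(scenario_yaml)
    checksums = {}
    data_dir = out / "data"
    if data_dir.is_dir():
        for p in sorted(data_dir.rglob("*")):
            if p.is_file():
                checksums[str(p.relative_to(out))] = _sha256(p)
    manifest = {
        "version": __version__,
        "seed": scenario.seed,
        "config_sha256": _sha256(scenario_yaml),
        "input_checksums": checksums,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
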