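"""Run configuration, orchestration and result files.

A :class:`RunConfig` gathers every tunable of the pipeline in one
serializable (YAML) record, so a whole assay is reproducible from the
config plus the seed.  :func:`run_assay` dispatches to the assay
workflows (mortality scoring, length measurement, live counting,
fecundity, lifespan, habituation) and writes CSV/JSON results, each
stamped with a provenance block -- software version and a hash of the
config -- but no timestamps, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counting import count_moving
from .endpoints import (
    DoseGroup,
    SurvivalSeries,
    fecundity_curves,
    fit_probit,
    habituation_series,
    lifespan_summary,
)
from .image import GrayscaleImage, read_tiff, read_tiff_stack
from .morphometry import measure_region
from .movement import score_pair
from .registration import ScanPair, align
from .segmentation import (
    FILTER_NAMES,
    FilterBankConfig,
    SegmentationModel,
    ThresholdSegmenter,
)

__all__ = ["RunConfig", "run_assay", "ASSAYS"]

log = logging.getLogger("wormscan")

ASSAYS = ("mortality", "length", "count", "fecundity", "lifespan", "habituation")


@dataclass
class RunConfig:
    """Every pipeline parameter, with documented defaults.

    Paths are assay-dependent: ``first``/``second`` for scan pairs,
    ``series`` for a multi-page scan stack, ``table`` for tabular
    inputs, ``model`` for a trained segmentation model.
    """

    # imaging
    dpi: float = 2400.0
    bit_depth: int = 16
    interval_s: float = 90.0
    # segmentation
    enabled_filters: tuple[str, ...] = FILTER_NAMES
    sigma_min: float = 2.0
    sigma_max: float = 16.0
    membrane_thickness: int = 19
    membrane_patch: int = 1
    use_membrane: bool = False
    min_area_px: int = 200
    max_area_px: int = 20000
    # registration
    max_shift_px: float = 50.0
    # movement / counting
    hysteresis_low: float | None = None   # None -> noise-adaptive
    hysteresis_high: float | None = None
    mortality_threshold: float = 0.10
    count_min_area_px: int = 50
    count_max_area_px: int = 40000
    merge_radius_px: float = 3.0
    # endpoints
    dose_scale: str = "linear"
    # run
    seed: int = 0
    first: str | None = None
    second: str | None = None
    series: str | None = None
    table: str | None = None
    model: str | None = None
    out_dir: str = "."
    log_level: str = "INFO"

    def filter_config(self) -> FilterBankConfig:
        return FilterBankConfig(
            enabled_filters=tuple(self.enabled_filters),
            sigma_min=self.sigma_min,
            sigma_max=self.sigma_max,
            membrane_thickness=self.membrane_thickness,
            membrane_patch=self.membrane_patch,
            use_membrane=self.use_membrane,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enabled_filters"] = list(d["enabled_filters"])
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["enabled_filters"] = tuple(d.get("enabled_filters", FILTER_NAMES))
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths and logging excluded)."""
        d = self.to_dict()
        for key in ("first", "second", "series", "table", "model", "out_dir", "log_level"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> str:
    return f"wormscan {__version__} config_sha256={config.config_hash()}"


def _write_csv(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_provenance(config)}\n")
        df.to_csv(fh, index=False)


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"provenance": _provenance(config), **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _segmenter(config: RunConfig):
    if config.model:
        return SegmentationModel.load(config.model)
    log.info("no trained model given; using intensity-threshold segmentation")
    return ThresholdSegmenter()


def _load_pair(config: RunConfig) -> ScanPair:
    if not config.first or not config.second:
        raise FileNotFoundError("mortality/count assays need --first and --second scans")
    first = read_tiff(config.first, bit_depth=config.bit_depth)
    second = read_tiff(config.second, bit_depth=config.bit_depth)
    for im in (first, second):
        im.dpi = config.dpi
    return ScanPair(first=first, second=second, interval_s=config.interval_s)


def run_assay(config: RunConfig, assay: str) -> dict[str, Path]:
    """Run one assay workflow and write its result files.

    Returns a mapping of short result names to written paths.  All
    randomness flows from ``config.seed``; outputs are deterministic.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; choose from {ASSAYS}")
    logging.basicConfig(level=config.log_level, stream=sys.stderr, force=False)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if assay == "mortality":
        pair = align(_load_pair(config), max_shift_px=config.max_shift_px)
        log.info("aligned pair, shift=%s", pair.estimated_shift)
        records, summary, dm = score_pair(
            pair,
            _segmenter(config),
            low=config.hysteresis_low,
            high=config.hysteresis_high,
            mortality_threshold=config.mortality_threshold,
            min_area_px=config.min_area_px,
            max_area_px=config.max_area_px,
        )
        df = pd.DataFrame(
            {
                "worm_id": [r.worm_id for r in records],
                "area_px": [r.area_px for r in records],
                "movement_fraction": [round(r.movement_fraction, 6) for r in records],
                "alive": [r.alive for r in records],
            }
        )
        _write_csv(out / "movement.csv", df, config)
        _write_json(
            out / "plate_summary.json",
            {
                "n_alive": summary.n_alive,
                "n_dead": summary.n_dead,
                "mortality": summary.mortality if summary.n_total else None,
                "estimated_shift": list(pair.estimated_shift),
                "hysteresis_low": dm.low,
                "hysteresis_high": dm.high,
            },
            config,
        )
        written = {"movement": out / "movement.csv", "summary": out / "plate_summary.json"}

    elif assay == "length":
        if not config.first:
            raise FileNotFoundError("length assay needs --first scan")
        image = read_tiff(config.first, bit_depth=config.bit_depth)
        image.dpi = config.dpi
        regions = _segmenter(config).segment(
            image, min_area_px=config.min_area_px, max_area_px=config.max_area_px
        )
        recs = [measure_region(r, dpi=config.dpi) for r in regions]
        df = pd.DataFrame(
            {
                "worm_id": [r.worm_id for r in recs],
                "length_px": [round(r.length_px, 3) for r in recs],
                "length_mm": [round(r.length_mm, 4) for r in recs],
                "n_branches": [r.n_branches for r in recs],
            }
        )
        _write_csv(out / "lengths.csv", df, config)
        written = {"lengths": out / "lengths.csv"}

    elif assay == "count":
        pair = align(_load_pair(config), max_shift_px=config.max_shift_px)
        result = count_moving(
            pair,
            low=config.hysteresis_low,
            high=config.hysteresis_high,
            min_area_px=config.count_min_area_px,
            max_area_px=config.count_max_area_px,
            merge_radius_px=config.merge_radius_px,
        )
        _write_json(
            out / "count.json",
            {
                "n_moving": result.n_moving,
                "component_areas": result.component_areas.tolist(),
                "hysteresis_low": result.low,
                "hysteresis_high": result.high,
                "merge_radius_px": result.merge_radius_px,
            },
            config,
        )
        written = {"count": out / "count.json"}

    elif assay == "fecundity":
        # long table: plate_id, day, count
        df = pd.read_csv(config.table, comment="#")
        wide = df.pivot_table(index="plate_id", columns="day", values="count").sort_index()
        if wide.isna().any().any():
            raise ValueError("ragged day grids: every plate needs every day")
        series = fecundity_curves(wide.to_numpy(), days=wide.columns.to_numpy())
        res = pd.DataFrame(
            {
                "day": series.days,
                "per_day_mean": series.per_day_mean,
                "per_day_lo95": series.per_day_ci[0],
                "per_day_hi95": series.per_day_ci[1],
                "cumulative_mean": series.cumulative_mean,
                "cumulative_lo95": series.cumulative_ci[0],
                "cumulative_hi95": series.cumulative_ci[1],
            }
        ).round(4)
        _write_csv(out / "fecundity.csv", res, config)
        written = {"fecundity": out / "fecundity.csv"}

    elif assay == "lifespan":
        # long table: trial, day, n_alive
        df = pd.read_csv(config.table, comment="#")
        wide = df.pivot_table(index="trial", columns="day", values="n_alive").sort_index()
        series = SurvivalSeries(days=wide.columns.to_numpy(), n_alive=wide.to_numpy())
        summ = lifespan_summary(series)
        _write_json(
            out / "lifespan.json",
            {
                "mean_lifespan_days": round(summ.mean_days, 3),
                "se_days": round(summ.se_days, 3) if np.isfinite(summ.se_days) else None,
                "n_deaths": summ.n_deaths,
                "trial_means": [round(m, 3) for m in summ.trial_means],
            },
            config,
        )
        written = {"lifespan": out / "lifespan.json"}

    elif assay == "habituation":
        if not config.series:
            raise FileNotFoundError("habituation assay needs --series scan stack")
        scans = read_tiff_stack(config.series, bit_depth=config.bit_depth)
        for im in scans:
            im.dpi = config.dpi
        series = habituation_series(
            scans,
            _segmenter(config),
            interval_s=config.interval_s,
            response_threshold=config.mortality_threshold,
            min_area_px=config.min_area_px,
            max_area_px=config.max_area_px,
            low=config.hysteresis_low,
            high=config.hysteresis_high,
        )
        df = pd.DataFrame(
            {
                "interval": np.arange(1, len(series.responding_fraction) + 1),
                "responding_fraction": np.round(series.responding_fraction, 6),
                "n_scored": series.n_scored,
            }
        )
        _write_csv(out / "habituation.csv", df, config)
        written = {"habituation": out / "habituation.csv"}

    return written


def fit_lc50_from_table(config: RunConfig) -> dict:
    """Probit LC50 from a long dose table (concentration, n_total, n_dead[, replicate])."""
    df = pd.read_csv(config.table, comment="#")
    groups = [
        DoseGroup(
            float(r.concentration),
            int(r.n_total),
            int(r.n_dead),
            replicate=int(getattr(r, "replicate", 0)),
        )
        for r in df.itertuples()
    ]
    fit = fit_probit(groups, dose_scale=config.dose_scale)
    return {
        "intercept": fit.intercept,
        "slope": fit.slope,
        "se_intercept": fit.se_intercept,
        "se_slope": fit.se_slope,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "dose_scale": fit.dose_scale,
        "lc50": fit.lc50 if fit.valid else None,
        "lc50_se": fit.lc50_se if fit.valid else None,
    }
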