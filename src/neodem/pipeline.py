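"""End-to-end orchestration: calibrate -> track front -> regionalise -> test.

The stages are thin compositions of the core modules; everything stochastic
takes its seed from the run configuration, and every record-dropping filter
reports its counts through logging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calcurve, fronts, mcspd, spd
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "calibrate_table",
    "prepare_dates",
    "run_front",
    "neolithization_of",
    "RegionResult",
    "test_region",
    "test_all_regions",
]


def calibrate_table(dates: pd.DataFrame, curve: calcurve.CalibrationCurve) -> pd.DataFrame:
    """Append a ``mode_age`` column; rows that cannot be calibrated are
    dropped with a logged count."""
    modes = np.full(len(dates), np.nan)
    bad = 0
    for i, (cra, sig) in enumerate(zip(dates["cra"], dates["sigma_lab"])):
        try:
            modes[i] = calcurve.calibrate(float(cra), float(sig), curve).mode
        except (calcurve.CurveRangeError, ValueError):
            bad += 1
    out = dates.copy()
    out["mode_age"] = modes
    if bad:
        logger.warning("calibrate_table: dropped %d uncalibratable rows", bad)
        out = out[np.isfinite(modes)].reset_index(drop=True)
    return out


def prepare_dates(dates: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Apply the lab-error quality cut and the optional outlier list."""
    kept, dropped = calcurve.apply_quality_filter(dates, config.max_sigma_lab)
    logger.info("quality filter: kept %d, dropped %d (sigma_lab > %s)",
                len(kept), dropped, config.max_sigma_lab)
    if config.outlier_file:
        with open(config.outlier_file) as fh:
            outliers = {line.strip() for line in fh if line.strip()}
        before = len(kept)
        kept = kept[~kept["lab_code"].isin(outliers)].reset_index(drop=True)
        logger.info("outlier list: dropped %d of %d", before - len(kept), before)
    return kept


def run_front(calibrated: pd.DataFrame, config: RunConfig):
    """Hull series, pulses, and region partition from a calibrated table."""
    neo = calibrated[calibrated["period"] == "Neolithic"]
    if len(neo) < 3:
        raise ValueError("fewer than 3 Neolithic points; cannot track the front")
    series = fronts.hull_series(
        neo, step=config.hull_step, time_range=(config.hull_old, config.hull_young)
    )
    pulses = fronts.detect_pulses(series, config.growth_frac, config.pause_len)
    partition = fronts.region_polygons(series, pulses)
    return series, pulses, partition


def neolithization_of(region_dates: pd.DataFrame, override: float | None = None) -> float:
    """Regional moment of first farming arrival: the mode of the earliest
    (oldest-mode) Neolithic date, unless overridden from config."""
    if override is not None:
        return float(override)
    neo = region_dates[region_dates["period"] == "Neolithic"]
    if neo.empty:
        raise ValueError("region has no Neolithic dates")
    return float(neo["mode_age"].max())


@dataclass
class RegionResult:
    region: str
    n_bins: int
    neolithization: float
    test: mcspd.MCTestResult
    fit_raw: spd.GrowthFit | None
    fit_tapho: spd.GrowthFit | None
    observed: spd.SPDResult


def test_region(
    region_dates: pd.DataFrame,
    label: str,
    curve: calcurve.CalibrationCurve,
    config: RunConfig,
    fits: bool = True,
) -> RegionResult:
    """Observed SPD, Mesolithic null, MCSPD test and growth fits for one region."""
    young = config.bracket_for(label)
    window = (float(config.bracket_old), float(young))
    t_neo = neolithization_of(
        region_dates, config.neolithization_overrides.get(label)
    )
    bins = spd.bin_dates(region_dates, h=config.h)
    observed = spd.compute_spd(bins, curve, window)
    observed.region = label
    # the simulation stage needs only the null's point rate, not its SE
    model = mcspd.fit_null(region_dates, t_neo, curve, h=config.h,
                           old_bracket=config.bracket_old, n_boot=0, rng=config.seed)
    result = mcspd.run_mcspd(
        observed,
        model,
        region_dates["sigma_lab"].to_numpy(float),
        curve,
        n_sim=config.n_sim,
        seed=config.seed,
    )
    fit_raw = fit_tapho = None
    if fits:
        # growth fits exclude the edge-affected spans near the brackets
        fit_window = (window[0] - config.edge_margin, window[1] + config.edge_margin)
        fit_raw = spd.fit_exponential(observed, fit_window, rng=config.seed)
        fit_tapho = spd.fit_exponential(
            spd.taphonomic_correct(observed), fit_window, rng=config.seed
        )
    return RegionResult(
        region=label,
        n_bins=bins.n_bins,
        neolithization=t_neo,
        test=result,
        fit_raw=fit_raw,
        fit_tapho=fit_tapho,
        observed=observed,
    )


def test_all_regions(
    assigned: pd.DataFrame,
    curve: calcurve.CalibrationCurve,
    config: RunConfig,
    fits: bool = True,
) -> dict[str, RegionResult]:
    """Run the per-region MCSPD test for every assigned region.

    Regions with too little Mesolithic data (or no Neolithic dates) are
    skipped with an explicit log entry.
    """
    out: dict[str, RegionResult] = {}
    for label, sub in assigned.groupby("region", sort=False):
        if label == "unassigned":
            logger.info("skipping %d unassigned dates", len(sub))
            continue
        try:
            out[label] = test_region(sub.reset_index(drop=True), str(label), curve,
                                     config, fits=fits)
        except (mcspd.InsufficientDataError, ValueError) as exc:
            logger.warning("region %s skipped: %s", label, exc)
    return out
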