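"""Radiocarbon calibration: curves, calibrated densities, and their inverse.

A calibration curve maps calendar age t (cal BP, years before 1950; larger =
older) to an expected conventional radiocarbon age mu(t) with curve error
sigma_curve(t). Calibrating a lab determination (cra, sigma_lab) places a
Gaussian likelihood over calendar ages:

    mass(t) ∝ N(cra | mu(t), sigma_lab² + sigma_curve(t)²)

normalised to a unit probability mass on a 1-yr calendar grid — the standard
intercept-free calibration with measurement and curve variances added in
quadrature. ``uncalibrate`` is the forward simulation used by the Monte-Carlo
machinery: draw a CRA for a known calendar age through the same error model.

All ages in this package are cal BP; no BC/AD conversion occurs anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "CalibratedDensity",
    "CurveFormatError",
    "CurveRangeError",
    "read_curve",
    "write_curve",
    "calibrate",
    "calibrate_many",
    "mode_of",
    "uncalibrate",
    "read_dates",
    "apply_quality_filter",
    "MAX_SIGMA_LAB",
]

#: Dataset-level quality cut: retain only dates with sigma_lab at or below this.
MAX_SIGMA_LAB = 150.0

DATE_COLUMNS = ["lab_code", "cra", "sigma_lab", "site", "lon", "lat", "period", "culture"]


class CurveFormatError(ValueError):
    """Malformed calibration-curve file."""


class CurveRangeError(ValueError):
    """Radiocarbon or calendar age outside the span of the curve."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Calibration curve on a 1-yr calendar grid.

    Attributes
    ----------
    grid : ndarray
        Strictly ascending calendar ages, cal BP, 1-yr spacing.
    mu : ndarray
        Expected radiocarbon age (14C yr BP) at each grid age.
    sigma_curve : ndarray
        1-sigma curve error (14C yr) at each grid age, non-negative.
    name : str
        Identifier, e.g. ``"intcal13"`` or ``"toy"``.
    """

    grid: np.ndarray
    mu: np.ndarray
    sigma_curve: np.ndarray
    name: str = "curve"

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sig = np.asarray(self.sigma_curve, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise CurveFormatError("curve needs at least two grid points")
        if not np.all(np.diff(grid) > 0):
            raise CurveFormatError("calendar grid must be strictly increasing")
        if np.any(sig < 0):
            raise CurveFormatError("sigma_curve must be non-negative")
        if not np.all(np.isfinite(mu)):
            raise CurveFormatError("mu must be finite")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma_curve", sig)

    @property
    def span(self) -> tuple[float, float]:
        """(youngest, oldest) calendar age covered, cal BP."""
        return float(self.grid[0]), float(self.grid[-1])

    def mu_at(self, t):
        return np.interp(np.asarray(t, dtype=float), self.grid, self.mu)

    def sigma_at(self, t):
        return np.interp(np.asarray(t, dtype=float), self.grid, self.sigma_curve)


@dataclass(frozen=True)
class CalibratedDensity:
    """Normalised calendar-age probability mass of one calibrated date.

    ``grid`` is the contiguous 1-yr support kept after tail truncation; ``mass``
    sums to one; ``mode`` is the grid age of maximum mass (ties broken toward
    the older age).
    """

    grid: np.ndarray
    mass: np.ndarray
    mode: float = field(init=False)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.shape != mass.shape or grid.ndim != 1:
            raise ValueError("grid and mass must be matching 1-d arrays")
        if np.any(mass < 0):
            raise ValueError("mass must be non-negative")
        total = mass.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"mass must sum to 1 (got {total!r})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mass", mass)
        object.__setattr__(self, "mode", _argmax_oldest(grid, mass))


def _argmax_oldest(grid: np.ndarray, mass: np.ndarray) -> float:
    """Age of maximum mass; exact ties go to the larger (older) cal BP."""
    m = mass.max()
    return float(grid[mass == m].max())


_SPLIT = re.compile(r"[,\s]+")


def read_curve(path, name: str | None = None) -> CalibrationCurve:
    """Read a calibration curve in the IntCal ``.14c`` dialect.

    Header/comment lines start with ``#``; data rows hold at least three
    columns (cal BP, 14C age BP, 1-sigma error); comma- and whitespace-
    separated files are both accepted. The cal BP column must be monotone
    (either direction). The curve is linearly interpolated to a 1-yr grid
    over the file's span.
    """
    cal, mu, sig = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _SPLIT.split(line) if p]
            if len(parts) < 3:
                raise CurveFormatError(f"line {lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise CurveFormatError(f"line {lineno}: non-numeric field ({exc})") from None
            cal.append(vals[0])
            mu.append(vals[1])
            sig.append(vals[2])
    if len(cal) < 2:
        raise CurveFormatError("curve file holds fewer than two data rows")
    cal = np.asarray(cal)
    mu = np.asarray(mu)
    sig = np.asarray(sig)
    d = np.diff(cal)
    if np.all(d < 0):  # IntCal files list oldest first; reorder ascending
        cal, mu, sig = cal[::-1], mu[::-1], sig[::-1]
    elif not np.all(d > 0):
        raise CurveFormatError("cal BP column is not monotone")
    grid = np.arange(np.ceil(cal[0]), np.floor(cal[-1]) + 1.0)
    return CalibrationCurve(
        grid=grid,
        mu=np.interp(grid, cal, mu),
        sigma_curve=np.interp(grid, cal, sig),
        name=name or str(path),
    )


def write_curve(curve: CalibrationCurve, path, step: int = 5) -> None:
    """Write a curve in the IntCal ``.14c`` dialect (oldest first, 5 columns)."""
    idx = np.arange(curve.grid.size - 1, -1, -step)
    with open(path, "w") as fh:
        fh.write(f"# {curve.name}\n# CAL BP, 14C age BP, Error, Delta14C, Sigma\n")
        for i in idx:
            fh.write(
                f"{curve.grid[i]:.0f},{curve.mu[i]:.1f},{curve.sigma_curve[i]:.1f},0.0,0.0\n"
            )


def _check_in_span(cra: float, curve: CalibrationCurve, sigma_lab: float) -> None:
    sig = float(np.sqrt(sigma_lab**2 + curve.sigma_curve.max() ** 2))
    lo, hi = curve.mu.min() - 10 * sig, curve.mu.max() + 10 * sig
    if not (lo <= cra <= hi):
        raise CurveRangeError(
            f"CRA {cra} outside curve span [{curve.mu.min():.0f}, {curve.mu.max():.0f}] "
            f"+/- 10 sigma"
        )


def calibrate(
    cra: float,
    sigma_lab: float,
    curve: CalibrationCurve,
    trunc: float = 1e-5,
) -> CalibratedDensity:
    """Calibrate one determination to a calendar probability density.

    Parameters
    ----------
    cra, sigma_lab : float
        Conventional radiocarbon age and its 1-sigma lab error (14C yr).
    curve : CalibrationCurve
    trunc : float
        Total tail mass removed when truncating the support to a contiguous
        window (half from each tail); the retained mass is renormalised to 1.
    """
    if sigma_lab <= 0:
        raise ValueError("sigma_lab must be positive")
    _check_in_span(cra, curve, sigma_lab)
    var = sigma_lab**2 + curve.sigma_curve**2
    mass = np.exp(-0.5 * (cra - curve.mu) ** 2 / var) / np.sqrt(var)
    total = mass.sum()
    if total <= 0 or not np.isfinite(total):
        raise CurveRangeError(f"CRA {cra} has no support on curve {curve.name!r}")
    mass /= total
    if trunc > 0:
        cum = np.cumsum(mass)
        lo = int(np.searchsorted(cum, trunc / 2.0))
        hi = int(np.searchsorted(cum, 1.0 - trunc / 2.0)) + 1
        hi = min(hi, mass.size)
        mass = mass[lo:hi]
        grid = curve.grid[lo:hi]
        mass = mass / mass.sum()
    else:
        grid = curve.grid
    return CalibratedDensity(grid=grid, mass=mass)


def calibrate_many(
    cra: np.ndarray,
    sigma_lab: np.ndarray,
    curve: CalibrationCurve,
    grid: np.ndarray,
    pad: float = 800.0,
    chunk: int = 256,
) -> np.ndarray:
    """Calibrated densities of many dates evaluated on a shared grid.

    Each date's density is normalised over ``grid`` extended by ``pad`` years
    on both sides (clipped to the curve span), then restricted to ``grid``;
    this keeps per-date normalisation honest near window edges while letting
    the whole batch be computed as a few dense matrix operations. Returns an
    array of shape ``(n_dates, grid.size)`` whose rows each sum to <= 1.
    """
    cra = np.asarray(cra, dtype=float)
    sigma_lab = np.asarray(sigma_lab, dtype=float)
    slope = np.diff(curve.mu) / np.diff(curve.grid)
    lo = max(curve.grid[0], grid[0] - pad)
    hi = min(curve.grid[-1], grid[-1] + pad)
    wide = np.arange(lo, hi + 1.0)
    mu = curve.mu_at(wide)
    sc2 = curve.sigma_at(wide) ** 2
    start = int(grid[0] - wide[0])
    if np.all(slope > 0):
        # banded fast path: each date only matters within a few combined
        # standard deviations of its inverted calendar position
        stretch = 1.0 / max(float(slope.min()), 0.2)
        sd_max = float(np.sqrt(sigma_lab.max() ** 2 + curve.sigma_curve.max() ** 2))
        half = int(np.ceil(8.0 * sd_max * stretch))
        centers = np.rint(np.interp(cra, curve.mu, curve.grid) - wide[0]).astype(np.int64)
        offsets = np.arange(-half, half + 1, dtype=np.int64)
        out = np.zeros((cra.size, grid.size))
        for s in range(0, cra.size, chunk):
            e = min(s + chunk, cra.size)
            idx = centers[s:e, None] + offsets[None, :]
            valid = (idx >= 0) & (idx < wide.size)
            idxc = np.clip(idx, 0, wide.size - 1)
            var = sigma_lab[s:e, None] ** 2 + sc2[idxc]
            m = np.exp(-0.5 * (cra[s:e, None] - mu[idxc]) ** 2 / var) / np.sqrt(var)
            m[~valid] = 0.0
            norm = m.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            m /= norm
            # scatter rows into the window; out-of-window band cells dropped
            buf = np.zeros((e - s, wide.size + 1))
            tgt = np.where(valid, idxc, wide.size)
            np.put_along_axis(buf, tgt, m, axis=1)
            out[s:e] = buf[:, start:start + grid.size]
        return out
    out = np.empty((cra.size, grid.size))
    for s in range(0, cra.size, chunk):
        e = min(s + chunk, cra.size)
        var = sigma_lab[s:e, None] ** 2 + sc2[None, :]
        m = np.exp(-0.5 * (cra[s:e, None] - mu[None, :]) ** 2 / var) / np.sqrt(var)
        m /= m.sum(axis=1, keepdims=True)
        out[s:e] = m[:, start:start + grid.size]
    return out


def sum_calibrated(
    cra: np.ndarray,
    sigma_lab: np.ndarray,
    curve: CalibrationCurve,
    grid: np.ndarray,
    nsigma: float = 5.0,
) -> np.ndarray:
    """Sum of normalised calibrated densities of many dates on a shared grid.

    Equivalent to ``calibrate_many(...).sum(axis=0)`` but evaluates each date
    only on a band of ``nsigma`` combined standard deviations around its
    calendar position (found by inverting the curve), then scatter-adds into
    the output — the hot path for Monte-Carlo ensembles. Requires a strictly
    increasing ``mu``; falls back to the dense evaluation otherwise.
    """
    cra = np.asarray(cra, dtype=float)
    sig = np.asarray(sigma_lab, dtype=float)
    slope = np.diff(curve.mu) / np.diff(curve.grid)
    if not np.all(slope > 0):
        return calibrate_many(cra, sig, curve, grid).sum(axis=0)
    stretch = 1.0 / max(float(slope.min()), 0.2)
    sc_const = float(curve.sigma_curve.max() - curve.sigma_curve.min()) < 1e-9
    sd_max = float(np.sqrt(sig.max() ** 2 + curve.sigma_curve.max() ** 2))
    half = int(np.ceil(nsigma * sd_max * stretch))
    lo = max(curve.grid[0], grid[0] - half)
    hi = min(curve.grid[-1], grid[-1] + half)
    wide = np.arange(lo, hi + 1.0)
    mu_w = curve.mu_at(wide)
    sc2_w = curve.sigma_at(wide) ** 2
    centers = np.rint(np.interp(cra, curve.mu, curve.grid) - wide[0]).astype(np.int64)
    offsets = np.arange(-half, half + 1, dtype=np.int64)
    idx = centers[:, None] + offsets[None, :]
    valid = (idx >= 0) & (idx < wide.size)
    idxc = np.clip(idx, 0, wide.size - 1)
    q = cra[:, None].astype(np.float32) - mu_w.astype(np.float32)[idxc]
    if sc_const:
        # row-constant variance: the 1/sqrt(var) prefactor cancels in the
        # per-date normalisation and can be dropped
        inv2v = (0.5 / (sig**2 + curve.sigma_curve[0] ** 2)).astype(np.float32)
        m = np.exp(-(q * q) * inv2v[:, None])
    else:
        var = (sig[:, None] ** 2).astype(np.float32) + sc2_w.astype(np.float32)[idxc]
        m = np.exp(-0.5 * (q * q) / var) / np.sqrt(var)
    m[~valid] = 0.0
    norm = m.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    m /= norm
    total = np.bincount(idxc.ravel(), weights=m.ravel().astype(np.float64),
                        minlength=wide.size)
    start = int(grid[0] - wide[0])
    return total[start:start + grid.size]


def mode_of(density: CalibratedDensity) -> float:
    """Calendar age (cal BP) of maximum mass; ties break toward the older age."""
    return _argmax_oldest(density.grid, density.mass)


def uncalibrate(
    t_true,
    curve: CalibrationCurve,
    sigma_lab,
    rng: np.random.Generator | int,
):
    """Simulate CRA(s) for known calendar age(s) through the curve error model.

    Draws ``cra = mu(t_true) + N(0, sqrt(sigma_curve(t_true)² + sigma_lab²))``.
    The combined variance is applied in this single draw; recalibration of the
    result must not add the curve error again on the simulated draw's behalf
    (it re-enters only through the likelihood, as for a real date). Vectorised
    over ``t_true``/``sigma_lab``; deterministic given a seeded generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = np.asarray(t_true, dtype=float)
    if np.any(t < curve.grid[0]) or np.any(t > curve.grid[-1]):
        raise CurveRangeError("t_true outside curve span")
    sig = np.sqrt(curve.sigma_at(t) ** 2 + np.asarray(sigma_lab, dtype=float) ** 2)
    cra = curve.mu_at(t) + rng.standard_normal(t.shape if t.shape else None) * sig
    return cra


def read_dates(path) -> pd.DataFrame:
    """Read a radiocarbon date table (CSV with the canonical column schema).

    Required columns: lab_code, cra, sigma_lab, site, lon, lat, period;
    ``culture`` is optional and filled with NA when absent. Validates
    coordinate ranges and positive lab errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in DATE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"date table missing columns: {missing}")
    if "culture" not in df.columns:
        df["culture"] = pd.NA
    df = df[DATE_COLUMNS].copy()
    for col in ("cra", "sigma_lab", "lon", "lat"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["sigma_lab"] <= 0).any():
        raise ValueError("sigma_lab must be positive for every date")
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise ValueError("coordinates outside WGS84 bounds")
    return df


def apply_quality_filter(
    df: pd.DataFrame, max_sigma: float = MAX_SIGMA_LAB
) -> tuple[pd.DataFrame, int]:
    """Drop dates with sigma_lab above the quality cut; returns (kept, n_dropped)."""
    keep = df["sigma_lab"] <= max_sigma
    return df[keep].reset_index(drop=True), int((~keep).sum())
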