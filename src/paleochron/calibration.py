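"""Radiocarbon calibration: curves, dates, and calendar-axis probability densities.

Ages are expressed in cal BP (calendar years before 1950 CE) throughout; larger
values are older.  Quantiles use the *from-old* convention: ``q`` is the
cumulative probability mass on the old side of the returned age, so the 0.05
quantile is an old (large) age and the 0.95 quantile a young (small) age.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, TextIO, Union

import numpy as np

__all__ = [
    "CalibrationCurve",
    "GeochronDate",
    "CalibratedDensity",
    "ChronControl",
    "CurveParseError",
    "OutOfRangeError",
    "load_calibration_curve",
    "calibrate_radiocarbon",
    "calendar_density",
    "density_quantile",
    "summarize_control",
]

MAX_C14_CAL_BP = 55_000  # practical ceiling of the radiocarbon method


class CurveParseError(ValueError):
    """Raised when a calibration-curve file cannot be parsed."""


class OutOfRangeError(ValueError):
    """Raised when a date has no probability mass anywhere on the curve grid."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Calendar-age -> 14C-age mapping on a uniform cal BP grid.

    Attributes
    ----------
    grid : ndarray of int
        Calendar ages in cal BP, strictly ascending, uniform spacing.
    mu : ndarray of float
        Expected 14C age (14C BP) at each grid point.
    sigma : ndarray of float
        Curve 1-sigma uncertainty (14C yr) at each grid point; strictly positive.
    name : str
        Label (e.g. ``"intcal20"`` or ``"identity"``).
    """

    grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    name: str = "unnamed"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("curve grid must be 1-D with at least two points")
        if not (np.diff(grid) > 0).all():
            raise ValueError("curve grid must be strictly increasing")
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError("curve grid spacing must be uniform")
        if mu.shape != grid.shape or sigma.shape != grid.shape:
            raise ValueError("mu/sigma must match grid shape")
        if (sigma < 0).any():
            raise ValueError("curve sigma must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def resolution(self) -> int:
        return int(self.grid[1] - self.grid[0])

    @property
    def min_age(self) -> int:
        return int(self.grid[0])

    @property
    def max_age(self) -> int:
        return int(self.grid[-1])


@dataclass
class GeochronDate:
    """One raw geochronological measurement.

    ``age`` is in 14C BP for ``kind='radiocarbon'`` and cal BP for
    ``kind='calendar'`` (TL/OSL/U-series/Ar-Ar/paleomagnetic or pre-calibrated
    radiocarbon).  ``error_minus``/``error_plus`` are the 1-sigma errors on the
    younger and older side of the measurement; symmetric dates carry the same
    value on both sides.
    """

    age: float
    error_minus: float
    error_plus: float
    kind: str = "radiocarbon"
    lab_id: Optional[str] = None
    material: Optional[str] = None
    method: Optional[str] = None
    rejected: bool = False
    human_remains: bool = False
    single_sided: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("radiocarbon", "calendar"):
            raise ValueError(f"unknown date kind {self.kind!r}")
        if self.error_minus < 0 or self.error_plus < 0:
            raise ValueError("errors must be non-negative")

    @classmethod
    def symmetric(cls, age: float, error: float, **kwargs) -> "GeochronDate":
        return cls(age=age, error_minus=error, error_plus=error, **kwargs)

    @property
    def is_symmetric(self) -> bool:
        return self.error_minus == self.error_plus


@dataclass(frozen=True)
class CalibratedDensity:
    """Normalized probability mass function on a cal BP grid."""

    grid: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        p = np.asarray(self.p, dtype=float)
        if grid.shape != p.shape:
            raise ValueError("grid/p shape mismatch")
        if (p < 0).any():
            raise ValueError("density has negative mass")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"density mass {total} != 1")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "p", p)

    def cdf_from_old(self) -> np.ndarray:
        """Cumulative mass at or above each grid age (from the old end)."""
        return np.cumsum(self.p[::-1])[::-1]


@dataclass
class ChronControl:
    """One dated control point summarized as median and 5%/95% from-old quantiles."""

    geochron_ref: GeochronDate
    age: int
    agelimitolder: int
    agelimityounger: int
    control_type: str = "Radiocarbon, calibrated"
    analysis_unit_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.agelimityounger <= self.age <= self.agelimitolder):
            raise ValueError(
                "chron control ordering violated: "
                f"{self.agelimityounger} <= {self.age} <= {self.agelimitolder}"
            )


def load_calibration_curve(
    source: Union[str, TextIO],
    resolution: int = 1,
    name: Optional[str] = None,
) -> CalibrationCurve:
    """Parse an IntCal-style ``.14c`` text stream onto a uniform grid.

    The dialect: '#'-prefixed header comments, then rows of at least three
    comma- or whitespace-separated numbers (cal BP, 14C age, 1-sigma); extra
    columns are ignored.  Rows may appear in any order and are sorted
    ascending in cal BP, then linearly interpolated onto a uniform grid at
    ``resolution`` (years).

    Parameters
    ----------
    source : str or text stream
        File path or an open text stream.
    resolution : int
        Target grid spacing in years (1 or 5).
    """
    if resolution not in (1, 5):
        raise ValueError("resolution must be 1 or 5")
    if isinstance(source, str):
        with open(source, "rt") as fh:
            return load_calibration_curve(fh, resolution=resolution, name=name or source)

    rows = []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) < 3:
            raise CurveParseError(f"line {lineno}: expected >=3 columns, got {len(parts)}")
        try:
            cal, c14, sig = float(parts[0]), float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise CurveParseError(f"line {lineno}: non-numeric value ({exc})") from None
        rows.append((cal, c14, sig))

    if len(rows) < 2:
        raise CurveParseError("curve needs at least two data rows")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if (np.diff(arr[:, 0]) <= 0).any():
        raise CurveParseError("duplicate cal BP ages in curve")
    if (arr[:, 2] <= 0).any():
        raise CurveParseError("curve 1-sigma column missing or non-positive")

    lo = int(np.ceil(arr[0, 0]))
    hi = int(np.floor(arr[-1, 0]))
    lo -= lo % resolution
    grid = np.arange(lo, hi + 1, resolution)
    mu = np.interp(grid, arr[:, 0], arr[:, 1])
    sigma = np.interp(grid, arr[:, 0], arr[:, 2])
    return CalibrationCurve(grid=grid, mu=mu, sigma=sigma, name=name or "curve")


def _two_piece_weights(x: np.ndarray, center: float, s_minus: float, s_plus: float) -> np.ndarray:
    """Unnormalized two-piece Gaussian density of ``x`` around ``center``.

    ``s_plus`` applies where x > center (measurement above observed value,
    i.e. the observation sits on the low side), ``s_minus`` where x <= center.
    Reduces to an ordinary Gaussian when the two spreads coincide.
    """
    s = np.where(x > center, s_plus, s_minus)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, (x - center) / np.where(s > 0, s, 1.0), np.where(x == center, 0.0, np.inf))
    return np.exp(-0.5 * z * z)


def calibrate_radiocarbon(date: GeochronDate, curve: CalibrationCurve) -> CalibratedDensity:
    """Calibrate an uncalibrated 14C date against a curve.

    For each grid age theta the weight is the two-piece Gaussian density of the
    measured age ``x`` under mean ``mu(theta)`` with spread
    ``sqrt(sigma_side^2 + sigma_c(theta)^2)``, where ``sigma_side`` is
    ``error_plus`` when ``x < mu(theta)`` and ``error_minus`` otherwise.
    """
    if date.kind != "radiocarbon":
        raise ValueError("calibrate_radiocarbon requires a radiocarbon date")
    if date.single_sided:
        raise ValueError("single-sided dates cannot be calibrated")
    if date.error_minus <= 0 or date.error_plus <= 0:
        raise ValueError("calibration requires positive errors on both sides")

    s_minus = np.sqrt(date.error_minus**2 + curve.sigma**2)
    s_plus = np.sqrt(date.error_plus**2 + curve.sigma**2)
    # x below mu(theta): the curve value exceeds the measurement -> the
    # measurement errs on its high (older) side -> error_plus governs.
    s = np.where(date.age < curve.mu, s_plus, s_minus)
    z = (date.age - curve.mu) / s
    w = np.exp(-0.5 * z * z)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise OutOfRangeError(
            f"date {date.age} +/- {date.error_plus}/{date.error_minus} has no "
            "support on the curve grid"
        )
    return CalibratedDensity(grid=curve.grid, p=w / total)


def calendar_density(date: GeochronDate, curve: CalibrationCurve) -> CalibratedDensity:
    """Place a calendar-scale date directly on the cal BP grid.

    Two-piece Gaussian on the calendar axis, truncated to the curve grid and
    renormalized.  ``error_plus`` governs the older (larger cal BP) side.
    """
    if date.error_minus <= 0 or date.error_plus <= 0:
        raise ValueError("calendar density requires positive errors")
    w = _two_piece_weights(curve.grid.astype(float), date.age, date.error_minus, date.error_plus)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise OutOfRangeError(f"calendar date {date.age} outside the model grid")
    return CalibratedDensity(grid=curve.grid, p=w / total)


def density_quantile(d: CalibratedDensity, q_from_old: float) -> int:
    """Age at which the cumulative mass on the old side equals ``q_from_old``.

    Linear interpolation within grid cells; result rounded to the nearest year.
    Smaller ``q_from_old`` yields older (larger) ages.
    """
    if not (0.0 < q_from_old < 1.0):
        raise ValueError("q_from_old must be in (0, 1)")
    # cumulative from the young end; target mass below = 1 - q_from_old
    cdf = np.cumsum(d.p)
    target = 1.0 - q_from_old
    grid = d.grid.astype(float)
    h = grid[1] - grid[0] if len(grid) > 1 else 1.0
    idx = int(np.searchsorted(cdf, target, side="left"))
    idx = min(idx, len(grid) - 1)
    c_hi = cdf[idx]
    c_lo = cdf[idx - 1] if idx > 0 else 0.0
    # each grid point carries the mass of the cell centred on it
    if c_hi <= c_lo:
        age = grid[idx]
    else:
        frac = (target - c_lo) / (c_hi - c_lo)
        age = (grid[idx] - 0.5 * h) + frac * h
    return int(round(age))


def summarize_control(d: CalibratedDensity, ref: GeochronDate) -> ChronControl:
    """Summarize a calibrated density as a chron control row.

    Median plus 5% and 95% from-old quantiles (older and younger limits).
    """
    control_type = (
        "Radiocarbon, calibrated" if ref.kind == "radiocarbon" else "Calendar date"
    )
    return ChronControl(
        geochron_ref=ref,
        age=density_quantile(d, 0.5),
        agelimitolder=density_quantile(d, 0.05),
        agelimityounger=density_quantile(d, 0.95),
        control_type=control_type,
    )
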