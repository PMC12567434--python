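"""Standard-uncertainty evaluators for every component of the assay budget.

Type A statistics (standard deviation of the mean), Type B distribution
conversions (rectangular / triangular half-widths), volumetric glassware
(calibration tolerance + temperature expansion), calibration-curve inverse
prediction, pooled repeatability, and system-suitability summaries.  Raw-data
surfaces are plain CSV read with pandas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError

__all__ = [
    "TypeA",
    "type_a_uncertainty",
    "rectangular_u",
    "triangular_u",
    "temperature_volume_effect",
    "VolumeItem",
    "volume_item",
    "combine_volume",
    "dilution_relative_u",
    "CalibrationRegression",
    "fit_calibration",
    "prediction_u",
    "RepeatabilityStudy",
    "pooled_repeatability",
    "ChannelStats",
    "SstSummary",
    "sst_statistics",
    "read_calibration_csv",
    "read_repeatability_csv",
    "read_sst_csv",
]

SQRT3 = math.sqrt(3.0)
SQRT6 = math.sqrt(6.0)

#: volume expansion coefficient of water, per deg C
WATER_ALPHA = 2.1e-4


class TypeA(NamedTuple):
    """Standard uncertainty of a mean with its degrees of freedom."""

    u: float
    dof: int


def type_a_uncertainty(
    observations: Sequence[float] | None = None,
    *,
    sd: float | None = None,
    m: int | None = None,
) -> TypeA:
    """Type A standard uncertainty: the standard deviation of the mean.

    Either pass raw ``observations`` or a precomputed sample ``sd`` with the
    number of measurements ``m``.  Returns ``s/sqrt(m)`` with ``dof = m - 1``.
    """
    if observations is not None:
        obs = np.asarray(observations, dtype=float)
        if obs.ndim != 1 or obs.size < 2:
            raise InsufficientDataError("need at least 2 observations")
        m = int(obs.size)
        sd = float(np.std(obs, ddof=1))
    if sd is None or m is None:
        raise InsufficientDataError("need observations, or sd together with m")
    if m < 2:
        raise InsufficientDataError(f"need m >= 2 measurements, got {m}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return TypeA(u=sd / math.sqrt(m), dof=m - 1)


def rectangular_u(half_width: float) -> float:
    """Standard uncertainty of a rectangular distribution: half-width / sqrt(3)."""
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    return half_width / SQRT3


def triangular_u(half_width: float) -> float:
    """Standard uncertainty of a symmetric triangular distribution: half-width / sqrt(6)."""
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    return half_width / SQRT6


def temperature_volume_effect(
    volume: float, delta_t: float, alpha: float = WATER_ALPHA
) -> tuple[float, float]:
    """Volume half-width and standard uncertainty from a temperature excursion.

    The working temperature may differ from the glassware calibration
    temperature by up to ``delta_t`` degrees; the liquid expands by ``alpha``
    per degree, so the half-width is ``V * delta_t * alpha`` and the
    distribution over the excursion is rectangular.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if delta_t < 0:
        raise ValueError("delta_t must be non-negative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    hw = volume * delta_t * alpha
    return hw, rectangular_u(hw)


@dataclass(frozen=True)
class VolumeItem:
    """One piece of volumetric glassware with its uncertainty components (mL)."""

    nominal: float
    u_cal: float
    u_temp: float
    cal_half_width: float | None = None
    temp_half_width: float | None = None

    @property
    def u_combined(self) -> float:
        return math.hypot(self.u_cal, self.u_temp)

    @property
    def relative(self) -> float:
        return self.u_combined / self.nominal


def volume_item(
    nominal: float,
    cal_half_width: float,
    delta_t: float = 4.0,
    alpha: float = WATER_ALPHA,
) -> VolumeItem:
    """Build a :class:`VolumeItem` from manufacturer tolerance and temperature range.

    Calibration tolerance is treated as triangular (values near the mark are
    most probable); the temperature effect as rectangular.
    """
    if nominal <= 0:
        raise ValueError("nominal volume must be positive")
    temp_hw, u_temp = temperature_volume_effect(nominal, delta_t, alpha)
    return VolumeItem(
        nominal=nominal,
        u_cal=triangular_u(cal_half_width),
        u_temp=u_temp,
        cal_half_width=cal_half_width,
        temp_half_width=temp_hw,
    )


def combine_volume(item: VolumeItem) -> tuple[float, float]:
    """Quadrature-combined volume uncertainty and its relative value."""
    return item.u_combined, item.relative


def dilution_relative_u(items: Iterable[VolumeItem | float]) -> float:
    """Relative uncertainty of a dilution chain: quadrature of item relatives."""
    rels = [it.relative if isinstance(it, VolumeItem) else float(it) for it in items]
    if not rels:
        raise ValueError("need at least one volume item")
    return math.sqrt(sum(r * r for r in rels))


# ---------------------------------------------------------------------------
# calibration curve


@dataclass(frozen=True)
class CalibrationRegression:
    """Ordinary least-squares line fitted to (concentration, response) points.

    ``sres`` is the residual standard deviation sqrt(SS_res/(n-2)); ``ssdx``
    the sum of squared concentration deviations around ``c_bar``.
    """

    slope: float
    intercept: float
    sres: float
    n: int
    c_bar: float
    ssdx: float
    levels: tuple[float, ...]
    replicates: tuple[int, ...]


def fit_calibration(
    concentrations: Sequence[float], responses: Sequence[float] | None = None
) -> CalibrationRegression:
    """Fit the calibration line response = a0 + a1*concentration by OLS.

    Accepts two parallel sequences, or a single (n, 2) array / DataFrame with
    columns (concentration, response).
    """
    if responses is None:
        arr = np.asarray(concentrations, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (concentration, response)")
        c, y = arr[:, 0], arr[:, 1]
    else:
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(responses, dtype=float)
    if c.size != y.size:
        raise ValueError("concentration and response lengths differ")
    n = int(c.size)
    if n < 3:
        raise InsufficientDataError("need at least 3 calibration points")
    if np.unique(c).size < 2:
        raise ValueError("singular design: all concentrations identical")
    c_bar = float(np.mean(c))
    ssdx = float(np.sum((c - c_bar) ** 2))
    # normal equations for the straight line
    slope = float(np.sum((c - c_bar) * (y - np.mean(y))) / ssdx)
    intercept = float(np.mean(y) - slope * c_bar)
    resid = y - (intercept + slope * c)
    sres = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    levels, counts = np.unique(c, return_counts=True)
    return CalibrationRegression(
        slope=slope,
        intercept=intercept,
        sres=sres,
        n=n,
        c_bar=c_bar,
        ssdx=ssdx,
        levels=tuple(float(v) for v in levels),
        replicates=tuple(int(k) for k in counts),
    )


def prediction_u(reg: CalibrationRegression, p: int, cx: float) -> float:
    """Standard uncertainty of a concentration predicted from the calibration line.

    For the mean of ``p`` replicate responses inverted through the line:

        u(Cx) = (Sres/a1) * sqrt(1/p + 1/n + (Cx - C_bar)^2 / SSDx)
    """
    if p < 1:
        raise ValueError("replicate count p must be >= 1")
    if reg.slope == 0:
        raise ValueError("calibration slope is zero")
    return (reg.sres / abs(reg.slope)) * math.sqrt(
        1.0 / p + 1.0 / reg.n + (cx - reg.c_bar) ** 2 / reg.ssdx
    )


# ---------------------------------------------------------------------------
# repeatability


@dataclass(frozen=True)
class RepeatabilityStudy:
    """Pooled within-run repeatability of the complete procedure.

    ``sr`` is the pooled within-run standard deviation, ``sr_mean`` the
    standard uncertainty of repeatability ``Sr/sqrt(n_total)``.
    """

    data: tuple[tuple[float, ...], ...]
    sr: float
    n_total: int
    sr_mean: float
    dof: int


def pooled_repeatability(
    matrix, divisor: str = "total"
) -> RepeatabilityStudy:
    """Pool within-run standard deviations across runs (rows = runs).

    ``divisor="total"`` (default) divides Sr by sqrt(total measurement count);
    ``divisor="per_run"`` divides by sqrt(replicates per run) instead, for the
    uncertainty of a single future run mean.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise InsufficientDataError("expected a runs x replicates matrix")
    runs, reps = arr.shape
    if runs < 2 or reps < 2:
        raise InsufficientDataError(
            f"need >= 2 runs of >= 2 replicates, got {runs} x {reps}"
        )
    if divisor not in ("total", "per_run"):
        raise ValueError("divisor must be 'total' or 'per_run'")
    run_vars = np.var(arr, axis=1, ddof=1)
    dof = runs * (reps - 1)
    sr = float(np.sqrt(np.sum((reps - 1) * run_vars) / dof))
    n_total = runs * reps
    denom = n_total if divisor == "total" else reps
    return RepeatabilityStudy(
        data=tuple(tuple(float(v) for v in row) for row in arr),
        sr=sr,
        n_total=n_total,
        sr_mean=sr / math.sqrt(denom),
        dof=n_total - runs,
    )


# ---------------------------------------------------------------------------
# system suitability


@dataclass(frozen=True)
class ChannelStats:
    """Replicate-injection statistics for one chromatographic channel."""

    name: str
    n: int
    mean: float
    sd: float
    cv_pct: float
    sd_of_mean: float
    cv_limit_pct: float
    passed: bool


@dataclass(frozen=True)
class SstSummary:
    retention: ChannelStats
    area: ChannelStats

    @property
    def passed(self) -> bool:
        return self.retention.passed and self.area.passed


def _channel(name: str, values, limit: float) -> ChannelStats:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"{name}: need at least 2 injections")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    cv = 100.0 * sd / mean
    return ChannelStats(
        name=name,
        n=int(v.size),
        mean=mean,
        sd=sd,
        cv_pct=cv,
        sd_of_mean=sd / math.sqrt(v.size),
        cv_limit_pct=limit,
        passed=cv < limit,
    )


def sst_statistics(
    retention_times: Sequence[float],
    areas: Sequence[float],
    retention_cv_limit: float = 1.0,
    area_cv_limit: float = 2.0,
) -> SstSummary:
    """System-suitability summary: mean, sd, CV%, sd of the mean per channel.

    Flags each channel against the acceptance criteria (CV of peak areas
    < 2.0%, CV of retention times < 1.0% by default).
    """
    return SstSummary(
        retention=_channel("retention_time", retention_times, retention_cv_limit),
        area=_channel("area", areas, area_cv_limit),
    )


# ---------------------------------------------------------------------------
# CSV readers (header row required; decimal point; UTF-8)


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    """Read calibration points: columns ``concentration``, ``response``."""
    return _read_csv(path, ("concentration", "response"))


def read_repeatability_csv(path: str | Path) -> np.ndarray:
    """Read a repeatability study (columns ``run``, ``replicate``, ``value``)
    and pivot it into a runs x replicates matrix."""
    df = _read_csv(path, ("run", "replicate", "value"))
    wide = df.pivot(index="run", columns="replicate", values="value")
    if wide.isna().any().any():
        raise SchemaError(f"{path}: ragged or duplicated run/replicate entries")
    return wide.to_numpy(dtype=float)


def read_sst_csv(path: str | Path) -> pd.DataFrame:
    """Read a system-suitability series: columns ``injection``,
    ``retention_time``, ``area``."""
    return _read_csv(path, ("injection", "retention_time", "area"))
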