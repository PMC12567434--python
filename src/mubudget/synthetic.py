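"""Synthetic raw-data generation matching the study designs the budget assumes.

Emulates, at the summary level the analysis consumes (no chromatogram or
peak-shape simulation):

* a 5-level x 3-replicate linear calibration over 0.12–0.28 mg/mL (60–140% of
  the 0.2 mg/mL working level) with homoscedastic normal residuals,
* a 3-run x 6-replicate repeatability study of content determinations,
* a 6-injection system-suitability series (retention time and peak area).

Defaults mirror the observable summaries of the packaged assay budget: the
calibration design gives SSDx = 0.048 (mg/mL)^2; the default slope puts the
response at the working level near 70.5 area units with residual sd chosen so
Sres/a1 is about 8.1e-4 (the slope itself is arbitrary — the prediction
uncertainty depends only on that ratio); repeatability is generated at a
relative within-run sd of about 5e-4 on a ~99.7% content scale.

All generators are deterministic per seed and write the same CSV dialects the
evaluators read.  :func:`recovery_u_cx` is the parameter-recovery oracle for
the calibration prediction-uncertainty formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .evaluators import CalibrationRegression, fit_calibration, prediction_u

__all__ = [
    "SyntheticDesign",
    "gen_calibration",
    "gen_repeatability",
    "gen_sst",
    "recovery_u_cx",
    "RecoveryResult",
    "write_study",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """True parameters of the simulated assay study."""

    levels: tuple[float, ...] = (0.12, 0.16, 0.20, 0.24, 0.28)  # mg/mL
    replicates: int = 3
    slope: float = 352.5          # response per mg/mL
    intercept: float = 0.0
    residual_sd: float = 0.287    # response units; slope ratio ~8.1e-4 mg/mL

    repeat_runs: int = 3
    repeat_replicates: int = 6
    repeat_mean: float = 99.7     # content %
    repeat_within_sd: float = 0.05

    sst_n: int = 6
    retention_mean: float = 3.808     # minutes
    retention_sd: float = 0.003807
    area_mean: float = 70.509
    area_sd: float = 0.001568

    def __post_init__(self) -> None:
        if len(self.levels) < 2 or self.replicates < 1:
            raise ValueError("need >= 2 levels and >= 1 replicate")
        for name in ("residual_sd", "repeat_within_sd", "retention_sd", "area_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def concentrations(self) -> np.ndarray:
        """All calibration concentrations, replicates expanded."""
        return np.repeat(np.asarray(self.levels, dtype=float), self.replicates)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_calibration(
    design: SyntheticDesign, rng: int | np.random.Generator | None = 0
) -> pd.DataFrame:
    """Simulate calibration points: response = a0 + a1*c + N(0, sigma)."""
    rng = _rng(rng)
    c = design.concentrations
    y = design.intercept + design.slope * c + rng.normal(0.0, design.residual_sd, c.size)
    return pd.DataFrame({"concentration": c, "response": y})


def gen_repeatability(
    design: SyntheticDesign, rng: int | np.random.Generator | None = 0
) -> pd.DataFrame:
    """Simulate a runs x replicates repeatability study in long CSV form."""
    rng = _rng(rng)
    rows = []
    for run in range(1, design.repeat_runs + 1):
        vals = rng.normal(
            design.repeat_mean, design.repeat_within_sd, design.repeat_replicates
        )
        for rep, v in enumerate(vals, start=1):
            rows.append({"run": run, "replicate": rep, "value": v})
    return pd.DataFrame(rows)


def gen_sst(
    design: SyntheticDesign, rng: int | np.random.Generator | None = 0
) -> pd.DataFrame:
    """Simulate a replicate-injection system-suitability series."""
    rng = _rng(rng)
    n = design.sst_n
    return pd.DataFrame(
        {
            "injection": np.arange(1, n + 1),
            "retention_time": rng.normal(design.retention_mean, design.retention_sd, n),
            "area": rng.normal(design.area_mean, design.area_sd, n),
        }
    )


class RecoveryResult(NamedTuple):
    """Empirical vs formula prediction uncertainty from repeated simulation."""

    empirical_sd: float
    formula_u: float
    ratio: float
    repetitions: int


def recovery_u_cx(
    design: SyntheticDesign,
    p: int = 6,
    cx_true: float = 0.2,
    repetitions: int = 2000,
    rng: int | np.random.Generator | None = 0,
) -> RecoveryResult:
    """Parameter-recovery check of the calibration prediction uncertainty.

    Repeatedly simulates a fresh calibration set, fits the line, simulates the
    mean of ``p`` replicate responses at the true concentration and inverts it
    through the fitted line.  The empirical sd of the predicted concentrations
    is compared with the formula value evaluated at the true parameters.
    """
    if repetitions < 1000:
        raise InsufficientDataError("need >= 1000 repetitions for a stable sd")
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = _rng(rng)
    c = design.concentrations
    n = c.size
    true_at = design.intercept + design.slope * cx_true
    # vectorized over repetitions: closed-form OLS per simulated data set
    y = (
        design.intercept
        + design.slope * c
        + rng.normal(0.0, design.residual_sd, (repetitions, n))
    )
    c_bar = c.mean()
    ssdx = np.sum((c - c_bar) ** 2)
    slope = (y - y.mean(axis=1, keepdims=True)) @ (c - c_bar) / ssdx
    intercept = y.mean(axis=1) - slope * c_bar
    at_mean = true_at + rng.normal(
        0.0, design.residual_sd / np.sqrt(p), repetitions
    )
    cx_hat = (at_mean - intercept) / slope
    empirical = float(np.std(cx_hat, ddof=1))
    truth = CalibrationRegression(
        slope=design.slope,
        intercept=design.intercept,
        sres=design.residual_sd,
        n=n,
        c_bar=float(c_bar),
        ssdx=float(ssdx),
        levels=design.levels,
        replicates=(design.replicates,) * len(design.levels),
    )
    formula = prediction_u(truth, p, cx_true)
    return RecoveryResult(
        empirical_sd=empirical,
        formula_u=formula,
        ratio=empirical / formula if formula > 0 else float("nan"),
        repetitions=repetitions,
    )


def write_study(
    directory: str | Path,
    design: SyntheticDesign | None = None,
    seed: int | None = 0,
) -> dict[str, Path]:
    """Materialize a complete synthetic study directory of CSV files.

    Returns the paths of the calibration, repeatability and SST files; the
    files round-trip through the evaluators' readers.
    """
    design = design or SyntheticDesign()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    paths = {
        "calibration": directory / "calibration.csv",
        "repeatability": directory / "repeatability.csv",
        "sst": directory / "sst.csv",
    }
    gen_calibration(design, rng).to_csv(paths["calibration"], index=False)
    gen_repeatability(design, rng).to_csv(paths["repeatability"], index=False)
    gen_sst(design, rng).to_csv(paths["sst"], index=False)
    return paths
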