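"""Monte Carlo propagation of the assigned probability distributions.

Every input quantity is sampled independently from its assigned distribution
components and the content model is evaluated per trial; the output sample is
summarized by its moments and an equal-tailed coverage interval.  Triangular
variates are generated as ``a + (b-a)/2 * (U1 + U2)`` with independent
standard uniforms — the sum-of-two-uniforms construction.

A quantity may carry several independent components (e.g. a volume's
calibration tolerance and its temperature effect).  Each trial value is the
nominal value times ``1 + sum_k (draw_k - center_k)/center_k``: components
enter as deviations around their shared center, and distributions stated on a
different physical scale than the model factor (the calibration-prediction
factor ``Cx``, normal around 0.2 mg/mL while the factor is unit-valued)
reduce to the correct multiplicative perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .budget_model import Budget, DistributionSpec
from .errors import SchemaError

__all__ = [
    "McsResult",
    "sample",
    "run_mcs",
    "summarize",
    "mcs_budget",
    "convergence_study",
]

#: minimum sample size for which coverage-interval estimates are reported
MIN_INTERVAL_SAMPLES = 1000


@dataclass(frozen=True)
class McsResult:
    """Summary of a Monte Carlo output sample.

    Interval fields are ``None`` when the sample was too small for stable
    percentile estimates (< 1000 trials).  ``k_emp`` is the empirical coverage
    factor: half-width of the coverage interval over the sample sd.
    """

    m: int
    mean: float
    median: float
    sd: float
    skewness: float
    coverage: float = 0.95
    y_low: float | None = None
    y_high: float | None = None
    expanded_u: float | None = None
    k_emp: float | None = None
    seed: int | None = None

    @property
    def interval(self) -> tuple[float, float] | None:
        if self.y_low is None or self.y_high is None:
            return None
        return (self.y_low, self.y_high)


def sample(dist: DistributionSpec, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``m`` variates from one distribution component."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if dist.family == "normal":
        return rng.normal(dist.mean, dist.sd, size=m)
    a, b = float(dist.a), float(dist.b)  # type: ignore[arg-type]
    if dist.family == "rectangular":
        return rng.uniform(a, b, size=m)
    if dist.family == "triangular":
        return a + 0.5 * (b - a) * (rng.random(m) + rng.random(m))
    raise SchemaError(f"unknown distribution family {dist.family!r}")


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def run_mcs(
    budget: Budget, m: int, seed: int | np.random.Generator | None = 0
) -> np.ndarray:
    """Propagate the budget's distributions through the model; return content draws.

    Symbols without a distribution assignment stay fixed at their nominal
    value.  Deterministic for a fixed integer seed: symbols are traversed in
    model order and components in sorted name order.
    """
    rng = _rng(seed)
    values: dict[str, np.ndarray | float] = {}
    for sym in budget.model.symbols:
        if sym not in budget.quantities:
            raise SchemaError(f"model symbol {sym!r} has neither value nor distribution")
        q = budget.quantities[sym]
        comps = budget.distributions.get(sym)
        if not comps:
            values[sym] = q.value
            continue
        factor = np.zeros(m)
        for name in sorted(comps):
            d = comps[name]
            c = d.center
            factor += (sample(d, m, rng) - c) / c
        values[sym] = q.value * (1.0 + factor)
    return np.asarray(budget.model.evaluate(values), dtype=float)


def summarize(
    samples: np.ndarray,
    coverage: float = 0.95,
    shortest: bool = False,
    seed: int | None = None,
) -> McsResult:
    """Moments plus a coverage interval of a Monte Carlo output sample.

    The interval is equal-tailed percentile by default; ``shortest=True``
    selects the minimum-width interval with the requested coverage instead.
    Intervals are refused (None) below 1000 samples.
    """
    y = np.asarray(samples, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("empty sample")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    mean = float(np.mean(y))
    median = float(np.median(y))
    sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    # near-constant samples: skewness is 0 by symmetry, and the third-moment
    # computation would only produce cancellation noise
    degenerate = sd <= 1e-14 * max(abs(mean), 1.0)
    skewness = float(stats.skew(y)) if y.size > 2 and not degenerate else 0.0
    base = dict(
        m=int(y.size), mean=mean, median=median, sd=sd,
        skewness=skewness, coverage=coverage, seed=seed,
    )
    if y.size < MIN_INTERVAL_SAMPLES:
        return McsResult(**base)
    if shortest:
        ys = np.sort(y)
        w = int(math.ceil(coverage * y.size))
        widths = ys[w - 1 :] - ys[: y.size - w + 1]
        i = int(np.argmin(widths))
        y_low, y_high = float(ys[i]), float(ys[i + w - 1])
    else:
        alpha = 0.5 * (1.0 - coverage)
        y_low, y_high = (float(v) for v in np.quantile(y, [alpha, 1.0 - alpha]))
    half = 0.5 * (y_high - y_low)
    return McsResult(
        **base,
        y_low=y_low,
        y_high=y_high,
        expanded_u=half,
        k_emp=half / sd if sd > 0 else math.inf,
    )


def mcs_budget(
    budget: Budget,
    m: int = 1_000_000,
    seed: int | None = 0,
    coverage: float = 0.95,
    shortest: bool = False,
) -> McsResult:
    """Run the Monte Carlo stage end to end on a loaded budget."""
    samples = run_mcs(budget, m, seed)
    return summarize(samples, coverage=coverage, shortest=shortest, seed=seed)


def convergence_study(
    budget: Budget,
    m_list: list[int],
    seed: int | None = 0,
    coverage: float = 0.95,
    width_tol: float = 0.01,
) -> pd.DataFrame:
    """Coverage-interval width as a function of the trial count.

    Runs an independent simulation per trial count (sub-streams spawned from
    one seed, so the study is deterministic) and tabulates the interval width,
    its absolute change versus the previous M (in the measurand's units, the
    scale on which stabilization is declared) and the relative change.
    ``stable`` flags absolute changes below ``width_tol``.
    """
    if any(b <= a for a, b in zip(m_list, m_list[1:])):
        raise ValueError("m_list must be strictly ascending")
    streams = np.random.SeedSequence(seed).spawn(len(m_list))
    rows = []
    prev_width = None
    for m, ss in zip(m_list, streams):
        res = summarize(run_mcs(budget, m, np.random.default_rng(ss)), coverage)
        if res.y_low is None:
            raise ValueError(f"M = {m} too small for interval estimates")
        width = res.y_high - res.y_low  # type: ignore[operator]
        if prev_width is None:
            abs_change = rel_change = math.nan
            stable = pd.NA
        else:
            abs_change = abs(width - prev_width)
            if prev_width > 0:
                rel_change = abs_change / prev_width
            else:
                rel_change = 0.0 if abs_change == 0 else math.inf
            stable = abs_change < width_tol
        rows.append(
            {
                "m": m,
                "width": width,
                "abs_change": abs_change,
                "rel_change": rel_change,
                "stable": stable,
            }
        )
        prev_width = width
    return pd.DataFrame(rows)
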