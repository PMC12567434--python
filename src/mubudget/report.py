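"""Report tables and text summaries for the budget, MCS and validation stages."""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .budget_model import Budget
from .gum import GumResult
from .mcs import McsResult
from .validation import ValidationResult

__all__ = [
    "budget_table",
    "gum_text_summary",
    "mcs_table",
    "mcs_text_summary",
    "validation_table",
    "validation_text_summary",
    "histogram_table",
    "RunManifest",
]


def budget_table(budget: Budget, result: GumResult) -> pd.DataFrame:
    """Budget sheet: symbol, value, u, u_rel, variance share, cumulative share."""
    rows = []
    for sym in budget.model.symbols:
        q = budget.quantities[sym]
        rows.append(
            {
                "symbol": sym,
                "value": q.value,
                "unit": q.unit,
                "u": q.standard_uncertainty,
                "u_rel": q.relative_uncertainty,
                "share": result.shares.get(sym, 0.0),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "share", ascending=False, kind="stable", ignore_index=True
    )
    df["cumulative_share"] = df["share"].cumsum()
    return df


def gum_text_summary(result: GumResult, label: str = "C") -> str:
    """One-block summary, e.g. ``C = (99.41 ± 0.69)% (k = 2)``."""
    lines = [
        f"{label} = ({result.content:.2f} ± {result.expanded_u:.2f})% "
        f"(k = {result.k:g})",
        f"combined standard uncertainty u({label}) = {result.u_c:.4f}%",
        f"relative combined uncertainty     = {result.u_rel:.6f}",
    ]
    if result.nu_eff is not None and math.isfinite(result.nu_eff):
        lines.append(f"effective degrees of freedom      = {result.nu_eff:.1f}")
    return "\n".join(lines)


def mcs_table(result: McsResult) -> pd.DataFrame:
    """Monte Carlo summary in two-column (parameter, value) form."""
    rows = [
        ("Trials M", result.m),
        ("Mean (content %)", result.mean),
        ("Median (%)", result.median),
        ("Standard uncertainty %", result.sd),
        ("Skewness", result.skewness),
    ]
    if result.interval is not None:
        rows += [
            ("Expanded uncertainty", result.expanded_u),
            ("Coverage factor k", result.k_emp),
            (
                f"Coverage interval {100 * result.coverage:g}%",
                f"[{result.y_low:.4f}; {result.y_high:.4f}]",
            ),
        ]
    return pd.DataFrame(rows, columns=["parameter", "value"])


def mcs_text_summary(result: McsResult) -> str:
    df = mcs_table(result)
    width = max(len(str(p)) for p in df["parameter"])
    lines = []
    for _, row in df.iterrows():
        v = row["value"]
        if isinstance(v, float):
            v = f"{v:.4f}"
        lines.append(f"{row['parameter']:<{width}}  {v}")
    if result.interval is None:
        lines.append("(coverage interval refused: fewer than 1000 trials)")
    return "\n".join(lines)


def validation_table(vr: ValidationResult) -> pd.DataFrame:
    """Interval-comparison sheet with both endpoint differences and the verdict."""
    return pd.DataFrame(
        [
            {
                "bound": "low",
                "gum": vr.gum_low,
                "mcs": vr.mcs_low,
                "d": vr.d_low,
                "delta": vr.delta,
                "within": vr.d_low < vr.delta,
            },
            {
                "bound": "high",
                "gum": vr.gum_high,
                "mcs": vr.mcs_high,
                "d": vr.d_high,
                "delta": vr.delta,
                "within": vr.d_high < vr.delta,
            },
        ]
    )


def validation_text_summary(vr: ValidationResult) -> str:
    mantissa = (
        f" (u = {vr.c}e{vr.l})" if vr.c is not None and vr.l is not None else ""
    )
    verdict = "validated" if vr.validated else "not validated"
    return "\n".join(
        [
            f"tolerance delta = {vr.delta:g}{mantissa}",
            f"GUM interval [{vr.gum_low:.4f}, {vr.gum_high:.4f}]",
            f"MCS interval [{vr.mcs_low:.4f}, {vr.mcs_high:.4f}]",
            f"d_low = {vr.d_low:.4f}, d_high = {vr.d_high:.4f}",
            f"verdict: {verdict}",
        ]
    )


def histogram_table(samples: np.ndarray, bins: int = 100) -> pd.DataFrame:
    """Binned output sample for CSV export: bin_left, bin_right, count."""
    counts, edges = np.histogram(np.asarray(samples, dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


@dataclass
class RunManifest:
    """Provenance record written next to every multi-stage report."""

    config: str
    seed: int | None
    trials: int | None
    coverage: float
    tool_version: str
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat(
            timespec="seconds"
        )
    )
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2), "utf-8")
        return path
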