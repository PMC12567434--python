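"""Numerical-tolerance validation of the GUM interval against the MCS interval.

Following GUM Supplement 1: write the combined standard uncertainty as
``u = c * 10^l`` with ``c`` an integer of one or two significant digits, take
the tolerance ``delta = 0.5 * 10^l``, and declare the GUM result validated
when both absolute endpoint differences between the GUM expanded interval
``[y - U, y + U]`` and the Monte Carlo coverage interval are below delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .gum import GumResult
from .mcs import McsResult

__all__ = ["ValidationResult", "tolerance", "validate", "validate_gum_mcs"]


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of the GUM-vs-MCS interval comparison."""

    delta: float
    gum_low: float
    gum_high: float
    mcs_low: float
    mcs_high: float
    d_low: float
    d_high: float
    validated: bool
    c: int | None = None
    l: int | None = None


def tolerance(u: float, significant_digits: int = 1) -> tuple[float, int, int]:
    """Validation tolerance from the standard uncertainty.

    Expresses ``u = c * 10^l`` with ``c`` an integer of the requested digit
    count (round half away from zero) and returns ``(delta, c, l)`` with
    ``delta = 0.5 * 10^l``.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    if significant_digits not in (1, 2):
        raise ValueError("significant_digits must be 1 or 2")
    l = math.floor(math.log10(u)) - significant_digits + 1
    # decimal arithmetic so printed half-way mantissas (e.g. 0.95) round
    # half away from zero instead of falling to binary representation noise
    c = int(
        Decimal(repr(u)).scaleb(-l).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    )
    if c >= 10**significant_digits:  # rounding carried into the next decade
        c //= 10
        l += 1
    return 0.5 * 10.0**l, c, l


def validate(
    y: float,
    expanded_u: float,
    mcs_low: float,
    mcs_high: float,
    delta: float,
    c: int | None = None,
    l: int | None = None,
) -> ValidationResult:
    """Compare the GUM interval [y - U, y + U] with an MCS coverage interval."""
    if expanded_u < 0:
        raise ValueError("expanded uncertainty must be non-negative")
    if mcs_low > mcs_high:
        raise ValueError("mcs interval must be ordered")
    gum_low, gum_high = y - expanded_u, y + expanded_u
    d_low = abs(gum_low - mcs_low)
    d_high = abs(gum_high - mcs_high)
    return ValidationResult(
        delta=delta,
        gum_low=gum_low,
        gum_high=gum_high,
        mcs_low=mcs_low,
        mcs_high=mcs_high,
        d_low=d_low,
        d_high=d_high,
        validated=bool(d_low < delta and d_high < delta),
        c=c,
        l=l,
    )


def validate_gum_mcs(
    gum: GumResult, mcs: McsResult, significant_digits: int = 1
) -> ValidationResult:
    """Validate a GUM stage result against an MCS stage result.

    The tolerance is derived from the GUM combined standard uncertainty with
    the requested mantissa digit count.
    """
    if mcs.y_low is None or mcs.y_high is None:
        raise ValueError("MCS result carries no coverage interval")
    delta, c, l = tolerance(gum.u_c, significant_digits)
    return validate(
        gum.content, gum.expanded_u, mcs.y_low, mcs.y_high, delta, c=c, l=l
    )
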