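"""Bottom-up (GUM) propagation of the uncertainty budget.

For a pure product/quotient model the law of propagation reduces to the
quadrature of relative uncertainties,

    u(C)/C = sqrt( sum_i (u(x_i)/x_i)^2 ),

which :func:`combine_relative` implements directly.  A general
finite-difference sensitivity path (:func:`propagate_numeric`) is kept as an
internal numerical oracle: on product models the two agree to first order
exactly.  Expanded uncertainty uses a fixed coverage factor k = 2 by default
(about 95% under normality); a Welch–Satterthwaite effective-dof coverage
factor is available as an opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .budget_model import Budget, InputQuantity, MeasurementModel

__all__ = [
    "GumResult",
    "combine_relative",
    "expanded",
    "welch_satterthwaite",
    "contributions",
    "propagate_numeric",
    "gum_budget",
]

#: two-sided 95% normal quantile, the infinite-dof coverage factor
K_NORMAL_95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class GumResult:
    """Combined GUM result for the content and its uncertainty budget."""

    content: float
    u_rel: float
    u_c: float
    k: float
    expanded_u: float
    interval: tuple[float, float]
    shares: dict[str, float]
    nu_eff: float | None = None

    @property
    def low(self) -> float:
        return self.interval[0]

    @property
    def high(self) -> float:
        return self.interval[1]


def _as_quantities(
    quantities: Mapping[str, InputQuantity] | Iterable[InputQuantity],
) -> list[InputQuantity]:
    qs = list(quantities.values()) if isinstance(quantities, Mapping) else list(quantities)
    if not qs:
        raise ValueError("empty uncertainty budget")
    for q in qs:
        r = q.relative_uncertainty
        if r is None or not math.isfinite(r):
            raise ValueError(f"quantity {q.symbol!r} has no finite relative uncertainty")
    return qs


def combine_relative(
    quantities: Mapping[str, InputQuantity] | Iterable[InputQuantity],
    content: float,
    k: float = 2.0,
    use_welch_satterthwaite: bool = False,
) -> GumResult:
    """Combine relative standard uncertainties in quadrature and expand.

    ``content`` is the value of the measurand the relative uncertainty is
    scaled by.  With ``use_welch_satterthwaite=True`` the coverage factor is
    the 95% two-tailed Student t at the effective degrees of freedom instead
    of the supplied ``k``.
    """
    qs = _as_quantities(quantities)
    rel2 = {q.symbol: q.relative_uncertainty**2 for q in qs}
    total = sum(rel2.values())
    u_rel = math.sqrt(total)
    shares = (
        {s: v / total for s, v in rel2.items()}
        if total > 0
        else {s: 0.0 for s in rel2}
    )
    nu_eff = None
    if use_welch_satterthwaite:
        nu_eff, k = welch_satterthwaite(
            [(q.relative_uncertainty, q.dof) for q in qs]
        )
    u_c = u_rel * content
    big_u = expanded(u_c, k)
    return GumResult(
        content=content,
        u_rel=u_rel,
        u_c=u_c,
        k=k,
        expanded_u=big_u,
        interval=(content - big_u, content + big_u),
        shares=shares,
        nu_eff=nu_eff,
    )


def expanded(u_c: float, k: float = 2.0) -> float:
    """Expanded uncertainty U = k * u(C)."""
    if u_c < 0:
        raise ValueError("u_c must be non-negative")
    if k <= 0:
        raise ValueError("coverage factor k must be positive")
    return k * u_c


def welch_satterthwaite(
    components: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Effective degrees of freedom and the matching 95% coverage factor.

    ``components`` are ``(u_i, nu_i)`` pairs of uncertainty contributions and
    their degrees of freedom (``math.inf`` allowed; infinite-dof components
    drop out of the denominator):

        nu_eff = u^4 / sum_i u_i^4 / nu_i

    ``nu_eff`` is truncated down to an integer for the t-quantile lookup.
    Returns ``(nu_eff, k)`` with ``k`` the two-tailed 97.5th t-quantile, or
    the normal quantile 1.95996 when every dof is infinite.
    """
    if not components:
        raise ValueError("empty component list")
    u2 = sum(u * u for u, _ in components)
    denom = sum((u**4) / nu for u, nu in components if math.isfinite(nu))
    if denom == 0.0:
        return math.inf, K_NORMAL_95
    nu_eff = (u2 * u2) / denom
    k = float(stats.t.ppf(0.975, math.floor(nu_eff)))
    return nu_eff, k


def contributions(
    quantities: Mapping[str, InputQuantity] | Iterable[InputQuantity],
) -> pd.DataFrame:
    """Variance shares of each budget term, Pareto-ordered with cumulatives.

    Shares are squared relative uncertainties over their sum, so they add to 1.
    """
    qs = _as_quantities(quantities)
    rel = np.array([q.relative_uncertainty for q in qs])
    share = rel**2 / np.sum(rel**2)
    df = pd.DataFrame(
        {
            "symbol": [q.symbol for q in qs],
            "relative_u": rel,
            "share": share,
        }
    ).sort_values("share", ascending=False, kind="stable", ignore_index=True)
    df["cumulative_share"] = df["share"].cumsum()
    return df


def propagate_numeric(
    model: MeasurementModel,
    quantities: Mapping[str, InputQuantity] | Iterable[InputQuantity],
    rel_step: float = 1e-6,
) -> float:
    """Combined standard uncertainty by finite-difference sensitivities.

    Central differences with a relative step around each nominal give the
    sensitivity coefficients c_i = dC/dx_i; then u^2 = sum c_i^2 u(x_i)^2.
    Each quantity's uncertainty enters in the model's own units as
    ``relative_uncertainty * value`` (for relative-effect factors the declared
    standard uncertainty may be stated in physical units instead).

    This is the general propagation-law oracle: on product/quotient models it
    must agree with :func:`combine_relative` to within ~1e-6 relative.
    """
    if isinstance(quantities, Mapping):
        qmap = dict(quantities)
    else:
        qmap = {q.symbol: q for q in quantities}
    values = {s: q.value for s, q in qmap.items()}
    y0 = model.evaluate(values)
    if not np.isfinite(y0):
        raise ValueError("model is not finite at the nominal point")
    var = 0.0
    for sym in model.symbols:
        q = qmap[sym]
        h = rel_step * q.value
        hi = dict(values, **{sym: q.value + h})
        lo = dict(values, **{sym: q.value - h})
        ci = (model.evaluate(hi) - model.evaluate(lo)) / (2.0 * h)
        if not np.isfinite(ci):
            raise ValueError(f"model not finite near the nominal of {sym!r}")
        u_i = q.relative_uncertainty * q.value
        var += (ci * u_i) ** 2
    return math.sqrt(var)


def gum_budget(
    budget: Budget,
    content: float | str | None = None,
    k: float = 2.0,
    use_welch_satterthwaite: bool = False,
) -> GumResult:
    """Run the GUM stage on a loaded budget.

    ``content=None`` (default) evaluates the model at the nominal values;
    ``content="reported"`` uses the budget's recorded published content;
    a float is used as given.
    """
    if content is None:
        c = budget.content()
    elif content == "reported":
        if budget.reported_content is None:
            raise ValueError("budget has no reported content value")
        c = budget.reported_content
    elif isinstance(content, str):
        raise ValueError(f"content must be None, 'reported' or a number, got {content!r}")
    else:
        c = float(content)
    return combine_relative(
        budget.model_quantities(),
        content=c,
        k=k,
        use_welch_satterthwaite=use_welch_satterthwaite,
    )
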