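"""Measurand definition, input-quantity data model and budget configuration I/O.

The measurand is the content ``C`` (in percent of label claim) of a drug in an
injectable solution, expressed as a pure product/quotient of input quantities
times exact scale constants:

    C% = (At/Ast) * (Pt/Vt1) * (Vp/Vt2) * (Vt/VSample) * P * delta_r * Cx * const

where ``At``/``Ast`` are sample and standard peak areas, ``Pt`` the reference
mass, the ``V*`` symbols the volumes of the dilution chain, ``P`` the purity
of the reference substance (stored as the dimensionless fraction, e.g. 0.9999)
and ``delta_r``/``Cx`` unit-valued *relative-effect* factors carrying the
method repeatability and the calibration-prediction uncertainty.  The scalar
constant absorbs the dose ratio (1 mL per 10 mg, i.e. 0.1 mL/mg) and the
percent scaling, so for the nominal dilution design all volume factors cancel
and the model evaluates to ``P * 100``.

A budget configuration is a structured key-value text file (TOML is the
reference dialect, JSON is accepted) with sections

* ``[model]`` — numerator/denominator symbol lists and the scalar constant,
* ``[quantities.<symbol>]`` — nominal value, unit, standard or relative
  uncertainty, degrees of freedom,
* ``[distributions.<symbol>.<component>]`` — the probability distribution(s)
  assigned to each symbol for Monte Carlo propagation (a symbol may carry
  several independent components, e.g. glassware calibration + temperature).

The packaged ``mpz`` fixture is the published uncertainty budget of an
HPLC-UV assay of Metopimazine (an antiemetic) in injectable solution.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import SchemaError

__all__ = [
    "DistributionSpec",
    "InputQuantity",
    "MeasurementModel",
    "Budget",
    "evaluate_content",
    "load_budget",
    "read_budget",
    "dumps_budget",
    "budget_to_dict",
    "check_distributions",
    "mpz_budget",
]

_FAMILIES = ("normal", "rectangular", "triangular")

SQRT3 = math.sqrt(3.0)
SQRT6 = math.sqrt(6.0)


@dataclass(frozen=True)
class DistributionSpec:
    """A probability distribution assigned to one uncertainty component.

    ``normal`` uses ``mean``/``sd``; ``rectangular`` and ``triangular`` use the
    bounds ``a``/``b`` (symmetric triangular on [a, b]).
    """

    family: str
    mean: float | None = None
    sd: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise SchemaError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        if self.family == "normal":
            if self.mean is None or self.sd is None:
                raise SchemaError("normal distribution requires mean and sd")
            if not self.sd > 0:
                raise SchemaError(f"normal distribution requires sd > 0, got {self.sd}")
        else:
            if self.a is None or self.b is None:
                raise SchemaError(f"{self.family} distribution requires bounds a and b")
            if not self.a < self.b:
                raise SchemaError(
                    f"{self.family} distribution requires a < b, got a={self.a}, b={self.b}"
                )

    @property
    def center(self) -> float:
        """Expectation of the distribution (midpoint for bounded families)."""
        if self.family == "normal":
            return float(self.mean)  # type: ignore[arg-type]
        return 0.5 * (float(self.a) + float(self.b))  # type: ignore[arg-type]

    @property
    def half_width(self) -> float | None:
        """(b - a)/2 for bounded families, None for normal."""
        if self.family == "normal":
            return None
        return 0.5 * (float(self.b) - float(self.a))  # type: ignore[arg-type]

    @property
    def implied_sd(self) -> float:
        """Standard deviation implied by the family and its parameters.

        Rectangular: (b-a)/(2*sqrt(3)); triangular: (b-a)/(2*sqrt(6)).
        """
        if self.family == "normal":
            return float(self.sd)  # type: ignore[arg-type]
        hw = self.half_width
        assert hw is not None
        return hw / SQRT3 if self.family == "rectangular" else hw / SQRT6


@dataclass
class InputQuantity:
    """One symbol of the content model with its standard uncertainty.

    ``relative_effect`` marks unit-valued factors (repeatability ``delta_r``,
    calibration prediction ``Cx``) whose relative uncertainty is supplied
    directly rather than derived as standard/value — for ``Cx`` the standard
    uncertainty is stated in concentration units (mg/mL) while the factor
    itself is dimensionless with nominal value 1.
    """

    symbol: str
    value: float
    unit: str = ""
    standard_uncertainty: float | None = None
    relative_uncertainty: float | None = None
    dof: float = math.inf
    relative_effect: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.value, (int, float)) and math.isfinite(self.value)):
            raise SchemaError(f"quantities.{self.symbol}.value: must be finite")
        if not self.value > 0:
            raise SchemaError(
                f"quantities.{self.symbol}.value: must be > 0 for a product model, "
                f"got {self.value}"
            )
        if math.isfinite(self.dof) and self.dof < 1:
            raise SchemaError(f"quantities.{self.symbol}.dof: must be >= 1 when finite")
        su, ru = self.standard_uncertainty, self.relative_uncertainty
        if su is None and ru is None:
            raise SchemaError(
                f"quantities.{self.symbol}: needs standard_uncertainty or "
                "relative_uncertainty"
            )
        if su is not None and su < 0:
            raise SchemaError(f"quantities.{self.symbol}.standard_uncertainty: negative")
        if ru is not None and ru < 0:
            raise SchemaError(f"quantities.{self.symbol}.relative_uncertainty: negative")
        if self.relative_effect:
            if ru is None:
                raise SchemaError(
                    f"quantities.{self.symbol}: relative-effect factors must state "
                    "relative_uncertainty directly"
                )
            return
        if ru is None:
            self.relative_uncertainty = su / self.value  # type: ignore[operator]
        elif su is None:
            self.standard_uncertainty = ru * self.value
        else:
            # consistency cross-check: relative must equal standard/value
            if ru > 0 and abs(ru - su / self.value) > 1e-6 * ru:
                raise SchemaError(
                    f"quantities.{self.symbol}: relative_uncertainty {ru} inconsistent "
                    f"with standard/value = {su / self.value:.8g}"
                )


@dataclass(frozen=True)
class MeasurementModel:
    """Product-form content model: constant * prod(numerator) / prod(denominator)."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()
    constant: float = 1.0

    def __post_init__(self) -> None:
        if not self.numerator and not self.denominator:
            raise SchemaError("model: needs at least one symbol")
        dup = set(self.numerator) & set(self.denominator)
        if dup:
            raise SchemaError(f"model: symbols on both sides: {sorted(dup)}")

    @property
    def symbols(self) -> tuple[str, ...]:
        return self.numerator + self.denominator

    def evaluate(self, values: Mapping[str, float | np.ndarray]):
        """Evaluate the product at the given symbol values (scalars or arrays)."""
        out = self.constant
        for sym in self.numerator:
            out = out * self._get(values, sym)
        for sym in self.denominator:
            d = self._get(values, sym)
            if np.any(np.asarray(d) <= 0):
                raise ValueError(f"denominator symbol {sym!r} is zero or negative")
            out = out / d
        return out

    @staticmethod
    def _get(values: Mapping[str, float | np.ndarray], sym: str):
        try:
            return values[sym]
        except KeyError:
            raise SchemaError(f"model references unknown symbol {sym!r}") from None


@dataclass
class Budget:
    """A complete uncertainty budget: model + quantities + distribution assignments."""

    model: MeasurementModel
    quantities: dict[str, InputQuantity]
    distributions: dict[str, dict[str, DistributionSpec]] = field(default_factory=dict)
    reported_content: float | None = None
    name: str = ""

    def content(self) -> float:
        """Content at the nominal values (pure product, no rounding)."""
        return float(evaluate_content(self.model, self.quantities))

    @property
    def n_distribution_rows(self) -> int:
        return sum(len(c) for c in self.distributions.values())

    def model_quantities(self) -> list[InputQuantity]:
        """Quantities referenced by the model, in model order."""
        missing = [s for s in self.model.symbols if s not in self.quantities]
        if missing:
            raise SchemaError(f"model references unknown symbol(s) {missing}")
        return [self.quantities[s] for s in self.model.symbols]


def evaluate_content(
    model: MeasurementModel,
    quantities: Mapping[str, InputQuantity] | Iterable[InputQuantity],
) -> float:
    """Evaluate the content model with every quantity at its nominal value."""
    if not isinstance(quantities, Mapping):
        quantities = {q.symbol: q for q in quantities}
    values = {s: q.value for s, q in quantities.items()}
    return float(model.evaluate(values))


# ---------------------------------------------------------------------------
# configuration I/O


def _as_float(section: str, key: str, raw: Mapping, required: bool = True):
    if key not in raw:
        if required:
            raise SchemaError(f"{section}: missing required field {key!r}")
        return None
    v = raw[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"{section}.{key}: expected a number, got {v!r}")
    return float(v)


def _budget_from_dict(cfg: Mapping) -> Budget:
    if "model" not in cfg:
        raise SchemaError("model: section missing")
    mraw = cfg["model"]
    model = MeasurementModel(
        numerator=tuple(mraw.get("numerator", ())),
        denominator=tuple(mraw.get("denominator", ())),
        constant=float(mraw.get("constant", 1.0)),
    )

    qraw = cfg.get("quantities", {})
    if not qraw:
        raise SchemaError("quantities: empty quantity list")
    quantities: dict[str, InputQuantity] = {}
    for sym, entry in qraw.items():
        sec = f"quantities.{sym}"
        dof = entry.get("dof", math.inf)
        if isinstance(dof, str):
            if dof not in ("inf", "infinite"):
                raise SchemaError(f"{sec}.dof: expected a number or 'inf', got {dof!r}")
            dof = math.inf
        quantities[sym] = InputQuantity(
            symbol=sym,
            value=_as_float(sec, "value", entry),
            unit=str(entry.get("unit", "")),
            standard_uncertainty=_as_float(sec, "standard_uncertainty", entry, False),
            relative_uncertainty=_as_float(sec, "relative_uncertainty", entry, False),
            dof=float(dof),
            relative_effect=bool(entry.get("relative_effect", False)),
        )

    distributions: dict[str, dict[str, DistributionSpec]] = {}
    for sym, comps in cfg.get("distributions", {}).items():
        if sym not in quantities:
            raise SchemaError(f"distributions.{sym}: no such quantity")
        distributions[sym] = {}
        for comp, entry in comps.items():
            sec = f"distributions.{sym}.{comp}"
            try:
                distributions[sym][comp] = DistributionSpec(
                    family=str(entry.get("family", "")),
                    mean=_as_float(sec, "mean", entry, False),
                    sd=_as_float(sec, "sd", entry, False),
                    a=_as_float(sec, "a", entry, False),
                    b=_as_float(sec, "b", entry, False),
                )
            except SchemaError as exc:
                raise SchemaError(f"{sec}: {exc}") from None

    reported = cfg.get("reported_content")
    return Budget(
        model=model,
        quantities=quantities,
        distributions=distributions,
        reported_content=float(reported) if reported is not None else None,
        name=str(cfg.get("name", "")),
    )


def check_distributions(budget: Budget, tol: float = 0.03) -> None:
    """Cross-check distribution assignments against declared uncertainties.

    For each symbol carrying distributions, the relative standard deviation
    implied by the assigned components (combined in quadrature around their
    centers) must match the declared relative uncertainty within ``tol``
    (default 3%).  Raises :class:`SchemaError` on any mismatch.
    """
    bad = []
    for sym, comps in budget.distributions.items():
        q = budget.quantities[sym]
        declared = q.relative_uncertainty
        if not declared:
            continue
        implied = math.sqrt(
            sum((d.implied_sd / d.center) ** 2 for d in comps.values())
        )
        if abs(implied - declared) > tol * declared:
            bad.append(
                f"distributions.{sym}: implied relative sd {implied:.6g} vs "
                f"declared {declared:.6g}"
            )
    if bad:
        raise SchemaError("; ".join(bad))


def load_budget(text: str, fmt: str = "toml", check: bool = True) -> Budget:
    """Parse a budget configuration from TOML (reference dialect) or JSON text."""
    if fmt == "toml":
        try:
            cfg = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise SchemaError(f"invalid TOML: {exc}") from None
    elif fmt == "json":
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON: {exc}") from None
    else:
        raise SchemaError(f"unknown budget format {fmt!r}")
    budget = _budget_from_dict(cfg)
    if check:
        check_distributions(budget)
    return budget


def read_budget(path: str | Path, check: bool = True) -> Budget:
    """Load a budget configuration file; the format follows the suffix."""
    path = Path(path)
    fmt = "json" if path.suffix.lower() == ".json" else "toml"
    return load_budget(path.read_text(encoding="utf-8"), fmt=fmt, check=check)


def budget_to_dict(budget: Budget) -> dict:
    """Serialize a budget to the plain-dict form of the configuration schema."""
    cfg: dict = {
        "name": budget.name,
        "model": {
            "numerator": list(budget.model.numerator),
            "denominator": list(budget.model.denominator),
            "constant": budget.model.constant,
        },
        "quantities": {},
        "distributions": {},
    }
    if budget.reported_content is not None:
        cfg["reported_content"] = budget.reported_content
    for sym, q in budget.quantities.items():
        entry: dict = {"value": q.value, "unit": q.unit}
        if q.standard_uncertainty is not None:
            entry["standard_uncertainty"] = q.standard_uncertainty
        if q.relative_uncertainty is not None:
            entry["relative_uncertainty"] = q.relative_uncertainty
        if math.isfinite(q.dof):
            entry["dof"] = q.dof
        if q.relative_effect:
            entry["relative_effect"] = True
        cfg["quantities"][sym] = entry
    for sym, comps in budget.distributions.items():
        cfg["distributions"][sym] = {}
        for comp, d in comps.items():
            de: dict = {"family": d.family}
            for k in ("mean", "sd", "a", "b"):
                v = getattr(d, k)
                if v is not None:
                    de[k] = v
            cfg["distributions"][sym][comp] = de
    return cfg


def dumps_budget(budget: Budget) -> str:
    """Serialize a budget as JSON text (round-trips through :func:`load_budget`)."""
    return json.dumps(budget_to_dict(budget), indent=2)


def mpz_budget() -> Budget:
    """Load the packaged Metopimazine HPLC-UV assay budget fixture."""
    text = (
        resources.files("mubudget").joinpath("data/mpz_budget.toml").read_text("utf-8")
    )
    return load_budget(text, fmt="toml")
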