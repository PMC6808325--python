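"""Model parameter containers, validation and (de)serialization.

Every printed model input — the eight annual cost components per modality,
the EQ-5D utility indices, the four annual transition rates, the scenario
initial-mix definitions and the economic settings — lives in a single
:class:`ModelParameters` bundle.  The bundle is loaded from one YAML file
(a default transcription of the published tables ships with the package),
validated against the domain invariants, and can be written back so that
``load(save(x))`` round-trips bit-identically.

Each uncertain input carries a :class:`ParamRange` (mean, low, high); the
sensitivity module interprets the range as a central 95% interval when it
fits gamma/beta sampling distributions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Any, Mapping

import yaml

__all__ = [
    "MODALITIES",
    "COST_COMPONENTS",
    "RATE_KEYS",
    "ConfigurationError",
    "ValidationError",
    "ParamRange",
    "CostProfile",
    "CostTotalCheck",
    "UtilitySet",
    "TransitionRateSet",
    "ScenarioSpec",
    "EconomicSettings",
    "ModelParameters",
    "load_parameters",
    "default_parameters",
    "save_parameters",
    "validate_cost_totals",
]

MODALITIES = ("HD", "CAPD")

#: The eight annual cost components collected per modality (RM/patient/year).
COST_COMPONENTS = (
    "outpatient",
    "access_surgeries",
    "building_land",
    "equipment",
    "staff",
    "overheads",
    "dialysis_consumables",
    "hospitalization",
)

#: Directed transitions carrying an annual event rate (events/patient-year).
RATE_KEYS = ("CAPD_HD", "CAPD_death", "HD_CAPD", "HD_death")

#: Printed totals are rounded to the sen; allow half of the last full RM.
COST_SUM_TOLERANCE = 0.5

#: Short component suffixes used in sensitivity-analysis input labels.
_LABEL_SUFFIX = {
    "outpatient": "outpatient",
    "access_surgeries": "access",
    "building_land": "building_land",
    "equipment": "equipment",
    "staff": "staffing",
    "overheads": "overheads",
    "dialysis_consumables": "consumables",
    "hospitalization": "hosp",
}


class ConfigurationError(Exception):
    """A required key is missing from, or malformed in, a config document."""


class ValidationError(ValueError):
    """A parameter value violates a domain invariant."""


@dataclass(frozen=True)
class ParamRange:
    """A point estimate with its plausible (low, high) range."""

    mean: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValidationError(
                f"mean {self.mean} outside range [{self.low}, {self.high}]"
            )

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class CostProfile:
    """Annual per-patient treatment cost of one modality, by component.

    ``annual_cost`` (the quantity the Markov model accrues per life-year in
    the state) is the *sum of component means*, so that perturbing a single
    component in sensitivity analysis propagates; the printed ``total`` is
    retained as a transcription cross-check (see
    :func:`validate_cost_totals`).
    """

    modality: str
    components: Mapping[str, ParamRange]
    total: ParamRange

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        missing = set(COST_COMPONENTS) - set(self.components)
        if missing:
            raise ValidationError(
                f"{self.modality} cost profile missing components {sorted(missing)}"
            )
        for name, rng in self.components.items():
            if rng.low < 0:
                raise ValidationError(
                    f"{self.modality} cost component {name!r}: low {rng.low} < 0"
                )

    @property
    def annual_cost(self) -> float:
        """RM per patient per year: sum of the component means."""
        return float(sum(r.mean for r in self.components.values()))

    @property
    def total_mean(self) -> float:
        return self.total.mean


@dataclass(frozen=True)
class CostTotalCheck:
    """Report of a component-sum vs printed-total consistency check."""

    modality: str
    component_sum: float
    printed_total: float
    discrepancy: float
    tolerance: float
    passed: bool


@dataclass(frozen=True)
class UtilitySet:
    """EQ-5D-3L utility index (0..1) per modality, with ranges."""

    HD: ParamRange
    CAPD: ParamRange

    def __post_init__(self) -> None:
        for modality in MODALITIES:
            rng = getattr(self, modality)
            if not (0.0 <= rng.low and rng.high <= 1.0):
                raise ValidationError(
                    f"utility for {modality} must lie in [0, 1]; got "
                    f"[{rng.low}, {rng.high}]"
                )

    def for_modality(self, modality: str) -> ParamRange:
        return getattr(self, modality)


@dataclass(frozen=True)
class TransitionRateSet:
    """Annual event rates (events per patient-year) for the four transitions."""

    CAPD_HD: ParamRange
    CAPD_death: ParamRange
    HD_CAPD: ParamRange
    HD_death: ParamRange

    # A per-modality exit-rate sum below this keeps the per-cycle stay
    # probability strictly positive after 1 - exp(-r t) conversion.
    _EXIT_SUM_BOUND = 3.0

    def __post_init__(self) -> None:
        for key in RATE_KEYS:
            rng = getattr(self, key)
            if rng.mean <= 0:
                raise ValidationError(f"rate {key} must be > 0; got {rng.mean}")
        for modality, total in self.exit_rate_sums().items():
            if total >= self._EXIT_SUM_BOUND:
                raise ValidationError(
                    f"exit rates out of {modality} sum to {total:.3f} "
                    f">= {self._EXIT_SUM_BOUND}"
                )

    def exit_rate_sums(self) -> dict[str, float]:
        return {
            "HD": self.HD_CAPD.mean + self.HD_death.mean,
            "CAPD": self.CAPD_HD.mean + self.CAPD_death.mean,
        }


@dataclass(frozen=True)
class ScenarioSpec:
    """A provision strategy: the initial HD:CAPD mix of the incident cohort."""

    name: str
    init_HD: float
    init_CAPD: float

    def __post_init__(self) -> None:
        for label, p in (("init_HD", self.init_HD), ("init_CAPD", self.init_CAPD)):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{label} = {p} outside [0, 1]")
        if abs(self.init_HD + self.init_CAPD - 1.0) > 1e-9:
            raise ValidationError(
                f"scenario {self.name!r}: init_HD + init_CAPD = "
                f"{self.init_HD + self.init_CAPD} != 1"
            )

    @property
    def initial_vector(self) -> tuple[float, float, float]:
        """Initial occupancy over (HD, CAPD, Death)."""
        return (self.init_HD, self.init_CAPD, 0.0)


@dataclass(frozen=True)
class EconomicSettings:
    """Discounting, horizon, willingness-to-pay thresholds and mean LYs."""

    discount_rate: float = 0.03
    n_cycles: int = 5
    cycle_length: float = 1.0
    wtp_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {
            "very_cost_effective": 40_000.0,
            "cost_effective": 120_000.0,
        }
    )
    life_years: Mapping[str, float] = field(
        default_factory=lambda: {"HD": 4.15, "CAPD": 3.70}
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValidationError(f"discount_rate {self.discount_rate} outside [0, 1)")
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length must be > 0")
        very = self.wtp_thresholds.get("very_cost_effective")
        ce = self.wtp_thresholds.get("cost_effective")
        if very is None or ce is None:
            raise ConfigurationError(
                "wtp_thresholds must define 'very_cost_effective' and 'cost_effective'"
            )
        if not (0 < very <= ce):
            raise ValidationError(
                f"thresholds must be positive and ordered; got {very}, {ce}"
            )


@dataclass(frozen=True)
class ModelParameters:
    """Validated bundle of every model input."""

    costs: Mapping[str, CostProfile]
    utilities: UtilitySet
    rates: TransitionRateSet
    scenarios: Mapping[str, ScenarioSpec]
    economics: EconomicSettings
    currency: str = "RM (2017)"

    def scenario(self, name: str) -> ScenarioSpec:
        try:
            return self.scenarios[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown scenario {name!r}; available: {sorted(self.scenarios)}"
            ) from None

    # -- labelled inputs for sensitivity analysis --------------------------

    def labelled_inputs(self) -> dict[str, ParamRange]:
        """All uncertain inputs keyed by their sensitivity-analysis label.

        Labels follow the published convention: ``cHD_hosp``,
        ``cCAPD_consumables``, ..., ``uHD``, ``uCAPD``, ``pHD_death``,
        ``pCAPD_HD``, ...
        """
        out: dict[str, ParamRange] = {}
        for modality in MODALITIES:
            for comp, rng in self.costs[modality].components.items():
                out[f"c{modality}_{_LABEL_SUFFIX[comp]}"] = rng
        out["uHD"] = self.utilities.HD
        out["uCAPD"] = self.utilities.CAPD
        for key in RATE_KEYS:
            out[f"p{key}"] = getattr(self.rates, key)
        return out

    def with_value(self, label: str, value: float) -> "ModelParameters":
        """A copy with the mean of one labelled input replaced.

        The range is left untouched, so ``value`` must lie inside it.
        Used by the one-way sensitivity analysis to pin a single input at
        its low/high bound.
        """
        if label.startswith("c"):
            body = label[1:]
            for modality in MODALITIES:
                prefix = modality + "_"
                if body.startswith(prefix):
                    suffix = body[len(prefix):]
                    names = [k for k, v in _LABEL_SUFFIX.items() if v == suffix]
                    if names:
                        comp = names[0]
                        profile = self.costs[modality]
                        new_components = dict(profile.components)
                        new_components[comp] = replace(
                            new_components[comp], mean=float(value)
                        )
                        new_profile = replace(profile, components=new_components)
                        return replace(
                            self, costs={**self.costs, modality: new_profile}
                        )
        elif label in ("uHD", "uCAPD"):
            modality = label[1:]
            new_util = replace(
                self.utilities,
                **{modality: replace(getattr(self.utilities, modality),
                                     mean=float(value))},
            )
            return replace(self, utilities=new_util)
        elif label.startswith("p") and label[1:] in RATE_KEYS:
            key = label[1:]
            new_rates = replace(
                self.rates, **{key: replace(getattr(self.rates, key),
                                            mean=float(value))}
            )
            return replace(self, rates=new_rates)
        raise ConfigurationError(f"unknown input label {label!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def rng_d(r: ParamRange) -> dict[str, float]:
            return {"mean": r.mean, "low": r.low, "high": r.high}

        return {
            "currency": self.currency,
            "costs": {
                m: {
                    "components": {
                        k: rng_d(v) for k, v in self.costs[m].components.items()
                    },
                    "total": rng_d(self.costs[m].total),
                }
                for m in MODALITIES
            },
            "utilities": {m: rng_d(self.utilities.for_modality(m)) for m in MODALITIES},
            "transition_rates": {k: rng_d(getattr(self.rates, k)) for k in RATE_KEYS},
            "scenarios": {
                name: {"init_HD": s.init_HD, "init_CAPD": s.init_CAPD}
                for name, s in self.scenarios.items()
            },
            "economics": {
                "discount_rate": self.economics.discount_rate,
                "n_cycles": self.economics.n_cycles,
                "cycle_length": self.economics.cycle_length,
                "wtp_thresholds": dict(self.economics.wtp_thresholds),
                "life_years": dict(self.economics.life_years),
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "ModelParameters":
        return _parse_document(doc)


# ---------------------------------------------------------------------------
# parsing / loading


def _require(doc: Mapping[str, Any], key: str, context: str) -> Any:
    if not isinstance(doc, Mapping) or key not in doc:
        raise ConfigurationError(f"missing key {key!r} in {context}")
    return doc[key]


def _parse_range(doc: Mapping[str, Any], context: str) -> ParamRange:
    return ParamRange(
        mean=float(_require(doc, "mean", context)),
        low=float(_require(doc, "low", context)),
        high=float(_require(doc, "high", context)),
    )


def _parse_document(doc: Mapping[str, Any]) -> ModelParameters:
    costs_doc = _require(doc, "costs", "config")
    costs: dict[str, CostProfile] = {}
    for modality in MODALITIES:
        mdoc = _require(costs_doc, modality, "costs")
        comp_doc = _require(mdoc, "components", f"costs.{modality}")
        components = {
            name: _parse_range(
                _require(comp_doc, name, f"costs.{modality}.components"),
                f"costs.{modality}.components.{name}",
            )
            for name in COST_COMPONENTS
        }
        total = _parse_range(
            _require(mdoc, "total", f"costs.{modality}"), f"costs.{modality}.total"
        )
        costs[modality] = CostProfile(modality, components, total)

    util_doc = _require(doc, "utilities", "config")
    utilities = UtilitySet(
        HD=_parse_range(_require(util_doc, "HD", "utilities"), "utilities.HD"),
        CAPD=_parse_range(_require(util_doc, "CAPD", "utilities"), "utilities.CAPD"),
    )

    rates_doc = _require(doc, "transition_rates", "config")
    rates = TransitionRateSet(
        **{
            key: _parse_range(
                _require(rates_doc, key, "transition_rates"),
                f"transition_rates.{key}",
            )
            for key in RATE_KEYS
        }
    )

    scen_doc = _require(doc, "scenarios", "config")
    if not scen_doc:
        raise ConfigurationError("at least one scenario must be defined")
    scenarios = {
        name: ScenarioSpec(
            name=name,
            init_HD=float(_require(sdoc, "init_HD", f"scenarios.{name}")),
            init_CAPD=float(_require(sdoc, "init_CAPD", f"scenarios.{name}")),
        )
        for name, sdoc in scen_doc.items()
    }

    econ_doc = _require(doc, "economics", "config")
    economics = EconomicSettings(
        discount_rate=float(_require(econ_doc, "discount_rate", "economics")),
        n_cycles=int(_require(econ_doc, "n_cycles", "economics")),
        cycle_length=float(_require(econ_doc, "cycle_length", "economics")),
        wtp_thresholds={
            k: float(v)
            for k, v in _require(econ_doc, "wtp_thresholds", "economics").items()
        },
        life_years={
            k: float(v)
            for k, v in _require(econ_doc, "life_years", "economics").items()
        },
    )

    params = ModelParameters(
        costs=costs,
        utilities=utilities,
        rates=rates,
        scenarios=scenarios,
        economics=economics,
        currency=str(doc.get("currency", "RM (2017)")),
    )

    # Cross-check transcription: component sums must reproduce printed totals.
    for modality in MODALITIES:
        check = validate_cost_totals(params.costs[modality])
        if not check.passed:
            raise ValidationError(
                f"{modality} cost components sum to {check.component_sum:.2f} "
                f"but printed total is {check.printed_total:.2f} "
                f"(discrepancy {check.discrepancy:.2f} RM > {check.tolerance} RM)"
            )
    return params


def validate_cost_totals(
    profile: CostProfile, tolerance: float = COST_SUM_TOLERANCE
) -> CostTotalCheck:
    """Check that the component means sum to the printed total.

    Returns a report rather than raising, so inconsistent profiles can be
    inspected; :func:`load_parameters` turns a failing report into a
    :class:`ValidationError`.
    """
    component_sum = profile.annual_cost
    discrepancy = abs(component_sum - profile.total.mean)
    return CostTotalCheck(
        modality=profile.modality,
        component_sum=component_sum,
        printed_total=profile.total.mean,
        discrepancy=discrepancy,
        tolerance=tolerance,
        passed=discrepancy <= tolerance,
    )


def load_parameters(source: str | Path | IO[str] | Mapping[str, Any]) -> ModelParameters:
    """Load and validate a parameter bundle.

    ``source`` may be a path to a YAML file, an open text stream, or an
    already-parsed mapping.
    """
    if isinstance(source, Mapping):
        doc = source
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, Mapping):
        raise ConfigurationError("config document did not parse to a mapping")
    return _parse_document(doc)


def default_parameters() -> ModelParameters:
    """The bundled default inputs (published cost/utility/rate tables)."""
    from importlib import resources

    text = (
        resources.files("dialysis_cea").joinpath("data/default_config.yaml").read_text()
    )
    return load_parameters(io.StringIO(text))


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialize a bundle back to YAML (round-trips bit-identically)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
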