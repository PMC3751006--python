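"""Model parameters: containers, validation, loading, and derivation rules.

The default parameter set bundles the baseline epidemiology (screening
yields, annual transition probabilities between glucose-tolerance and
complication states), societal costs in US$, health-state utilities by
initiation age, and the global economic settings (3% discount rate,
40-year horizon, 1-year cycles, 20,000 simulated subjects, 6-year
intervention tunnel).

Three derivation rules used to construct those baselines are exposed as
functions so user-supplied alternatives can be built the same way:

* age scaling of the IGT->diabetes transition with the 1 : 2.6 : 8
  incidence ratio at ages 25 : 40 : 60 (:func:`scale_rate_by_age_ratio`),
* conversion of a k-year cumulative incidence to an annual probability
  (:func:`annual_rate_from_cumulative`), and
* age/comorbidity adjustment of the age-40 median disease utilities
  (:func:`adjust_utility`).
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger(__name__)

STRATEGY_IDS = ("diet", "exercise", "duo", "screen_only", "control")
INTERVENTION_IDS = ("diet", "exercise", "duo")
INITIATION_AGES = (25, 40, 60)
HEALTH_STATES = (
    "normal", "igt", "onset_dm", "cvd", "retinopathy",
    "nephropathy", "neuropathy", "death",
)
COMPLICATIONS = ("cvd", "retinopathy", "nephropathy", "neuropathy")

#: Incidence ratio of diabetes at ages 25 : 40 : 60.
AGE_RATIO = {25: 1.0, 40: 2.6, 60: 8.0}

#: Chinese yuan per US dollar (exchange rate of June 15, 2007).
FX_CHY_PER_USD = 7.6948


class ParameterError(ValueError):
    """A configuration value is missing, malformed or out of range."""


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return float(value)


def _check_nonneg(name: str, value: float) -> float:
    if value < 0:
        raise ParameterError(f"{name} must be non-negative, got {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategySpec:
    """One decision-tree arm and its Markov transition/cost overrides."""

    id: str
    igt_to_dm_rate_by_age: Mapping[int, float]
    complication_incidence: Mapping[str, float]
    complication_mortality: Mapping[str, float]
    annual_intervention_cost: float
    has_screening: bool

    def __post_init__(self) -> None:
        if self.id not in STRATEGY_IDS:
            raise ParameterError(f"unknown strategy id {self.id!r}")
        for age in INITIATION_AGES:
            if age not in self.igt_to_dm_rate_by_age:
                raise ParameterError(
                    f"strategies.{self.id}.igt_to_dm_rate_by_age missing age {age}")
            _check_prob(f"strategies.{self.id}.igt_to_dm_rate_by_age[{age}]",
                        self.igt_to_dm_rate_by_age[age])
        for comp in COMPLICATIONS:
            _check_prob(f"strategies.{self.id}.complication_incidence[{comp}]",
                        self.complication_incidence[comp])
        for comp in ("cvd", "nephropathy"):
            _check_prob(f"strategies.{self.id}.complication_mortality[{comp}]",
                        self.complication_mortality[comp])
        _check_nonneg(f"strategies.{self.id}.annual_intervention_cost",
                      self.annual_intervention_cost)
        if self.id == "control" and self.has_screening:
            raise ParameterError("control arm cannot have screening")


@dataclass(frozen=True)
class ScreeningProfile:
    """Screening test yields plus programme performance levers."""

    neg_rate_2hpg: float
    ogtt_positive_rate: float
    igt_fraction_of_positive: float
    detection_level: float = 1.0
    compliance: float = 1.0
    screening_cost: float = 3.0

    def __post_init__(self) -> None:
        for name in ("neg_rate_2hpg", "ogtt_positive_rate",
                     "igt_fraction_of_positive", "detection_level", "compliance"):
            _check_prob(f"screening.{name}", getattr(self, name))
        _check_nonneg("screening.screening_cost", self.screening_cost)


@dataclass(frozen=True)
class SharedRates:
    """Annual transition probabilities common to every arm."""

    normal_to_igt: float = 0.0128
    igt_to_normal: float = 0.116

    def __post_init__(self) -> None:
        _check_prob("shared.normal_to_igt", self.normal_to_igt)
        _check_prob("shared.igt_to_normal", self.igt_to_normal)


@dataclass(frozen=True)
class CostTable:
    """Annual societal treatment costs and one-off screening cost (US$)."""

    onset_dm: float = 897.0
    cvd: float = 2078.0
    nephropathy: float = 1089.0
    neuropathy: float = 1324.0
    retinopathy: float = 888.0
    screening: float = 3.0
    diet_or_exercise: float = 362.0
    duo: float = 371.0

    def __post_init__(self) -> None:
        for name in ("onset_dm", "cvd", "nephropathy", "neuropathy",
                     "retinopathy", "screening", "diet_or_exercise", "duo"):
            _check_nonneg(f"costs.{name}", getattr(self, name))

    def state_cost(self, state: str) -> float:
        """Annual cost of occupying a health state (normal/IGT/death are 0)."""
        if state in ("normal", "igt", "death"):
            return 0.0
        return {"onset_dm": self.onset_dm, "cvd": self.cvd,
                "nephropathy": self.nephropathy, "neuropathy": self.neuropathy,
                "retinopathy": self.retinopathy}[state]


@dataclass(frozen=True)
class UtilityTable:
    """Health-state utilities by initiation age, with adjustment coefficients."""

    by_age_and_state: Mapping[int, Mapping[str, float]]
    age_coefficient: float = -0.0003
    comorbidity_coefficient: float = 0.084

    def __post_init__(self) -> None:
        for age in INITIATION_AGES:
            row = self.by_age_and_state.get(age)
            if row is None:
                raise ParameterError(f"utilities.by_age_and_state missing age {age}")
            for state in HEALTH_STATES:
                _check_prob(f"utilities[{age}][{state}]", row[state])
            if row["normal"] != 1.0 or row["death"] != 0.0:
                raise ParameterError(
                    f"utilities at age {age}: normal must be 1 and death 0")
        for state in HEALTH_STATES:
            u25, u40, u60 = (self.by_age_and_state[a][state] for a in INITIATION_AGES)
            if not (u25 >= u40 >= u60):
                raise ParameterError(
                    f"utility for {state} must be non-increasing with age")

    def utility(self, age: int, state: str) -> float:
        return self.by_age_and_state[age][state]


@dataclass(frozen=True)
class EconSettings:
    """Global constants: discounting, horizon, cohort and tunnel sizes."""

    discount_rate: float = 0.03
    horizon: int = 40
    cycle_length: int = 1
    cohort_size: int = 20000
    tunnel_length: int = 6
    fx_rate: float = FX_CHY_PER_USD
    age_ratio: Mapping[int, float] = field(default_factory=lambda: dict(AGE_RATIO))

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ParameterError("settings.horizon must be positive")
        if self.tunnel_length > self.horizon:
            raise ParameterError("settings.tunnel_length must not exceed horizon")
        if self.discount_rate < 0:
            raise ParameterError("settings.discount_rate must be >= 0")
        if self.cohort_size < 1:
            raise ParameterError("settings.cohort_size must be >= 1")


@dataclass(frozen=True)
class Conventions:
    """Reporting conventions the underlying study leaves open.

    cost_population: population over which mean discounted cost is the
        headline (``subgroup`` = diabetes/IGT subjects, ``all`` = whole
        simulated cohort; both are always computed).
    eligibility: membership rule for the diabetes/IGT subgroup
        (``baseline`` = IGT or diabetes at entry; ``incident`` also counts
        subjects who develop diabetes within the horizon).
    post_tunnel_rate: IGT->diabetes rate applied to intervention
        recipients after the 6 tunnel years (``control`` or
        ``last_intervention``).
    range_kind: the parenthesised ranges in reports (``percentile`` =
        subject-level 2.5th-97.5th percentiles, or ``minmax``).
    """

    cost_population: str = "subgroup"
    eligibility: str = "baseline"
    post_tunnel_rate: str = "control"
    range_kind: str = "percentile"

    def __post_init__(self) -> None:
        allowed = {"cost_population": ("subgroup", "all"),
                   "eligibility": ("baseline", "incident"),
                   "post_tunnel_rate": ("control", "last_intervention"),
                   "range_kind": ("percentile", "minmax")}
        for name, options in allowed.items():
            if getattr(self, name) not in options:
                raise ParameterError(
                    f"conventions.{name} must be one of {options}, "
                    f"got {getattr(self, name)!r}")


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated parameter set for one model run."""

    strategies: Mapping[str, StrategySpec]
    screening: ScreeningProfile
    shared: SharedRates
    costs: CostTable
    utilities: UtilityTable
    settings: EconSettings
    conventions: Conventions = field(default_factory=Conventions)

    def __post_init__(self) -> None:
        for sid in STRATEGY_IDS:
            if sid not in self.strategies:
                raise ParameterError(f"strategies missing arm {sid!r}")
        control = self.strategies["control"]
        for sid in INTERVENTION_IDS:
            arm = self.strategies[sid]
            for age in INITIATION_AGES:
                if arm.igt_to_dm_rate_by_age[age] > control.igt_to_dm_rate_by_age[age]:
                    raise ParameterError(
                        f"strategies.{sid} IGT->DM rate at age {age} exceeds control")

    @property
    def control(self) -> StrategySpec:
        return self.strategies["control"]

    def intervention_cost(self, strategy_id: str) -> float:
        return self.strategies[strategy_id].annual_intervention_cost

    def with_overrides(self, **kwargs: Any) -> "ModelParameters":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """The bundled default configuration as a nested dict."""
    text = resources.files("prediasim").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _int_keys(mapping: Mapping) -> dict:
    return {int(k): v for k, v in mapping.items()}


def load_parameters(config_source: str | Path | Mapping | None = None) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from a config source.

    ``config_source`` may be ``None`` (pure defaults), a mapping of
    overrides, a path to a YAML/JSON file, or a YAML string.  Missing keys
    fall back to the bundled defaults; every value is range-checked.
    """
    config = default_config()
    if config_source is not None:
        if isinstance(config_source, Mapping):
            override = config_source
        else:
            path = Path(config_source)
            if path.exists():
                text = path.read_text()
            else:
                text = str(config_source)
            try:
                override = yaml.safe_load(text)
            except yaml.YAMLError as exc:
                raise ParameterError(f"could not parse configuration: {exc}") from exc
            if override is None:
                override = {}
            if not isinstance(override, Mapping):
                raise ParameterError(
                    "configuration must be a mapping of sections, "
                    f"got {type(override).__name__}")
        config = _deep_merge(config, override)

    try:
        strategies = {
            sid: StrategySpec(
                id=sid,
                igt_to_dm_rate_by_age=_int_keys(spec["igt_to_dm_rate_by_age"]),
                complication_incidence=dict(spec["complication_incidence"]),
                complication_mortality=dict(spec["complication_mortality"]),
                annual_intervention_cost=spec["annual_intervention_cost"],
                has_screening=spec["has_screening"],
            )
            for sid, spec in config["strategies"].items()
        }
        utilities_cfg = config["utilities"]
        params = ModelParameters(
            strategies=strategies,
            screening=ScreeningProfile(**config["screening"]),
            shared=SharedRates(**config["shared"]),
            costs=CostTable(**config["costs"]),
            utilities=UtilityTable(
                by_age_and_state={int(a): dict(row) for a, row
                                  in utilities_cfg["by_age_and_state"].items()},
                age_coefficient=utilities_cfg["age_coefficient"],
                comorbidity_coefficient=utilities_cfg["comorbidity_coefficient"],
            ),
            settings=EconSettings(**{
                **config["settings"],
                "age_ratio": _int_keys(config["settings"]["age_ratio"]),
            }),
            conventions=Conventions(**config.get("conventions", {})),
        )
    except KeyError as exc:
        raise ParameterError(f"configuration missing required key {exc}") from exc
    except (TypeError, AttributeError) as exc:
        raise ParameterError(f"malformed configuration: {exc}") from exc
    return params


# ---------------------------------------------------------------------------
# Derivation rules
# ---------------------------------------------------------------------------

def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (the convention of the reported parameters).

    Decimal-based so that values like 0.7045, which binary floats store
    fractionally below the half, still round upward as they do on paper.
    """
    import decimal
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(round(value, ndigits + 6)))
    return float(d.quantize(quantum, rounding=decimal.ROUND_HALF_UP))


def scale_rate_by_age_ratio(rate_age40: float, target_age: int,
                            ratio: Mapping[int, float] | None = None) -> float:
    """Scale an age-40 annual probability by the age-incidence ratio.

    Uses the 1 : 2.6 : 8 diabetes-incidence ratio at ages 25 : 40 : 60.
    The result is clamped to [0, 1]; a clamp is logged as a warning.
    """
    ratio = dict(AGE_RATIO if ratio is None else ratio)
    _check_prob("rate_age40", rate_age40)
    if target_age not in ratio:
        raise ParameterError(f"target_age must be one of {sorted(ratio)}")
    scaled = rate_age40 * ratio[target_age] / ratio[40]
    if scaled > 1.0:
        logger.warning("age-scaled rate %.4f exceeds 1; clamping", scaled)
        scaled = 1.0
    return scaled


def derive_igt_dm_rates(rate_age40: float, ndigits: int = 4) -> dict[int, float]:
    """Derive the age-25/40/60 IGT->diabetes rates the way the baselines were.

    The reported intervention-arm values follow a chained rounding: the
    age-25 rate is the age-40 rate divided by 2.6, rounded; the age-60
    rate is that *rounded* age-25 value times 8 (e.g. 0.0710 -> 0.0273 ->
    0.2184, where the direct ratio would give 0.21846 -> 0.2185).
    """
    r25 = round_half_away(scale_rate_by_age_ratio(rate_age40, 25), ndigits)
    r60 = round_half_away(min(1.0, r25 * 8.0), ndigits)
    return {25: r25, 40: rate_age40, 60: r60}


def annual_rate_from_cumulative(cum_prob: float, years: int) -> float:
    """Annual probability equivalent to a ``years``-year cumulative incidence."""
    if not 0.0 <= cum_prob < 1.0:
        raise ParameterError(
            f"cumulative probability must be in [0, 1), got {cum_prob!r}")
    if years < 1:
        raise ParameterError("years must be >= 1")
    return 1.0 - (1.0 - cum_prob) ** (1.0 / years)


def adjust_utility(base_utility_age40: float, target_age: int,
                   extra_comorbidity: bool = False,
                   age_coefficient: float = -0.0003,
                   comorbidity_coefficient: float = 0.084) -> float:
    """Adjust an age-40 median disease utility to another initiation age.

    Applies the per-year age coefficient relative to age 40 and, for the
    older cohort's complication states (diabetes + complication + the one
    additional universal coexisting condition), subtracts the
    three-condition comorbidity coefficient.  E.g. diabetes-with-CVD at
    age 60: 0.674 - 0.006 - 0.084 = 0.584.
    """
    _check_prob("base_utility_age40", base_utility_age40)
    adjusted = base_utility_age40 + (target_age - 40) * age_coefficient
    if extra_comorbidity:
        adjusted -= comorbidity_coefficient
    return min(1.0, max(0.0, adjusted))


def yuan_to_usd(amount_chy: float, fx_rate: float = FX_CHY_PER_USD) -> float:
    """Convert Chinese yuan to US dollars at the fixed study exchange rate."""
    if amount_chy < 0:
        raise ParameterError(f"amount must be non-negative, got {amount_chy!r}")
    return amount_chy / fx_rate
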