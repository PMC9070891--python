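"""Model inputs: uncertainty specifications, validation, and derived unit quantities.

Every input of the decision model is registered here with its base-case value,
sensitivity-analysis range, and sampling family (``beta`` for probabilities with a
published CI, ``triangular`` for ratios / costs / utilities, ``fixed`` for settings
that are not varied).  Monetary values are US dollars; probabilities and rates are
monthly unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import SimpleNamespace
from typing import Iterable, Mapping

import yaml


class ConfigError(ValueError):
    """Invalid or incomplete model configuration."""


# --------------------------------------------------------------------------- #
# distribution specification
# --------------------------------------------------------------------------- #

_FAMILIES = ("beta", "triangular", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Base-case value plus sensitivity range and sampling family for one input."""

    family: str
    base: float
    low: float
    high: float

    def validate(self, name: str = "<param>") -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"{name}: unknown family {self.family!r}")
        if not (self.low <= self.base <= self.high):
            raise ConfigError(
                f"{name}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ConfigError(f"{name}: beta family requires bounds in [0, 1]")

    @property
    def degenerate(self) -> bool:
        """True when the range collapses to a point (nothing to vary)."""
        return self.low == self.high


def _fixed(base: float) -> DistributionSpec:
    return DistributionSpec("fixed", base, base, base)


def _beta(base: float, low: float, high: float) -> DistributionSpec:
    return DistributionSpec("beta", base, low, high)


def _tri(base: float, low: float, high: float) -> DistributionSpec:
    return DistributionSpec("triangular", base, low, high)


# --------------------------------------------------------------------------- #
# input registry
# --------------------------------------------------------------------------- #

#: Every model input: clinical, utility, cost, and the fixed analysis settings.
TABLE1: dict[str, DistributionSpec] = {
    # uptake of CBT
    "accept_fcbt": _beta(0.633, 0.506, 0.760),
    "rr_accept_icbt": _tri(1.19, 0.952, 1.428),
    "adhere_fcbt": _beta(0.775, 0.62, 0.93),
    "rr_adhere_icbt": _tri(0.99, 0.84, 1.0),
    # programme-level outcomes of low-intensity CBT
    "recovery_none": _beta(0.25, 0.20, 0.30),
    "recovery_licbt": _beta(0.639, 0.511, 0.767),
    "rr_recovery_icbt": _tri(1.00, 0.95, 1.05),
    "deterioration_none": _beta(0.174, 0.139, 0.209),
    "deterioration_licbt": _beta(0.053, 0.042, 0.064),
    "rr_deterioration_icbt": _tri(1.00, 0.95, 1.05),
    # monthly transition probabilities between symptom states
    "p_well_mild": _beta(0.0044, 0.0035, 0.0053),
    "p_well_mod": _beta(0.0053, 0.0042, 0.0064),
    "p_well_sev": _beta(0.0166, 0.0133, 0.0199),
    "p_mild_well": _beta(0.0239, 0.0191, 0.0287),
    "p_mild_mod": _beta(0.0073, 0.0058, 0.0088),
    "p_mild_sev": _beta(0.0067, 0.0054, 0.0080),
    "p_mod_well": _beta(0.0448, 0.0358, 0.0538),
    "p_mod_mild": _beta(0.0801, 0.0641, 0.0961),
    "p_mod_sev": _beta(0.0275, 0.0220, 0.0330),
    "p_sev_well": _beta(0.0387, 0.0310, 0.0464),
    "p_sev_mild": _beta(0.0314, 0.0251, 0.0377),
    "p_sev_mod": _beta(0.0391, 0.0313, 0.0469),
    # events and mortality
    "p_hosp_severe": _beta(0.0114, 0.0091, 0.0137),
    "mortality_monthly": _beta(0.000025, 0.000020, 0.000030),
    "rr_mortality_anxiety": _tri(1.66, 1.56, 1.77),
    # utilities
    "age_years": _tri(21, 19, 23),
    "utility_age": _fixed(0.92),
    "utility_well": _tri(0.72, 0.69, 0.75),
    "utility_mild": _tri(0.64, 0.62, 0.66),
    "utility_mod": _tri(0.60, 0.58, 0.62),
    "utility_sev": _tri(0.53, 0.50, 0.56),
    # direct medical unit costs
    "wage_psych": _tri(52, 42, 62),
    "li_sessions": _tri(8, 5, 10),
    "li_session_hours": _fixed(0.5),
    "hi_sessions": _tri(14, 12, 15),
    "hi_session_hours": _fixed(1.0),
    "platform_cost_icbt": _tri(19, 15, 23),
    "time_fraction_icbt": _tri(0.22, 0.17, 0.26),
    "outpatient_monthly": _tri(220, 185, 348),
    "hosp_cost_episode": _tri(1278, 1022, 1534),
    # indirect (friction) cost inputs
    "labor_participation": _beta(0.364, 0.353, 0.387),
    "unemployment": _beta(0.13, 0.114, 0.144),
    "student_wage": _tri(10, 8, 12),
    "hours_per_month": _tri(56, 40, 72),
    # analysis settings (not varied)
    "discount_annual": _fixed(0.03),
    "horizon_cycles": _fixed(60),
    "wtp": _fixed(46070),
}

#: keys whose values must lie in [0, 1]
PROBABILITY_KEYS = frozenset(
    k
    for k in TABLE1
    if k.startswith(("p_", "accept", "adhere", "recovery_", "deterioration_"))
    or k in ("mortality_monthly", "labor_participation", "unemployment",
             "time_fraction_icbt")
)

#: keys holding utility weights, in [0, 1]
UTILITY_KEYS = frozenset(k for k in TABLE1 if k.startswith("utility_"))

#: keys holding money amounts, >= 0
COST_KEYS = frozenset(
    ("wage_psych", "platform_cost_icbt", "outpatient_monthly",
     "hosp_cost_episode", "student_wage", "wtp")
)


# --------------------------------------------------------------------------- #
# parameter set
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated collection of model inputs.

    Attribute access returns the :class:`DistributionSpec` for a key
    (``params.accept_fcbt.base``); :meth:`point` flattens to base values for
    the simulation engine.
    """

    specs: Mapping[str, DistributionSpec] = field(default_factory=lambda: dict(TABLE1))

    def __post_init__(self) -> None:
        self.validate()

    def __getattr__(self, name: str) -> DistributionSpec:
        specs = object.__getattribute__(self, "specs")
        try:
            return specs[name]
        except KeyError:
            raise AttributeError(name) from None

    def keys(self) -> Iterable[str]:
        return self.specs.keys()

    def validate(self) -> None:
        unknown = set(self.specs) - set(TABLE1)
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
        missing = set(TABLE1) - set(self.specs)
        if missing:
            raise ConfigError(f"missing parameter key(s): {sorted(missing)}")
        for name, spec in self.specs.items():
            spec.validate(name)
            for v, what in ((spec.base, "base"), (spec.low, "low"), (spec.high, "high")):
                if name in PROBABILITY_KEYS and not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}: probability {what}={v} outside [0, 1]")
                if name in UTILITY_KEYS and not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}: utility {what}={v} outside [0, 1]")
                if name in COST_KEYS and v < 0:
                    raise ConfigError(f"{name}: cost {what}={v} is negative")

    def point(self) -> SimpleNamespace:
        """Base-case point values as a flat attribute namespace."""
        return SimpleNamespace(**{k: s.base for k, s in self.specs.items()})

    def with_base(self, key: str, value: float) -> "ParameterSet":
        """New set with one base value replaced (range and family preserved)."""
        if key not in self.specs:
            raise ConfigError(f"unknown parameter key: {key!r}")
        spec = self.specs[key]
        new = replace(spec, base=value,
                      low=min(spec.low, value), high=max(spec.high, value))
        return ParameterSet({**self.specs, key: new})

    def with_specs(self, **overrides: DistributionSpec) -> "ParameterSet":
        return ParameterSet({**self.specs, **overrides})


def default_parameters() -> ParameterSet:
    """The shipped base-case input set."""
    return ParameterSet(dict(TABLE1))


# --------------------------------------------------------------------------- #
# structural configuration
# --------------------------------------------------------------------------- #

_ALIVE_SYMPTOM_STATES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class StructuralConfig:
    """Structural modelling choices the published inputs leave open.

    Defaults are the calibrated reference configuration; every switch is a
    documented alternative, not a tuning dial.
    """

    phase_cycles: int = 3
    deterioration_split_rule: str = "proportional"  # or "all_moderate"
    outpatient_states: frozenset[str] = frozenset({"moderate", "severe"})
    escalation_enabled: bool = True
    escalation_recipients: str = "all_not_well"  # or "accepters_not_well"
    course_cost_nonadherent: str = "full"  # or "half"
    half_cycle_correction: bool = False
    mortality_rr_states: frozenset[str] = frozenset({"mild", "moderate", "severe"})

    def __post_init__(self) -> None:
        if not 1 <= self.phase_cycles:
            raise ConfigError("phase_cycles must be >= 1")
        if self.deterioration_split_rule not in ("proportional", "all_moderate"):
            raise ConfigError(
                f"deterioration_split_rule: {self.deterioration_split_rule!r}")
        if self.escalation_recipients not in ("accepters_not_well", "all_not_well"):
            raise ConfigError(f"escalation_recipients: {self.escalation_recipients!r}")
        if self.course_cost_nonadherent not in ("full", "half"):
            raise ConfigError(f"course_cost_nonadherent: {self.course_cost_nonadherent!r}")
        for fld in ("outpatient_states", "mortality_rr_states"):
            vals = getattr(self, fld)
            object.__setattr__(self, fld, frozenset(vals))
            bad = set(getattr(self, fld)) - set(_ALIVE_SYMPTOM_STATES)
            if bad:
                raise ConfigError(f"{fld}: unknown state(s) {sorted(bad)}")


# --------------------------------------------------------------------------- #
# config file I/O
# --------------------------------------------------------------------------- #


def load_parameters(config_text: str) -> tuple[ParameterSet, StructuralConfig]:
    """Parse a YAML configuration into a validated parameter set + structure.

    The file carries a ``parameters`` mapping (key -> family/base/low/high) and
    an optional ``structural`` block; missing structural keys take the defaults.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config does not parse: {exc}") from exc
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ConfigError("config must be a mapping with a 'parameters' block")

    specs: dict[str, DistributionSpec] = {}
    for key, entry in doc["parameters"].items():
        if key not in TABLE1:
            raise ConfigError(f"unknown parameter key: {key!r}")
        if not isinstance(entry, Mapping):
            raise ConfigError(f"{key}: entry must be a mapping")
        extra = set(entry) - {"family", "base", "low", "high"}
        if extra:
            raise ConfigError(f"{key}: unknown field(s) {sorted(extra)}")
        try:
            spec = DistributionSpec(
                family=str(entry["family"]),
                base=float(entry["base"]),
                low=float(entry["low"]),
                high=float(entry["high"]),
            )
        except KeyError as exc:
            raise ConfigError(f"{key}: missing field {exc}") from None
        specs[key] = spec
    params = ParameterSet(specs)  # validates completeness and bounds

    structural = dict(doc.get("structural") or {})
    for fld in ("outpatient_states", "mortality_rr_states"):
        if fld in structural:
            structural[fld] = frozenset(structural[fld])
    try:
        cfg = StructuralConfig(**structural)
    except TypeError as exc:
        raise ConfigError(f"structural block: {exc}") from None
    if cfg.phase_cycles > params.horizon_cycles.base:
        raise ConfigError("phase_cycles exceeds horizon_cycles")
    return params, cfg


def dump_config(params: ParameterSet, cfg: StructuralConfig | None = None) -> str:
    """Serialise a parameter set (+ structural block) back to YAML text."""
    cfg = cfg if cfg is not None else StructuralConfig()
    doc = {
        "parameters": {
            k: {"family": s.family, "base": s.base, "low": s.low, "high": s.high}
            for k, s in params.specs.items()
        },
        "structural": {
            "phase_cycles": cfg.phase_cycles,
            "deterioration_split_rule": cfg.deterioration_split_rule,
            "outpatient_states": sorted(cfg.outpatient_states),
            "escalation_enabled": cfg.escalation_enabled,
            "escalation_recipients": cfg.escalation_recipients,
            "course_cost_nonadherent": cfg.course_cost_nonadherent,
            "half_cycle_correction": cfg.half_cycle_correction,
            "mortality_rr_states": sorted(cfg.mortality_rr_states),
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def parameter_table(params: ParameterSet) -> "list[dict]":
    """Rows (key, family, base, low, high) for the CSV parameter dump."""
    return [
        {"key": k, "family": s.family, "base": s.base, "low": s.low, "high": s.high}
        for k, s in params.specs.items()
    ]


# --------------------------------------------------------------------------- #
# derived unit quantities
# --------------------------------------------------------------------------- #


def course_cost(params: ParameterSet | SimpleNamespace, mode: str) -> float:
    """Cost of one CBT course.

    ``f_low``  therapist wage x session hours x sessions (low-intensity, in person)
    ``i_low``  platform overhead + guided-therapist time fraction x f_low
    ``f_high`` high-intensity face-to-face course (escalation after non-response)
    """
    pt = params.point() if isinstance(params, ParameterSet) else params
    f_low = pt.wage_psych * pt.li_session_hours * pt.li_sessions
    if mode == "f_low":
        return f_low
    if mode == "i_low":
        return pt.platform_cost_icbt + pt.time_fraction_icbt * f_low
    if mode == "f_high":
        return pt.wage_psych * pt.hi_session_hours * pt.hi_sessions
    raise ConfigError(f"unknown course mode {mode!r}")


def effective_uptake(
    params: ParameterSet | SimpleNamespace, arm: str
) -> tuple[float, float, float]:
    """(p_accept, p_adhere, p_effective) for one arm.

    The internet arm applies the relative differences multiplicatively to the
    face-to-face base values, capping at 1 since these are probabilities.
    """
    pt = params.point() if isinstance(params, ParameterSet) else params
    if arm == "fcbt":
        p_acc, p_adh = pt.accept_fcbt, pt.adhere_fcbt
    elif arm == "icbt":
        p_acc = min(1.0, pt.accept_fcbt * pt.rr_accept_icbt)
        p_adh = min(1.0, pt.adhere_fcbt * pt.rr_adhere_icbt)
    else:
        raise ConfigError(f"unknown arm {arm!r}")
    return p_acc, p_adh, p_acc * p_adh


def employment_fraction(params: ParameterSet | SimpleNamespace) -> float:
    """Fraction of students in paid work: participation x (1 - unemployment)."""
    pt = params.point() if isinstance(params, ParameterSet) else params
    return pt.labor_participation * (1.0 - pt.unemployment)
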