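"""Model parameter registry: typed inputs, config I/O, PSA distributions.

Every numeric input of the cost-effectiveness model lives here as a
:class:`ParameterSpec` carrying its base value, plausible range (used for
one-way sensitivity analysis) and probabilistic-sensitivity-analysis
distribution family.  A :class:`InputSet` is one concrete assignment of
values, either deterministic (base case, OWSA endpoints, scenarios) or a
Monte-Carlo draw.

Distribution hyperparameters are fitted by the method of moments: the
plausible range is treated as a 95% interval, so the implied standard
deviation is ``(high - low) / 3.92`` and the mean equals the base value.
Uniform parameters use the range endpoints directly.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)

GROUPS = (
    "general",
    "test_performance",
    "prevalence",
    "transition",
    "effect_modifier",
    "cost",
    "utility",
)

DISTRIBUTIONS = ("beta", "gamma", "normal", "uniform", "fixed")

#: DKD stages at which risk stratification is performed.
EARLY_STAGES = ("g1", "g2", "g3a", "g3b")


class ConfigError(ValueError):
    """Raised when a parameter config is incomplete or violates an invariant."""


class ScenarioError(ValueError):
    """Raised when a scenario is requested without its required inputs."""


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with its uncertainty description.

    Attributes
    ----------
    name, group, units:
        Identification; ``group`` is one of :data:`GROUPS`.
    base, low, high:
        Base-case value and plausible range (OWSA endpoints).  ``low == high``
        means the parameter is not varied in one-way analyses.
    distribution:
        PSA family, one of :data:`DISTRIBUTIONS`; ``fixed`` parameters are
        never sampled.
    domain:
        Admissible open/closed interval for the value; draws falling outside
        are rejected and resampled (relevant for normal families).
    note:
        Free-text provenance remark (e.g. substituted ranges).
    """

    name: str
    group: str
    base: float
    low: float
    high: float
    distribution: str
    units: str = ""
    domain: tuple[float, float] = (-math.inf, math.inf)
    note: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"{self.name}: unknown group {self.group!r}")
        if self.distribution not in DISTRIBUTIONS:
            raise ConfigError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )

    @property
    def varies(self) -> bool:
        """Whether the OWSA range is non-degenerate."""
        return self.high > self.low


def _p(name, group, base, low, high, dist, units, domain, note=""):
    return ParameterSpec(name, group, base, low, high, dist, units, domain, note)


_PROB = (0.0, 1.0)
_POS = (0.0, math.inf)


def _build_registry() -> dict[str, ParameterSpec]:
    entries = [
        # -- general -------------------------------------------------------
        _p("age", "general", 65, 50, 70, "fixed", "years", (18, 110)),
        _p("cycle_length", "general", 1, 1, 1, "fixed", "years", (0, 10)),
        _p("time_horizon", "general", 5, 5, 5, "fixed", "years", (1, 100)),
        _p("discount_rate", "general", 0.03, 0.03, 0.03, "fixed", "per year", _PROB),
        # -- diagnostic test performance -----------------------------------
        _p("aikd_sensitivity", "test_performance", 0.51, 0.41, 0.61, "beta",
           "probability", _PROB),
        _p("aikd_specificity", "test_performance", 0.93, 0.66, 1.00, "beta",
           "probability", _PROB),
        _p("soc_sensitivity", "test_performance", 0.28, 0.23, 0.34, "beta",
           "probability", _PROB),
        _p("soc_specificity", "test_performance", 0.88, 0.66, 1.00, "beta",
           "probability", _PROB),
        # -- prevalence of prospective PDKF and of initial stages ----------
        # Stage-level PDKF prevalences use the midpoint of the published
        # plausible range as the working base; the published point values
        # (0.617 / 0.610 / 0.794 / 0.815) are inconsistent with the ranges
        # and with the model's other published outputs (see docs/methods.md).
        _p("pdkf_prevalence_g1", "prevalence", 0.210, 0.11, 0.31, "beta",
           "probability", _PROB,
           "published point value 0.617; range midpoint used as base"),
        _p("pdkf_prevalence_g2", "prevalence", 0.205, 0.11, 0.30, "beta",
           "probability", _PROB,
           "published point value 0.610; range midpoint used as base"),
        _p("pdkf_prevalence_g3a", "prevalence", 0.260, 0.16, 0.36, "beta",
           "probability", _PROB,
           "published point value 0.794; range midpoint used as base"),
        _p("pdkf_prevalence_g3b", "prevalence", 0.270, 0.17, 0.37, "beta",
           "probability", _PROB,
           "published point value 0.815; range midpoint used as base"),
        _p("pdkf_prevalence_overall", "prevalence", 0.766, 0.60, 0.90, "beta",
           "probability", _PROB,
           "published overall value; used only when stage-specific prevalence "
           "is disabled"),
        _p("stage_share_g1", "prevalence", 0.028, 0.028, 0.029, "beta",
           "fraction of cohort", _PROB),
        _p("stage_share_g2", "prevalence", 0.139, 0.138, 0.140, "beta",
           "fraction of cohort", _PROB),
        _p("stage_share_g3a", "prevalence", 0.689, 0.687, 0.690, "beta",
           "fraction of cohort", _PROB),
        _p("stage_share_g3b", "prevalence", 0.144, 0.144, 0.144, "fixed",
           "fraction of cohort", _PROB,
           "complement of the other stage shares in PSA draws"),
        # -- annual composite exit probabilities (progression or death) ----
        _p("exit_g1", "transition", 0.110, 0.106, 0.112, "beta",
           "probability/year", _PROB),
        _p("exit_g2", "transition", 0.088, 0.086, 0.089, "beta",
           "probability/year", _PROB),
        _p("exit_g3a", "transition", 0.105, 0.104, 0.106, "beta",
           "probability/year", _PROB),
        _p("exit_g3b", "transition", 0.150, 0.148, 0.151, "beta",
           "probability/year", _PROB),
        _p("exit_g4", "transition", 0.242, 0.238, 0.246, "beta",
           "probability/year", _PROB),
        _p("exit_g5", "transition", 0.326, 0.316, 0.337, "beta",
           "probability/year", _PROB),
        _p("exit_dialysis", "transition", 0.222, 0.216, 0.228, "beta",
           "probability/year", _PROB),
        _p("exit_kt", "transition", 0.049, 0.036750, 0.061250, "beta",
           "probability/year", _PROB,
           "published range 0.034-0.045 does not bracket the base; "
           "substitute +/-25% range used"),
        _p("exit_post_kt", "transition", 0.077, 0.057750, 0.096250, "beta",
           "probability/year", _PROB,
           "published range 0.059-0.071 does not bracket the base; "
           "substitute +/-25% range used"),
        # -- treatment-effect modifiers ------------------------------------
        _p("hr_comp_tp_g1", "effect_modifier", 0.37, 0.28, 0.46, "normal",
           "hazard ratio", (0.0, 1.0)),
        _p("hr_comp_tp_g2", "effect_modifier", 0.60, 0.45, 0.75, "normal",
           "hazard ratio", (0.0, 1.0)),
        _p("hr_comp_tp_g3a", "effect_modifier", 0.55, 0.45, 0.75, "normal",
           "hazard ratio", (0.0, 1.0)),
        _p("hr_comp_tp_g3b", "effect_modifier", 0.70, 0.45, 0.75, "normal",
           "hazard ratio", (0.0, 1.0)),
        _p("hr_comp_fp", "effect_modifier", 0.95, 0.90, 1.00, "normal",
           "hazard ratio", (0.0, 1.0)),
        _p("rr_pdkf_g1", "effect_modifier", 1.671, 1.651, 1.690, "normal",
           "relative risk", (1.0, math.inf)),
        _p("rr_pdkf_g2", "effect_modifier", 1.986, 1.979, 1.993, "normal",
           "relative risk", (1.0, math.inf)),
        _p("rr_pdkf_g3a", "effect_modifier", 1.579, 1.577, 1.582, "normal",
           "relative risk", (1.0, math.inf)),
        _p("rr_pdkf_g3b", "effect_modifier", 1.315, 1.310, 1.320, "normal",
           "relative risk", (1.0, math.inf)),
        # -- costs (USD, annual unless noted) ------------------------------
        _p("cost_test", "cost", 1050, 854, 1266, "gamma", "USD one-time", _POS),
        _p("cost_g1", "cost", 19164, 15593, 23098, "gamma", "USD/year", _POS),
        _p("cost_g2", "cost", 21264, 17031, 25629, "gamma", "USD/year", _POS),
        _p("cost_g3a", "cost", 34284, 27895, 41322, "gamma", "USD/year", _POS),
        _p("cost_g3b", "cost", 44664, 36340, 53833, "gamma", "USD/year", _POS),
        _p("cost_g4", "cost", 66060, 53749, 79621, "gamma", "USD/year", _POS),
        _p("cost_g5", "cost", 83988, 68336, 101230, "gamma", "USD/year", _POS),
        _p("cost_dialysis", "cost", 147576, 120074, 177872, "gamma",
           "USD/year", _POS),
        _p("cost_kt", "cost", 71958, 53968.50, 89947.50, "gamma", "USD/year",
           _POS,
           "published range $123,340-$182,710 does not bracket the base; "
           "substitute +/-25% range used"),
        _p("cost_post_kt", "cost", 79632, 64792, 95980, "gamma", "USD/year",
           _POS),
        _p("cost_comprehensive_care", "cost", 2655, 1991.25, 3318.75, "gamma",
           "USD/year", _POS,
           "SGLT2i replacement plus additional primary/nephrology visits"),
        _p("cost_education", "cost", 143, 108, 179, "uniform", "USD/year",
           _POS, "dietitian visit $32.53 + CKD education $109.46"),
        # -- health utilities ----------------------------------------------
        _p("utility_constant", "utility", 0.944, 0.892, 0.997, "beta",
           "utility", _PROB),
        _p("utility_age_decrement", "utility", 0.0007, 0.0006, 0.0008, "beta",
           "utility/year of age", _PROB),
        _p("disutility_g1", "utility", 0.150, 0.121, 0.180, "beta", "utility",
           _PROB),
        _p("disutility_g2", "utility", 0.150, 0.121, 0.180, "beta", "utility",
           _PROB),
        _p("disutility_g3a", "utility", 0.200, 0.162, 0.241, "beta", "utility",
           _PROB),
        _p("disutility_g3b", "utility", 0.200, 0.162, 0.241, "beta", "utility",
           _PROB),
        _p("disutility_g4", "utility", 0.260, 0.211, 0.313, "beta", "utility",
           _PROB),
        _p("disutility_g5", "utility", 0.270, 0.219, 0.325, "beta", "utility",
           _PROB),
        _p("disutility_dialysis", "utility", 0.530, 0.426, 0.633, "beta",
           "utility", _PROB),
        _p("disutility_kt", "utility", 0.530, 0.426, 0.633, "beta", "utility",
           _PROB),
        _p("disutility_post_kt", "utility", 0.290, 0.235, 0.348, "beta",
           "utility", _PROB),
    ]
    reg = {e.name: e for e in entries}
    if len(reg) != len(entries):  # pragma: no cover - registry typo guard
        raise ConfigError("duplicate parameter names in registry")
    return reg


#: The canonical registry: the in-code image of the published input table.
REGISTRY: dict[str, ParameterSpec] = _build_registry()


@dataclass
class ModelSettings:
    """Structural switches of the model that are not sampled parameters.

    death_share
        Fraction of each G-stage's composite annual exit probability that is
        death rather than progression to the next severity state.  The source
        rates are "progression to any advanced stage or death" without a
        printed split; 0.5 is the package default (see docs/methods.md).
    kt_entry_rate
        Annual dialysis -> transient-transplant probability; the remainder of
        the dialysis exit mass goes to death.
    kt_cost_blend
        Weight of the transplant state's own cost/disutility in the transient
        transplant cycle (remainder uses post-transplant values); default 0.25
        reflects a 3-month perioperative period in a 1-year cycle.
    """

    stage_specific_prevalence: bool = True
    death_share: float = 0.5
    kt_entry_rate: float = 0.049
    kt_cost_blend: float = 0.25
    comp_care_in_advanced: bool = False
    test_cost_recurring: bool = False
    half_cycle_correction: bool = False
    discount_from_cycle_one: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.death_share <= 1.0:
            raise ConfigError("death_share must be in [0, 1]")
        if not 0.0 <= self.kt_entry_rate <= 1.0:
            raise ConfigError("kt_entry_rate must be in [0, 1]")
        if not 0.0 <= self.kt_cost_blend <= 1.0:
            raise ConfigError("kt_cost_blend must be in [0, 1]")


@dataclass
class InputSet:
    """One complete assignment of values to every registry parameter."""

    values: dict[str, float]
    settings: ModelSettings = field(default_factory=ModelSettings)
    scenario: str = "base_case"

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def replace(self, **updates: float) -> "InputSet":
        """Return a copy with the given parameter values substituted."""
        unknown = set(updates) - set(self.values)
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
        vals = dict(self.values)
        vals.update(updates)
        return InputSet(vals, copy.deepcopy(self.settings), self.scenario)

    def validate(self) -> "InputSet":
        """Check completeness and domain invariants; return self."""
        missing = sorted(set(REGISTRY) - set(self.values))
        if missing:
            raise ConfigError(f"missing parameters: {', '.join(missing)}")
        unknown = sorted(set(self.values) - set(REGISTRY))
        if unknown:
            raise ConfigError(f"unknown parameters: {', '.join(unknown)}")
        for name, spec in REGISTRY.items():
            v = self.values[name]
            if not np.isfinite(v):
                raise ConfigError(f"{name}: non-finite value {v!r}")
            lo, hi = spec.domain
            if not (lo <= v <= hi):
                raise ConfigError(
                    f"{name}: value {v} outside domain [{lo}, {hi}]"
                )
            if spec.group in ("test_performance", "prevalence", "transition") \
                    and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: probability {v} outside [0, 1]")
            if spec.group == "cost" and v < 0:
                raise ConfigError(f"{name}: cost {v} is negative")
            if spec.group == "utility" and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: utility {v} outside [0, 1]")
        self.settings.validate()
        return self


def base_inputs() -> InputSet:
    """The base-case :class:`InputSet` built from the in-code registry."""
    return InputSet({n: s.base for n, s in REGISTRY.items()}).validate()


# --------------------------------------------------------------------------
# config I/O


def _settings_from_mapping(m: Mapping) -> ModelSettings:
    fields = {f.name for f in dataclasses.fields(ModelSettings)}
    unknown = set(m) - fields
    if unknown:
        raise ConfigError(f"unknown settings: {sorted(unknown)}")
    return ModelSettings(**m)


def load_inputs(config_path: str | Path) -> InputSet:
    """Load and validate an :class:`InputSet` from a YAML (or JSON) config."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'parameters' key")
    values: dict[str, float] = {}
    for group, params in doc["parameters"].items():
        if group not in GROUPS:
            raise ConfigError(f"{path}: unknown parameter group {group!r}")
        for name, entry in params.items():
            if name not in REGISTRY:
                raise ConfigError(f"{path}: unknown parameter {name!r}")
            if REGISTRY[name].group != group:
                raise ConfigError(
                    f"{path}: parameter {name!r} listed under group {group!r}, "
                    f"expected {REGISTRY[name].group!r}"
                )
            base = entry["base"] if isinstance(entry, Mapping) else entry
            values[name] = float(base)
    settings = _settings_from_mapping(doc.get("settings", {}) or {})
    scenario_tag = doc.get("scenario", "base_case")
    return InputSet(values, settings, scenario_tag).validate()


def dump_inputs(inputs: InputSet, path: str | Path | None = None) -> str:
    """Serialize an :class:`InputSet` to YAML; optionally write to ``path``."""
    params: dict[str, dict] = {g: {} for g in GROUPS}
    for name, spec in REGISTRY.items():
        entry = {
            "base": inputs.values[name],
            "low": spec.low,
            "high": spec.high,
            "distribution": spec.distribution,
            "units": spec.units,
        }
        if spec.note:
            entry["note"] = spec.note
        params[spec.group][name] = entry
    doc = {
        "scenario": inputs.scenario,
        "settings": dataclasses.asdict(inputs.settings),
        "parameters": params,
    }
    text = yaml.safe_dump(doc, sort_keys=False, width=100)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def default_inputs() -> InputSet:
    """Load the packaged default config (mirrors the in-code registry)."""
    ref = resources.files("dkdcea").joinpath("data/default_inputs.yaml")
    with resources.as_file(ref) as path:
        return load_inputs(path)


# --------------------------------------------------------------------------
# distribution fitting and PSA sampling


def fit_distribution(spec: ParameterSpec) -> dict:
    """Moment-matched hyperparameters for a parameter's PSA distribution.

    Mean is matched to ``base`` and SD to ``(high - low)/3.92`` (the range is
    read as a 95% interval); uniform uses the endpoints.  If a beta moment
    match is infeasible (implied variance >= m(1-m)) the parameter falls back
    to fixed with a logged warning.
    """
    if spec.distribution == "fixed":
        raise ConfigError(f"{spec.name}: fixed parameters have no distribution")
    if spec.distribution == "uniform":
        return {"family": "uniform", "low": spec.low, "high": spec.high}
    m = spec.base
    sd = (spec.high - spec.low) / 3.92
    if sd <= 0:
        log.warning("%s: degenerate range; treating as fixed", spec.name)
        return {"family": "fixed", "value": m}
    if spec.distribution == "beta":
        v = sd * sd
        if not 0.0 < m < 1.0 or v >= m * (1.0 - m):
            log.warning(
                "%s: beta moment match infeasible (m=%g, sd=%g); fixed",
                spec.name, m, sd,
            )
            return {"family": "fixed", "value": m}
        k = m * (1.0 - m) / v - 1.0
        return {"family": "beta", "alpha": m * k, "beta": (1.0 - m) * k}
    if spec.distribution == "gamma":
        if m <= 0:
            raise ConfigError(f"{spec.name}: gamma requires base > 0")
        return {"family": "gamma", "shape": (m / sd) ** 2, "scale": sd * sd / m}
    if spec.distribution == "normal":
        return {"family": "normal", "mean": m, "sd": sd}
    raise ConfigError(f"{spec.name}: unsupported distribution")  # pragma: no cover


def _draw(spec: ParameterSpec, hyper: dict, n: int,
          rng: np.random.Generator) -> np.ndarray:
    fam = hyper["family"]
    if fam == "fixed":
        return np.full(n, hyper["value"])
    if fam == "beta":
        return rng.beta(hyper["alpha"], hyper["beta"], n)
    if fam == "gamma":
        return rng.gamma(hyper["shape"], hyper["scale"], n)
    if fam == "uniform":
        return rng.uniform(hyper["low"], hyper["high"], n)
    # normal: truncate to the parameter domain by resampling
    lo, hi = spec.domain
    x = rng.normal(hyper["mean"], hyper["sd"], n)
    for _ in range(1000):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(hyper["mean"], hyper["sd"], int(bad.sum()))
    return np.clip(x, lo, hi)


def sample_psa(inputs: InputSet, n: int, seed: int) -> list[InputSet]:
    """Draw ``n`` independent PSA input sets from the fitted distributions.

    Parameters flagged ``fixed`` keep their current value.  The stage-share
    of G3b is set to the complement of the other three shares so the initial
    stage distribution remains a distribution in every draw.  Scenario
    adjustments already applied to ``inputs`` (e.g. a 50% prevalence) shift
    the sampled means: distributions are refitted around the current values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for name, spec in REGISTRY.items():
        current = inputs.values[name]
        if spec.distribution == "fixed":
            draws[name] = np.full(n, current)
            continue
        # recenter the spec on the current (possibly scenario-modified) value
        if current != spec.base:
            shift = current - spec.base
            spec = dataclasses.replace(
                spec, base=current, low=spec.low + shift, high=spec.high + shift
            )
        hyper = fit_distribution(spec)
        draws[name] = _draw(spec, hyper, n, rng)
    share_names = ("stage_share_g1", "stage_share_g2", "stage_share_g3a")
    if any(REGISTRY[s].distribution != "fixed" for s in share_names):
        share_rest = sum(draws[s] for s in share_names)
        draws["stage_share_g3b"] = np.clip(1.0 - share_rest, 0.0, 1.0)
    out = []
    for i in range(n):
        vals = {name: float(arr[i]) for name, arr in draws.items()}
        out.append(InputSet(vals, copy.deepcopy(inputs.settings), inputs.scenario))
    return out


# --------------------------------------------------------------------------
# scenarios


SCENARIOS = ("base_case", "liberal", "high_risk")

_TEST_PARAMS = ("aikd_sensitivity", "aikd_specificity",
                "soc_sensitivity", "soc_specificity")


def scenario(inputs: InputSet, tag: str,
             test_overrides: Mapping[str, float] | None = None) -> InputSet:
    """Return the :class:`InputSet` for a named scenario.

    ``high_risk`` sets the prospective-PDKF prevalence to 50% at every initial
    stage; ``liberal`` reruns the model with user-supplied alternative test
    sensitivity/specificity (no defaults are shipped because the source does
    not print the liberal-classification operating points); ``base_case`` is
    the identity.
    """
    if tag not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {tag!r}; expected {SCENARIOS}")
    if tag == "base_case":
        out = inputs.replace()
    elif tag == "high_risk":
        out = inputs.replace(
            pdkf_prevalence_g1=0.50, pdkf_prevalence_g2=0.50,
            pdkf_prevalence_g3a=0.50, pdkf_prevalence_g3b=0.50,
            pdkf_prevalence_overall=0.50,
        )
    else:  # liberal
        if not test_overrides:
            raise ScenarioError(
                "scenario inputs required: the liberal scenario needs "
                f"alternative test performance values for {_TEST_PARAMS}"
            )
        unknown = set(test_overrides) - set(_TEST_PARAMS)
        if unknown:
            raise ScenarioError(
                f"liberal scenario overrides must be test-performance "
                f"parameters; got {sorted(unknown)}"
            )
        out = inputs.replace(**dict(test_overrides))
    out.scenario = tag
    return out.validate()
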