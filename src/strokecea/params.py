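"""Parameter data model, configuration I/O and the packaged base-case fixture.

The model compares two cytoprotective treatment arms for acute ischemic
stroke — edaravone dexborneol (``"edb"``) and human urinary kallidinogenase
(``"huk"``).  Every input the lifetime model needs is collected in a single
:class:`ModelParams` bundle: the day-90 modified Rankin Scale (mRS) outcome
distribution per arm, costs (2021 CNY), health-state utilities, mortality
(life table plus mRS-specific hazard ratios), recurrent-stroke inputs,
economic settings, and the sampling distributions / one-way ranges used by
the sensitivity analyses.

Configuration files are YAML trees mirroring the structure of the published
input tables; :func:`paper_fixture` loads the packaged base-case file.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "ARMS",
    "MRS_STATES",
    "DEATH_STATE",
    "ParamValidationError",
    "MRSDistribution",
    "ArmParams",
    "CostParams",
    "UtilityParams",
    "MortalityParams",
    "RecurrenceParams",
    "EconParams",
    "DistributionSpec",
    "DSARange",
    "ModelParams",
    "load_params",
    "save_params",
    "paper_fixture",
    "get_param_value",
    "set_param_value",
    "params_equal",
]

ARMS = ("edb", "huk")
#: mRS health states 0..6; 6 is the absorbing death state.
MRS_STATES = tuple(range(7))
DEATH_STATE = 6


class ParamValidationError(ValueError):
    """A configuration value violates the model's invariants.

    Carries the dotted path of the offending field in ``field_path``.
    """

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


@dataclass
class MRSDistribution:
    """Probability vector over mRS states 0..6."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)

    def validate(self, path: str = "mrs_distribution") -> None:
        if self.p.shape != (7,):
            raise ParamValidationError(path, f"expected 7 entries, got {self.p.shape}")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ParamValidationError(path, f"entries outside [0, 1]: {self.p}")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ParamValidationError(path, f"entries sum to {self.p.sum():.8f}, not 1")

    def normalized(self) -> "MRSDistribution":
        s = self.p.sum()
        if abs(s - 1.0) < 1e-12:   # keep exact values; round-trips stay stable
            return MRSDistribution(self.p.copy())
        return MRSDistribution(self.p / s)

    @property
    def alive_mass(self) -> float:
        return float(1.0 - self.p[DEATH_STATE])


@dataclass
class ArmParams:
    """Per-arm inputs: day-90 outcome distribution and drug acquisition cost.

    Drug cost is unit price x units/day x treatment days, so one-way
    sensitivity on the unit price scales the whole course cost.
    """

    d90: MRSDistribution
    drug_price_per_unit: float
    units_per_day: float
    treatment_days: int

    @property
    def drug_cost_per_day(self) -> float:
        return self.drug_price_per_unit * self.units_per_day

    @property
    def drug_cost(self) -> float:
        """Total acquisition cost of the treatment course (CNY)."""
        return self.drug_cost_per_day * self.treatment_days


@dataclass
class CostParams:
    hosp_cost_by_group: dict[str, float]         # keys mrs0_2, mrs3_5, mrs6
    annual_post_stroke_cost_by_group: dict[str, float]  # keys mrs0_2, mrs3_5
    hospital_days: float = 0.0

    def validate(self, path: str = "costs") -> None:
        for key in ("mrs0_2", "mrs3_5", "mrs6"):
            if key not in self.hosp_cost_by_group:
                raise ParamValidationError(f"{path}.hospitalization.{key}", "missing")
            if self.hosp_cost_by_group[key] < 0:
                raise ParamValidationError(f"{path}.hospitalization.{key}", "negative cost")
        for key in ("mrs0_2", "mrs3_5"):
            if key not in self.annual_post_stroke_cost_by_group:
                raise ParamValidationError(f"{path}.annual_post_stroke.{key}", "missing")
            if self.annual_post_stroke_cost_by_group[key] < 0:
                raise ParamValidationError(f"{path}.annual_post_stroke.{key}", "negative cost")


@dataclass
class UtilityParams:
    u: np.ndarray                 # annual QALY weight for mRS 0..5
    stroke_disutility: float      # decrement applied in the year of a stroke

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)

    def validate(self, path: str = "utilities") -> None:
        if self.u.shape != (6,):
            raise ParamValidationError(f"{path}.mrs", "expected 6 utilities (mRS 0..5)")
        for s, val in enumerate(self.u):
            if not 0.0 <= val <= 1.0:
                raise ParamValidationError(f"{path}.mrs[{s}]", f"utility {val} outside [0, 1]")
        if not 0.0 <= self.stroke_disutility <= 1.0:
            raise ParamValidationError(
                f"{path}.stroke_disutility",
                f"disutility {self.stroke_disutility} outside [0, 1]",
            )


@dataclass
class MortalityParams:
    """Life-table mortality with mRS-specific excess-mortality hazard ratios."""

    life_table: list[tuple[int, int | None, float]]  # (age_lo, age_hi, annual prob)
    hr: np.ndarray                                   # hazard ratio, mRS 0..5

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)

    def validate(self, path: str = "mortality") -> None:
        if not self.life_table:
            raise ParamValidationError(f"{path}.life_table", "empty")
        for i, (lo, hi, q) in enumerate(self.life_table):
            if not 0.0 < q < 1.0:
                raise ParamValidationError(f"{path}.life_table[{i}]", f"probability {q} outside (0, 1)")
            if hi is not None and hi < lo:
                raise ParamValidationError(f"{path}.life_table[{i}]", "age_hi < age_lo")
        if self.life_table[-1][1] is not None:
            raise ParamValidationError(f"{path}.life_table", "last band must be open-ended (age_hi null)")
        if self.hr.shape != (6,):
            raise ParamValidationError(f"{path}.hazard_ratios", "expected 6 hazard ratios (mRS 0..5)")
        for s, h in enumerate(self.hr):
            if h <= 0:
                raise ParamValidationError(f"{path}.hazard_ratios[{s}]", f"hazard ratio {h} must be > 0")


@dataclass
class RecurrenceParams:
    """Recurrent-stroke risk and post-recurrence state redistribution.

    ``redistribution[post, pre]`` is the probability of landing in state
    ``post`` given a recurrence while in state ``pre`` *and* surviving it.
    The per-column remainder to 1 is the recurrence case fatality.
    """

    annual_recurrence_prob: np.ndarray   # years 1..len since index stroke
    late_recurrence_prob: float          # beyond the tabulated years
    redistribution: np.ndarray           # 6x6, [post, pre]

    def __post_init__(self) -> None:
        self.annual_recurrence_prob = np.asarray(self.annual_recurrence_prob, dtype=float)
        self.redistribution = np.asarray(self.redistribution, dtype=float)

    @property
    def case_fatality(self) -> np.ndarray:
        """Per-pre-state probability of death given recurrence."""
        return 1.0 - self.redistribution.sum(axis=0)

    def validate(self, path: str = "recurrence") -> None:
        for i, r in enumerate(self.annual_recurrence_prob):
            if not 0.0 <= r < 1.0:
                raise ParamValidationError(f"{path}.annual_prob[{i}]", f"probability {r} outside [0, 1)")
        if not 0.0 <= self.late_recurrence_prob < 1.0:
            raise ParamValidationError(f"{path}.annual_prob_late", "probability outside [0, 1)")
        if self.redistribution.shape != (6, 6):
            raise ParamValidationError(f"{path}.redistribution", "expected a 6x6 matrix")
        if np.any(self.redistribution < 0):
            raise ParamValidationError(f"{path}.redistribution", "negative entry")
        for pre in range(6):
            col_sum = self.redistribution[:, pre].sum()
            if col_sum > 1.0 + 1e-9:
                raise ParamValidationError(
                    f"{path}.redistribution[:, {pre}]", f"column sums to {col_sum} > 1"
                )
            # disability never improves after a recurrence
            if np.any(self.redistribution[:pre, pre] > 0):
                raise ParamValidationError(
                    f"{path}.redistribution[:, {pre}]",
                    "mass on a post-recurrence state milder than the pre-recurrence state",
                )


@dataclass
class EconParams:
    discount_rate_cost: float = 0.05
    discount_rate_outcome: float = 0.05
    wtp: float = 80976.0
    horizon_cycles: int = 40
    cycle_length: float = 1.0
    start_age: int = 60

    def validate(self, path: str = "economics") -> None:
        for name in ("discount_rate_cost", "discount_rate_outcome"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.2:
                raise ParamValidationError(f"{path}.{name}", f"rate {r} outside [0, 0.2]")
        if self.horizon_cycles < 1:
            raise ParamValidationError(f"{path}.horizon_cycles", "must be >= 1")
        if self.wtp < 0:
            raise ParamValidationError(f"{path}.wtp", "negative willingness-to-pay")


@dataclass
class DistributionSpec:
    """Second-order sampling distribution of one parameter.

    gamma(shape=alpha, scale=beta); beta(alpha, beta);
    lognormal(log-mean=alpha, log-sd=beta); ``fixed`` holds ``value``.
    """

    family: str
    alpha: float = 0.0
    beta: float = 0.0
    value: float = 0.0

    FAMILIES = ("gamma", "beta", "lognormal", "fixed")

    def validate(self, path: str) -> None:
        if self.family not in self.FAMILIES:
            raise ParamValidationError(path, f"unknown family {self.family!r}")
        if self.family in ("gamma", "beta") and (self.alpha <= 0 or self.beta <= 0):
            raise ParamValidationError(path, "alpha and beta must be > 0")
        if self.family == "lognormal" and self.beta <= 0:
            raise ParamValidationError(path, "log-sd must be > 0")

    def mean_or_median(self) -> float:
        """Base-value check: gamma/beta mean, lognormal median."""
        if self.family == "gamma":
            return self.alpha * self.beta
        if self.family == "beta":
            return self.alpha / (self.alpha + self.beta)
        if self.family == "lognormal":
            return float(np.exp(self.alpha))
        return self.value


@dataclass
class DSARange:
    param: str
    low: float
    high: float

    def validate(self, path: str) -> None:
        if self.low > self.high:
            raise ParamValidationError(path, f"low {self.low} > high {self.high}")


@dataclass
class ModelParams:
    """Complete input bundle for the lifetime cost-effectiveness model."""

    arms: dict[str, ArmParams]
    initial_mrs01_split: tuple[float, float]
    costs: CostParams
    utilities: UtilityParams
    mortality: MortalityParams
    recurrence: RecurrenceParams
    econ: EconParams
    psa_specs: dict[str, DistributionSpec] = field(default_factory=dict)
    dsa_ranges: list[DSARange] = field(default_factory=list)

    def validate(self) -> None:
        for name in ARMS:
            if name not in self.arms:
                raise ParamValidationError(f"arms.{name}", "missing arm")
            arm = self.arms[name]
            arm.d90.validate(f"arms.{name}.d90")
            if arm.drug_price_per_unit < 0 or arm.units_per_day < 0:
                raise ParamValidationError(f"arms.{name}", "negative drug price inputs")
            if arm.treatment_days < 0:
                raise ParamValidationError(f"arms.{name}.treatment_days", "negative")
        if abs(sum(self.initial_mrs01_split) - 1.0) > 1e-9:
            raise ParamValidationError("initial_mrs01_split", "must sum to 1")
        self.costs.validate()
        self.utilities.validate()
        self.mortality.validate()
        self.recurrence.validate()
        self.econ.validate()
        for pid, spec in self.psa_specs.items():
            spec.validate(f"psa.{pid}")
            if pid not in _PARAM_REGISTRY:
                raise ParamValidationError(f"psa.{pid}", "unknown parameter id")
        for rng in self.dsa_ranges:
            rng.validate(f"dsa.{rng.param}")
            if rng.param not in _PARAM_REGISTRY:
                raise ParamValidationError(f"dsa.{rng.param}", "unknown parameter id")
            base = get_param_value(self, rng.param)
            if not rng.low - 1e-9 <= base <= rng.high + 1e-9:
                raise ParamValidationError(
                    f"dsa.{rng.param}", f"base value {base} outside [{rng.low}, {rng.high}]"
                )

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Named-parameter registry (shared by the DSA and PSA machinery)

def _arm_price(arm: str):
    return (
        lambda p: p.arms[arm].drug_price_per_unit,
        lambda p, v: setattr(p.arms[arm], "drug_price_per_unit", v),
    )


def _hosp(key: str):
    return (
        lambda p: p.costs.hosp_cost_by_group[key],
        lambda p, v: p.costs.hosp_cost_by_group.__setitem__(key, v),
    )


def _post(key: str):
    return (
        lambda p: p.costs.annual_post_stroke_cost_by_group[key],
        lambda p, v: p.costs.annual_post_stroke_cost_by_group.__setitem__(key, v),
    )


def _utility(s: int):
    return (
        lambda p: float(p.utilities.u[s]),
        lambda p, v: p.utilities.u.__setitem__(s, v),
    )


def _hr(s: int):
    return (
        lambda p: float(p.mortality.hr[s]),
        lambda p, v: p.mortality.hr.__setitem__(s, v),
    )


_PARAM_REGISTRY: dict[str, tuple] = {
    "drug_price_edb": _arm_price("edb"),
    "drug_price_huk": _arm_price("huk"),
    "hosp_cost_mrs0_2": _hosp("mrs0_2"),
    "hosp_cost_mrs3_5": _hosp("mrs3_5"),
    "hosp_cost_mrs6": _hosp("mrs6"),
    "post_cost_mrs0_2": _post("mrs0_2"),
    "post_cost_mrs3_5": _post("mrs3_5"),
    **{f"utility_mrs{s}": _utility(s) for s in range(6)},
    "stroke_disutility": (
        lambda p: p.utilities.stroke_disutility,
        lambda p, v: setattr(p.utilities, "stroke_disutility", v),
    ),
    **{f"hr_mrs{s}": _hr(s) for s in range(6)},
    "discount_rate_cost": (
        lambda p: p.econ.discount_rate_cost,
        lambda p, v: setattr(p.econ, "discount_rate_cost", v),
    ),
    "discount_rate_outcome": (
        lambda p: p.econ.discount_rate_outcome,
        lambda p, v: setattr(p.econ, "discount_rate_outcome", v),
    ),
}


def parameter_ids() -> Iterator[str]:
    return iter(_PARAM_REGISTRY)


def get_param_value(params: ModelParams, pid: str) -> float:
    """Read a named scalar parameter (see :func:`parameter_ids`)."""
    getter, _ = _PARAM_REGISTRY[pid]
    return float(getter(params))


def set_param_value(params: ModelParams, pid: str, value: float) -> ModelParams:
    """Return a deep copy of ``params`` with one named parameter replaced."""
    out = params.copy()
    _, setter = _PARAM_REGISTRY[pid]
    setter(out, float(value))
    return out


def set_param_inplace(params: ModelParams, pid: str, value: float) -> None:
    """Mutate one named parameter in place (hot path for Monte Carlo draws)."""
    _, setter = _PARAM_REGISTRY[pid]
    setter(params, float(value))


# ---------------------------------------------------------------------------
# Configuration I/O

def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ParamValidationError(f"{path}.{key}", "missing key")
    return mapping[key]


def _params_from_dict(cfg: dict) -> ModelParams:
    arms = {}
    arms_cfg = _require(cfg, "arms", "")
    for name in ARMS:
        a = _require(arms_cfg, name, "arms")
        arms[name] = ArmParams(
            d90=MRSDistribution(np.asarray(_require(a, "d90", f"arms.{name}"), dtype=float)).normalized(),
            drug_price_per_unit=float(_require(a, "drug_price_per_unit", f"arms.{name}")),
            units_per_day=float(_require(a, "units_per_day", f"arms.{name}")),
            treatment_days=int(_require(a, "treatment_days", f"arms.{name}")),
        )
    costs_cfg = _require(cfg, "costs", "")
    costs = CostParams(
        hosp_cost_by_group={k: float(v) for k, v in _require(costs_cfg, "hospitalization", "costs").items()},
        annual_post_stroke_cost_by_group={
            k: float(v) for k, v in _require(costs_cfg, "annual_post_stroke", "costs").items()
        },
        hospital_days=float(costs_cfg.get("hospital_days", 0.0)),
    )
    util_cfg = _require(cfg, "utilities", "")
    utilities = UtilityParams(
        u=np.asarray(_require(util_cfg, "mrs", "utilities"), dtype=float),
        stroke_disutility=float(_require(util_cfg, "stroke_disutility", "utilities")),
    )
    mort_cfg = _require(cfg, "mortality", "")
    life_table = [
        (int(row["age_lo"]), None if row["age_hi"] is None else int(row["age_hi"]), float(row["q"]))
        for row in _require(mort_cfg, "life_table", "mortality")
    ]
    mortality = MortalityParams(
        life_table=life_table,
        hr=np.asarray(_require(mort_cfg, "hazard_ratios", "mortality"), dtype=float),
    )
    rec_cfg = _require(cfg, "recurrence", "")
    recurrence = RecurrenceParams(
        annual_recurrence_prob=np.asarray(_require(rec_cfg, "annual_prob", "recurrence"), dtype=float),
        late_recurrence_prob=float(_require(rec_cfg, "annual_prob_late", "recurrence")),
        redistribution=np.asarray(_require(rec_cfg, "redistribution", "recurrence"), dtype=float),
    )
    econ_cfg = _require(cfg, "economics", "")
    econ = EconParams(
        discount_rate_cost=float(_require(econ_cfg, "discount_rate_cost", "economics")),
        discount_rate_outcome=float(_require(econ_cfg, "discount_rate_outcome", "economics")),
        wtp=float(_require(econ_cfg, "wtp", "economics")),
        horizon_cycles=int(_require(econ_cfg, "horizon_cycles", "economics")),
        cycle_length=float(econ_cfg.get("cycle_length", 1.0)),
        start_age=int(_require(econ_cfg, "start_age", "economics")),
    )
    psa_specs = {}
    for pid, spec in (cfg.get("psa") or {}).items():
        psa_specs[pid] = DistributionSpec(
            family=str(_require(spec, "family", f"psa.{pid}")),
            alpha=float(spec.get("alpha", 0.0)),
            beta=float(spec.get("beta", 0.0)),
            value=float(spec.get("value", 0.0)),
        )
    dsa_ranges = [
        DSARange(param=str(_require(r, "param", "dsa")), low=float(r["low"]), high=float(r["high"]))
        for r in (cfg.get("dsa") or [])
    ]
    split = cfg.get("initial_mrs01_split", [1.0, 0.0])
    params = ModelParams(
        arms=arms,
        initial_mrs01_split=(float(split[0]), float(split[1])),
        costs=costs,
        utilities=utilities,
        mortality=mortality,
        recurrence=recurrence,
        econ=econ,
        psa_specs=psa_specs,
        dsa_ranges=dsa_ranges,
    )
    params.validate()
    return params


def load_params(config_path: str | Path) -> ModelParams:
    """Load and validate a model configuration from a YAML file."""
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParamValidationError("<root>", "configuration must be a mapping")
    return _params_from_dict(cfg)


def _params_to_dict(p: ModelParams) -> dict:
    return {
        "arms": {
            name: {
                "d90": [float(x) for x in arm.d90.p],
                "drug_price_per_unit": arm.drug_price_per_unit,
                "units_per_day": arm.units_per_day,
                "treatment_days": arm.treatment_days,
            }
            for name, arm in p.arms.items()
        },
        "initial_mrs01_split": list(p.initial_mrs01_split),
        "costs": {
            "hospitalization": dict(p.costs.hosp_cost_by_group),
            "annual_post_stroke": dict(p.costs.annual_post_stroke_cost_by_group),
            "hospital_days": p.costs.hospital_days,
        },
        "utilities": {
            "mrs": [float(x) for x in p.utilities.u],
            "stroke_disutility": p.utilities.stroke_disutility,
        },
        "mortality": {
            "life_table": [
                {"age_lo": lo, "age_hi": hi, "q": q} for lo, hi, q in p.mortality.life_table
            ],
            "hazard_ratios": [float(x) for x in p.mortality.hr],
        },
        "recurrence": {
            "annual_prob": [float(x) for x in p.recurrence.annual_recurrence_prob],
            "annual_prob_late": p.recurrence.late_recurrence_prob,
            "redistribution": [[float(x) for x in row] for row in p.recurrence.redistribution],
        },
        "economics": {
            "discount_rate_cost": p.econ.discount_rate_cost,
            "discount_rate_outcome": p.econ.discount_rate_outcome,
            "wtp": p.econ.wtp,
            "horizon_cycles": p.econ.horizon_cycles,
            "cycle_length": p.econ.cycle_length,
            "start_age": p.econ.start_age,
        },
        "psa": {
            pid: {"family": s.family, "alpha": s.alpha, "beta": s.beta, "value": s.value}
            for pid, s in p.psa_specs.items()
        },
        "dsa": [{"param": r.param, "low": r.low, "high": r.high} for r in p.dsa_ranges],
    }


def save_params(params: ModelParams, config_path: str | Path) -> None:
    """Write a configuration file that :func:`load_params` round-trips."""
    with open(config_path, "w") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)


def params_equal(a: ModelParams, b: ModelParams, atol: float = 0.0) -> bool:
    """Field-by-field equality of two parameter bundles."""
    da, db = _params_to_dict(a), _params_to_dict(b)

    def eq(x, y) -> bool:
        if isinstance(x, dict):
            return isinstance(y, dict) and x.keys() == y.keys() and all(eq(x[k], y[k]) for k in x)
        if isinstance(x, (list, tuple)):
            return len(x) == len(y) and all(eq(u, v) for u, v in zip(x, y))
        if isinstance(x, float) or isinstance(y, float):
            return abs(float(x) - float(y)) <= atol
        return x == y

    return eq(da, db)


def fixture_path() -> Path:
    """Path of the packaged base-case configuration file."""
    ref = importlib.resources.files("strokecea") / "data" / "paper_2021_cny.yaml"
    return Path(str(ref))


def paper_fixture() -> ModelParams:
    """The published base-case parameter set (2021 CNY)."""
    return load_params(fixture_path())
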