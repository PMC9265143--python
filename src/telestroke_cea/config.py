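"""Model configuration: domain types, validation, defaults, YAML I/O.

The configuration gathers every input of the long-term telestroke
cost-effectiveness model: annual transition probabilities (recurrent
stroke, case fatality, background-mortality hazard ratios by modified
Rankin Scale score), per-state costs and utility weights, economic
settings (discount rate, horizon, willingness-to-pay), the per-arm
day-365 mRS distributions and first-year cost/outcome inputs, and an
age-indexed life table.

The packaged default carries the literature-calibrated base-case values
for the Australian telestroke evaluation (2018 AUD, annual cycles);
its baselines and life table are synthetic stand-ins produced by
:mod:`telestroke_cea.synthetic` because the underlying patient-level
trial data are not public.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

#: Living disability levels (modified Rankin Scale 0-5).
MRS = tuple(f"mRS{i}" for i in range(6))
#: Day-365 outcome categories, including death within the first year (mRS 6).
MRS7 = tuple(f"mRS{i}" for i in range(7))

ARMS = ("intervention", "control")
PERSPECTIVES = ("societal", "healthcare")

COST_COMPONENTS = (
    "first12mo",
    "program",
    "management",
    "rehospitalisation",
    "nursing_home",
    "nonmedical",
)


class ConfigError(ValueError):
    """Raised on schema or invariant violations in a model configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class TransitionParams:
    """Annual transition inputs shared by both treatment arms.

    ``hr_mortality`` multiplies the background (all-other-cause) hazard on
    the log-survival scale per mRS level.  ``worsening_matrix`` (6x6,
    row-stochastic, zero below the diagonal) redistributes survivors of a
    recurrent stroke over equal-or-worse mRS states; ``None`` means derive
    it at run time from the arm's day-365 distribution.
    """

    p_recur_year1: float
    p_recur_later: float
    rr_recur_after_recur: float
    p_death_after_recur: float
    hr_mortality: np.ndarray  # (6,) indexed by mRS 0..5
    worsening_matrix: np.ndarray | None = None  # (6, 6)

    def __post_init__(self) -> None:
        self.hr_mortality = np.asarray(self.hr_mortality, dtype=float)
        if self.worsening_matrix is not None:
            self.worsening_matrix = np.asarray(self.worsening_matrix, dtype=float)


@dataclass(eq=False)
class CostParams:
    """Per-state annual costs (2018 AUD).

    ``rehosp`` prices a recurrent-stroke admission by destination state
    (the mRS 6 row prices fatal recurrences).  ``mgmt_year1`` applies to the
    year of a modelled recurrence, ``mgmt_later`` to every other living
    person-year.  ``nonmedical`` and ``p_nonmedical_use`` cover informal and
    community care (societal perspective only, mRS 1-5); ``nursing_home``
    accrues for person-time in mRS 4-5.
    """

    rehosp: np.ndarray  # (7,) mRS0..mRS6, $/event
    mgmt_year1: np.ndarray  # (6,) $/yr
    mgmt_later: np.ndarray  # (6,) $/yr
    nonmedical: np.ndarray  # (6,) $/yr; mRS0 entry is structurally 0
    p_nonmedical_use: np.ndarray  # (6,) probability; mRS0 entry 0
    nursing_home: float  # $/yr, mRS4-5 only
    program_cost_per_patient: float
    program_total_implementation: float
    first12mo_note: str = "per-arm first-12-month costs live in ArmBaseline"

    def __post_init__(self) -> None:
        for name in ("rehosp", "mgmt_year1", "mgmt_later", "nonmedical", "p_nonmedical_use"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(eq=False)
class UtilityParams:
    """EQ-5D utility weights by mRS level; death is fixed at 0."""

    utility: np.ndarray  # (6,)

    def __post_init__(self) -> None:
        self.utility = np.asarray(self.utility, dtype=float)


@dataclass
class EconSettings:
    discount_rate: float = 0.03
    horizon_years: int = 25
    start_age: int = 74
    wtp: float = 50_000.0
    cohort_size: int = 10_000
    perspective: str = "societal"
    half_cycle_correction: bool = False


@dataclass(eq=False)
class ArmBaseline:
    """Per-arm model entry conditions.

    ``mrs_day365`` is the day-365 outcome distribution over mRS 0-6; the
    mRS 6 mass (died during the first year) enters the engine as stroke
    death at cycle 0 and contributes only first-12-month costs.
    """

    arm: str
    mrs_day365: np.ndarray  # (7,) sums to 1
    first12mo_cost_societal: float
    first12mo_cost_healthcare: float
    first12mo_qaly: float
    first12mo_ly: float

    def __post_init__(self) -> None:
        self.mrs_day365 = np.asarray(self.mrs_day365, dtype=float)


@dataclass(eq=False)
class ModelConfig:
    transition: TransitionParams
    costs: CostParams
    utilities: UtilityParams
    settings: EconSettings
    baselines: dict[str, ArmBaseline]
    life_table: dict[int, float]
    baseline_provenance: str = "synthetic"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        t, c, u, s = self.transition, self.costs, self.utilities, self.settings
        d: dict[str, Any] = {
            "transition": {
                "p_recur_year1": float(t.p_recur_year1),
                "p_recur_later": float(t.p_recur_later),
                "rr_recur_after_recur": float(t.rr_recur_after_recur),
                "p_death_after_recur": float(t.p_death_after_recur),
                "hr_mortality": _label(t.hr_mortality, MRS),
                "worsening_matrix": None
                if t.worsening_matrix is None
                else {MRS[k]: _label(t.worsening_matrix[k], MRS) for k in range(6)},
            },
            "costs": {
                "rehosp": _label(c.rehosp, MRS7),
                "mgmt_year1": _label(c.mgmt_year1, MRS),
                "mgmt_later": _label(c.mgmt_later, MRS),
                "nonmedical": _label(c.nonmedical[1:], MRS[1:]),
                "p_nonmedical_use": _label(c.p_nonmedical_use[1:], MRS[1:]),
                "nursing_home": float(c.nursing_home),
                "program_cost_per_patient": float(c.program_cost_per_patient),
                "program_total_implementation": float(c.program_total_implementation),
            },
            "utilities": _label(u.utility, MRS),
            "settings": {
                "discount_rate": float(s.discount_rate),
                "horizon_years": int(s.horizon_years),
                "start_age": int(s.start_age),
                "wtp": float(s.wtp),
                "cohort_size": int(s.cohort_size),
                "perspective": s.perspective,
                "half_cycle_correction": bool(s.half_cycle_correction),
            },
            "baselines": {
                arm: {
                    "mrs_day365": [float(v) for v in b.mrs_day365],
                    "first12mo_cost_societal": float(b.first12mo_cost_societal),
                    "first12mo_cost_healthcare": float(b.first12mo_cost_healthcare),
                    "first12mo_qaly": float(b.first12mo_qaly),
                    "first12mo_ly": float(b.first12mo_ly),
                }
                for arm, b in self.baselines.items()
            },
            "life_table": {int(a): float(q) for a, q in sorted(self.life_table.items())},
            "baseline_provenance": self.baseline_provenance,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        _require_keys(d, {"transition", "costs", "utilities", "settings", "baselines", "life_table"}, "config", optional={"baseline_provenance"})
        td = d["transition"]
        _require_keys(
            td,
            {"p_recur_year1", "p_recur_later", "rr_recur_after_recur", "p_death_after_recur", "hr_mortality"},
            "transition",
            optional={"worsening_matrix"},
        )
        wm = td.get("worsening_matrix")
        transition = TransitionParams(
            p_recur_year1=float(td["p_recur_year1"]),
            p_recur_later=float(td["p_recur_later"]),
            rr_recur_after_recur=float(td["rr_recur_after_recur"]),
            p_death_after_recur=float(td["p_death_after_recur"]),
            hr_mortality=_unlabel(td["hr_mortality"], MRS, "transition.hr_mortality"),
            worsening_matrix=None
            if wm is None
            else np.array([_unlabel(wm[k], MRS, f"worsening_matrix.{k}") for k in MRS]),
        )
        cd = d["costs"]
        _require_keys(
            cd,
            {"rehosp", "mgmt_year1", "mgmt_later", "nonmedical", "p_nonmedical_use", "nursing_home", "program_cost_per_patient", "program_total_implementation"},
            "costs",
        )
        costs = CostParams(
            rehosp=_unlabel(cd["rehosp"], MRS7, "costs.rehosp"),
            mgmt_year1=_unlabel(cd["mgmt_year1"], MRS, "costs.mgmt_year1"),
            mgmt_later=_unlabel(cd["mgmt_later"], MRS, "costs.mgmt_later"),
            nonmedical=np.concatenate([[0.0], _unlabel(cd["nonmedical"], MRS[1:], "costs.nonmedical")]),
            p_nonmedical_use=np.concatenate([[0.0], _unlabel(cd["p_nonmedical_use"], MRS[1:], "costs.p_nonmedical_use")]),
            nursing_home=float(cd["nursing_home"]),
            program_cost_per_patient=float(cd["program_cost_per_patient"]),
            program_total_implementation=float(cd["program_total_implementation"]),
        )
        utilities = UtilityParams(utility=_unlabel(d["utilities"], MRS, "utilities"))
        sd = d["settings"]
        _require_keys(
            sd,
            {"discount_rate", "horizon_years", "start_age", "wtp", "cohort_size", "perspective"},
            "settings",
            optional={"half_cycle_correction"},
        )
        settings = EconSettings(
            discount_rate=float(sd["discount_rate"]),
            horizon_years=int(sd["horizon_years"]),
            start_age=int(sd["start_age"]),
            wtp=float(sd["wtp"]),
            cohort_size=int(sd["cohort_size"]),
            perspective=str(sd["perspective"]),
            half_cycle_correction=bool(sd.get("half_cycle_correction", False)),
        )
        baselines = {}
        for arm in ARMS:
            if arm not in d["baselines"]:
                raise ConfigError(f"baselines: missing arm '{arm}'")
            bd = d["baselines"][arm]
            _require_keys(
                bd,
                {"mrs_day365", "first12mo_cost_societal", "first12mo_cost_healthcare", "first12mo_qaly", "first12mo_ly"},
                f"baselines.{arm}",
            )
            baselines[arm] = ArmBaseline(
                arm=arm,
                mrs_day365=np.asarray(bd["mrs_day365"], dtype=float),
                first12mo_cost_societal=float(bd["first12mo_cost_societal"]),
                first12mo_cost_healthcare=float(bd["first12mo_cost_healthcare"]),
                first12mo_qaly=float(bd["first12mo_qaly"]),
                first12mo_ly=float(bd["first12mo_ly"]),
            )
        life_table = {int(a): float(q) for a, q in d["life_table"].items()}
        return cls(
            transition=transition,
            costs=costs,
            utilities=utilities,
            settings=settings,
            baselines=baselines,
            life_table=life_table,
            baseline_provenance=str(d.get("baseline_provenance", "synthetic")),
        )

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelConfig):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _label(values: np.ndarray, labels: tuple[str, ...]) -> dict[str, float]:
    return {lab: float(v) for lab, v in zip(labels, values)}


def _unlabel(d: Any, labels: tuple[str, ...], where: str) -> np.ndarray:
    if not isinstance(d, dict):
        raise ConfigError(f"{where}: expected a mapping keyed by {labels[0]}..{labels[-1]}")
    unknown = set(d) - set(labels)
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    missing = set(labels) - set(d)
    if missing:
        raise ConfigError(f"{where}: missing keys {sorted(missing)}")
    return np.array([float(d[lab]) for lab in labels])


def _require_keys(d: Any, required: set[str], where: str, optional: set[str] = frozenset()) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{where}: expected a mapping")
    unknown = set(d) - required - set(optional)
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"{where}: missing keys {sorted(missing)}")


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

#: Literature base-case values (2018 AUD, annual probabilities).
TABLE1 = {
    "p_recur_year1": 0.0649,
    "p_recur_later": 0.0201,
    "rr_recur_after_recur": 1.48,
    "p_death_after_recur": 0.1783,
    "p_death_after_recur_alt": 0.11,  # low alternative used in sensitivity analysis
    "hr_mortality": (1.53, 1.52, 2.17, 3.18, 4.55, 6.55),
    "rehosp": (10_886.0, 10_086.0, 16_662.0, 16_662.0, 22_086.0, 22_086.0, 10_886.0),
    "mgmt_year1": (10_499.0, 13_230.0, 15_943.0, 17_540.0, 20_772.0, 24_169.0),
    "mgmt_later": (1_431.0, 1_814.0, 1_814.0, 1_814.0, 1_814.0, 1_814.0),
    "nonmedical": (1_318.0, 2_231.0, 5_430.0, 6_552.0, 24_420.0),  # mRS1..mRS5
    "p_nonmedical_use": (0.9138, 0.8431, 0.9070, 0.8963, 0.9232),  # mRS1..mRS5
    "nursing_home": 40_689.0,
    "program_cost_per_patient": 2_959.0,
    "program_total_implementation": 1_762_892.0,
    "utility": (0.836, 0.777, 0.694, 0.437, 0.242, 0.064),
}


def base_parameters() -> tuple[TransitionParams, CostParams, UtilityParams, EconSettings]:
    """The base-case parameter blocks, without baselines or a life table."""
    t = TABLE1
    transition = TransitionParams(
        p_recur_year1=t["p_recur_year1"],
        p_recur_later=t["p_recur_later"],
        rr_recur_after_recur=t["rr_recur_after_recur"],
        p_death_after_recur=t["p_death_after_recur"],
        hr_mortality=np.array(t["hr_mortality"]),
        worsening_matrix=None,
    )
    costs = CostParams(
        rehosp=np.array(t["rehosp"]),
        mgmt_year1=np.array(t["mgmt_year1"]),
        mgmt_later=np.array(t["mgmt_later"]),
        nonmedical=np.concatenate([[0.0], t["nonmedical"]]),
        p_nonmedical_use=np.concatenate([[0.0], t["p_nonmedical_use"]]),
        nursing_home=t["nursing_home"],
        program_cost_per_patient=t["program_cost_per_patient"],
        program_total_implementation=t["program_total_implementation"],
    )
    utilities = UtilityParams(utility=np.array(t["utility"]))
    settings = EconSettings()
    return transition, costs, utilities, settings


DEFAULT_SEED = 0


def default_config(seed: int = DEFAULT_SEED) -> "ModelConfig":
    """Base-case configuration with synthetic baselines and life table.

    Every shared parameter takes its literature base-case value; the
    per-arm day-365 mRS distributions and the life table, which are not
    public, come from :func:`telestroke_cea.synthetic.make_fixture`.
    """
    from . import synthetic  # late import: synthetic builds on this module

    return synthetic.make_fixture(seed)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_config(cfg: ModelConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v: list[str] = []
    t, c, u, s = cfg.transition, cfg.costs, cfg.utilities, cfg.settings

    for name in ("p_recur_year1", "p_recur_later", "p_death_after_recur"):
        p = getattr(t, name)
        if not 0.0 <= p <= 1.0:
            v.append(f"transition.{name}={p}: probability must lie in [0, 1]")
    if t.rr_recur_after_recur <= 0:
        v.append(f"transition.rr_recur_after_recur={t.rr_recur_after_recur}: must be > 0")
    if t.hr_mortality.shape != (6,):
        v.append("transition.hr_mortality: expected 6 entries (mRS0..mRS5)")
    elif np.any(t.hr_mortality <= 0):
        v.append(f"transition.hr_mortality={t.hr_mortality.tolist()}: hazard ratios must be > 0")
    if t.worsening_matrix is not None:
        W = t.worsening_matrix
        if W.shape != (6, 6):
            v.append("transition.worsening_matrix: expected a 6x6 matrix")
        else:
            if np.any(W < -1e-12):
                v.append("transition.worsening_matrix: negative entries")
            rows = W.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                v.append(f"transition.worsening_matrix: rows must sum to 1 (got {rows.tolist()})")
            if any(abs(W[k, j]) > 1e-12 for k in range(6) for j in range(k)):
                v.append(
                    "transition.worsening_matrix: mass on destinations better than the "
                    "origin violates the equal-or-worse recurrence rule"
                )

    for name in ("rehosp", "mgmt_year1", "mgmt_later", "nonmedical"):
        arr = getattr(c, name)
        if np.any(arr < 0):
            v.append(f"costs.{name}={arr.tolist()}: costs must be >= 0")
    if np.any((c.p_nonmedical_use < 0) | (c.p_nonmedical_use > 1)):
        v.append(f"costs.p_nonmedical_use={c.p_nonmedical_use.tolist()}: probabilities must lie in [0, 1]")
    for name in ("nursing_home", "program_cost_per_patient", "program_total_implementation"):
        if getattr(c, name) < 0:
            v.append(f"costs.{name}={getattr(c, name)}: must be >= 0")

    if u.utility.shape != (6,):
        v.append("utilities: expected 6 entries (mRS0..mRS5)")
    elif np.any((u.utility < -1) | (u.utility > 1)):
        v.append(f"utilities={u.utility.tolist()}: weights must lie in [-1, 1]")

    if s.discount_rate < 0:
        v.append(f"settings.discount_rate={s.discount_rate}: must be >= 0")
    if s.horizon_years < 1:
        v.append(f"settings.horizon_years={s.horizon_years}: must be >= 1")
    if s.cohort_size < 1:
        v.append(f"settings.cohort_size={s.cohort_size}: must be >= 1")
    if s.perspective not in PERSPECTIVES:
        v.append(f"settings.perspective={s.perspective!r}: must be one of {PERSPECTIVES}")

    for arm in ARMS:
        if arm not in cfg.baselines:
            v.append(f"baselines: missing arm '{arm}'")
            continue
        b = cfg.baselines[arm]
        if b.mrs_day365.shape != (7,):
            v.append(f"baselines.{arm}.mrs_day365: expected 7 entries (mRS0..mRS6)")
            continue
        if np.any(b.mrs_day365 < 0):
            v.append(f"baselines.{arm}.mrs_day365={b.mrs_day365.tolist()}: entries must be >= 0")
        if abs(b.mrs_day365.sum() - 1.0) > 1e-9:
            v.append(
                f"baselines.{arm}.mrs_day365 sums to {b.mrs_day365.sum():.12f}: must sum to 1 within 1e-9"
            )
        for name in ("first12mo_cost_societal", "first12mo_cost_healthcare"):
            if getattr(b, name) < 0:
                v.append(f"baselines.{arm}.{name}={getattr(b, name)}: must be >= 0")
        if b.first12mo_ly < 0:
            v.append(f"baselines.{arm}.first12mo_ly={b.first12mo_ly}: must be >= 0")

    ages_needed = range(s.start_age, s.start_age + s.horizon_years + 1)
    missing = [a for a in ages_needed if a not in cfg.life_table]
    if missing:
        v.append(
            f"life_table: missing ages {missing[:5]}{'...' if len(missing) > 5 else ''}; "
            f"must cover [{s.start_age}, {s.start_age + s.horizon_years}]"
        )
    bad_q = {a: q for a, q in cfg.life_table.items() if not 0.0 <= q < 1.0}
    if bad_q:
        v.append(f"life_table: annual death probabilities must lie in [0, 1): bad entries {bad_q}")

    return v


def _validated(cfg: ModelConfig) -> ModelConfig:
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(violations))
    return cfg


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML (full schema, lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path, merge_defaults: bool = True) -> ModelConfig:
    """Load and validate a YAML configuration.

    With ``merge_defaults`` (the default), keys absent from the file take
    their values from :func:`default_config`, so a file may override a
    single parameter.  Unknown keys raise :class:`ConfigError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at top level")
    if merge_defaults:
        base = default_config().to_dict()
        merged = _deep_merge(base, raw)
    else:
        merged = raw
    cfg = ModelConfig.from_dict(merged)
    return _validated(cfg)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict) and key != "life_table":
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


# ---------------------------------------------------------------------------
# dotted-path parameter access (used by the sensitivity analyses)
# ---------------------------------------------------------------------------


def get_param(cfg: ModelConfig, path: str) -> float:
    """Read a scalar parameter by dotted path, e.g. ``costs.mgmt_year1.mRS3``.

    The virtual path ``life_table.multiplier`` always reads 1.0 and, on
    :func:`set_param`, scales every annual death probability.
    """
    if path == "life_table.multiplier":
        return 1.0
    node: Any = cfg.to_dict()
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"unknown parameter path: {path!r}")
        node = node[part]
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        return float(node)
    raise ConfigError(f"parameter path {path!r} does not point at a scalar")


def set_param(cfg: ModelConfig, path: str, value: float) -> ModelConfig:
    """Return a new config with the parameter at ``path`` replaced."""
    d = cfg.to_dict()
    if path == "life_table.multiplier":
        d["life_table"] = {a: min(float(q) * value, 1.0 - 1e-12) for a, q in d["life_table"].items()}
        return ModelConfig.from_dict(d)
    parts = path.split(".")
    node: Any = d
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"unknown parameter path: {path!r}")
        node = node[part]
    leaf = parts[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise ConfigError(f"unknown parameter path: {path!r}")
    if leaf in ("horizon_years", "start_age", "cohort_size"):
        node[leaf] = int(round(value))
    else:
        node[leaf] = float(value)
    return ModelConfig.from_dict(d)
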