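"""Synthetic stand-ins for the non-public model inputs.

The long-term model starts from each arm's day-365 modified Rankin Scale
distribution and first-year cost/outcome totals, which come from
patient-level trial data that cannot be shared, and from national life
tables.  This module generates plausible substitutes so that the whole
pipeline runs and can be tested offline:

* a control-arm day-365 mRS distribution drawn from a Dirichlet around a
  fixed synthetic reference shape for regional Australian stroke patients;
* an intervention-arm distribution obtained by shifting probability mass
  toward lower disability, scaled by the uplift in thrombolysis treatment
  (17% -> 26% of arrivals within 4.5 h), so that the intervention arm
  first-order stochastically dominates the control arm toward less
  disability;
* a Gompertz life table for background (non-stroke) mortality;
* first-year per-person costs and QALYs, defaulting to the published
  12-month trial means.

Generated baselines are labelled synthetic in the configuration and are
never claimed to reproduce the trial's actual distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import (
    ARMS,
    ArmBaseline,
    ConfigError,
    EconSettings,
    ModelConfig,
    _validated,
    base_parameters,
)

#: Fixed synthetic reference shape for the control arm's day-365 mRS
#: distribution (mRS 0..6).  Roughly 28% first-year case fatality and a
#: heavy severe-disability tail, typical of elderly regional stroke
#: cohorts; chosen once so that lifetime model outputs land in a
#: realistic range (per-person lifetime costs of order $10^5, about 4
#: discounted QALYs, roughly 3,000 of 10,000 patients ever needing
#: nursing-home care).
REFERENCE_CONTROL_MRS = np.array([0.10, 0.13, 0.12, 0.12, 0.13, 0.12, 0.28])


@dataclass
class EffectSpec:
    """Treatment-effect specification for the baseline generator.

    ``mrs_shift_per_treated`` is the expected number of one-category mRS
    improvements per additional thrombolysed patient; values above 1 model
    multi-category gains.  The fraction of each category's mass moved down
    one level is ``(rate_intervention - rate_control) * mrs_shift_per_treated``.
    """

    thrombolysis_rate_control: float = 0.17
    thrombolysis_rate_intervention: float = 0.26
    mrs_shift_per_treated: float = 3.0
    concentration: float = 200.0


@dataclass
class LifeTableSpec:
    """Gompertz background-mortality model: hazard a*exp(b*(age - start))."""

    a: float = 0.02
    b: float = 0.09
    start_age: int = 74
    span_years: int = 25
    model: str = "Gompertz"


def gen_baseline_mrs(effect: EffectSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate (intervention, control) day-365 mRS distributions.

    The control vector is a Dirichlet draw around the packaged reference
    shape; the intervention vector moves a fraction of each living
    category's mass one level toward less disability.  First-year death
    (mRS 6) is left untouched: the modelled mechanism is disability
    averted among survivors, and the long-term event rates are identical
    between arms.  By construction the intervention CDF over mRS 0..k is
    >= the control CDF for every k (first-order dominance toward less
    disability).
    """
    if not (0.0 <= effect.thrombolysis_rate_control <= 1.0 and 0.0 <= effect.thrombolysis_rate_intervention <= 1.0):
        raise ConfigError("thrombolysis rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alpha = REFERENCE_CONTROL_MRS * effect.concentration
    control = rng.dirichlet(alpha)
    frac = (effect.thrombolysis_rate_intervention - effect.thrombolysis_rate_control) * effect.mrs_shift_per_treated
    if frac < 0 or frac > 1:
        warnings.warn(f"mRS shift fraction {frac:.3f} clipped to [0, 1]", stacklevel=2)
        frac = min(max(frac, 0.0), 1.0)
    intervention = _shift_down(control, frac)
    return intervention, control


def _shift_down(p: np.ndarray, frac: float) -> np.ndarray:
    """Move ``frac`` of each living category's mass one mRS level lower."""
    out = p.astype(float).copy()
    moved = frac * p[1:6]
    out[1:6] -= moved
    out[0:5] += moved
    return out


def gen_life_table(spec: LifeTableSpec) -> dict[int, float]:
    """Annual all-cause death probabilities q(age) = 1 - exp(-a*e^{b*(age-start)}).

    Strictly increasing in age when ``b > 0``; parameters implying q >= 1
    anywhere in the covered range are rejected.
    """
    if spec.a <= 0 or spec.b < 0:
        raise ConfigError(f"life table requires a > 0 and b >= 0 (got a={spec.a}, b={spec.b})")
    table: dict[int, float] = {}
    for age in range(spec.start_age, spec.start_age + spec.span_years + 1):
        q = 1.0 - math.exp(-spec.a * math.exp(spec.b * (age - spec.start_age)))
        if q >= 1.0:
            raise ConfigError(f"life table parameters yield q >= 1 at age {age}")
        table[age] = q
    return table


#: Published first-year per-person means used as deterministic defaults:
#: 12-month costs (societal, 2018 AUD) and QALYs for the telestroke
#: intervention and control arms.
FIRST_YEAR_MEANS = {
    "intervention": {"cost_societal": 78_859.0, "qaly": 0.53},
    "control": {"cost_societal": 76_954.0, "qaly": 0.38},
}


def gen_first_year(
    arm: str,
    seed: int | None = None,
    dispersion: float = 0.0,
    mrs6: float | None = None,
) -> dict[str, float]:
    """First-year per-person cost/QALY/LY inputs for one arm.

    With ``dispersion = 0`` (the default) returns the published 12-month
    means exactly.  A positive ``dispersion`` is the coefficient of
    variation of a Gamma (cost) / moment-matched Beta (QALY) draw around
    those means.  The healthcare-perspective cost has no published
    counterpart and defaults to the societal value (synthetic stand-in).
    Life-years default to survival-weighted exposure: survivors of the
    first year contribute 1.0, first-year deaths 0.5 on average.
    """
    if arm not in ARMS:
        raise ConfigError(f"unknown arm {arm!r}; expected one of {ARMS}")
    means = FIRST_YEAR_MEANS[arm]
    cost, qaly = means["cost_societal"], means["qaly"]
    if dispersion > 0:
        rng = np.random.default_rng(seed)
        shape = 1.0 / dispersion**2
        cost = rng.gamma(shape, cost / shape)
        m, s = qaly, dispersion * qaly
        v = m * (1 - m) / s**2 - 1.0
        qaly = rng.beta(m * v, (1 - m) * v) if v > 0 else qaly
    ly = 1.0 if mrs6 is None else 1.0 - 0.5 * mrs6
    return {
        "cost_societal": float(cost),
        "cost_healthcare": float(cost),
        "qaly": float(qaly),
        "ly": float(ly),
    }


def make_fixture(seed: int, effect: EffectSpec | None = None, life_spec: LifeTableSpec | None = None) -> ModelConfig:
    """Assemble a complete, validated model configuration.

    Shared parameters take the literature base-case values; baselines and
    the life table are generated from ``seed``.  Identical seeds yield
    identical configurations.
    """
    effect = effect or EffectSpec()
    transition, costs, utilities, settings = base_parameters()
    life_spec = life_spec or LifeTableSpec(start_age=settings.start_age, span_years=settings.horizon_years)
    mrs_int, mrs_ctl = gen_baseline_mrs(effect, seed)
    baselines = {}
    for arm, vec in (("intervention", mrs_int), ("control", mrs_ctl)):
        fy = gen_first_year(arm, mrs6=float(vec[6]))
        baselines[arm] = ArmBaseline(
            arm=arm,
            mrs_day365=vec,
            first12mo_cost_societal=fy["cost_societal"],
            first12mo_cost_healthcare=fy["cost_healthcare"],
            first12mo_qaly=fy["qaly"],
            first12mo_ly=fy["ly"],
        )
    cfg = ModelConfig(
        transition=transition,
        costs=costs,
        utilities=utilities,
        settings=settings,
        baselines=baselines,
        life_table=gen_life_table(life_spec),
        baseline_provenance=f"synthetic (seed={seed})",
    )
    return _validated(cfg)
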