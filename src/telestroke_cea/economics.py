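"""Discounted cost, QALY and life-year accounting and incremental summaries.

Accrual conventions
-------------------
* Cycle 0 holds the trial-informed first-12-month inputs, undiscounted,
  plus the telemedicine program cost for the intervention arm;
  discounting starts at cycle 1 with weight ``(1 + r)**-t``.
* State-occupancy costs and outcomes (management, nursing home,
  non-medical care, utilities, life-years) use end-of-cycle occupancy;
  an optional half-cycle correction averages adjacent occupancy rows.
* "Year 1" management costs attach to the year of a modelled recurrence
  (the inflow into the post-recurrence layer); all other living
  person-time accrues the long-term management cost.
* Recurrence admissions are priced by destination mRS level; fatal
  recurrences by the mRS 6 admission cost.
* The societal perspective includes every component; the healthcare
  perspective keeps only medical care (first-12-month healthcare costs,
  program, management, rehospitalisation), excluding nursing-home and
  non-medical care.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTrace, EventCounts, run_cohort
from .config import COST_COMPONENTS, ArmBaseline, ConfigError, ModelConfig

HEALTHCARE_EXCLUDED = ("nursing_home", "nonmedical")


@dataclass
class ArmResult:
    """Discounted per-person lifetime results for one arm."""

    arm: str
    perspective: str
    total_cost: float
    cost_components: dict[str, float] = field(default_factory=dict)
    qalys: float = 0.0
    lys: float = 0.0
    nursing_home_count: int = 0  # persons per cohort over the lifetime
    discounted: bool = True


@dataclass
class CEResult:
    """Incremental (intervention minus control) cost-effectiveness summary."""

    perspective: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    classification: str  # dominant | dominated | ratio
    icer: float  # $/QALY; nan unless classification == "ratio"
    component_deltas: dict[str, float] = field(default_factory=dict)


def discount_weight(t: int, r: float) -> float:
    """Present-value weight ``(1 + r)**-t`` for cycle ``t``."""
    if r < 0:
        raise ValueError(f"discount rate must be >= 0, got {r}")
    return (1.0 + r) ** (-t)


def accrue_arm(
    trace: CohortTrace,
    events: EventCounts,
    baseline: ArmBaseline,
    cfg: ModelConfig,
    perspective: str,
    discounted: bool = True,
) -> ArmResult:
    """Turn a cohort trace and its event flows into per-person lifetime totals."""
    if perspective not in ("societal", "healthcare"):
        raise ConfigError(f"unknown perspective {perspective!r}")
    c, u, s = cfg.costs, cfg.utilities.utility, cfg.settings
    r = s.discount_rate if discounted else 0.0
    H = trace.n_cycles

    comp = dict.fromkeys(COST_COMPONENTS, 0.0)
    comp["first12mo"] = (
        baseline.first12mo_cost_societal if perspective == "societal" else baseline.first12mo_cost_healthcare
    )
    if baseline.arm == "intervention":
        comp["program"] = c.program_cost_per_patient
    qalys = baseline.first12mo_qaly
    lys = baseline.first12mo_ly

    for t in range(1, H + 1):
        w = discount_weight(t, r)
        L = trace.living(t)
        if s.half_cycle_correction:
            L = 0.5 * (L + trace.living(t - 1))
        inflow = events.recur_survivor_inflow[t]
        later_mass = np.maximum(L - inflow, 0.0)
        comp["management"] += w * float(inflow @ c.mgmt_year1 + later_mass @ c.mgmt_later)
        comp["rehospitalisation"] += w * float(inflow @ c.rehosp[:6] + events.fatal_recurrences[t] * c.rehosp[6])
        if perspective == "societal":
            comp["nursing_home"] += w * float((L[4] + L[5]) * c.nursing_home)
            comp["nonmedical"] += w * float(L @ (c.nonmedical * c.p_nonmedical_use))
        qalys += w * float(L @ u)
        lys += w * float(L.sum())

    return ArmResult(
        arm=baseline.arm,
        perspective=perspective,
        total_cost=sum(comp.values()),
        cost_components=comp,
        qalys=qalys,
        lys=lys,
        nursing_home_count=nursing_home_tally(events, s.cohort_size),
        discounted=discounted,
    )


def nursing_home_tally(events: EventCounts, cohort_size: int) -> int:
    """Expected lifetime count of cohort members ever needing nursing-home care."""
    if cohort_size < 1:
        raise ValueError(f"cohort_size must be >= 1, got {cohort_size}")
    return int(round(float(events.nursing_home_entries[-1]) * cohort_size))


def incremental_summary(intv: ArmResult, ctrl: ArmResult) -> CEResult:
    """Incremental summary with dominance classification.

    ``dominant``: no more costly and at least as effective (one strict) —
    the intervention wins outright and the ICER is undefined.
    ``dominated``: the mirror image.  Otherwise a finite ICER
    ``delta_cost / delta_qaly`` is reported.
    """
    if intv.perspective != ctrl.perspective:
        raise ConfigError("arms evaluated under different perspectives")
    dc = intv.total_cost - ctrl.total_cost
    dq = intv.qalys - ctrl.qalys
    dly = intv.lys - ctrl.lys
    if dc <= 0 and dq >= 0 and (dc < 0 or dq > 0):
        cls, icer = "dominant", math.nan
    elif dc >= 0 and dq <= 0 and (dc > 0 or dq < 0):
        cls, icer = "dominated", math.nan
    elif dq == 0 and dc == 0:
        cls, icer = "ratio", math.nan
    else:
        cls, icer = "ratio", dc / dq
    keys = set(intv.cost_components) | set(ctrl.cost_components)
    deltas = {k: intv.cost_components.get(k, 0.0) - ctrl.cost_components.get(k, 0.0) for k in keys}
    return CEResult(
        perspective=intv.perspective,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dly,
        classification=cls,
        icer=icer,
        component_deltas=deltas,
    )


def net_monetary_benefit(ce: CEResult, wtp: float) -> float:
    """NMB = wtp * delta_QALY - delta_cost; positive means cost-effective."""
    return wtp * ce.delta_qaly - ce.delta_cost


def evaluate(
    cfg: ModelConfig, perspective: str | None = None, discounted: bool = True
) -> tuple[ArmResult, ArmResult, CEResult]:
    """Run both arms through the cohort engine and summarise incrementally."""
    perspective = perspective or cfg.settings.perspective
    results = {}
    for arm in ("intervention", "control"):
        baseline = cfg.baselines[arm]
        trace, events = run_cohort(baseline, cfg)
        results[arm] = accrue_arm(trace, events, baseline, cfg, perspective, discounted=discounted)
    ce = incremental_summary(results["intervention"], results["control"])
    return results["intervention"], results["control"], ce


def summary_frame(intv: ArmResult, ctrl: ArmResult, ce: CEResult) -> pd.DataFrame:
    """Base-case table: QALYs, LYs, totals and cost components per arm."""
    rows = [
        ("total_qalys", intv.qalys, ctrl.qalys, ce.delta_qaly),
        ("total_lys", intv.lys, ctrl.lys, ce.delta_ly),
        (f"total_costs_{ce.perspective}", intv.total_cost, ctrl.total_cost, ce.delta_cost),
        (
            "icer_per_qaly",
            math.nan,
            math.nan,
            ce.icer if ce.classification == "ratio" else math.nan,
        ),
        (
            "nursing_home_patients",
            intv.nursing_home_count,
            ctrl.nursing_home_count,
            intv.nursing_home_count - ctrl.nursing_home_count,
        ),
    ] + [
        (f"cost_{k}", intv.cost_components.get(k, 0.0), ctrl.cost_components.get(k, 0.0), ce.component_deltas.get(k, 0.0))
        for k in COST_COMPONENTS
    ]
    df = pd.DataFrame(rows, columns=["quantity", "intervention", "control", "difference"])
    df.attrs["classification"] = ce.classification
    return df
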