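"""Published base-case results of the Australian telestroke evaluation.

These per-arm lifetime summaries are reference values used to cross-check
the incremental-summary routines; the underlying patient-level inputs
that produced them are not public, so the model itself is exercised on
synthetic baselines.  Discounted totals come from the headline summary;
the component table reports undiscounted accounting (2018 AUD).
"""

from __future__ import annotations

from .economics import ArmResult

#: Headline discounted per-person lifetime results.
DISCOUNTED = {
    "intervention": {
        "cost_societal": 126_461.0,
        "cost_healthcare": 76_680.0,
        "qalys": 4.428,
        "lys": 7.687,
    },
    "control": {
        "cost_societal": 127_987.0,
        "cost_healthcare": 75_901.0,
        "qalys": 3.979,
        "lys": 7.145,
    },
}

#: Undiscounted component accounting per person (program cost excluded
#: from these published totals) and nursing-home users per 10,000.
UNDISCOUNTED = {
    "intervention": {
        "cost_societal": 152_209.0,
        "cost_healthcare": 102_429.0,
        "nursing_home_count": 2_861,
        "components": {
            "first12mo": 78_859.0,
            "management": 11_267.0,
            "rehospitalisation": 12_303.0,
            "nursing_home": 46_590.0,
            "nonmedical": 3_190.0,
        },
    },
    "control": {
        "cost_societal": 152_607.0,
        "cost_healthcare": 100_520.0,
        "nursing_home_count": 2_962,
        "components": {
            "first12mo": 76_954.0,
            "management": 10_454.0,
            "rehospitalisation": 13_113.0,
            "nursing_home": 48_769.0,
            "nonmedical": 3_318.0,
        },
    },
}


def published_arm_result(arm: str, perspective: str) -> ArmResult:
    """Published discounted lifetime totals for one arm as an ArmResult."""
    d = DISCOUNTED[arm]
    u = UNDISCOUNTED[arm]
    return ArmResult(
        arm=arm,
        perspective=perspective,
        total_cost=d[f"cost_{perspective}"],
        cost_components={},
        qalys=d["qalys"],
        lys=d["lys"],
        nursing_home_count=u["nursing_home_count"],
        discounted=True,
    )
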