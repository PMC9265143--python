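"""Markov cohort engine over the expanded poststroke state space.

Living patients occupy one of six modified Rankin Scale levels (mRS 0-5),
each doubled by a post-recurrence flag so that the elevated risk of a
further stroke after a first recurrence stays Markovian; two absorbing
states hold stroke death (including fatal recurrences and first-year
deaths) and death from all other causes — 14 engine states in total.

Within each annual cycle events compose in a fixed order shared by the
cohort recursion and the individual-level microsimulation oracle:

1. background (other-cause) death, with the life-table probability
   adjusted by the mRS-specific hazard ratio on the log-survival scale;
2. among survivors, recurrent stroke;
3. among recurrers, case fatality (to stroke death);
4. survivors of a recurrence redistribute over equal-or-worse mRS levels
   via the worsening matrix, entering the post-recurrence layer.

Non-recurrers retain their state and flag.  Ages advance one year per
cycle from the cohort start age; life-table lookups clamp at the table's
maximum age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArmBaseline, ConfigError, ModelConfig, validate_config

N_LIVING = 12  # 6 mRS levels x 2 recurrence flags
DEAD_STROKE = 12
DEAD_OTHER = 13
N_STATES = 14

STATE_LABELS = tuple(
    [f"mRS{k}" for k in range(6)]
    + [f"mRS{k}_postrec" for k in range(6)]
    + ["DeadStroke", "DeadOther"]
)

#: mRS level of each living engine state (index 0..11).
_MRS_OF_STATE = np.array([k for k in range(6)] * 2)
#: post-recurrence flag of each living engine state.
_FLAG_OF_STATE = np.array([0] * 6 + [1] * 6)


def state_index(mrs: int, post_recurrence: bool) -> int:
    """Engine index of a living state."""
    if not 0 <= mrs <= 5:
        raise ValueError(f"mRS level must be 0..5, got {mrs}")
    return mrs + 6 * int(post_recurrence)


@dataclass(eq=False)
class CohortTrace:
    """Per-cycle cohort occupancy (rows sum to 1) and attained ages."""

    occupancy: np.ndarray  # (horizon+1, 14)
    age_at_cycle: np.ndarray  # (horizon+1,)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def living(self, cycle: int) -> np.ndarray:
        """Living occupancy by mRS level (flags summed), shape (6,)."""
        occ = self.occupancy[cycle]
        return occ[:6] + occ[6:12]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cycle": t, "age": int(self.age_at_cycle[t]), "state": STATE_LABELS[s], "fraction": self.occupancy[t, s]}
            for t in range(self.occupancy.shape[0])
            for s in range(N_STATES)
        ]
        return pd.DataFrame(rows)


@dataclass(eq=False)
class EventCounts:
    """Expected per-person event flows by cycle.

    ``recur_survivor_inflow[t, j]`` is the mass arriving in mRS level
    ``j`` of the post-recurrence layer during cycle ``t`` (recurrence
    survivors), used to price recurrence admissions and first-year
    management.  ``nursing_home_entries`` is the cumulative expected
    number of first entries into mRS 4-5 per person (people entering
    residential care), including cohort members who start there.
    """

    recurrent_strokes: np.ndarray  # (horizon+1,)
    fatal_recurrences: np.ndarray  # (horizon+1,)
    recur_survivor_inflow: np.ndarray  # (horizon+1, 6)
    nursing_home_entries: np.ndarray  # (horizon+1,) cumulative

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(len(self.recurrent_strokes)):
            rows += [
                {"cycle": t, "event": "recurrent_strokes", "expected_per_person": self.recurrent_strokes[t]},
                {"cycle": t, "event": "fatal_recurrences", "expected_per_person": self.fatal_recurrences[t]},
                {"cycle": t, "event": "nursing_home_entries_cum", "expected_per_person": self.nursing_home_entries[t]},
            ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-cycle building blocks
# ---------------------------------------------------------------------------


def adjust_mortality(p_base: float, hr: float) -> float:
    """Apply a hazard ratio to an annual death probability.

    Works on the log-survival scale: ``1 - (1 - p_base)**hr``, the exact
    transformation for proportional hazards with annual probabilities.
    """
    if not 0.0 <= p_base < 1.0:
        raise ValueError(f"p_base must lie in [0, 1), got {p_base}")
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    return 1.0 - (1.0 - p_base) ** hr


def recurrence_prob(cycle: int, post_recurrence: bool, tp) -> float:
    """Annual recurrent-stroke probability for a given model cycle.

    The first model cycle (day 366-730) uses the first-year rate; later
    cycles the long-term rate.  A prior modelled recurrence multiplies the
    rate by the relative risk, capped at 1.
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    base = tp.p_recur_year1 if cycle == 1 else tp.p_recur_later
    if post_recurrence:
        base *= tp.rr_recur_after_recur
    return min(base, 1.0)


def default_worsening_matrix(mrs_day365: np.ndarray) -> np.ndarray:
    """Worsening matrix derived from an arm's day-365 distribution.

    On non-fatal recurrence from level ``k``, destination mass is the
    baseline living distribution restricted to levels >= k, renormalised;
    a degenerate tail keeps the patient at ``k``.
    """
    living = np.asarray(mrs_day365, dtype=float)[:6]
    W = np.zeros((6, 6))
    for k in range(6):
        tail = living[k:]
        total = tail.sum()
        if total <= 0:
            W[k, k] = 1.0
        else:
            W[k, k:] = tail / total
    return W


def resolve_worsening(cfg: ModelConfig, baseline: ArmBaseline) -> np.ndarray:
    """Config-supplied worsening matrix, or the arm-specific default."""
    if cfg.transition.worsening_matrix is not None:
        return cfg.transition.worsening_matrix
    return default_worsening_matrix(baseline.mrs_day365)


def _life_table_q(cfg: ModelConfig, age: int) -> float:
    table = cfg.life_table
    if age in table:
        return table[age]
    max_age = max(table)
    if age > max_age:  # clamp beyond tabulated range
        return table[max_age]
    raise ConfigError(f"life table does not cover age {age}")


def _cycle_hazards(cycle: int, age: int, cfg: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """(p_other_death, p_recurrence) over the 12 living states."""
    q = _life_table_q(cfg, age)
    hr = cfg.transition.hr_mortality
    p_die = np.array([adjust_mortality(q, hr[_MRS_OF_STATE[s]]) for s in range(N_LIVING)])
    p_rec = np.array(
        [recurrence_prob(cycle, bool(_FLAG_OF_STATE[s]), cfg.transition) for s in range(N_LIVING)]
    )
    return p_die, p_rec


def build_cycle_matrix(
    cycle: int, age: int, cfg: ModelConfig, worsening: np.ndarray | None = None
) -> np.ndarray:
    """Row-stochastic 14x14 transition matrix for one annual cycle.

    ``worsening`` defaults to the config-level matrix; supply the
    arm-resolved matrix when the config leaves it unset.
    """
    if worsening is None:
        worsening = cfg.transition.worsening_matrix
        if worsening is None:
            raise ConfigError(
                "no worsening matrix: set transition.worsening_matrix or pass the "
                "arm-resolved matrix (see resolve_worsening)"
            )
    p_die, p_rec = _cycle_hazards(cycle, age, cfg)
    pdr = cfg.transition.p_death_after_recur
    M = np.zeros((N_STATES, N_STATES))
    M[DEAD_STROKE, DEAD_STROKE] = 1.0
    M[DEAD_OTHER, DEAD_OTHER] = 1.0
    for s in range(N_LIVING):
        k = _MRS_OF_STATE[s]
        surv = 1.0 - p_die[s]
        ev = surv * p_rec[s]
        M[s, DEAD_OTHER] = p_die[s]
        M[s, DEAD_STROKE] = ev * pdr
        M[s, 6:12] += ev * (1.0 - pdr) * worsening[k]
        M[s, s] += surv * (1.0 - p_rec[s])
    return M


# ---------------------------------------------------------------------------
# cohort recursion
# ---------------------------------------------------------------------------


def initial_occupancy(baseline: ArmBaseline) -> np.ndarray:
    """Cycle-0 occupancy: living mass from mRS 0-5, mRS 6 mass as stroke death.

    Patients who died within the first year stay in the trace (so that
    per-person results average over the full inception cohort) but accrue
    nothing beyond their first-12-month inputs.
    """
    occ = np.zeros(N_STATES)
    occ[:6] = baseline.mrs_day365[:6]
    occ[DEAD_STROKE] = baseline.mrs_day365[6]
    return occ


def run_cohort(baseline: ArmBaseline, cfg: ModelConfig) -> tuple[CohortTrace, EventCounts]:
    """Propagate the cohort for the full horizon and tally event flows."""
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    W = resolve_worsening(cfg, baseline)
    H = cfg.settings.horizon_years
    start_age = cfg.settings.start_age
    pdr = cfg.transition.p_death_after_recur

    occ = np.zeros((H + 1, N_STATES))
    occ[0] = initial_occupancy(baseline)
    recur = np.zeros(H + 1)
    fatal = np.zeros(H + 1)
    inflow = np.zeros((H + 1, 6))
    nh_cum = np.zeros(H + 1)
    nh_cum[0] = occ[0, 4] + occ[0, 5]  # cohort members starting in mRS 4-5

    for t in range(1, H + 1):
        age = start_age + t - 1  # age during the cycle
        p_die, p_rec = _cycle_hazards(t, age, cfg)
        o = occ[t - 1, :N_LIVING]
        events = o * (1.0 - p_die) * p_rec
        nonfatal = events * (1.0 - pdr)
        recur[t] = events.sum()
        fatal[t] = events.sum() * pdr
        # redistribute non-fatal recurrences by source mRS level
        by_level = np.zeros(6)
        for s in range(N_LIVING):
            by_level += nonfatal[s] * W[_MRS_OF_STATE[s]]
        inflow[t] = by_level
        # first entries to mRS 4-5: non-fatal recurrences from mRS <= 3
        nh_new = sum(
            nonfatal[s] * W[_MRS_OF_STATE[s], 4:6].sum()
            for s in range(N_LIVING)
            if _MRS_OF_STATE[s] <= 3
        )
        nh_cum[t] = nh_cum[t - 1] + nh_new

        M = build_cycle_matrix(t, age, cfg, worsening=W)
        occ[t] = occ[t - 1] @ M

    ages = np.arange(start_age, start_age + H + 1)
    return (
        CohortTrace(occupancy=occ, age_at_cycle=ages),
        EventCounts(
            recurrent_strokes=recur,
            fatal_recurrences=fatal,
            recur_survivor_inflow=inflow,
            nursing_home_entries=nh_cum,
        ),
    )


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------


def run_microsim(
    baseline: ArmBaseline, cfg: ModelConfig, n: int, seed: int
) -> tuple[CohortTrace, EventCounts]:
    """Individual-level Monte-Carlo counterpart of :func:`run_cohort`.

    Simulates ``n`` independent trajectories with the same within-cycle
    event ordering and per-state probabilities as the cohort recursion and
    returns empirical occupancy fractions and event rates.  Serves as an
    independent stochastic cross-check: occupancy converges to the cohort
    recursion at the binomial rate.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    rng = np.random.default_rng(seed)
    W = resolve_worsening(cfg, baseline)
    Wcum = np.cumsum(W, axis=1)
    H = cfg.settings.horizon_years
    start_age = cfg.settings.start_age
    pdr = cfg.transition.p_death_after_recur

    # draw initial day-365 categories; category 6 -> stroke death
    cats = rng.choice(7, size=n, p=baseline.mrs_day365 / baseline.mrs_day365.sum())
    states = np.where(cats == 6, DEAD_STROKE, cats).astype(np.int64)
    ever_nh = (cats == 4) | (cats == 5)

    occ = np.zeros((H + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n
    recur = np.zeros(H + 1)
    fatal = np.zeros(H + 1)
    inflow = np.zeros((H + 1, 6))
    nh_cum = np.zeros(H + 1)
    nh_cum[0] = ever_nh.mean()

    for t in range(1, H + 1):
        age = start_age + t - 1
        p_die, p_rec = _cycle_hazards(t, age, cfg)
        new_states = states.copy()
        for s in range(N_LIVING):
            idx = np.flatnonzero(states == s)
            if idx.size == 0:
                continue
            k = _MRS_OF_STATE[s]
            u_die = rng.random(idx.size)
            died_other = u_die < p_die[s]
            new_states[idx[died_other]] = DEAD_OTHER
            alive = idx[~died_other]
            u_rec = rng.random(alive.size)
            had_event = u_rec < p_rec[s]
            ev_idx = alive[had_event]
            recur[t] += ev_idx.size
            u_fatal = rng.random(ev_idx.size)
            died_stroke = u_fatal < pdr
            new_states[ev_idx[died_stroke]] = DEAD_STROKE
            fatal[t] += int(died_stroke.sum())
            surv_idx = ev_idx[~died_stroke]
            if surv_idx.size:
                dest = np.searchsorted(Wcum[k], rng.random(surv_idx.size), side="right")
                dest = np.minimum(dest, 5)
                new_states[surv_idx] = dest + 6  # post-recurrence layer
                np.add.at(inflow[t], dest, 1.0)
                if k <= 3:
                    ever_nh[surv_idx[dest >= 4]] = True
        states = new_states
        occ[t] = np.bincount(states, minlength=N_STATES) / n
        nh_cum[t] = ever_nh.mean()

    ages = np.arange(start_age, start_age + H + 1)
    return (
        CohortTrace(occupancy=occ, age_at_cycle=ages),
        EventCounts(
            recurrent_strokes=recur / n,
            fatal_recurrences=fatal / n,
            recur_survivor_inflow=inflow / n,
            nursing_home_entries=nh_cum,
        ),
    )
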