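"""Sensitivity and threshold analyses.

* One-way deterministic sensitivity analysis (tornado): each parameter is
  set to its low and high value in turn, both arms are re-run, and the
  resulting ICER (or, when an endpoint is dominant/dominated and the ICER
  is undefined, the net monetary benefit at the analysis willingness-to-pay,
  flagged as such) is recorded; rows are sorted by descending range.
* Probabilistic sensitivity analysis: parameters are drawn independently
  (a Dirichlet over the intervention arm's day-365 mRS distribution, Beta
  for probabilities and utilities, Gamma for costs), each draw re-runs
  the full model, and the cloud of incremental (cost, QALY) pairs yields
  the probability of dominance and a cost-effectiveness acceptability
  curve.
* Threshold analysis: the per-patient program cost is replaced by a fixed
  implementation total divided by the regional stroke volume ``n``;
  bisection finds the smallest ``n`` at which the program is
  cost-effective (monotone, since per-person cost falls with ``n``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MRS, ConfigError, ModelConfig, get_param, set_param, validate_config
from .economics import CEResult, evaluate, net_monetary_benefit

# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class DSASpec:
    """Low/base/high values for a single parameter path."""

    path: str
    low: float
    high: float
    base: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ConfigError(f"DSA spec for {self.path}: requires low <= base <= high")


def default_dsa_specs(cfg: ModelConfig, rel: float = 0.20) -> list[DSASpec]:
    """The packaged one-way analysis set.

    Costs, probabilities and utilities vary by ±20% of base (clamped to
    their domains); recurrence case fatality uses its published low
    alternative 0.11; background mortality is scaled ±20% through the
    life-table multiplier; the discount rate spans 0-5% and the horizon
    10 years to lifetime.
    """
    specs: list[DSASpec] = []

    def pm(path: str, lo_clip: float = 0.0, hi_clip: float = math.inf) -> None:
        base = get_param(cfg, path)
        specs.append(
            DSASpec(
                path=path,
                low=max(base * (1 - rel), lo_clip),
                high=min(base * (1 + rel), hi_clip),
                base=base,
            )
        )

    pm("transition.p_recur_year1", hi_clip=1.0)
    pm("transition.p_recur_later", hi_clip=1.0)
    base_pdr = get_param(cfg, "transition.p_death_after_recur")
    specs.append(DSASpec("transition.p_death_after_recur", low=min(0.11, base_pdr), high=base_pdr, base=base_pdr))
    specs.append(DSASpec("life_table.multiplier", low=1 - rel, high=1 + rel, base=1.0))
    for lab in MRS:
        pm(f"utilities.{lab}", hi_clip=1.0)
        pm(f"costs.mgmt_year1.{lab}")
        pm(f"costs.mgmt_later.{lab}")
    pm("costs.nursing_home")
    pm("costs.program_cost_per_patient")
    r = get_param(cfg, "settings.discount_rate")
    specs.append(DSASpec("settings.discount_rate", low=0.0, high=max(0.05, r), base=r))
    h = get_param(cfg, "settings.horizon_years")
    specs.append(DSASpec("settings.horizon_years", low=min(10, h), high=h, base=h))
    return specs


def _endpoint_metric(ce: CEResult, wtp: float) -> tuple[float, str]:
    """(value, scale) for one DSA endpoint: the ICER when defined, else NMB."""
    if ce.classification == "ratio" and math.isfinite(ce.icer):
        return ce.icer, "icer"
    return net_monetary_benefit(ce, wtp), "nmb"


def run_one_way_dsa(
    cfg: ModelConfig,
    specs: list[DSASpec] | None = None,
    perspective: str | None = None,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Tornado table: one row per parameter, sorted by descending range.

    Because ranges cannot be compared across the ICER/NMB scales, the
    sort key is always the NMB span between the two endpoints; the
    reported per-endpoint metric is the ICER whenever it is defined.
    """
    specs = default_dsa_specs(cfg) if specs is None else specs
    perspective = perspective or cfg.settings.perspective
    wtp = wtp if wtp is not None else cfg.settings.wtp
    rows = []
    for spec in specs:
        get_param(cfg, spec.path)  # raises ConfigError on unknown paths
        rec: dict[str, object] = {"parameter": spec.path, "low_value": spec.low, "high_value": spec.high}
        nmbs = {}
        for end, value in (("low", spec.low), ("high", spec.high)):
            _, _, ce = evaluate(set_param(cfg, spec.path, value), perspective)
            metric, scale = _endpoint_metric(ce, wtp)
            rec[f"metric_{end}"] = metric
            rec[f"scale_{end}"] = scale
            rec[f"classification_{end}"] = ce.classification
            nmbs[end] = net_monetary_benefit(ce, wtp)
        rec["nmb_range"] = abs(nmbs["high"] - nmbs["low"])
        rows.append(rec)
    df = pd.DataFrame(rows).sort_values("nmb_range", ascending=False, kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class ParamDist:
    """Sampling distribution for one parameter path.

    family: ``point`` (degenerate), ``beta`` (params = (alpha, beta)),
    ``gamma`` (params = (shape, scale)), or ``dirichlet`` (params = alpha
    vector; the path must point at an arm's mrs_day365 vector).
    """

    path: str
    family: str
    params: tuple[float, ...] = ()


@dataclass
class PSADistributions:
    entries: list[ParamDist] = field(default_factory=list)
    max_retries: int = 100


def _beta_moment_match(mean: float, sd: float) -> tuple[float, float]:
    sd = min(sd, 0.95 * math.sqrt(mean * (1 - mean))) if 0 < mean < 1 else 0.0
    if sd <= 0:
        raise ConfigError(f"cannot moment-match a Beta at mean {mean}")
    nu = mean * (1 - mean) / sd**2 - 1.0
    return mean * nu, (1 - mean) * nu


def default_psa_distributions(
    cfg: ModelConfig,
    se_frac: float = 0.20,
    dirichlet_ess: float = 5000.0,
    dirichlet_arms: tuple[str, ...] = ("intervention",),
) -> PSADistributions:
    """Independent distributions for the key uncertain parameters.

    The intervention arm's day-365 mRS distribution gets a Dirichlet with
    concentration = baseline proportions x an effective sample size (the
    one-year outcome uncertainty tested in the original analysis; the
    default ESS is of the order of the modelled inception cohort that
    informs the day-365 proportions, and ``dirichlet_arms`` can add the
    control arm); probabilities and utilities get Betas, costs Gammas,
    both moment-matched to the base value with SE = ``se_frac`` of it (no
    dispersions are published for these inputs).
    """
    entries: list[ParamDist] = []
    for arm in dirichlet_arms:
        alpha = np.maximum(cfg.baselines[arm].mrs_day365, 1e-6) * dirichlet_ess
        entries.append(ParamDist(f"baselines.{arm}.mrs_day365", "dirichlet", tuple(alpha)))

    def beta(path: str) -> None:
        m = get_param(cfg, path)
        if m <= 0 or m >= 1:
            entries.append(ParamDist(path, "point", (m,)))
        else:
            entries.append(ParamDist(path, "beta", _beta_moment_match(m, se_frac * m)))

    def gamma(path: str) -> None:
        m = get_param(cfg, path)
        if m <= 0:
            entries.append(ParamDist(path, "point", (m,)))
        else:
            shape = 1.0 / se_frac**2
            entries.append(ParamDist(path, "gamma", (shape, m / shape)))

    for p in ("p_recur_year1", "p_recur_later", "p_death_after_recur"):
        beta(f"transition.{p}")
    for lab in MRS:
        beta(f"utilities.{lab}")
        gamma(f"costs.mgmt_year1.{lab}")
        gamma(f"costs.mgmt_later.{lab}")
    for lab in MRS[1:]:
        beta(f"costs.p_nonmedical_use.{lab}")
        gamma(f"costs.nonmedical.{lab}")
    for lab in (f"mRS{i}" for i in range(7)):
        gamma(f"costs.rehosp.{lab}")
    gamma("costs.nursing_home")
    gamma("costs.program_cost_per_patient")
    return PSADistributions(entries=entries)


def point_mass_distributions(cfg: ModelConfig) -> PSADistributions:
    """Degenerate distributions that reproduce the base case exactly."""
    dists = default_psa_distributions(cfg)
    entries = []
    for e in dists.entries:
        if e.family == "dirichlet":
            arm = e.path.split(".")[1]
            entries.append(ParamDist(e.path, "point", tuple(cfg.baselines[arm].mrs_day365)))
        else:
            entries.append(ParamDist(e.path, "point", (get_param(cfg, e.path),)))
    return PSADistributions(entries=entries)


def _set_mrs_vector(cfg: ModelConfig, arm: str, vec: np.ndarray) -> ModelConfig:
    d = cfg.to_dict()
    d["baselines"][arm]["mrs_day365"] = [float(v) for v in vec]
    return ModelConfig.from_dict(d)


def draw_psa_config(
    cfg: ModelConfig, dists: PSADistributions, seed: int | np.random.Generator
) -> ModelConfig:
    """One sampled configuration; identical seeds give identical samples."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for attempt in range(dists.max_retries):
        sampled = cfg
        for e in dists.entries:
            if e.family == "point":
                if e.path.endswith("mrs_day365"):
                    sampled = _set_mrs_vector(sampled, e.path.split(".")[1], np.asarray(e.params))
                else:
                    sampled = set_param(sampled, e.path, e.params[0])
            elif e.family == "dirichlet":
                vec = rng.dirichlet(np.asarray(e.params))
                sampled = _set_mrs_vector(sampled, e.path.split(".")[1], vec)
            elif e.family == "beta":
                sampled = set_param(sampled, e.path, float(rng.beta(*e.params)))
            elif e.family == "gamma":
                sampled = set_param(sampled, e.path, float(rng.gamma(*e.params)))
            else:
                raise ConfigError(f"unknown distribution family {e.family!r}")
        if not validate_config(sampled):
            return sampled
    raise ConfigError(f"no valid PSA draw after {dists.max_retries} attempts")


@dataclass(eq=False)
class PSAOutput:
    draws: np.ndarray  # (n_draws, 2): delta_cost, delta_qaly
    prob_dominant: float
    prob_cost_effective_at_wtp: float
    wtp: float
    ceac: pd.DataFrame  # columns: wtp, probability

    def plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"draw": np.arange(len(self.draws)), "delta_cost": self.draws[:, 0], "delta_qaly": self.draws[:, 1]}
        )


DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 105_000, 5_000))


def run_psa(
    cfg: ModelConfig,
    dists: PSADistributions | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    wtp: float | None = None,
    perspective: str | None = None,
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID,
) -> PSAOutput:
    """Monte-Carlo decision-uncertainty analysis.

    Each draw samples a full configuration, runs both arms, and records
    the incremental (cost, QALY) pair.  A draw is counted cost-effective
    at a willingness-to-pay when its net monetary benefit is >= 0, and
    dominant when it saves costs without losing QALYs.
    """
    dists = dists or default_psa_distributions(cfg)
    wtp = wtp if wtp is not None else cfg.settings.wtp
    perspective = perspective or cfg.settings.perspective
    if n_draws < 1:
        raise ConfigError(f"n_draws must be >= 1, got {n_draws}")
    streams = np.random.SeedSequence(seed).spawn(n_draws)
    pairs = np.empty((n_draws, 2))
    for i, stream in enumerate(streams):
        sampled = draw_psa_config(cfg, dists, np.random.default_rng(stream))
        _, _, ce = evaluate(sampled, perspective)
        pairs[i] = (ce.delta_cost, ce.delta_qaly)
    dc, dq = pairs[:, 0], pairs[:, 1]
    dominant = (dc <= 0) & (dq >= 0) & ((dc < 0) | (dq > 0))
    grid = sorted(set(wtp_grid) | {wtp})
    ceac = pd.DataFrame(
        {"wtp": grid, "probability": [float(np.mean(g * dq - dc >= 0)) for g in grid]}
    )
    return PSAOutput(
        draws=pairs,
        prob_dominant=float(dominant.mean()),
        prob_cost_effective_at_wtp=float(np.mean(wtp * dq - dc >= 0)),
        wtp=wtp,
        ceac=ceac,
    )


# ---------------------------------------------------------------------------
# threshold analysis
# ---------------------------------------------------------------------------


def per_person_program_cost(total_implementation_cost: float, n: int) -> float:
    """Per-patient program cost when a fixed total is spread over ``n`` patients."""
    if total_implementation_cost <= 0:
        raise ConfigError("total implementation cost must be > 0")
    if n < 1:
        raise ConfigError(f"population size must be >= 1, got {n}")
    return total_implementation_cost / n


def _cost_effective_at(cfg: ModelConfig, total: float, n: int, wtp: float, perspective: str) -> bool:
    cfg_n = set_param(cfg, "costs.program_cost_per_patient", per_person_program_cost(total, n))
    _, _, ce = evaluate(cfg_n, perspective)
    if ce.delta_qaly <= 0:
        return ce.classification == "dominant"
    return net_monetary_benefit(ce, wtp) >= 0


def threshold_population(
    cfg: ModelConfig,
    total_implementation_cost: float | None = None,
    wtp: float | None = None,
    perspective: str | None = None,
    n_max: int = 1_000_000,
) -> tuple[int | None, float | None]:
    """Smallest regional stroke volume at which the program is cost-effective.

    The fixed implementation total divided by the volume ``n`` replaces
    the per-patient program cost; cost-effectiveness is monotone in ``n``
    because that per-person cost is decreasing, so bisection applies.
    Returns ``(None, None)`` when even ``n_max`` patients cannot make the
    program cost-effective.
    """
    total = (
        total_implementation_cost
        if total_implementation_cost is not None
        else cfg.costs.program_total_implementation
    )
    wtp = wtp if wtp is not None else cfg.settings.wtp
    perspective = perspective or cfg.settings.perspective
    if not _cost_effective_at(cfg, total, n_max, wtp, perspective):
        return None, None
    lo, hi = 1, n_max  # invariant: hi is cost-effective
    if _cost_effective_at(cfg, total, lo, wtp, perspective):
        return lo, per_person_program_cost(total, lo)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _cost_effective_at(cfg, total, mid, wtp, perspective):
            hi = mid
        else:
            lo = mid
    return hi, per_person_program_cost(total, hi)


def threshold_population_scan(
    cfg: ModelConfig,
    total_implementation_cost: float | None = None,
    wtp: float | None = None,
    perspective: str | None = None,
    n_max: int = 1000,
) -> int | None:
    """Exhaustive linear-scan oracle for :func:`threshold_population`."""
    total = (
        total_implementation_cost
        if total_implementation_cost is not None
        else cfg.costs.program_total_implementation
    )
    wtp = wtp if wtp is not None else cfg.settings.wtp
    perspective = perspective or cfg.settings.perspective
    for n in range(1, n_max + 1):
        if _cost_effective_at(cfg, total, n, wtp, perspective):
            return n
    return None
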