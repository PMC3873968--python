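"""Markov cohort engine for the five strategy arms.

Each arm propagates an asymptomatic cohort, stratified into low- and
high-risk groups by the prevalence of premalignant lesions, through annual
cycles. Incident cancers are assigned a clinical-stage distribution that
blends the program-detected and usual-practice stage mixes according to the
arm's OGD schedule (down-staging without any change in incidence), and the
stage cohorts are followed to death under combined cancer-specific and
background mortality.

Every arm -- including the no-intervention reference -- runs the same
risk-stratified transition structure so that the per-cycle incident cancer
mass is identical across arms by construction; arms differ only in OGD
delivery, detection weights and costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .epidemiology import PopulationWeights
from .parameters import ModelParams, StrategySpec

__all__ = [
    "N_STAGES",
    "MAX_POST_DX_YEARS",
    "STATE_NAMES",
    "CohortTrace",
    "SubgroupResult",
    "split_incidence",
    "annual_stage_death_prob",
    "combine_competing_risks",
    "detection_weight",
    "stage_mix_at_diagnosis",
    "ogd_delivered",
    "stage_cohort_survival",
    "run_cohort",
    "lifetime_outcomes",
    "aggregate",
    "run_population",
    "evaluate_strategies",
]

N_STAGES = 4
#: post-diagnosis year counter runs 0..5; >= 5 means "5+ years since dx"
MAX_POST_DX_YEARS = 5

STATE_NAMES = (
    ["asymptomatic_lowrisk", "asymptomatic_highrisk"]
    + [
        f"gc_stage{s}_y{k}"
        for s in range(1, N_STAGES + 1)
        for k in range(MAX_POST_DX_YEARS + 1)
    ]
    + ["dead_gc", "dead_other"]
)


# ---------------------------------------------------------------------------
# Elementary transition quantities
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def split_incidence(
    q_pop: float, p: float, odds_ratio: float
) -> tuple[float, float]:
    """Split a population annual GC probability into low-/high-risk rates.

    Solves for (q_low, q_high) such that

    * mixture:      p * q_high + (1 - p) * q_low = q_pop
    * odds ratio:   odds(q_high) = OR * odds(q_low)

    Returns ``(q_low, q_high)`` with ``q_low <= q_pop <= q_high``.
    """
    if not 0.0 <= q_pop < 1.0:
        raise ValueError(f"q_pop {q_pop} outside [0, 1)")
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence {p} outside (0, 1)")
    if odds_ratio < 1.0:
        raise ValueError(f"odds ratio {odds_ratio} < 1")
    if q_pop == 0.0 or odds_ratio == 1.0:
        return (q_pop, q_pop)

    def q_high_of(q_low: float) -> float:
        odds_high = odds_ratio * q_low / (1.0 - q_low)
        return odds_high / (1.0 + odds_high)

    def mixture_gap(q_low: float) -> float:
        return p * q_high_of(q_low) + (1.0 - p) * q_low - q_pop

    # q_low = q_pop overshoots (q_high >= q_pop), q_low = 0 undershoots
    lo, hi = 0.0, q_pop
    if mixture_gap(hi) < 0:  # cannot occur for valid inputs; guarded anyway
        raise ValueError("no root in (0, 1) for the incidence split")
    q_low = brentq(mixture_gap, lo, hi, xtol=1e-16, rtol=8.9e-16)
    q_high = q_high_of(q_low)
    return (q_low, q_high)


def annual_stage_death_prob(stage: int, survival) -> float:
    """Annual cancer-specific death probability from 5-year survival.

    Constant-hazard conversion ``p = 1 - S5 ** (1/5)``; an exact S5 of 0
    (stage 4) is replaced by ``survival.stage4_epsilon``.
    """
    if not 1 <= stage <= N_STAGES:
        raise ValueError(f"stage {stage} outside 1..{N_STAGES}")
    s5 = survival.five_year_survival[stage - 1]
    if not 0.0 <= s5 <= 1.0:
        raise ValueError(f"5-year survival {s5} outside [0, 1]")
    if s5 == 0.0:
        s5 = survival.stage4_epsilon
    return 1.0 - s5 ** 0.2


def combine_competing_risks(p_gc: float, p_background: float) -> float:
    """Total death probability under independent competing risks."""
    for name, v in (("p_gc", p_gc), ("p_background", p_background)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0, 1]")
    return 1.0 - (1.0 - p_gc) * (1.0 - p_background)


def _hazard_share(p_gc: float, p_background: float) -> float:
    """Fraction of within-cycle deaths attributed to the cancer cause.

    Deaths are split in proportion to the -ln(1 - p) hazards.
    """
    if p_gc >= 1.0:
        return 1.0
    if p_background >= 1.0:
        return 0.0
    h_gc = -math.log1p(-p_gc)
    h_bg = -math.log1p(-p_background)
    total = h_gc + h_bg
    return h_gc / total if total > 0 else 0.0


def ogd_delivered(strategy: StrategySpec, risk_group: str, cycle_index: int) -> bool:
    """Whether the group's schedule delivers an OGD in this cycle.

    Cycle 0 is the baseline examination for every group of an arm with a
    baseline OGD; 2-yearly schedules then deliver in even cycles counted
    from program entry.
    """
    if cycle_index == 0:
        return strategy.baseline_ogd_all
    period = (
        strategy.highrisk_ogd_period
        if risk_group == "high"
        else strategy.lowrisk_ogd_period
    )
    if period is None:
        return False
    return period == 1 or cycle_index % period == 0


def detection_weight(
    strategy: StrategySpec,
    risk_group: str,
    cycle_index: int,
    sensitivity: float,
) -> float:
    """Program detection weight w in [0, 1] for this group and cycle.

    w = Se in OGD years, Se * interval_effect_fraction in the interval years
    of a 2-yearly schedule, 0 for groups with no OGD at all.
    """
    if risk_group not in ("low", "high"):
        raise ValueError(f"unknown risk group {risk_group!r}")
    if ogd_delivered(strategy, risk_group, cycle_index):
        return sensitivity
    period = (
        strategy.highrisk_ogd_period
        if risk_group == "high"
        else strategy.lowrisk_ogd_period
    )
    if period == 2:
        return sensitivity * strategy.interval_effect_fraction
    return 0.0


def stage_mix_at_diagnosis(
    w: float,
    program_dist: tuple[float, ...],
    usual_dist: tuple[float, ...],
) -> tuple[float, ...]:
    """Blend of program and usual-practice stage distributions at weight w."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"detection weight {w} outside [0, 1]")
    return tuple(
        w * a + (1.0 - w) * b for a, b in zip(program_dist, usual_dist)
    )


def stage_cohort_survival(
    stage: int,
    n_cycles: int,
    params: ModelParams,
    background_prob: float = 0.0,
) -> float:
    """Survival of a pure stage-``stage`` cohort after ``n_cycles`` cycles,
    using the same per-cycle mortality combination as the cohort engine."""
    p_gc = annual_stage_death_prob(stage, params.survival)
    alive = 1.0
    for _ in range(n_cycles):
        alive *= 1.0 - combine_competing_risks(p_gc, background_prob)
    return alive


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle record of one strategy arm for one (sex, start age) cohort.

    ``cost`` and ``qaly`` are *discounted* per-cycle increments; ``ogd``,
    ``gc_incidence`` and ``gc_deaths`` are undiscounted per-person counts.
    ``states`` holds start-of-next-cycle occupancy (i.e. occupancy after the
    cycle's transitions), one row per cycle, columns in :data:`STATE_NAMES`.
    """

    strategy: str
    sex: str
    start_age: int
    discount_rate: float
    cycles: np.ndarray
    ages: np.ndarray
    states: np.ndarray
    cost: np.ndarray
    qaly: np.ndarray
    ogd: np.ndarray
    gc_incidence: np.ndarray
    gc_deaths: np.ndarray

    def n_cycles(self) -> int:
        return len(self.cycles)

    def occupancy_totals(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def dead_fraction(self) -> np.ndarray:
        return self.states[:, -2:].sum(axis=1)

    def alive_fraction(self) -> np.ndarray:
        return 1.0 - self.dead_fraction()

    def asymptomatic_fraction(self) -> np.ndarray:
        return self.states[:, :2].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", self.cycles)
        df["cost"] = self.cost
        df["qaly"] = self.qaly
        df["ogd"] = self.ogd
        df["gc_incidence"] = self.gc_incidence
        df["gc_deaths"] = self.gc_deaths
        return df


@dataclass
class SubgroupResult:
    """Discounted lifetime outcomes per person for one subgroup/strategy."""

    strategy: str
    sex: str
    start_age: int | str
    cost: float
    qaly: float
    ogd: float
    gc_deaths: float
    gc_cases: float = 0.0


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def run_cohort(
    strategy: StrategySpec | str,
    sex: str,
    start_age: int,
    params: ModelParams,
) -> CohortTrace:
    """Run one strategy arm for a cohort starting asymptomatic at ``start_age``.

    Event order within a cycle: OGD delivery and its costs for alive
    asymptomatic subjects -> incidence draw -> stage assignment with
    diagnosis/treatment costs -> mortality (cancer-specific combined with
    background). Utilities accrue on start-of-cycle occupancy with incident
    cases switching to their stage utility in the incidence cycle; no
    half-cycle correction unless ``params.econ.half_cycle_correction``.
    """
    if isinstance(strategy, str):
        strategy = params.strategies[strategy]
    econ = params.econ
    risk = params.risk
    test = params.test
    costs = params.costs
    util = params.utilities
    prog = params.stage_program.as_tuple()
    usual = params.stage_usual.as_tuple()
    p_gc_death = [
        annual_stage_death_prob(s, params.survival) for s in range(1, N_STAGES + 1)
    ]

    # a rate table not covering an age requested before termination raises
    # KeyError from RateTable.value
    last_age = econ.max_age

    # state arrays
    a = {"low": 1.0 - risk.prevalence, "high": risk.prevalence}
    gc = [[0.0] * (MAX_POST_DX_YEARS + 1) for _ in range(N_STAGES)]
    dead_gc = 0.0
    dead_other = 0.0

    rows = []
    rec_cost, rec_qaly, rec_ogd, rec_inc, rec_gcd = [], [], [], [], []
    ages, cycles = [], []

    t = 0
    while True:
        age = start_age + t
        disc = (1.0 + econ.discount_rate) ** (-t)
        q_bg = params.mortality.annual_probability(age, sex)
        q_pop = params.incidence.annual_probability(age, sex)
        q_grp = dict(
            zip(("low", "high"), split_incidence(q_pop, risk.prevalence,
                                                 risk.odds_ratio))
        )

        cost_t = 0.0
        qaly_t = 0.0
        ogd_t = 0.0
        inc_t = 0.0
        gcd_t = 0.0

        # ---- OGD delivery, incidence, stage assignment per risk group ----
        new_gc = [0.0] * N_STAGES
        for g in ("low", "high"):
            mass = a[g]
            if mass <= 0.0:
                a[g] = 0.0
                continue
            incident = mass * q_grp[g]
            inc_t += incident
            delivered = ogd_delivered(strategy, g, t)
            if delivered:
                unit = costs.baseline_ogd if t == 0 else costs.followup_ogd
                cost_t += mass * unit / (1.0 - costs.program_cost_proportion)
                ogd_t += mass
                # false-positive workup among screened subjects without cancer
                cost_t += (
                    (mass - incident)
                    * (1.0 - test.specificity)
                    * costs.dx_staging_program
                )
            w = detection_weight(strategy, g, t, test.sensitivity)
            mix = stage_mix_at_diagnosis(w, prog, usual)
            cost_t += incident * (
                w * costs.dx_staging_program + (1.0 - w) * costs.dx_staging_usual
            )
            for s in range(N_STAGES):
                share = incident * mix[s]
                new_gc[s] += share
                cost_t += share * costs.treatment_by_stage[s]
                qaly_t += share * util.stage[s]
            qaly_t += (mass - incident) * util.asymptomatic
            a[g] = mass - incident

        # ---- prevalent cancer states: follow-up cost and utility ----
        for s in range(N_STAGES):
            cells = gc[s]
            for k in range(MAX_POST_DX_YEARS + 1):
                occ = cells[k]
                if occ == 0.0:
                    continue
                qaly_t += occ * util.stage[s]
                if 1 <= k <= MAX_POST_DX_YEARS:
                    cost_t += occ * costs.post_treatment_followup_annual
            cells[0] += new_gc[s]

        # ---- mortality ----
        for g in ("low", "high"):
            deaths = a[g] * q_bg
            dead_other += deaths
            a[g] -= deaths
        for s in range(N_STAGES):
            p_total = combine_competing_risks(p_gc_death[s], q_bg)
            share_gc = _hazard_share(p_gc_death[s], q_bg)
            cells = gc[s]
            survived = [0.0] * (MAX_POST_DX_YEARS + 1)
            for k in range(MAX_POST_DX_YEARS + 1):
                occ = cells[k]
                if occ == 0.0:
                    continue
                d = occ * p_total
                dead_gc += d * share_gc
                dead_other += d * (1.0 - share_gc)
                gcd_t += d * share_gc
                survived[min(k + 1, MAX_POST_DX_YEARS)] += occ - d
            gc[s] = survived

        if econ.half_cycle_correction and t == 0:
            qaly_t *= 0.5

        # ---- record ----
        cycles.append(t)
        ages.append(age)
        rec_cost.append(cost_t * disc)
        rec_qaly.append(qaly_t * disc)
        rec_ogd.append(ogd_t)
        rec_inc.append(inc_t)
        rec_gcd.append(gcd_t)
        state_row = [a["low"], a["high"]]
        for s in range(N_STAGES):
            state_row.extend(gc[s])
        state_row.extend([dead_gc, dead_other])
        rows.append(state_row)

        t += 1
        dead = dead_gc + dead_other
        if dead >= econ.termination_fraction or start_age + t > last_age:
            break

    return CohortTrace(
        strategy=strategy.name,
        sex=sex,
        start_age=start_age,
        discount_rate=econ.discount_rate,
        cycles=np.asarray(cycles),
        ages=np.asarray(ages),
        states=np.asarray(rows),
        cost=np.asarray(rec_cost),
        qaly=np.asarray(rec_qaly),
        ogd=np.asarray(rec_ogd),
        gc_incidence=np.asarray(rec_inc),
        gc_deaths=np.asarray(rec_gcd),
    )


def lifetime_outcomes(trace: CohortTrace) -> SubgroupResult:
    """Sum a trace's discounted increments into per-person lifetime outcomes."""
    return SubgroupResult(
        strategy=trace.strategy,
        sex=trace.sex,
        start_age=trace.start_age,
        cost=float(trace.cost.sum()),
        qaly=float(trace.qaly.sum()),
        ogd=float(trace.ogd.sum()),
        gc_deaths=float(trace.gc_deaths.sum()),
        gc_cases=float(trace.gc_incidence.sum()),
    )


def aggregate(
    results: dict[tuple[int, str], SubgroupResult],
    weights: PopulationWeights,
) -> SubgroupResult:
    """Weight-average per-person outcomes over (age, sex) subgroups."""
    keys = set(results)
    wkeys = {k for k, _ in weights.items()}
    if keys != wkeys:
        raise ValueError(
            f"subgroup keys {sorted(keys)} do not match weight keys {sorted(wkeys)}"
        )
    strategies = {r.strategy for r in results.values()}
    if len(strategies) != 1:
        raise ValueError("cannot aggregate results from different strategies")
    cost = qaly = ogd = gcd = cases = 0.0
    for key, w in weights.items():
        r = results[key]
        cost += w * r.cost
        qaly += w * r.qaly
        ogd += w * r.ogd
        gcd += w * r.gc_deaths
        cases += w * r.gc_cases
    return SubgroupResult(
        strategy=strategies.pop(),
        sex="all",
        start_age="all",
        cost=cost,
        qaly=qaly,
        ogd=ogd,
        gc_deaths=gcd,
        gc_cases=cases,
    )


def run_population(
    strategy: str,
    params: ModelParams,
    weights: PopulationWeights | None = None,
) -> SubgroupResult:
    """Run one arm over every (age, sex) cell of the population weights."""
    weights = weights or params.weights
    results = {
        (age, sex): lifetime_outcomes(run_cohort(strategy, sex, age, params))
        for (age, sex), _w in weights.items()
    }
    return aggregate(results, weights)


def evaluate_strategies(
    params: ModelParams,
    subgroup: tuple[int, str] | None = None,
    strategies: tuple[str, ...] | None = None,
) -> dict[str, SubgroupResult]:
    """Lifetime outcomes for each arm, population-weighted or at one subgroup.

    ``subgroup`` is an (age, sex) pair; when omitted the arm is averaged
    over ``params.weights``.
    """
    names = strategies or tuple(params.strategies)
    out: dict[str, SubgroupResult] = {}
    for name in names:
        if subgroup is None:
            out[name] = run_population(name, params)
        else:
            age, sex = subgroup
            out[name] = lifetime_outcomes(run_cohort(name, sex, age, params))
    return out
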