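"""Deterministic and probabilistic sensitivity analysis, and internal
validation of the cohort engine against its input tables.

* One-way DSA re-runs the full five-arm model across a parameter grid and
  reports per-strategy net-health-benefit (NHB) curves, influence flags and
  the direction of the NHB relationship.
* Threshold finding bisects on the NHB gap between competing strategies to
  locate the parameter values at which the optimal strategy switches.
* PSA draws parameters from method-of-moments distributions (gamma,
  lognormal, beta, Dirichlet, empirical starting age), runs the model per
  draw and summarises the cost-effectiveness acceptability frontier (CEAF).
* Internal validation compares projected all-cause survival and cumulative
  cancer incidence against curves built directly from the input rate tables
  using the Mantel-Cox log-rank statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .epidemiology import PopulationWeights
from .frontier import StrategyOutcome, build_frontier, nhb, nmb, optimal_at_wtp
from .markov import (
    CohortTrace,
    N_STAGES,
    annual_stage_death_prob,
    combine_competing_risks,
    evaluate_strategies,
    lifetime_outcomes,
    run_cohort,
    split_incidence,
)
from .parameters import (
    PARAM_RANGES,
    ModelParams,
    get_param,
    set_param,
)

__all__ = [
    "ParamRange",
    "ThresholdFinding",
    "DistributionSpec",
    "PSASamples",
    "CEAFPoint",
    "INFLUENCE_THRESHOLD_QALY",
    "one_way_dsa",
    "dsa_direction",
    "find_crossings",
    "find_switch_thresholds",
    "fit_moments",
    "default_psa_specs",
    "sample_params",
    "run_psa",
    "default_wtp_grid",
    "logrank_from_counts",
    "expected_curves",
    "logrank_validation",
]

#: parameters causing at least this much NHB swing are flagged influential
INFLUENCE_THRESHOLD_QALY = 0.2


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class ParamRange:
    path: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.path}: low {self.low} >= high {self.high}")


def _evaluate_at(params: ModelParams, path: str, value) -> dict[str, tuple]:
    """(cost, qaly) per strategy with one parameter moved off base case."""
    if path == "start_age":
        # starting age is a population attribute, not a ModelParams scalar:
        # evaluate at a single integer start age, sexes weighted equally
        age = int(round(value))
        out = {}
        for name in params.strategies:
            cost = qaly = 0.0
            for sex in ("male", "female"):
                r = lifetime_outcomes(run_cohort(name, sex, age, params))
                cost += 0.5 * r.cost
                qaly += 0.5 * r.qaly
            out[name] = (cost, qaly)
        return out
    moved = set_param(params, path, float(value))
    return {
        name: (r.cost, r.qaly)
        for name, r in evaluate_strategies(moved).items()
    }


def one_way_dsa(
    param_path: str,
    value_range: tuple[float, float] | None,
    grid_size: int,
    params: ModelParams,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Per-strategy NHB curves over a parameter grid, all else at base case.

    Returns a tidy frame with columns parameter, value, strategy, cost,
    qaly, nhb.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if value_range is None:
        if param_path not in PARAM_RANGES:
            raise KeyError(f"no stored range for parameter {param_path!r}")
        value_range = PARAM_RANGES[param_path]
    lo, hi = value_range
    if lo > hi:
        raise ValueError(f"empty range ({lo}, {hi})")
    wtp = params.econ.wtp if wtp is None else wtp
    if param_path == "start_age":
        values = sorted({int(round(v)) for v in np.linspace(lo, hi, grid_size)})
    else:
        values = list(np.linspace(lo, hi, grid_size))
    rows = []
    for v in values:
        for name, (cost, qaly) in _evaluate_at(params, param_path, v).items():
            rows.append(
                {
                    "parameter": param_path,
                    "value": float(v),
                    "strategy": name,
                    "cost": cost,
                    "qaly": qaly,
                    "nhb": nhb(cost, qaly, wtp),
                }
            )
    return pd.DataFrame(rows)


def dsa_direction(curves: pd.DataFrame, eps: float = 1e-6) -> dict:
    """Summarise a one-way DSA frame.

    The reported ``direction`` is that of the *model* NHB -- the upper
    envelope over strategies, i.e. the NHB attained by choosing the optimal
    strategy at each grid value: "positive" when non-decreasing with a net
    rise, "negative" when non-increasing with a net fall, "flat" when the
    envelope barely moves, "mixed" otherwise. Per-strategy swings, the
    maximum swing and the ``influential`` flag (max swing >= 0.2 QALY) are
    also returned.
    """
    swings = {
        name: float(grp["nhb"].max() - grp["nhb"].min())
        for name, grp in curves.groupby("strategy")
    }
    envelope = (
        curves.groupby("value")["nhb"].max().sort_index().to_numpy()
    )
    diffs = np.diff(envelope)
    total = float(envelope[-1] - envelope[0])
    span = float(envelope.max() - envelope.min())
    if span <= eps:
        direction = "flat"
    elif (diffs >= -eps).all() and total > eps:
        direction = "positive"
    elif (diffs <= eps).all() and total < -eps:
        direction = "negative"
    else:
        direction = "mixed"
    max_swing = max(swings.values()) if swings else 0.0
    return {
        "swings": swings,
        "max_swing": max_swing,
        "influential": max_swing >= INFLUENCE_THRESHOLD_QALY,
        "direction": direction,
    }


# ---------------------------------------------------------------------------
# Switch-threshold finding
# ---------------------------------------------------------------------------

@dataclass
class ThresholdFinding:
    parameter: str
    low: float
    high: float
    cut_points: list[float]
    optimal_by_interval: list[str]
    direction: str = "unknown"

    def intervals(self) -> list[tuple[float, float, str]]:
        edges = [self.low] + list(self.cut_points) + [self.high]
        return [
            (a, b, s)
            for a, b, s in zip(edges, edges[1:], self.optimal_by_interval)
        ]


def _argmax_nhb(nhb_by_strategy: dict[str, float]) -> str:
    return max(sorted(nhb_by_strategy), key=lambda k: nhb_by_strategy[k])


def find_crossings(
    eval_fn,
    low: float,
    high: float,
    tol: float = 1e-6,
    n_scan: int = 33,
    max_crossings: int = 8,
) -> ThresholdFinding:
    """Locate optimal-strategy switch points of ``eval_fn`` on [low, high].

    ``eval_fn(theta)`` returns a dict strategy -> NHB. A coarse scan finds
    intervals where the argmax changes; bisection on the NHB gap between
    the two competing strategies then localises each crossing to ``tol``.
    """
    if not low < high:
        raise ValueError(f"empty range ({low}, {high})")
    grid = np.linspace(low, high, n_scan)
    evals = {float(g): eval_fn(float(g)) for g in grid}
    winners = [_argmax_nhb(evals[float(g)]) for g in grid]

    cuts: list[float] = []
    labels: list[str] = [winners[0]]
    for i in range(len(grid) - 1):
        if winners[i] == winners[i + 1]:
            continue
        a, b = float(grid[i]), float(grid[i + 1])
        wa, wb = winners[i], winners[i + 1]
        gap = lambda th, s1=wa, s2=wb: eval_fn(th)[s1] - eval_fn(th)[s2]
        ga, gb = gap(a), gap(b)
        if ga == 0.0:
            cut = a
        elif gb == 0.0:
            cut = b
        elif ga * gb < 0:
            while b - a > tol:
                mid = 0.5 * (a + b)
                gm = gap(mid)
                if gm == 0.0:
                    a = b = mid
                elif (gm > 0) == (ga > 0):
                    a, ga = mid, gm
                else:
                    b = mid
            cut = 0.5 * (a + b)
        else:
            # argmax changed without a pairwise sign change (third strategy
            # involved); fall back to the midpoint of the scan interval
            cut = 0.5 * (a + b)
        cuts.append(cut)
        labels.append(wb)
        if len(cuts) > max_crossings:
            raise RuntimeError(
                f"more than {max_crossings} optimal-strategy crossings detected;"
                " non-monotone NHB pathology"
            )
    # verify interval labels at midpoints
    edges = [low] + cuts + [high]
    verified = []
    for a, b in zip(edges, edges[1:]):
        verified.append(_argmax_nhb(eval_fn(0.5 * (a + b))))
    return ThresholdFinding(
        parameter="",
        low=low,
        high=high,
        cut_points=cuts,
        optimal_by_interval=verified,
    )


def find_switch_thresholds(
    param_path: str,
    value_range: tuple[float, float] | None,
    params: ModelParams,
    wtp: float | None = None,
    tol: float = 1e-4,
    n_scan: int = 17,
) -> ThresholdFinding:
    """Optimal-strategy switch points for one model parameter (Table-4 style)."""
    if value_range is None:
        value_range = PARAM_RANGES[param_path]
    lo, hi = value_range
    wtp = params.econ.wtp if wtp is None else wtp
    cache: dict[float, dict[str, float]] = {}

    def eval_fn(theta: float) -> dict[str, float]:
        if theta not in cache:
            cache[theta] = {
                name: nhb(cost, qaly, wtp)
                for name, (cost, qaly) in _evaluate_at(
                    params, param_path, theta
                ).items()
            }
        return cache[theta]

    finding = find_crossings(eval_fn, lo, hi, tol=tol, n_scan=n_scan)
    finding.parameter = param_path
    curves = one_way_dsa(param_path, (lo, hi), max(n_scan // 2, 5), params, wtp)
    finding.direction = dsa_direction(curves)["direction"]
    return finding


# ---------------------------------------------------------------------------
# Method-of-moments distributions and PSA
# ---------------------------------------------------------------------------

@dataclass
class DistributionSpec:
    """One PSA parameter: distribution family plus moments (or proportions).

    ``family`` is one of gamma, lognormal, beta, dirichlet, empirical_age.
    Gamma/lognormal/beta use (mean, sd); dirichlet uses ``proportions`` with
    an effective sample size ``ess``; empirical_age uses population weights.
    ``truncate_at_one`` clips draws at 1 (used for gamma-distributed
    utilities).
    """

    path: str
    family: str
    mean: float | None = None
    sd: float | None = None
    proportions: tuple[float, ...] | None = None
    ess: float = 100.0
    truncate_at_one: bool = False


def fit_moments(family: str, mean: float, sd: float):
    """Method-of-moments parameters plus a sampler for one family.

    Returns ``(param_dict, sampler)`` where ``sampler(rng, size=None)``
    draws from the fitted distribution.
    """
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma mean must be > 0")
        shape = (mean / sd) ** 2
        rate = mean / sd**2
        pars = {"shape": shape, "rate": rate}
        sampler = lambda rng, size=None: rng.gamma(shape, 1.0 / rate, size)
    elif family == "lognormal":
        if mean <= 0:
            raise ValueError("lognormal mean must be > 0")
        sigma2 = math.log(1.0 + sd**2 / mean**2)
        mu = math.log(mean) - sigma2 / 2.0
        sigma = math.sqrt(sigma2)
        pars = {"mu": mu, "sigma": sigma}
        sampler = lambda rng, size=None: rng.lognormal(mu, sigma, size)
    elif family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError("beta mean must lie in (0, 1)")
        if sd**2 >= mean * (1.0 - mean):
            raise ValueError(
                f"infeasible beta moments: sd^2 {sd**2:.6g} >= "
                f"mean(1-mean) {mean * (1 - mean):.6g}"
            )
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        alpha = mean * nu
        beta_par = (1.0 - mean) * nu
        pars = {"alpha": alpha, "beta": beta_par}
        sampler = lambda rng, size=None: rng.beta(alpha, beta_par, size)
    else:
        raise ValueError(f"unknown moment-fitted family {family!r}")
    return pars, sampler


def default_psa_specs(params: ModelParams, ess: float = 100.0) -> list[DistributionSpec]:
    """The nine PSA parameters: four stage utilities (gamma, truncated at 1),
    odds ratio (lognormal), premalignancy prevalence (beta), the two stage
    distributions (Dirichlet) and the starting age (empirical weights)."""
    u_sd = (0.05, 0.07, 0.10, 0.08)
    specs = [
        DistributionSpec(
            f"utilities.stage{i}",
            "gamma",
            mean=params.utilities.stage[i - 1],
            sd=u_sd[i - 1],
            truncate_at_one=True,
        )
        for i in range(1, N_STAGES + 1)
    ]
    specs.append(
        DistributionSpec("risk.odds_ratio", "lognormal", mean=6.00, sd=2.46)
    )
    specs.append(
        DistributionSpec("risk.prevalence", "beta", mean=0.135, sd=0.0675)
    )
    specs.append(
        DistributionSpec(
            "stage_program",
            "dirichlet",
            proportions=params.stage_program.as_tuple(),
            ess=ess,
        )
    )
    specs.append(
        DistributionSpec(
            "stage_usual",
            "dirichlet",
            proportions=params.stage_usual.as_tuple(),
            ess=ess,
        )
    )
    specs.append(DistributionSpec("start_age", "empirical_age"))
    return specs


def sample_params(
    base_params: ModelParams,
    specs: list[DistributionSpec],
    rng: np.random.Generator,
) -> tuple[ModelParams, tuple[int, str] | None]:
    """One PSA draw: a valid ModelParams plus the drawn (age, sex) subgroup.

    The subgroup is None when no empirical_age spec is present (the arm is
    then evaluated population-weighted).
    """
    draw = base_params.copy()
    subgroup: tuple[int, str] | None = None
    for spec in specs:
        if spec.family in ("gamma", "lognormal", "beta"):
            _, sampler = fit_moments(spec.family, spec.mean, spec.sd)
            value = float(sampler(rng))
            if spec.truncate_at_one:
                value = min(value, 1.0)
            draw = set_param(draw, spec.path, value)
        elif spec.family == "dirichlet":
            alpha = np.asarray(spec.proportions, dtype=float) * spec.ess
            props = rng.dirichlet(alpha)
            dist = getattr(draw, spec.path)
            dist.s1, dist.s2, dist.s3, dist.s4 = (float(x) for x in props)
        elif spec.family == "empirical_age":
            weights = base_params.weights
            keys = [k for k, _ in weights.items()]
            probs = np.array([w for _, w in weights.items()])
            idx = rng.choice(len(keys), p=probs / probs.sum())
            subgroup = keys[idx]
        else:
            raise ValueError(f"unknown PSA family {spec.family!r}")
    return draw, subgroup


@dataclass
class PSASamples:
    """Per-iteration (strategy -> cost, effect) pairs from the PSA."""

    seed: int
    frame: pd.DataFrame  # columns: iteration, strategy, cost, effect

    def n_iterations(self) -> int:
        return int(self.frame["iteration"].nunique())


@dataclass
class CEAFPoint:
    wtp: float
    strategy: str
    probability: float


def default_wtp_grid() -> np.ndarray:
    """$0-$100,000 in $1,000 steps (0 replaced by $500 to keep NHB finite)."""
    grid = np.arange(0.0, 100_001.0, 1000.0)
    grid[0] = 500.0
    return grid


def run_psa(
    params: ModelParams,
    specs: list[DistributionSpec] | None,
    n: int,
    seed: int,
    wtp_grid: np.ndarray | None = None,
) -> tuple[PSASamples, list[CEAFPoint]]:
    """Monte-Carlo PSA: n model runs on drawn parameters, plus the CEAF.

    At each willingness-to-pay the CEAF reports the strategy with maximal
    *expected* NMB and the fraction of iterations in which that strategy
    attains the per-iteration maximum (exact ties split equally).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = default_psa_specs(params) if specs is None else specs
    wtp_grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid)
    rng = np.random.default_rng(seed)
    names = list(params.strategies)
    rows = []
    costs = np.empty((n, len(names)))
    effects = np.empty((n, len(names)))
    for it in range(n):
        # per-iteration substream so earlier draws are stable when n changes
        it_rng = np.random.default_rng([seed, it])
        draw, subgroup = sample_params(params, specs, it_rng)
        outcomes = evaluate_strategies(draw, subgroup=subgroup)
        for j, name in enumerate(names):
            r = outcomes[name]
            costs[it, j] = r.cost
            effects[it, j] = r.qaly
            rows.append(
                {
                    "iteration": it,
                    "strategy": name,
                    "cost": r.cost,
                    "effect": r.qaly,
                }
            )
    samples = PSASamples(seed=seed, frame=pd.DataFrame(rows))

    ceaf: list[CEAFPoint] = []
    for lam in wtp_grid:
        nmb_matrix = lam * effects - costs  # (n, n_strategies)
        mean_nmb = nmb_matrix.mean(axis=0)
        best_j = int(np.argmax(mean_nmb))
        row_max = nmb_matrix.max(axis=1, keepdims=True)
        is_max = nmb_matrix == row_max
        share = is_max / is_max.sum(axis=1, keepdims=True)
        prob = float(share[:, best_j].mean())
        ceaf.append(CEAFPoint(wtp=float(lam), strategy=names[best_j],
                              probability=prob))
    return samples, ceaf


# ---------------------------------------------------------------------------
# Internal log-rank validation
# ---------------------------------------------------------------------------

def logrank_from_counts(
    n1: np.ndarray, d1: np.ndarray, n2: np.ndarray, d2: np.ndarray
) -> tuple[float, float]:
    """Mantel-Cox log-rank statistic from per-interval at-risk/event counts.

    Observed-minus-expected events in group 1 with the hypergeometric
    variance; returns the chi-square statistic (1 df) and its p-value.
    """
    n1, d1, n2, d2 = (np.asarray(x, dtype=float) for x in (n1, d1, n2, d2))
    if not (len(n1) == len(d1) == len(n2) == len(d2)):
        raise ValueError("count arrays must have equal length")
    ntot = n1 + n2
    dtot = d1 + d2
    mask = ntot > 0
    if not mask.any():
        raise ValueError("empty risk sets")
    n1, d1, ntot, dtot = n1[mask], d1[mask], ntot[mask], dtot[mask]
    expected = dtot * n1 / ntot
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dtot * (n1 / ntot) * (1.0 - n1 / ntot) * (ntot - dtot) / (ntot - 1.0)
    var = np.where(ntot > 1, var, 0.0)
    o_minus_e = float((d1 - expected).sum())
    v = float(var.sum())
    if v == 0.0:
        return 0.0, 1.0
    statistic = o_minus_e**2 / v
    return statistic, float(stats.chi2.sf(statistic, df=1))


def expected_curves(
    params: ModelParams,
    sex: str,
    start_age: int,
    n_cycles: int,
) -> pd.DataFrame:
    """All-cause survival and GC incidence built directly from the tables.

    A minimal recursion independent of the strategy machinery (no OGDs, no
    costs, no post-diagnosis bookkeeping): the asymptomatic pool -- risk-
    stratified by premalignancy prevalence so that selective depletion of
    the high-risk group is represented -- decays by the table incidence and
    background mortality; incident cancers take the usual-practice stage
    mix and die under combined cancer-specific plus background mortality.
    Columns: at_risk (start of cycle), deaths (events in cycle), asym
    (asymptomatic at start of cycle), incident (events in cycle).
    """
    usual = params.stage_usual.as_tuple()
    p_stage = [
        annual_stage_death_prob(s, params.survival) for s in range(1, N_STAGES + 1)
    ]
    prevalence = params.risk.prevalence
    odds_ratio = params.risk.odds_ratio
    a = [1.0 - prevalence, prevalence]  # low-, high-risk asymptomatic
    gc = [0.0] * N_STAGES
    rows = []
    for t in range(n_cycles):
        age = start_age + t
        q_bg = params.mortality.annual_probability(age, sex)
        q_pop = params.incidence.annual_probability(age, sex)
        q_grp = split_incidence(q_pop, prevalence, odds_ratio)
        at_risk = sum(a) + sum(gc)
        incident = sum(m * q for m, q in zip(a, q_grp))
        deaths = sum((m - m * q) * q_bg for m, q in zip(a, q_grp))
        new_gc = [incident * usual[s] for s in range(N_STAGES)]
        for s in range(N_STAGES):
            occ = gc[s] + new_gc[s]
            p_total = combine_competing_risks(p_stage[s], q_bg)
            deaths += occ * p_total
            gc[s] = occ * (1.0 - p_total)
        rows.append(
            {"cycle": t, "at_risk": at_risk, "deaths": deaths,
             "asym": sum(a), "incident": incident}
        )
        a = [(m - m * q) * (1.0 - q_bg) for m, q in zip(a, q_grp)]
    return pd.DataFrame(rows)


def logrank_validation(
    trace: CohortTrace,
    expected_mortality,
    expected_incidence,
    params: ModelParams,
    pseudo_n: float = 10_000.0,
) -> dict[str, tuple[float, float]]:
    """Log-rank goodness-of-fit of a trace against its input tables.

    Returns ``{"mortality": (chi2, p), "incidence": (chi2, p)}``. Cohort
    fractions are scaled to a pseudo-population of ``pseudo_n`` subjects.
    """
    if trace.n_cycles() < 2:
        raise ValueError("trace must cover at least 2 cycles")
    ref = replace(
        params.copy(), mortality=expected_mortality, incidence=expected_incidence
    )
    exp = expected_curves(ref, trace.sex, trace.start_age, trace.n_cycles())

    alive_end = trace.alive_fraction()
    alive_start = np.concatenate([[1.0], alive_end[:-1]])
    deaths = alive_start - alive_end

    asym_end = trace.asymptomatic_fraction()
    asym_start = np.concatenate([[1.0], asym_end[:-1]])

    out = {}
    out["mortality"] = logrank_from_counts(
        alive_start * pseudo_n,
        deaths * pseudo_n,
        exp["at_risk"].to_numpy() * pseudo_n,
        exp["deaths"].to_numpy() * pseudo_n,
    )
    out["incidence"] = logrank_from_counts(
        asym_start * pseudo_n,
        trace.gc_incidence * pseudo_n,
        exp["asym"].to_numpy() * pseudo_n,
        exp["incident"].to_numpy() * pseudo_n,
    )
    return out
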