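"""Cost-effectiveness frontier: ICERs, dominance and optimal-strategy choice.

Strategies are ordered by ascending cost; strictly dominated strategies are
removed first, then extendedly dominated ones (those whose incremental
cost-effectiveness ratio exceeds that of a more effective alternative) until
the surviving ICER sequence is strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "StrategyOutcome",
    "Frontier",
    "build_frontier",
    "optimal_at_wtp",
    "nhb",
    "nmb",
    "ON_FRONTIER",
    "DOMINATED",
    "EXTENDEDLY_DOMINATED",
]

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-person discounted lifetime cost ($) and effect (QALY) of one arm."""

    name: str
    cost: float
    effect: float


@dataclass
class Frontier:
    """Outcomes sorted by cost with dominance status and frontier ICERs.

    ``icers[name]`` is the ICER of an on-frontier strategy versus the
    previous on-frontier strategy (None for the cheapest one).
    """

    outcomes: list[StrategyOutcome]
    status: dict[str, str]
    icers: dict[str, float | None] = field(default_factory=dict)

    def on_frontier(self) -> list[StrategyOutcome]:
        return [o for o in self.outcomes if self.status[o.name] == ON_FRONTIER]

    def to_frame(self, wtp: float | None = None) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            row = {
                "strategy": o.name,
                "cost": o.cost,
                "qaly": o.effect,
                "status": self.status[o.name],
                "icer": self.icers.get(o.name),
            }
            if wtp is not None:
                row["nmb_at_wtp"] = nmb(o.cost, o.effect, wtp)
            rows.append(row)
        return pd.DataFrame(rows)


def _sort_key(o: StrategyOutcome):
    # ties in cost broken by higher effect, then name order
    return (o.cost, -o.effect, o.name)


def build_frontier(outcomes: list[StrategyOutcome]) -> Frontier:
    """Dominance / extended-dominance frontier over strategy outcomes."""
    if not outcomes:
        raise ValueError("at least one strategy outcome is required")
    names = [o.name for o in outcomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")

    ordered = sorted(outcomes, key=_sort_key)
    status = {o.name: ON_FRONTIER for o in ordered}

    # strict dominance (weak pairwise dominance with at least one strict
    # inequality); exact ties collapse to the first in sort order
    for i, o in enumerate(ordered):
        for j, other in enumerate(ordered):
            if i == j or status[other.name] != ON_FRONTIER:
                continue
            if other.cost <= o.cost and other.effect >= o.effect:
                if other.cost < o.cost or other.effect > o.effect:
                    status[o.name] = DOMINATED
                    break
                if j < i:  # exact tie: keep the earlier point
                    status[o.name] = DOMINATED
                    break

    # extended dominance: repeatedly drop the strategy whose ICER is not
    # strictly below that of the next (more effective) survivor
    while True:
        survivors = [o for o in ordered if status[o.name] == ON_FRONTIER]
        icers = _sequential_icers(survivors)
        removed = False
        for k in range(1, len(survivors) - 1):
            if icers[k] >= icers[k + 1]:
                status[survivors[k].name] = EXTENDEDLY_DOMINATED
                removed = True
                break
        if not removed:
            break

    survivors = [o for o in ordered if status[o.name] == ON_FRONTIER]
    seq = _sequential_icers(survivors)
    icer_map: dict[str, float | None] = {
        o.name: (None if k == 0 else seq[k]) for k, o in enumerate(survivors)
    }
    return Frontier(outcomes=ordered, status=status, icers=icer_map)


def _sequential_icers(survivors: list[StrategyOutcome]) -> list[float]:
    """ICER of each survivor vs the previous one (index 0 unused)."""
    icers = [float("nan")]
    for prev, cur in zip(survivors, survivors[1:]):
        d_eff = cur.effect - prev.effect
        d_cost = cur.cost - prev.cost
        icers.append(d_cost / d_eff if d_eff > 0 else float("inf"))
    return icers


def optimal_at_wtp(frontier: Frontier, wtp: float) -> str:
    """Most effective on-frontier strategy whose ICER is <= ``wtp``.

    Equals the argmax of net monetary benefit over all strategies; the
    cheapest (reference) strategy is returned when no ICER clears the
    threshold.
    """
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay must be > 0, got {wtp}")
    chain = frontier.on_frontier()
    for o in reversed(chain):
        icer = frontier.icers[o.name]
        if icer is None or icer <= wtp:
            return o.name
    return chain[0].name


def nhb(cost: float, effect: float, wtp: float) -> float:
    """Net health benefit in QALY: effect - cost / wtp."""
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay must be > 0, got {wtp}")
    return effect - cost / wtp


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit in $: wtp * effect - cost."""
    return wtp * effect - cost
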