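"""Frontier, ICER, net-benefit and acceptability machinery.

Strategies are compared as points in the (cost, effect) plane — effect
being QALYs per man for the cost-effectiveness frontier, or clinically
significant cancers detected per man for the detection frontier. The
efficiency frontier removes dominated points (costlier and no more
effective) and extended-dominated points (whose incremental
cost-effectiveness ratio against the previous frontier member exceeds
that of the next), leaving a chain with strictly increasing ICERs. A
point lies on the frontier exactly when it maximises net monetary
benefit, threshold x effect - cost, at some willingness-to-pay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CEPoint:
    label: str
    effect: float
    cost: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect) or not np.isfinite(self.cost):
            raise ValueError(f"non-finite cost/effect for {self.label}")
        if self.cost < 0:
            raise ValueError(f"negative cost for {self.label}")


class EqualEffectsError(ValueError):
    """ICER is undefined between points with equal effects."""


def icer(a: CEPoint, b: CEPoint) -> float:
    """Incremental cost-effectiveness ratio of a versus b (a more effective)."""
    if a.effect == b.effect:
        raise EqualEffectsError(f"equal effects for {a.label} and {b.label}")
    if a.effect < b.effect:
        raise ValueError("icer(a, b) requires a.effect > b.effect")
    return (a.cost - b.cost) / (a.effect - b.effect)


def net_benefit(p: CEPoint, threshold: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * p.effect - p.cost


@dataclass
class FrontierMember:
    point: CEPoint
    icer_vs_previous: Optional[float]  # None for the least costly member


@dataclass
class FrontierResult:
    members: List[FrontierMember]
    dominated: List[CEPoint] = field(default_factory=list)
    extended_dominated: List[CEPoint] = field(default_factory=list)

    @property
    def labels(self) -> List[str]:
        return [m.point.label for m in self.members]

    def classification(self) -> Dict[str, str]:
        out = {m.point.label: "frontier" for m in self.members}
        out.update({p.label: "dominated" for p in self.dominated})
        out.update({p.label: "extended_dominated" for p in self.extended_dominated})
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": m.point.label,
                    "effect": m.point.effect,
                    "cost": m.point.cost,
                    "icer_vs_previous": m.icer_vs_previous,
                }
                for m in self.members
            ]
        )


def efficiency_frontier(points: Sequence[CEPoint]) -> FrontierResult:
    """Efficiency frontier with strict/weak and extended dominance.

    Weak dominance (equal cost, higher effect; or equal effect, lower
    cost) removes the weaker point; exact ties on both axes keep the
    lexicographically first label. The returned members are ordered by
    strictly increasing effect and cost, and their ICER sequence is
    strictly increasing.
    """
    if not points:
        raise ValueError("at least one point required")
    pts = sorted(points, key=lambda p: (p.effect, p.cost, p.label))
    dominated: List[CEPoint] = []
    candidates: List[CEPoint] = []
    for p in pts:
        is_dominated = False
        for q in pts:
            if q is p:
                continue
            if q.effect > p.effect and q.cost <= p.cost:
                is_dominated = True
            elif q.effect >= p.effect and q.cost < p.cost:
                is_dominated = True
            elif (
                q.effect == p.effect and q.cost == p.cost and q.label < p.label
            ):  # exact tie: keep first label
                is_dominated = True
            if is_dominated:
                break
        (dominated if is_dominated else candidates).append(p)

    # extended dominance: walk by increasing effect, require increasing ICERs
    frontier: List[CEPoint] = []
    extended: List[CEPoint] = []
    for p in candidates:  # already sorted by effect
        while frontier:
            if len(frontier) == 1:
                prev_icer = -np.inf
            else:
                prev_icer = icer(frontier[-1], frontier[-2])
            if icer(p, frontier[-1]) <= prev_icer:
                extended.append(frontier.pop())
            else:
                break
        frontier.append(p)

    members = []
    for i, p in enumerate(frontier):
        members.append(
            FrontierMember(point=p, icer_vs_previous=None if i == 0 else icer(p, frontier[i - 1]))
        )
    return FrontierResult(members=members, dominated=dominated, extended_dominated=extended)


def detection_frontier(points: Sequence[CEPoint]) -> FrontierResult:
    """Efficiency frontier in the (testing cost, CS cancers detected) plane.

    Same algorithm as :func:`efficiency_frontier`; callers supply points
    whose effect is the expected number of CS cancers detected per man
    and whose cost is the expected testing cost per man.
    """
    return efficiency_frontier(points)


def best_at_threshold(points: Sequence[CEPoint], threshold: float) -> CEPoint:
    """Point maximising net benefit at a threshold; ties keep the first label."""
    ordered = sorted(points, key=lambda p: p.label)
    return max(ordered, key=lambda p: net_benefit(p, threshold))  # max keeps first of equals


def frontier_by_threshold_sweep(points: Sequence[CEPoint], thresholds: Sequence[float]) -> List[str]:
    """Labels of net-benefit maximisers over a sweep of thresholds (oracle)."""
    return sorted({best_at_threshold(points, lam).label for lam in thresholds})
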