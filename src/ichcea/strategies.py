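"""Comparator arms: usual care vs. minimally invasive surgery (MIS).

Usual care enters the model with the cohort's observed mRS distribution.
The MIS arm applies an absolute effectiveness epsilon: a proportion of the
whole cohort is moved from poor outcomes (mRS 4-6) into good outcomes
(mRS 0-3), split over mRS 0-3 by fixed allocation weights, and a one-off
surgical cost is charged at entry.  A scenario variant instead moves a
fraction of the cohort up by a single mRS level from one source state.

Both operations are pure mass moves on an occupancy vector: they conserve
the input's total mass and never create negative occupancy.  Transition
probabilities beyond 3 months post-ICH are identical between arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inputs_io import MRS_DEAD, N_STATES, ValidationError

#: Allocation of the absolute improvement over mRS 0-3 (increasing with
#: severity: 18% / 18% / 27% / 37%).
DEFAULT_ALLOCATION_WEIGHTS = (0.18, 0.18, 0.27, 0.37)
DEFAULT_EFFECTIVENESS = 0.11
DEFAULT_SURGICAL_COST = 10_000.0


class InfeasibleEffectError(ValueError):
    """The requested effect exceeds the movable mass; carries the maximum."""

    def __init__(self, msg: str, max_feasible: float):
        super().__init__(msg)
        self.max_feasible = max_feasible


@dataclass(frozen=True)
class MisStrategySpec:
    """Effectiveness, allocation and cost of the surgical strategy."""

    effectiveness: float = DEFAULT_EFFECTIVENESS
    allocation_weights: tuple[float, ...] = DEFAULT_ALLOCATION_WEIGHTS
    decrement_rule: str = "proportional"
    surgical_cost: float = DEFAULT_SURGICAL_COST

    def __post_init__(self):
        w = np.asarray(self.allocation_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("allocation weights must be 4 non-negative values summing to 1")
        object.__setattr__(self, "allocation_weights", tuple(float(x) for x in w))
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValidationError("effectiveness must lie in [0, 1]")
        if self.decrement_rule not in ("proportional", "equal_thirds"):
            raise ValidationError("decrement_rule must be 'proportional' or 'equal_thirds'")
        if self.surgical_cost < 0:
            raise ValidationError("surgical_cost must be non-negative")


@dataclass(frozen=True)
class ScenarioShiftSpec:
    """Single-state scenario: move a cohort fraction from one mRS level up."""

    from_state: int
    fraction: float
    surgical_cost: float = DEFAULT_SURGICAL_COST

    def __post_init__(self):
        if not 1 <= self.from_state <= MRS_DEAD:
            raise ValidationError("from_state must lie in mRS 1..6")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("fraction must lie in [0, 1]")
        if self.surgical_cost < 0:
            raise ValidationError("surgical_cost must be non-negative")


def max_feasible_effectiveness(dist: np.ndarray, rule: str = "proportional") -> float:
    """Largest epsilon the decrement rule can remove from mRS 4-6."""
    dist = np.asarray(dist, dtype=float)
    if rule == "proportional":
        return float(dist[4:].sum())
    return 3.0 * float(dist[4:].min())


def apply_mis_effect(dist: np.ndarray, spec: MisStrategySpec) -> np.ndarray:
    """Redistribute the entry occupancy under the surgical effect.

    Each good-outcome state s <= 3 gains ``eps * w_s``.  The same total
    ``eps`` is removed from mRS 4-6: proportionally to their occupancy
    (default) or in equal thirds.  Operates on any non-negative occupancy
    vector and conserves its total mass.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_STATES,) or np.any(dist < 0):
        raise ValidationError("occupancy vector must be 7 non-negative values")
    eps = spec.effectiveness
    if eps == 0.0:
        return dist.copy()
    max_eps = max_feasible_effectiveness(dist, spec.decrement_rule)
    if eps > max_eps + 1e-12:
        raise InfeasibleEffectError(
            f"effectiveness {eps:.4g} exceeds the movable mRS 4-6 mass; "
            f"maximum feasible under rule '{spec.decrement_rule}' is {max_eps:.4g}",
            max_feasible=max_eps,
        )
    out = dist.copy()
    out[:4] += eps * np.asarray(spec.allocation_weights)
    if spec.decrement_rule == "proportional":
        poor = dist[4:].sum()
        out[4:] -= eps * dist[4:] / poor
    else:
        out[4:] -= eps / 3.0
    return np.clip(out, 0.0, None)


class InfeasibleShiftError(ValueError):
    """The requested shift exceeds the source state's occupancy."""


def apply_single_state_shift(dist: np.ndarray, spec: ScenarioShiftSpec) -> np.ndarray:
    """Move an absolute cohort fraction from ``from_state`` to the next-better state."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_STATES,) or np.any(dist < 0):
        raise ValidationError("occupancy vector must be 7 non-negative values")
    s, q = spec.from_state, spec.fraction
    if q > dist[s] + 1e-12:
        raise InfeasibleShiftError(
            f"shift fraction {q:.4g} exceeds mRS {s} occupancy {dist[s]:.4g}")
    out = dist.copy()
    out[s] -= q
    out[s - 1] += q
    return np.clip(out, 0.0, None)


def mis_from_mapping(section) -> MisStrategySpec:
    """Build a :class:`MisStrategySpec` from a config 'strategy' mapping."""
    section = dict(section or {})
    return MisStrategySpec(
        effectiveness=float(section.get("effectiveness", DEFAULT_EFFECTIVENESS)),
        allocation_weights=tuple(section.get("weights", DEFAULT_ALLOCATION_WEIGHTS)),
        decrement_rule=section.get("decrement_rule", "proportional"),
        surgical_cost=float(section.get("surgical_cost", DEFAULT_SURGICAL_COST)),
    )
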