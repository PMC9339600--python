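"""Activation / extinction process and carrier-role assignment.

The node life cycle is Ignorant -> {Spreader, Variation, Oyster} -> Recovered.
The three middle states jointly form the *carrier* set C.  An ignorant wakes
up when the fraction of carriers among its neighbours reaches its personal
arousal threshold (an amended linear-threshold rule); a carrier is
extinguished — becomes permanently Recovered — according to a second,
independent per-node threshold, active only once the immunity-onset step has
been reached.  Both thresholds are drawn once per node from a normal
distribution truncated to [0, 1].
"""

from __future__ import annotations

import logging
from enum import IntEnum

import numpy as np

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "NodeState",
    "CARRIER_STATES",
    "is_carrier",
    "sample_thresholds",
    "arousal_decision",
    "extinguish_decision",
    "assign_carrier_role",
]


class NodeState(IntEnum):
    """Five-valued role state; S, V and O together are the rumor carriers."""

    IGNORANT = 0
    SPREADER = 1
    VARIATION = 2
    OYSTER = 3
    RECOVERED = 4


CARRIER_STATES = (NodeState.SPREADER, NodeState.VARIATION, NodeState.OYSTER)


def is_carrier(state: NodeState | int) -> bool:
    return NodeState.SPREADER <= state <= NodeState.OYSTER


def sample_thresholds(
    mean: float,
    sd: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw n i.i.d. Normal(mean, sd) thresholds truncated to [0, 1].

    Truncation is by rejection resampling, so the result follows the exact
    truncated-normal law (not a clipped normal).  ``sd = 0`` degenerates to a
    constant vector, which then must itself lie inside [0, 1].
    """
    if sd < 0:
        raise ParameterError(f"threshold sd must be nonnegative, got {sd}")
    if n < 1:
        raise ParameterError(f"threshold count must be >= 1, got {n}")
    if sd == 0 and not 0.0 <= mean <= 1.0:
        raise ParameterError(
            f"degenerate threshold mean {mean} lies outside [0, 1]"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = np.empty(n)
    need = np.arange(n)
    while need.size:
        draw = rng.normal(mean, sd, need.size)
        ok = (draw >= 0.0) & (draw <= 1.0)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def arousal_decision(
    carrier_neighbors: int,
    total_neighbors: int,
    threshold: float,
) -> int:
    """Linear-threshold wake-up rule for an ignorant node.

    Returns 1 iff carrier_neighbors / total_neighbors >= threshold.  A node
    with no neighbours has no exposure and never activates.
    """
    if total_neighbors < 0 or carrier_neighbors < 0:
        raise ParameterError("neighbor counts must be nonnegative")
    if carrier_neighbors > total_neighbors:
        raise ParameterError("carrier neighbors cannot exceed total neighbors")
    if total_neighbors == 0:
        return 0
    return int(carrier_neighbors / total_neighbors >= threshold)


def extinguish_decision(
    carrier_neighbors: int,
    total_neighbors: int,
    threshold: float,
    t: int,
    immune_start: int = 15,
    direction: str = "inverted",
) -> int:
    """Extinguishing rule turning a carrier into Recovered (absorbing).

    Inactive before the immunity-onset step (``t < immune_start`` always
    returns 0).  Afterwards, with ``direction="as_printed"`` the carrier
    recovers when its carrier-neighbour fraction is >= threshold; with
    ``direction="inverted"`` (default) it recovers when the fraction is
    below the threshold — the rumor's local energy has faded.  Both
    readings are kept because they describe the same rule from the two
    sides of its contradiction; see the methods note.
    """
    if t < immune_start:
        return 0
    frac = 0.0 if total_neighbors == 0 else carrier_neighbors / total_neighbors
    if direction == "as_printed":
        return int(frac >= threshold)
    if direction == "inverted":
        return int(frac < threshold)
    raise ParameterError(
        f"unknown extinction direction {direction!r}; "
        "expected 'as_printed' or 'inverted'"
    )


def assign_carrier_role(
    influence_s: float,
    influence_v: float,
    influence_o: float,
    r: float,
) -> NodeState:
    """Roulette-wheel role assignment for a freshly activated node.

    The unit interval is partitioned proportionally to the summed influence
    of neighbouring spreaders, variations and oysters; the uniform draw
    ``r`` selects the role.  If all three sums vanish (no activated
    neighbour carries positive influence) the node falls back to Spreader.
    """
    if min(influence_s, influence_v, influence_o) < 0:
        raise ParameterError("influence sums must be nonnegative")
    if not 0.0 <= r < 1.0:
        raise ParameterError(f"uniform draw r must lie in [0, 1), got {r}")
    total = influence_s + influence_v + influence_o
    if total <= 0.0:
        logger.warning("all neighbor influences are zero; falling back to SPREADER")
        return NodeState.SPREADER
    if r < influence_s / total:
        return NodeState.SPREADER
    if r < (influence_s + influence_v) / total:
        return NodeState.VARIATION
    return NodeState.OYSTER
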