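"""Bounded-trust (J-A style) opinion dynamics with silence intervals.

Every carrier holds a continuous opinion x in [-1, 1].  The sign encodes the
version of the rumor being spread (positive: the original story; negative: a
mutated one) and two "silence" windows [rho1, rho2] and [rho3, rho4] mark
wait-and-see regions.  The role of a carrier is a deterministic function of
its opinion:

    Spreader   x in [0, rho3) or (rho4, 1]
    Variation  x in [-1, rho1) or (rho2, 0)
    Oyster     x in [rho1, rho2] or [rho3, rho4]

Interval endpoints belong to the oyster and x = 0 to the spreader, which
makes the map total and deterministic on [-1, 1].

Opinions move toward the local mean when closer than the assimilation
distance d1 and away from it when farther than the exclusion distance d2;
in between nothing happens.  Once an opinion enters [0, rho3] it can no
longer decrease (a ratchet), so such a node never slides back toward the
variation side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import NodeState
from .errors import ParameterError

__all__ = [
    "SilenceIntervals",
    "BoundedTrustParams",
    "classify_opinion",
    "neighbor_mean_opinion",
    "opinion_update",
    "initialize_opinion",
    "role_intervals",
]

#: Sentinel meaning "no carrier interlocutor this step; opinion unchanged".
NO_NEIGHBOR = None


@dataclass(frozen=True)
class SilenceIntervals:
    """The four silence coefficients delimiting the oyster windows."""

    rho1: float = -0.4
    rho2: float = -0.2
    rho3: float = 0.2
    rho4: float = 0.3

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho1 < self.rho2 <= 0.0 <= self.rho3 < self.rho4 < 1.0):
            raise ParameterError(
                "silence coefficients must satisfy "
                "-1 < rho1 < rho2 <= 0 <= rho3 < rho4 < 1, got "
                f"({self.rho1}, {self.rho2}, {self.rho3}, {self.rho4})"
            )


@dataclass(frozen=True)
class BoundedTrustParams:
    """Trust rate and the assimilation/exclusion distances."""

    mu: float = 0.1
    d1: float = 1.0
    d2: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.mu <= 1.0:
            raise ParameterError(f"trust rate mu must lie in (0, 1], got {self.mu}")
        if not 0.0 < self.d1 < self.d2:
            raise ParameterError(
                f"distances must satisfy 0 < d1 < d2, got d1={self.d1}, d2={self.d2}"
            )


def role_intervals(role: NodeState, rho: SilenceIntervals) -> list[tuple[float, float]]:
    """The opinion sub-intervals consistent with a carrier role."""
    if role == NodeState.SPREADER:
        return [(0.0, rho.rho3), (rho.rho4, 1.0)]
    if role == NodeState.VARIATION:
        return [(-1.0, rho.rho1), (rho.rho2, 0.0)]
    if role == NodeState.OYSTER:
        return [(rho.rho1, rho.rho2), (rho.rho3, rho.rho4)]
    raise ParameterError(f"opinions exist only for carrier roles, got {role!r}")


def classify_opinion(x: float, rho: SilenceIntervals) -> NodeState:
    """Map an opinion value to its carrier role (total on [-1, 1])."""
    if not -1.0 <= x <= 1.0:
        raise ParameterError(f"opinion value must lie in [-1, 1], got {x}")
    if rho.rho1 <= x <= rho.rho2 or rho.rho3 <= x <= rho.rho4:
        return NodeState.OYSTER
    if x < 0.0:
        return NodeState.VARIATION
    return NodeState.SPREADER


def neighbor_mean_opinion(opinions: "list[float] | np.ndarray") -> float | None:
    """Mean opinion over a node's active carrier neighbours.

    ``opinions`` holds only the opinions of neighbours that are carriers and
    participating this step; ignorants, recovered and masked neighbours are
    excluded by the caller.  With no interlocutor the mean is undefined and
    the sentinel ``None`` (no update) is returned.
    """
    arr = np.asarray(opinions, dtype=float)
    if arr.size == 0:
        return NO_NEIGHBOR
    return float(arr.mean())


def opinion_update(
    x: float,
    xbar: float | None,
    params: BoundedTrustParams,
    rho: SilenceIntervals,
    literal: bool = False,
) -> float:
    """One bounded-trust update of a carrier's opinion against the local mean.

    Let d = |x - xbar|.  With the default signed rule, attraction
    (d < d1) moves x toward xbar by mu*(xbar - x) and exclusion (d > d2)
    moves it away by mu*(x - xbar); otherwise x is unchanged.  ``literal``
    restores the unsigned published forms x + mu*d (attraction) and
    x - mu*d (exclusion), which coincide with the signed rule when
    x < xbar.  The result is clamped to [-1, 1]; if x started inside
    [0, rho3] the ratchet forbids any decrease.
    """
    if xbar is NO_NEIGHBOR:
        return x
    delta = abs(x - xbar)
    if delta < params.d1:
        new = x + params.mu * delta if literal else x + params.mu * (xbar - x)
    elif delta > params.d2:
        new = x - params.mu * delta if literal else x + params.mu * (x - xbar)
    else:
        new = x
    new = min(1.0, max(-1.0, new))
    if 0.0 <= x <= rho.rho3:
        new = max(new, x)
    return new


def initialize_opinion(
    role: NodeState,
    rho: SilenceIntervals,
    rng: np.random.Generator | float,
) -> float:
    """Draw an initial opinion uniformly over the role's interval union.

    Each sub-interval is weighted by its length, so the draw is uniform on
    the union.  ``rng`` may be a Generator or a pre-drawn uniform in [0, 1)
    (used when replaying a recorded randomness tape).  The result always
    classifies back to ``role``; floating-point landings on a foreign
    boundary are nudged one ulp into the interior.
    """
    u = rng if isinstance(rng, float) else float(rng.random())
    intervals = role_intervals(role, rho)
    lengths = [hi - lo for lo, hi in intervals]
    total = sum(lengths)
    pos = u * total
    x = intervals[-1][1]
    for (lo, hi), length in zip(intervals, lengths):
        if pos < length:
            x = lo + pos
            break
        pos -= length
    # open endpoints of the spreader/variation unions can be hit by rounding
    for _ in range(4):
        if classify_opinion(x, rho) == role:
            return x
        lo, hi = next(
            (lo, hi) for lo, hi in intervals if lo <= x <= hi
        )
        x = np.nextafter(x, (lo + hi) / 2.0)
    return x
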