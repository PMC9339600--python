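"""Offline-probability masking and interlayer state synchronization.

The online layer is intermittently thinned: each step every online node is
independently offline with probability ``o`` and then neither sends nor
receives influence within the layer.  Between the layers, a node's state is
copied to its one-to-one counterpart with a social-reinforcement probability

    omega(n) = xi * n / (1 + gamma * n)

that grows with n, the number of the counterpart's neighbours already in the
source node's state, and saturates below xi / gamma.  Recovered counterparts
are never overwritten (recovery is absorbing in both layers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import NodeState
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SyncParams",
    "sample_offline",
    "sync_probability",
    "synchronize_states",
]


@dataclass(frozen=True)
class SyncParams:
    """Random-synchronization strength xi and social-reinforcement gamma."""

    xi: float = 0.1
    gamma: float = 0.2
    bidirectional: bool = False

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ParameterError(f"synchronization parameter xi must be >= 0, got {self.xi}")
        if not 0.0 < self.gamma < 1.0:
            raise ParameterError(
                f"reinforcement parameter gamma must lie in (0, 1), got {self.gamma}"
            )


def sample_offline(
    o: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw the per-step offline mask: i.i.d. Bernoulli(o) per node.

    ``True`` marks a node as offline (absent) this step.  The mask is
    redrawn every step; it is not a static trait.
    """
    if not 0.0 <= o <= 1.0:
        raise ParameterError(f"offline probability must lie in [0, 1], got {o}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.random(n) < o


def sync_probability(n_same: int | np.ndarray, params: SyncParams) -> float | np.ndarray:
    """Social-reinforcement synchronization probability omega(n).

    Monotone non-decreasing in ``n_same`` and bounded above by xi / gamma;
    values exceeding 1 (possible for large xi) are capped with a warning.
    """
    n_arr = np.asarray(n_same)
    if np.any(n_arr < 0):
        raise ParameterError("same-state neighbor count must be nonnegative")
    omega = params.xi * n_arr / (1.0 + params.gamma * n_arr)
    if np.any(omega > 1.0):
        warnings.warn(
            "synchronization probability exceeded 1 and was capped", stacklevel=2
        )
        omega = np.minimum(omega, 1.0)
    if np.ndim(n_same) == 0:
        return float(omega)
    return omega


def synchronize_states(
    source_states: np.ndarray,
    source_opinions: np.ndarray,
    target_states: np.ndarray,
    target_opinions: np.ndarray,
    target_adj,
    mapping: np.ndarray,
    params: SyncParams,
    u: np.ndarray,
) -> int:
    """Copy source-layer states onto counterparts, in place, one direction.

    For each source node ``i`` in a carrier state (S, V or O) with
    counterpart ``j = mapping[i]``, ``n_same`` counts j's target-layer
    neighbours whose state equals state(i); with probability omega(n_same)
    (compared against the supplied uniforms ``u``, indexed by source node)
    the counterpart adopts state(i) together with its opinion.  Only
    carrier states propagate: the mechanism synchronizes the rumor itself,
    and copying Ignorant or Recovered would revert a carrier counterpart,
    which the no-after-effect stipulation forbids.  Recovered counterparts
    are never overwritten.  All counts use the pre-call snapshot.  Returns
    the number of synchronization events.
    """
    snap_states = target_states.copy()
    # n_same per source node i, evaluated at its counterpart j = mapping[i]
    n_same = np.zeros(source_states.size)
    for s in NodeState:
        cnt_s = target_adj @ (snap_states == s).astype(float)
        n_same = np.where(source_states == s, cnt_s[mapping], n_same)
    omega = np.minimum(params.xi * n_same / (1.0 + params.gamma * n_same), 1.0)
    source_carrier = (source_states >= NodeState.SPREADER) & (
        source_states <= NodeState.OYSTER
    )
    do = (
        (u < omega)
        & source_carrier
        & (snap_states[mapping] != NodeState.RECOVERED)
    )
    idx = np.flatnonzero(do)
    targets = mapping[idx]
    target_states[targets] = source_states[idx]
    target_opinions[targets] = source_opinions[idx]
    return int(idx.size)
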