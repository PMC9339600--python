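"""Monte-Carlo engine: initialization, the per-step loop, runs and sweeps.

Update scheme
-------------
The dynamics are synchronous: every decision in a step is taken against the
state snapshot at the start of that step (after interlayer synchronization,
which runs first and itself uses the pre-sync snapshot).  One step applies,
in order:

1. draw the online-layer offline mask;
2. interlayer state synchronization (online -> offline, optionally also the
   mirrored direction, both evaluated on the pre-sync snapshot);
3. arousal of ignorants (linear-threshold rule over unmasked carrier
   neighbours, denominator = all neighbours);
4. carrier-role assignment of the newly aroused (influence-proportional
   roulette) and their opinion initialization;
5. bounded-trust opinion updates of existing unmasked carriers;
6. opinion-based reclassification of carriers (S/V/O follow the opinion);
7. extinction of carriers into the absorbing Recovered state (active only
   from the immunity-onset step onward; evaluated for every carrier,
   masked or not, since recovering is an internal decision rather than an
   act of transmission).

Randomness order (fixed, so that runs are reproducible and a recorded tape
can drive an independent re-implementation): the mask and synchronization
uniforms come from a shared step stream — per step ``rng.random(n)`` for the
mask, then ``rng.random(n)`` per synchronization direction — while each
layer owns a private stream supplying ``rng.random(k)`` for the role draws
of its k newly aroused nodes in ascending node order followed by
``rng.random(k)`` for their opinion-initialization draws.  Separate layer
streams keep the offline layer's randomness independent of how much the
online layer consumed, so an uncoupled (xi = 0) offline trajectory does not
depend on online activity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_config
from .coupling import SyncParams, synchronize_states
from .dynamics import NodeState, assign_carrier_role, sample_thresholds
from .errors import ConfigError, ParameterError
from .io_config import SimConfig
from .network import (
    CoupledNetwork,
    adjacency,
    build_ba_network,
    build_ws_network,
    couple_layers,
    eigen_centrality,
)
from .opinion import (
    BoundedTrustParams,
    SilenceIntervals,
    initialize_opinion,
)

logger = logging.getLogger(__name__)

LAYERS = ("online", "offline")

__all__ = ["LayerView", "RunSummary", "Simulation", "run", "sweep", "summarize_sweep"]


@dataclass
class LayerView:
    """Static per-layer structure plus the evolving node arrays."""

    adj: "object"
    degree: np.ndarray
    de: np.ndarray  # degree centrality
    ec: np.ndarray  # eigenvector centrality
    arousal: np.ndarray  # per-node wake-up thresholds
    extinguish: np.ndarray  # per-node blanking thresholds
    states: np.ndarray
    opinions: np.ndarray


@dataclass(frozen=True)
class RunSummary:
    """Headline statistics of one layer's trajectory."""

    peak_carrier: float
    peak_carrier_time: int
    peak_oyster: float
    final_recovered: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_layer_graph(config: SimConfig, which: str, seed: int):
    if which == "online":
        if config.online_edgelist:
            return io_config.load_edgelist(config.online_edgelist)
        return build_ba_network(config.n, config.m, seed=seed)
    if config.offline_topology == "file":
        if not config.offline_edgelist:
            raise ConfigError("offline_edgelist: required when offline_topology='file'")
        return io_config.load_edgelist(config.offline_edgelist)
    if config.offline_topology == "ws":
        return build_ws_network(config.n, config.offline_ws_k, config.offline_ws_p, seed=seed)
    return build_ba_network(config.n, config.offline_m or config.m, seed=seed)


class Simulation:
    """A single seeded realization of the coupled-network rumor process."""

    def __init__(self, config: SimConfig, network: CoupledNetwork | None = None):
        config.validate()
        self.config = config
        self.rho = SilenceIntervals(config.rho1, config.rho2, config.rho3, config.rho4)
        self.trust = BoundedTrustParams(config.mu, config.d1, config.d2)
        self.sync = SyncParams(
            xi=config.xi,
            gamma=config.reinforcement,
            bidirectional=config.sync_direction == "bidirectional",
        )

        ss = np.random.SeedSequence(config.seed)
        s_graph_on, s_graph_off, s_couple, s_init, s_dyn = ss.spawn(5)

        if network is None:
            g_on = _build_layer_graph(config, "online", _small_seed(s_graph_on))
            g_off = _build_layer_graph(config, "offline", _small_seed(s_graph_off))
            network = couple_layers(
                g_on, g_off, config.coupling_mode, seed=_small_seed(s_couple)
            )
        elif network.n != config.n:
            raise ParameterError(
                f"network has {network.n} nodes but config.n = {config.n}"
            )
        self.network = network
        self.n = network.n

        init_rng = np.random.default_rng(s_init)
        self.layers: dict[str, LayerView] = {}
        for name, g in (("online", network.online), ("offline", network.offline)):
            a = adjacency(g)
            deg = np.asarray(a.sum(axis=1)).ravel()
            self.layers[name] = LayerView(
                adj=a,
                degree=deg,
                de=deg / (self.n - 1) if self.n > 1 else np.zeros(self.n),
                ec=eigen_centrality(g),
                arousal=sample_thresholds(
                    config.arousal_mean, config.arousal_sd, self.n, init_rng
                ),
                extinguish=sample_thresholds(
                    config.extinguish_mean, config.extinguish_sd, self.n, init_rng
                ),
                states=np.full(self.n, NodeState.IGNORANT, dtype=np.int8),
                opinions=np.full(self.n, np.nan),
            )

        # seed carriers in both layers: the chosen online nodes and their
        # offline counterparts (the same individuals), same initial opinion
        k = config.n_initial_carriers()
        seeds = np.sort(init_rng.choice(self.n, size=k, replace=False))
        on, off = self.layers["online"], self.layers["offline"]
        for i in seeds:
            x = initialize_opinion(NodeState.SPREADER, self.rho, init_rng)
            j = self.network.mapping[i]
            on.states[i] = NodeState.SPREADER
            on.opinions[i] = x
            off.states[j] = NodeState.SPREADER
            off.opinions[j] = x

        s_step, s_on_dyn, s_off_dyn = s_dyn.spawn(3)
        self.rng = np.random.default_rng(s_step)
        self.layer_rng = {
            "online": np.random.default_rng(s_on_dyn),
            "offline": np.random.default_rng(s_off_dyn),
        }
        self.t = 0
        self._history: list[dict] = []
        self._statelog: list[pd.DataFrame] = []
        self._record()
        logger.debug(
            "initialized run: seed=%s config=%s n=%d carriers=%d",
            config.seed, config.digest(), self.n, k,
        )

    # -- bookkeeping --------------------------------------------------------

    def _record(self) -> None:
        for name in LAYERS:
            st = self.layers[name].states
            counts = np.bincount(st, minlength=5) / self.n
            i_, s_, v_, o_, r_ = counts
            self._history.append(
                {
                    "t": self.t, "layer": name,
                    "I": i_, "S": s_, "V": v_, "O": o_, "R": r_,
                    "C": s_ + v_ + o_,
                }
            )
            if self.config.log_states:
                self._statelog.append(
                    pd.DataFrame(
                        {
                            "t": self.t,
                            "node": np.arange(self.n),
                            "layer": name,
                            "state": [NodeState(x).name for x in st],
                            "opinion": self.layers[name].opinions,
                        }
                    )
                )

    @property
    def timeseries(self) -> pd.DataFrame:
        return pd.DataFrame(self._history)

    @property
    def statelog(self) -> pd.DataFrame:
        if not self.config.log_states:
            raise ParameterError("state logging is disabled; set log_states=true")
        return pd.concat(self._statelog, ignore_index=True)

    def summary(self) -> dict[str, RunSummary]:
        ts = self.timeseries
        out = {}
        for name in LAYERS:
            sub = ts[ts.layer == name].reset_index(drop=True)
            peak_idx = int(sub["C"].idxmax())
            out[name] = RunSummary(
                peak_carrier=float(sub["C"].max()),
                peak_carrier_time=int(sub.loc[peak_idx, "t"]),
                peak_oyster=float(sub["O"].max()),
                final_recovered=float(sub["R"].iloc[-1]),
            )
        return out

    # -- the step -----------------------------------------------------------

    def step(self) -> None:
        """Advance the coupled system by one synchronous step."""
        cfg = self.config
        n = self.n
        t_new = self.t + 1

        # 1. offline mask of the online layer
        p_off = 1.0 - cfg.offline_prob if cfg.invert_offline else cfg.offline_prob
        mask = self.rng.random(n) < p_off

        # 2. interlayer synchronization on the pre-sync snapshot
        on, off = self.layers["online"], self.layers["offline"]
        snap_on_states = on.states.copy()
        snap_on_ops = on.opinions.copy()
        snap_off_states = off.states.copy()
        snap_off_ops = off.opinions.copy()
        u_sync = self.rng.random(n)
        n_sync = synchronize_states(
            snap_on_states, snap_on_ops, off.states, off.opinions,
            off.adj, self.network.mapping, self.sync, u_sync,
        )
        if self.sync.bidirectional:
            u_sync2 = self.rng.random(n)
            n_sync += synchronize_states(
                snap_off_states, snap_off_ops, on.states, on.opinions,
                on.adj, self.network.inverse, self.sync, u_sync2,
            )

        # 3-7. intra-layer dynamics on the post-sync snapshot
        events = {"sync": n_sync}
        for name in LAYERS:
            layer = self.layers[name]
            active = ~mask if name == "online" else np.ones(n, dtype=bool)
            events[name] = self._substep(layer, active, t_new, self.layer_rng[name])
        self.t = t_new
        self._record()
        logger.debug("step %d events: %s", self.t, events)

    def _substep(
        self,
        layer: LayerView,
        active: np.ndarray,
        t_new: int,
        rng: np.random.Generator,
    ) -> dict:
        cfg, rho, trust = self.config, self.rho, self.trust
        st = layer.states.copy()  # post-sync snapshot
        op = layer.opinions.copy()
        a, deg = layer.adj, layer.degree

        carrier = (st >= NodeState.SPREADER) & (st <= NodeState.OYSTER)
        send = (carrier & active).astype(float)
        carr_cnt = a @ send
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(deg > 0, carr_cnt / np.maximum(deg, 1), 0.0)

        # 3. arousal of ignorants (receivers must be present and exposed)
        new_nodes = np.flatnonzero(
            (st == NodeState.IGNORANT) & active & (deg > 0) & (frac >= layer.arousal)
        )

        # 4. role assignment + opinion initialization of the newly aroused
        infl = layer.de * layer.ec
        sums = {}
        for role, alpha in (
            (NodeState.SPREADER, cfg.ar_s),
            (NodeState.VARIATION, cfg.ar_v),
            (NodeState.OYSTER, cfg.ar_o),
        ):
            sums[role] = a @ (infl * alpha * send * (st == role))
        u_role = rng.random(new_nodes.size)
        u_init = rng.random(new_nodes.size)
        new_states = st.copy()
        new_ops = op.copy()
        for pos, i in enumerate(new_nodes):
            role = assign_carrier_role(
                sums[NodeState.SPREADER][i],
                sums[NodeState.VARIATION][i],
                sums[NodeState.OYSTER][i],
                float(u_role[pos]),
            )
            new_states[i] = role
            new_ops[i] = initialize_opinion(role, rho, float(u_init[pos]))

        # 5. bounded-trust opinion updates of existing, unmasked carriers
        opin_filled = np.where(np.isnan(op), 0.0, op)
        num = a @ (opin_filled * send)
        talkers = carrier & active & (carr_cnt > 0)
        xbar = np.where(carr_cnt > 0, num / np.maximum(carr_cnt, 1), 0.0)
        x = op
        delta = np.abs(x - xbar)
        if cfg.unsigned_opinion_updates:
            attracted = x + trust.mu * delta
            repelled = x - trust.mu * delta
        else:
            attracted = x + trust.mu * (xbar - x)
            repelled = x + trust.mu * (x - xbar)
        upd = np.where(delta < trust.d1, attracted, np.where(delta > trust.d2, repelled, x))
        upd = np.clip(upd, -1.0, 1.0)
        ratchet = (x >= 0.0) & (x <= rho.rho3)
        upd = np.where(ratchet, np.maximum(upd, x), upd)
        new_ops = np.where(talkers, upd, new_ops)

        # 6. reclassification: carrier roles follow the (new) opinion
        xo = new_ops
        oyster = ((xo >= rho.rho1) & (xo <= rho.rho2)) | ((xo >= rho.rho3) & (xo <= rho.rho4))
        role_of = np.where(oyster, NodeState.OYSTER,
                           np.where(xo < 0.0, NodeState.VARIATION, NodeState.SPREADER))
        new_states = np.where(carrier, role_of, new_states).astype(np.int8)

        # 7. extinction (absorbing; internal decision, mask-independent)
        recovered = np.zeros(self.n, dtype=bool)
        if t_new >= cfg.immune_start:
            if cfg.extinction_direction == "as_printed":
                hit = frac >= layer.extinguish
            else:
                hit = frac < layer.extinguish
            recovered = carrier & hit
            if cfg.ignorant_direct_immunity:
                recovered |= (st == NodeState.IGNORANT) & (deg > 0) & hit
            new_states[recovered] = NodeState.RECOVERED
        layer.states = new_states
        layer.opinions = new_ops
        return {
            "aroused": int(new_nodes.size),
            "recovered": int(recovered.sum()),
        }

    def run(self) -> pd.DataFrame:
        """Advance to the configured horizon; returns the density table."""
        while self.t < self.config.horizon:
            self.step()
        return self.timeseries


def _small_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def run(config: SimConfig, network: CoupledNetwork | None = None):
    """One full simulation; returns ``(timeseries, {layer: RunSummary})``."""
    sim = Simulation(config, network=network)
    ts = sim.run()
    return ts, sim.summary()


def sweep(
    config: SimConfig,
    param_name: str,
    values,
    replicates: int = 20,
) -> pd.DataFrame:
    """Replicated parameter sweep; one tidy row per (value, replicate, layer).

    Replicate seeds are derived deterministically from the base config seed,
    the value index and the replicate index, so every cell of the sweep can
    be reproduced in isolation.
    """
    if param_name not in {f.name for f in dataclasses.fields(SimConfig)}:
        raise ConfigError(f"unknown sweep parameter {param_name!r}")
    if replicates < 1:
        raise ConfigError(f"replicates must be >= 1, got {replicates}")
    base = config.seed if config.seed is not None else 0
    rows = []
    for vi, value in enumerate(values):
        for rep in range(replicates):
            seed = _small_seed(np.random.SeedSequence([base, vi, rep]))
            cfg = config.replace(**{param_name: value, "seed": seed})
            _, summ = run(cfg)
            for layer_name, s in summ.items():
                rows.append(
                    {
                        "param": param_name, "value": value,
                        "replicate": rep, "seed": seed, "layer": layer_name,
                        **s.to_dict(),
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(tidy: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of every summary field per (value, layer)."""
    fields = ["peak_carrier", "peak_carrier_time", "peak_oyster", "final_recovered"]
    agg = tidy.groupby(["param", "value", "layer"])[fields].agg(["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
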