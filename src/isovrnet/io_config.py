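"""Configuration handling, file formats, and deterministic fixtures.

The configuration surface mirrors the case-study parameterization of the
model: every default below is the value used in the reference experiment
(BA layers with N = 2000, m = 5; offline probability 0.97; truncated-normal
thresholds; bounded-trust parameters mu = 0.1, d1 = 1, d2 = 1.5; silence
coefficients (-0.4, -0.2, 0.2, 0.3); immunity onset at step 15).
Config files are YAML or JSON (chosen by extension); unknown keys are
rejected and missing keys fall back to the defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParameterError

SCHEMA_VERSION = 1

__all__ = [
    "SimConfig",
    "read_config",
    "write_config",
    "write_timeseries",
    "read_timeseries",
    "write_summary",
    "load_edgelist",
    "save_edgelist",
    "load_graphml",
    "save_graphml",
    "make_fixture",
]


@dataclass
class SimConfig:
    """Complete parameter vector of a simulation run."""

    # network
    n: int = 2000
    m: int = 5
    coupling_mode: str = "random"
    offline_topology: str = "ba"  # ba | ws | file
    offline_m: int | None = None
    offline_ws_k: int = 10
    offline_ws_p: float = 0.1
    online_edgelist: str | None = None
    offline_edgelist: str | None = None

    # run control
    seed: int | None = None
    horizon: int = 100
    initial_carriers: int | None = None  # None -> 1% of n (at least 1)
    log_states: bool = False

    # offline masking of the online layer
    offline_prob: float = 0.97
    invert_offline: bool = False

    # thresholds (truncated normal)
    arousal_mean: float = 0.2
    arousal_sd: float = 0.5
    extinguish_mean: float = 0.2
    extinguish_sd: float = 0.15
    immune_start: int = 15
    extinction_direction: str = "inverted"  # inverted (prose) | as_printed
    ignorant_direct_immunity: bool = False

    # attribute influence of the carrier roles
    ar_s: float = 1.0
    ar_v: float = 1.5
    ar_o: float = 0.5

    # bounded-trust opinion dynamics
    mu: float = 0.1
    d1: float = 1.0
    d2: float = 1.5
    rho1: float = -0.4
    rho2: float = -0.2
    rho3: float = 0.2
    rho4: float = 0.3
    unsigned_opinion_updates: bool = False

    # interlayer synchronization
    xi: float = 0.1
    reinforcement: float = 0.2
    sync_direction: str = "online_to_offline"  # online_to_offline | bidirectional

    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self
        checks: list[tuple[bool, str]] = [
            (c.m >= 1, f"m: attachment parameter must be >= 1, got {c.m}"),
            (c.n > c.m, f"n: node count must exceed m, got n={c.n}, m={c.m}"),
            (c.horizon >= 0, f"horizon: must be >= 0, got {c.horizon}"),
            (
                c.initial_carriers is None or 0 <= c.initial_carriers <= c.n,
                f"initial_carriers: must lie in [0, n], got {c.initial_carriers}",
            ),
            (
                0.0 <= c.offline_prob <= 1.0,
                f"offline_prob: must lie in [0, 1], got {c.offline_prob}",
            ),
            (
                0.0 <= c.arousal_mean <= 1.0,
                f"arousal_mean: must lie in [0, 1], got {c.arousal_mean}",
            ),
            (c.arousal_sd >= 0, f"arousal_sd: must be >= 0, got {c.arousal_sd}"),
            (
                0.0 <= c.extinguish_mean <= 1.0,
                f"extinguish_mean: must lie in [0, 1], got {c.extinguish_mean}",
            ),
            (c.extinguish_sd >= 0, f"extinguish_sd: must be >= 0, got {c.extinguish_sd}"),
            (c.immune_start >= 0, f"immune_start: must be >= 0, got {c.immune_start}"),
            (
                c.extinction_direction in ("inverted", "as_printed"),
                f"extinction_direction: unknown value {c.extinction_direction!r}",
            ),
            (c.ar_s > 0, f"ar_s: must be > 0, got {c.ar_s}"),
            (c.ar_v > 0, f"ar_v: must be > 0, got {c.ar_v}"),
            (c.ar_o > 0, f"ar_o: must be > 0, got {c.ar_o}"),
            (0.0 < c.mu <= 1.0, f"mu: must lie in (0, 1], got {c.mu}"),
            (
                0.0 < c.d1 < c.d2,
                f"d1/d2: must satisfy 0 < d1 < d2, got d1={c.d1}, d2={c.d2}",
            ),
            (
                -1.0 < c.rho1 < c.rho2 <= 0.0 <= c.rho3 < c.rho4 < 1.0,
                "rho1..rho4: must satisfy -1 < rho1 < rho2 <= 0 <= rho3 < rho4 < 1, "
                f"got ({c.rho1}, {c.rho2}, {c.rho3}, {c.rho4})",
            ),
            (c.xi >= 0, f"xi: must be >= 0, got {c.xi}"),
            (
                0.0 < c.reinforcement < 1.0,
                f"reinforcement: must lie in (0, 1), got {c.reinforcement}",
            ),
            (
                c.sync_direction in ("online_to_offline", "bidirectional"),
                f"sync_direction: unknown value {c.sync_direction!r}",
            ),
            (
                c.coupling_mode in ("assortative", "disassortative", "random"),
                f"coupling_mode: unknown value {c.coupling_mode!r}",
            ),
            (
                c.offline_topology in ("ba", "ws", "file"),
                f"offline_topology: unknown value {c.offline_topology!r}",
            ),
            (
                c.schema_version == SCHEMA_VERSION,
                f"schema_version: expected {SCHEMA_VERSION}, got {c.schema_version}",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    # -- derived quantities -------------------------------------------------

    def n_initial_carriers(self) -> int:
        if self.initial_carriers is not None:
            return self.initial_carriers
        return max(1, round(0.01 * self.n))

    def replace(self, **kwargs) -> "SimConfig":
        if bad := set(kwargs) - {f.name for f in dataclasses.fields(self)}:
            raise ConfigError(f"unknown config key(s): {sorted(bad)}")
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the full parameter vector, for logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimConfig)}


def read_config(path: str | Path) -> SimConfig:
    """Load and validate a config file; missing keys take the defaults.

    YAML for ``.yaml``/``.yml``, JSON for ``.json``.  An empty document
    yields the full default configuration.  Unknown keys raise
    :class:`ConfigError` naming the key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text) if text.strip() else None
    else:
        raise ConfigError(f"unrecognized config extension {path.suffix!r}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping of keys to values")
    if bad := set(data) - _FIELD_NAMES:
        raise ConfigError(f"unknown config key(s): {sorted(bad)}")
    try:
        return SimConfig(**data)
    except TypeError as exc:  # e.g. a list where a scalar belongs
        raise ConfigError(str(exc)) from exc


def write_config(config: SimConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        raise ConfigError(f"unrecognized config extension {path.suffix!r}")


def write_timeseries(ts: pd.DataFrame, path: str | Path) -> None:
    """Write the per-step density table as CSV (6-decimal densities)."""
    if ts.empty:
        raise ParameterError("cannot write an empty time series")
    cols = ["t", "layer", "I", "S", "V", "O", "R", "C"]
    out = ts.loc[:, cols].sort_values(["t", "layer"], kind="stable")
    out.to_csv(path, index=False, float_format="%.6f")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def save_edgelist(g: nx.Graph, path: str | Path) -> None:
    nx.write_edgelist(g, str(path), data=False)


def load_edgelist(path: str | Path) -> nx.Graph:
    g = nx.read_edgelist(str(path), nodetype=int)
    # isolated high-numbered nodes are not representable in an edge list;
    # relabel contract: nodes must already be 0..n-1
    n = max(g.nodes) + 1 if g.number_of_nodes() else 0
    g.add_nodes_from(range(n))
    return g


def save_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def load_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(str(path), node_type=int)
    return nx.Graph(g)


# -- fixtures ----------------------------------------------------------------

#: Hand-specified 12-node layer topologies used by the oracle-equivalence
#: suite: a hub-and-ring online layer and a two-community offline layer.
TOY12_ONLINE_EDGES = [
    (0, 1), (0, 2), (0, 3), (0, 4), (0, 5),
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 1),
    (6, 7), (7, 8), (8, 9), (9, 10), (10, 11), (11, 6),
    (1, 6), (3, 8), (5, 10),
]
TOY12_OFFLINE_EDGES = [
    (0, 1), (1, 2), (2, 0), (0, 3), (1, 4), (2, 5),
    (3, 4), (4, 5), (5, 3),
    (6, 7), (7, 8), (8, 6), (6, 9), (7, 10), (8, 11),
    (9, 10), (10, 11), (11, 9),
    (4, 7), (5, 9),
]


def _graph_from_edges(n: int, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


def make_fixture(preset: str, seed: int = 0):
    """Deterministic network + config presets.

    toy12
        Two fixed 12-node layers with random coupling and a small, fast
        configuration (no masking dilution: offline_prob = 0.5).
    star / complete
        Ten-node star / complete graphs on both layers, assortative
        coupling — degenerate topologies for edge-case tests.
    case_study
        Two independent BA(2000, 5) layers under the full case-study
        configuration.

    Returns ``(CoupledNetwork, SimConfig)``.
    """
    from .network import build_ba_network, couple_layers

    if preset == "toy12":
        online = _graph_from_edges(12, TOY12_ONLINE_EDGES)
        offline = _graph_from_edges(12, TOY12_OFFLINE_EDGES)
        net = couple_layers(online, offline, "random", seed=seed)
        cfg = SimConfig(
            n=12, m=2, seed=seed, horizon=30, initial_carriers=3,
            offline_prob=0.5, immune_start=5,
        )
        return net, cfg
    if preset in ("star", "complete"):
        g1 = nx.star_graph(9) if preset == "star" else nx.complete_graph(10)
        g2 = nx.star_graph(9) if preset == "star" else nx.complete_graph(10)
        net = couple_layers(g1, g2, "assortative")
        cfg = SimConfig(n=10, m=2, seed=seed, horizon=20, initial_carriers=2)
        return net, cfg
    if preset == "case_study":
        rng = np.random.SeedSequence(seed)
        s_on, s_off, s_map = (int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(3))
        online = build_ba_network(2000, 5, seed=s_on)
        offline = build_ba_network(2000, 5, seed=s_off)
        net = couple_layers(online, offline, "random", seed=s_map)
        return net, SimConfig(seed=seed)
    raise ConfigError(
        f"unknown fixture preset {preset!r}; "
        "expected toy12, star, complete or case_study"
    )
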