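"""Engine step vs. an independent straight-line per-node re-implementation.

The engine advances the coupled system with vectorized sparse operations.
Here every rule — mask, synchronization, arousal, role roulette, opinion
initialization, bounded-trust update, reclassification, extinction — is
re-implemented as plain per-node Python loops, and both are driven by the
same recorded randomness tape.  States must agree exactly and opinions to
floating-point noise at every step.
"""

import numpy as np
import pytest

from isovrnet import NodeState, Simulation, make_fixture


class RecordingRNG:
    """Wraps a Generator, remembering every uniform block it hands out."""

    def __init__(self, inner):
        self.inner = inner
        self.tape = []

    def random(self, size=None):
        out = self.inner.random(size)
        self.tape.append(np.atleast_1d(np.copy(out)))
        return out


class TapeRNG:
    """Replays a recorded tape, asserting the draw shapes line up."""

    def __init__(self, tape):
        self.tape = list(tape)

    def random(self, size=None):
        block = self.tape.pop(0)
        want = 1 if size is None else size
        assert block.size == want, f"tape expected {block.size} draws, asked {want}"
        return block if size is not None else float(block[0])


def classify(x, cfg):
    if (cfg.rho1 <= x <= cfg.rho2) or (cfg.rho3 <= x <= cfg.rho4):
        return int(NodeState.OYSTER)
    return int(NodeState.VARIATION) if x < 0 else int(NodeState.SPREADER)


def draw_opinion(role, u, cfg):
    """Length-weighted uniform draw over the role's interval union."""
    pieces = {
        1: [(0.0, cfg.rho3), (cfg.rho4, 1.0)],
        2: [(-1.0, cfg.rho1), (cfg.rho2, 0.0)],
        3: [(cfg.rho1, cfg.rho2), (cfg.rho3, cfg.rho4)],
    }[role]
    total = sum(hi - lo for lo, hi in pieces)
    pos = u * total
    x = pieces[-1][1]
    for lo, hi in pieces:
        if pos < hi - lo:
            x = lo + pos
            break
        pos -= hi - lo
    for _ in range(4):
        if classify(x, cfg) == role:
            return x
        lo, hi = next((lo, hi) for lo, hi in pieces if lo <= x <= hi)
        x = np.nextafter(x, (lo + hi) / 2.0)
    return x


def oracle_step(layers, mapping, inverse, neighbors, de, ec, thresholds, cfg,
                tapes, t_new):
    """One synchronous step computed node by node from first principles."""
    carrier = lambda s: s in (1, 2, 3)
    n = len(layers["online"]["states"])
    step_tape = tapes["step"]

    # 1. offline mask of the online layer
    p_off = 1.0 - cfg.offline_prob if cfg.invert_offline else cfg.offline_prob
    u_mask = step_tape.random(n)
    mask = [u_mask[i] < p_off for i in range(n)]

    # 2. synchronization, all directions evaluated on the pre-sync snapshot
    snap = {
        name: (list(layers[name]["states"]), list(layers[name]["opinions"]))
        for name in ("online", "offline")
    }
    directions = [("online", "offline", mapping)]
    if cfg.sync_direction == "bidirectional":
        directions.append(("offline", "online", inverse))
    for src, dst, mp in directions:
        u = step_tape.random(n)
        src_states, src_ops = snap[src]
        dst_states, _ = snap[dst]
        for i in range(n):
            if not carrier(src_states[i]):
                continue
            j = mp[i]
            n_same = sum(
                1 for k in neighbors[dst][j] if dst_states[k] == src_states[i]
            )
            omega = min(cfg.xi * n_same / (1.0 + cfg.reinforcement * n_same), 1.0)
            if u[i] < omega and dst_states[j] != 4:
                layers[dst]["states"][j] = src_states[i]
                layers[dst]["opinions"][j] = src_ops[i]

    # 3-7. intra-layer dynamics on the post-sync snapshot
    for name in ("online", "offline"):
        lay = layers[name]
        st = list(lay["states"])
        op = list(lay["opinions"])
        nbrs = neighbors[name]
        active = [not mask[i] for i in range(n)] if name == "online" else [True] * n

        def sends(i):
            return carrier(st[i]) and active[i]

        # 3. arousal
        new_nodes = []
        for i in range(n):
            if st[i] != 0 or not active[i] or not nbrs[i]:
                continue
            c = sum(1 for j in nbrs[i] if sends(j))
            if c / len(nbrs[i]) >= thresholds[name]["arousal"][i]:
                new_nodes.append(i)

        # 4. role roulette + opinion initialization (ascending node order)
        u_role = tapes[name].random(len(new_nodes))
        u_init = tapes[name].random(len(new_nodes))
        alphas = {1: cfg.ar_s, 2: cfg.ar_v, 3: cfg.ar_o}
        for pos, i in enumerate(new_nodes):
            sums = {1: 0.0, 2: 0.0, 3: 0.0}
            for j in nbrs[i]:
                if sends(j):
                    sums[st[j]] += de[name][j] * ec[name][j] * alphas[st[j]]
            total = sums[1] + sums[2] + sums[3]
            r = float(u_role[pos])
            if total <= 0:
                role = 1
            elif r < sums[1] / total:
                role = 1
            elif r < (sums[1] + sums[2]) / total:
                role = 2
            else:
                role = 3
            lay["states"][i] = role
            lay["opinions"][i] = draw_opinion(role, float(u_init[pos]), cfg)

        # 5-6. opinion update + reclassification of snapshot carriers
        for i in range(n):
            if not carrier(st[i]):
                continue
            x = op[i]
            if active[i]:
                talking = [op[j] for j in nbrs[i] if sends(j)]
                if talking:
                    xbar = sum(talking) / len(talking)
                    delta = abs(x - xbar)
                    if delta < cfg.d1:
                        x = x + cfg.mu * delta if cfg.unsigned_opinion_updates \
                            else x + cfg.mu * (xbar - x)
                    elif delta > cfg.d2:
                        x = x - cfg.mu * delta if cfg.unsigned_opinion_updates \
                            else x + cfg.mu * (x - xbar)
                    x = min(1.0, max(-1.0, x))
                    if 0.0 <= op[i] <= cfg.rho3:
                        x = max(x, op[i])
            lay["opinions"][i] = x
            lay["states"][i] = classify(x, cfg)

        # 7. extinction (mask-independent, active from the onset step)
        if t_new >= cfg.immune_start:
            for i in range(n):
                hit = False
                if nbrs[i]:
                    frac = sum(1 for j in nbrs[i] if sends(j)) / len(nbrs[i])
                else:
                    frac = 0.0
                thr = thresholds[name]["extinguish"][i]
                fired = frac >= thr if cfg.extinction_direction == "as_printed" \
                    else frac < thr
                if carrier(st[i]) and fired:
                    hit = True
                if cfg.ignorant_direct_immunity and st[i] == 0 and nbrs[i] and fired:
                    hit = True
                if hit:
                    lay["states"][i] = 4


@pytest.mark.parametrize("sync_direction", ["online_to_offline", "bidirectional"])
@pytest.mark.parametrize("extinction_direction", ["inverted", "as_printed"])
def test_step_matches_brute_force_oracle(sync_direction, extinction_direction):
    net, cfg = make_fixture("toy12", seed=11)
    cfg = cfg.replace(
        sync_direction=sync_direction,
        extinction_direction=extinction_direction,
        ignorant_direct_immunity=extinction_direction == "as_printed",
    )
    sim = Simulation(cfg, network=net)

    # record every uniform block the engine consumes
    rec = {
        "step": RecordingRNG(sim.rng),
        "online": RecordingRNG(sim.layer_rng["online"]),
        "offline": RecordingRNG(sim.layer_rng["offline"]),
    }
    sim.rng = rec["step"]
    sim.layer_rng = {"online": rec["online"], "offline": rec["offline"]}

    # oracle bookkeeping built from the same initial conditions
    layers = {}
    thresholds = {}
    de, ec, neighbors = {}, {}, {}
    graphs = {"online": net.online, "offline": net.offline}
    for name in ("online", "offline"):
        lv = sim.layers[name]
        layers[name] = {
            "states": [int(s) for s in lv.states],
            "opinions": [float(x) for x in lv.opinions],
        }
        thresholds[name] = {
            "arousal": [float(x) for x in lv.arousal],
            "extinguish": [float(x) for x in lv.extinguish],
        }
        de[name] = [float(x) for x in lv.de]
        ec[name] = [float(x) for x in lv.ec]
        neighbors[name] = [sorted(graphs[name].neighbors(i)) for i in range(net.n)]

    for step_no in range(1, 16):
        sim.step()
        tapes = {k: TapeRNG(v.tape) for k, v in rec.items()}
        for v in rec.values():
            v.tape = []
        oracle_step(
            layers, net.mapping, net.inverse, neighbors, de, ec, thresholds,
            cfg, tapes, t_new=step_no,
        )
        for name in ("online", "offline"):
            got_states = np.asarray(sim.layers[name].states, dtype=int)
            want_states = np.asarray(layers[name]["states"], dtype=int)
            assert np.array_equal(got_states, want_states), (
                f"state mismatch in {name} at step {step_no}"
            )
            got_ops = np.asarray(sim.layers[name].opinions, dtype=float)
            want_ops = np.asarray(layers[name]["opinions"], dtype=float)
            both = ~(np.isnan(got_ops) & np.isnan(want_ops))
            assert np.allclose(
                got_ops[both], want_ops[both], atol=1e-12, equal_nan=True
            ), f"opinion mismatch in {name} at step {step_no}"
        assert all(len(t.tape) == 0 for t in tapes.values())
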