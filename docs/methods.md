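# Model and methods

## The process being simulated

`isovrnet` simulates rumor propagation over a two-layer coupled social
network: an *online Internet layer* and an *offline entity layer*, with the
same individuals present in both (a one-to-one node mapping).  Each node is
in one of five states — Ignorant (I), Spreader (S), Variation (V), Oyster
(O), Recovered (R) — where S, V, O jointly form the *carrier* compartment C:
people who have adopted the rumor.  A Variation spreads a mutated/distorted
version of the story; an Oyster has received it but stays silent
(wait-and-see).  Densities satisfy the structural identities
`I(t)+C(t)+R(t)=1` and `S(t)+V(t)+O(t)=C(t)` at every step.

Three mechanisms drive the dynamics:

1. **Threshold activation/extinction (amended linear threshold).**  An
   ignorant node i wakes up when the fraction of carriers among its
   neighbours reaches its personal arousal threshold `phi_i`; a carrier is
   extinguished into the absorbing Recovered state by a second per-node
   threshold `varphi_i`, active only from the immunity-onset step
   (`immune_start`, default 15) onward.  Both thresholds are drawn once per
   node and layer from `Normal(mean, sd)` truncated to `[0, 1]` by rejection
   resampling.

2. **Bounded-trust opinion dynamics.**  Each carrier holds an opinion
   `x in [-1, 1]`; the carrier role is a deterministic function of the
   opinion: S on `[0, rho3) u (rho4, 1]`, V on `[-1, rho1) u (rho2, 0)`,
   O on the silence windows `[rho1, rho2] u [rho3, rho4]`.  Against the mean
   opinion of its active carrier neighbours, a node assimilates when the
   distance is below `d1` (`x <- x + mu (xbar - x)`), is repelled when it
   exceeds `d2` (`x <- x + mu (x - xbar)`), and otherwise keeps its opinion.
   Opinions are clamped to `[-1, 1]` and a ratchet forbids any decrease once
   an opinion is inside `[0, rho3]`.

3. **Social-reinforcement interlayer synchronization.**  A carrier's state
   (and opinion) copies to its counterpart in the other layer with
   probability `omega(n) = xi n / (1 + gamma n)`, where n is the number of
   the counterpart's neighbours already in the source state.  `omega` is
   monotone in n and saturates below `xi/gamma`.  Recovered counterparts are
   never overwritten.

The online layer is additionally thinned every step: each node is offline
with probability `o` (default 0.97) and then neither sends nor receives
influence within the layer that step.

## Per-step schedule and randomness

Updates are synchronous; every rule is evaluated on the state snapshot at
the start of the step.  Order: (1) offline mask; (2) interlayer
synchronization, online→offline by default, both directions evaluated on
the pre-sync snapshot when bidirectional; (3) arousal; (4) role assignment
of the newly aroused by an influence-proportional roulette over their
carrier neighbours, with role-consistent length-weighted uniform opinion
initialization; (5) opinion updates; (6) opinion-based reclassification;
(7) extinction.  Newly activated nodes do not transmit until the next step.

Random draws follow a fixed order (documented in `engine.py`) from three
seeded streams — one shared stream for mask/synchronization uniforms and
one private stream per layer — so a run is bit-reproducible under a fixed
seed and, with `xi = 0`, the offline layer's trajectory is entirely
independent of online activity.  All streams derive from the single config
seed via `numpy.random.SeedSequence`.

## Influence

A carrier's influence factorises as `influence(i) = DE(i) * EC(i) * Ar(i)`:
degree centrality `deg(i)/(n-1)`, eigenvector centrality (dominant
adjacency eigenvector), and a role weight `Ar` (`ar_s=1, ar_v=1.5,
ar_o=0.5` by default — mutated content carries the most weight, silence the
least).  Eigenvector centrality is computed by power iteration on `A + I`
(the unit shift preserves eigenvectors while making the iteration converge
on bipartite graphs such as stars), normalised to unit Euclidean norm,
tolerance 1e-10, at most 10,000 iterations; the normalisation constant is a
free choice since only influence ratios within a neighbourhood matter.
Edgeless graphs get an all-zero centrality with a warning, and an all-zero
influence neighbourhood falls back to the Spreader role.

## Default configuration

All defaults are the reference case-study values: two independent BA
scale-free layers with `n=2000, m=5` (mean degree 9.975), random interlayer
coupling, `o=0.97`, arousal `N(0.2, 0.5)`, extinguishment `N(0.2, 0.15)`,
`immune_start=15`, `xi=0.1`, `gamma=0.2` (config key `reinforcement`),
`mu=0.1`, `d1=1`, `d2=1.5`, `rho=(-0.4, -0.2, 0.2, 0.3)`, horizon 100.
Initial carriers: 1% of the nodes, chosen uniformly, seeded as Spreaders
with spreader-interval opinions *in both layers* (the same individuals on
both sides, same opinion).  Seeding both layers is required for the offline
layer to have dynamics at all: the synchronization probability is zero when
the counterpart has no same-state neighbour, so an unseeded layer could
never acquire its first carrier.

## Interpretation choices where the formulation is ambiguous

These are genuinely open readings; each is config-gated where reasonable.

- **Extinction direction.**  The threshold rule for recovery can be read
  as firing when the carrier-neighbour fraction is *at least* the
  threshold (`as_printed`) or when the local rumor energy has faded
  *below* it (`inverted`).  The default is `inverted`: it matches the
  prose description of extinction, and under the heavy online masking it
  is the reading that makes immunity actually appear at the onset step in
  the online layer (under `as_printed`, online carriers almost never have
  an unmasked carrier neighbour, so recovery essentially never fires
  there).  `extinction_direction: as_printed` restores the other reading.
- **Mask scope.**  The offline mask suppresses transmission: masked nodes
  are excluded from all neighbour counts, influence sums and opinion
  means, and do not activate or update opinions.  Extinction, however, is
  modelled as an internal (rational) decision and is evaluated for masked
  carriers too.
- **Synchronization copies carriers only.**  Copying Ignorant or Recovered
  across layers would revert carrier counterparts (forbidden by the
  no-after-effect assumption) and, with a 97%-ignorant masked online
  layer, would actively erase the offline epidemic as `xi` grows —
  inverting the role of social reinforcement.
- **Denominators.**  `Amount(All)` in the activation/extinction fractions
  is the node's full neighbour count; reading it as "carrier neighbours"
  would force the fraction to 1.
- **Signed opinion updates.**  The unsigned forms `x ± mu |x - xbar|`
  would repel close opinions whenever `x > xbar`; the signed forms used by
  default reproduce them when `x < xbar` and honour the
  attraction/repulsion semantics otherwise (`unsigned_opinion_updates: true`
  restores the unsigned forms).
- **Boundaries.**  Silence-interval endpoints classify as Oyster; `x = 0`
  as Spreader; the variation window `(rho2, 0)` follows the sign-corrected
  reading (`[-rho2, 0]` would be empty for negative `rho2`).
- **Immunity onset** is implemented as a hard gate: the extinguishing rule
  is simply not evaluated while `t < immune_start`, which yields
  `R(t) = 0` for all `t < 15` under the defaults.
- An optional `ignorant_direct_immunity` flag lets ignorants jump straight
  to Recovered by the same rule (default off); `invert_offline` reads `o`
  as the probability of being *online* instead (default off, literal
  reading).

## What the generator emulates, and what it does not

The BA layers emulate the case study's heavy-tailed interaction network at
a convenient scale; they do not reproduce its community structure,
degree-degree correlations, or temporal growth, and the empirical network
itself is out of scope.  Passing tests therefore certify the mechanisms
and their couplings under scale-free topology and the stated parameters,
not quantitative agreement with any particular real event trajectory.

## Numerical and testing notes

- Densities are counts over n; the two conservation identities hold to
  1e-12 by construction and are asserted on full default runs.
- The engine's vectorized step is cross-checked against an independent
  per-node straight-line re-implementation of every rule, driven by the
  same recorded randomness tape, on a frozen 12-node two-layer fixture,
  for both synchronization directions and both extinction directions.
- Sampling checks (truncated-normal moments via `scipy.stats.truncnorm`,
  role-roulette frequencies, sub-interval weights, offline fractions) use
  three-standard-error or stated absolute tolerances.
- Directional (qualitative) comparisons use one-sided Mann-Whitney rank
  tests at alpha = 0.05 on 20 replicates at n = 500 with horizon 30 —
  sizes chosen so the whole suite runs in seconds.  The pre-immunity
  window `[0, immune_start]` defines the "early phase" of variation
  growth.

## Known limitations

- Raising the trust rate `mu` *shortens* mutant (V) lifetimes here:
  minority negative opinions are assimilated back into the positive
  majority faster, so V grows faster only transiently (first ~8 steps)
  and its pre-immunity growth rate decreases with `mu`.  If "trust" is
  instead identified with the assimilation distance `d1`, lowering trust
  (smaller `d1`) does markedly reduce the variation's rate and peak.
- Under the literal `o = 0.97` the online layer is ~97% frozen each step;
  its carrier curve is nearly flat until the immunity onset.  The
  recovered-density curves of the two layers move together; the carrier
  curves need not.
- Parameters are static over a run; no event-phase adaptation, no
  continuous-time scheduling, and no fitting of parameters to empirical
  trajectories.
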