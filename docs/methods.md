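# Methods

## Scope and assumptions

`sfhon` estimates the relative risk that commercial shipping transfers
aquatic nonindigenous species (NIS) between ports, separately for ballast
water and hull biofouling, and represents recurring indirect transfer
pathways explicitly as a higher-order network. The model is deliberately
coarse: species are not individuated; risk is a per-pathway probability of
"at least one successful transfer opportunity", and independence is assumed
wherever probabilities are combined (voyages within a pair, edges within a
pathway, parallel pathways into a port). Environmental exposure *along* a
voyage route is not modeled — only source/destination attributes enter.

## Pairwise risk model

`P(spread)_ij = P(nonindigenous)_ij · P(establish)_ij · P(intro)_ij`.

**Nonindigenous indicator.** Marine ecoregions approximate shared native
species pools; ports in the same or neighboring ecoregions score 0,
otherwise 1. The neighbor relation is symmetric and supplied as data.

**Establishment.** A Gaussian kernel on environmental mismatch,
`α·exp(−½[(ΔT/δ_T)² + (ΔS/δ_S)²])`, with defaults α = 0.00015, δ_T = 2 °C,
δ_S = 10 ppt. α bounds every spread probability from above: even a perfect
environmental match transfers species with small probability per
pair-aggregate. Ports lacking temperature or salinity are dropped at read
time and never scored.

**Biofouling introduction (per voyage).**
`A(type) · accum(d, zone) · e^(−γ·v)`:

- `A(type)` — share of ships of the type without an operational antifouling
  system: Container 0.19, Auto 0.20, Tanker 0.30, Passenger 0.31, Bulk
  0.42, General 0.53, all others 0.60. Raw type strings are case-folded
  through a configurable alias table; unmapped types fall back to 0.60
  (logged).
- `accum(d, zone)` — a zone-specific cubic `β₁d³ − β₂d² + β₃d` in the days
  spent at the source port, measuring the proportion of maximum fouling
  species richness. Tropical/subtropical (source-port latitude within ±35°,
  boundary inclusive) β = (1.29·10⁻⁷, 8.316·10⁻⁵, 0.0149); temperate
  β = (1.4·10⁻⁹, 1.6566·10⁻⁵, 5.193·10⁻³). The fitted tropical cubic
  exceeds 1 beyond roughly 430 days in port, so the value is clamped into
  [0, 1]; the clamp can be disabled for diagnostics
  (`RiskParams.clamp_accumulation`).
- survival `e^(−γ·v)` with γ = 0.008 per (km/day) and v the voyage velocity
  (great-circle distance / duration). At typical ship speeds of several
  hundred km/day this term is severe; it is implemented exactly as
  parameterized, and γ is configurable for sensitivity analyses.

**Ballast introduction (per voyage).** `ρ·(1 − e^(−λD))·e^(−μΔt)` with
μ = 0.02 /day (in-tank mortality), λ = 3.22·10⁻⁶ /m³ (introduction
potential per unit discharge), Δt the voyage duration in days and D the
discharge volume — observed when reported, otherwise a per-type coefficient
times gross weight tonnage. The shipped discharge coefficients
(m³/tonne: Container 0.10, Auto 0.20, Bulk 0.35, General 0.15, Tanker 0.30,
Passenger 0.20, other 0.15) are nominal fleet-survey-style values and fully
configurable; only their relative order matters for ranked outputs. ρ is a
ballast-management efficacy factor kept at its default 1 (no management
modeled); note that as written it scales risk *up* with "efficacy" — the
formula is kept exactly as parameterized and the semantics are the
caller's responsibility when setting per-voyage values.

**Aggregation.** Voyages from i to j combine as a union of independent
Bernoulli events, `P(intro) = 1 − ∏(1 − p⁽ᵛ⁾)`, computed in log1p space;
the result is order-invariant and dominated by its largest term.

## Kinematics and trajectories

Distances are haversine great-circle (R = 6371 km). Durations are
`arrival − sail` floored at 0.5 day (`duration_floor`, configurable) so
same-day voyages keep finite velocities. Port stay before a departure is
the gap since the ship's previous arrival; a ship's first observed
departure uses a configurable 7-day default (the cold-start stay is
unobservable). Self-loop voyages are excluded from risk and trajectories —
they move nothing between ports. Trajectories are per-ship chronological
port sequences with immediate repeats removed.

## Higher-order rule extraction

A pathway S is scored by the union of its consecutive edge risks
(`path_risk`). Extraction is bottom-up and deterministic:

1. every observed first-order transition with support ≥ `min_support`
   (default 5) is a rule;
2. a rule with context S and pathway risk P_S is extended by a preceding
   port x iff the extended pathway recurs ≥ `min_support` times and
   `(P_Snew − P_S)/P_S > threshold` (default 0.10), recursively up to
   `max_order` (default 5).

Contexts whose own pathway risk is zero are never extended: there is no
baseline risk for history to amplify, and the zero-risk first-order edge
already contributes nothing. The significance criterion is a relative risk
increase rather than a divergence test on next-step frequency
distributions; the support gate is what suppresses spurious contexts on
memoryless traffic, and the risk criterion is what keeps risk-irrelevant
(but frequent) histories out. Rules with zero pathway risk are retained
structurally but excluded from weighted outputs.

Wiring: rule (context → next, P) becomes an edge from the node labeled
`current|oldest,…,newest` to the highest-order existing node for `next`
whose context is a suffix of the extended history (falling back to the
first-order node), so walks through the network remain history-consistent.
Edge weights are raw pathway risks, *not* renormalized transition
probabilities — the graph is a risk field, not a Markov chain.

Collapsing back to ports combines parallel edges (several history-nodes of
one port) as a union by default (each pathway is an independent
opportunity); `sum` and `mean` modes exist for diagnostics. A port's
in-risk is the union of all incoming collapsed weights.

## Baselines

SF-FON keeps only the direct pair risks. The All-Paths baseline connects
every ordered pair of ports that co-occur (in order) on any trajectory,
scoring each subpath by the pathway union and combining contributions
across trajectories by union again; `max_span` can bound the subpath length
(unbounded by default; 5 reproduces the fixed-length variant used
elsewhere in the literature). Every All-Paths weight dominates the
corresponding first-order weight by construction — the mechanism behind its
systematic over-prediction. Repeated traversals of the same ordered index
pair within one trajectory count as separate Bernoulli terms.

## Network statistics

The comparison-table conventions are implemented as stated, not silently
corrected:

- clustering coefficient: directed, neighborhood = union of in/out
  neighbors, numerator counts directed edges among neighbors, k(k−1)
  denominator; nodes with fewer than two neighbors score 0;
- density: `|E|/(|V|²/2)` by default (`as_printed`), with the standard
  directed `|E|/(|V|(|V|−1))` available — the two disagree and both are
  exposed;
- betweenness: shortest paths on lengths 1/weight (inverting transfer
  probabilities; −log weight optional), endpoints excluded, ordered (s, t)
  pairs, normalized by (n−1)(n−2)/2. With this normalization a node on
  many reciprocal shortest paths can exceed 1; the convention is kept as
  defined. Zero-weight edges are untraversable;
- Freeman centralization: `2·Σ(C′_max − C′_i)/(n−1)`;
- components: weak (direction-blind) and strong (mutual reachability).

Realm flow matrices average collapsed pair risks over all source/target
port pairs of each realm pair and min-max normalize the matrix (degenerate
max = min maps to all-zero, logged). Ship-type summaries report record
shares (summing to 100%) and five-number summaries of per-voyage risks.
Temporal summaries pair the count of higher-order nodes with mean edge
risk per snapshot and report their Pearson correlation (undefined for
constant series; reported as None).

## Flow clustering

Two-level map equation over hard partitions. The walk normalizes out-edge
weights per node, teleports uniformly with probability 0.15, and dangling
nodes redistribute uniformly; visit rates come from power iteration
(tol 1e−12, max 10⁴ iterations). The optimizer is a seeded greedy search:
singleton start, local node moves among link-neighbor modules, module
merges, repeated to convergence, best of `n_restarts` (default 10).
Identical seeds give identical partitions. A port belongs to every cluster
containing one of its history-nodes, which is how multi-cluster port
membership arises. The optimizer is exact on the objective it evaluates
but heuristic in its search, adequate at desk scale (hundreds of nodes);
an external Infomap implementation can be swapped in behind the same
partition contract, and python-igraph's implementation serves as an
independent cross-check in the test suite.

## Evaluation

Port in-risks are averaged per state/country (mean, not sum or median:
unions saturate and medians vanish at region scale), min-max scaled per
model, and compared against min-max-scaled first-introduction counts by
MSE. Scaling is per model; a shared-scale variant is a one-flag change.
Model pairs are compared with a two-tailed *paired* t-test on per-region
squared errors (the errors are paired by region); all-zero differences are
reported as p = 1 with a degeneracy flag. The direction report counts
regions over- vs under-estimated, ties counting as neither.

## Synthetic study conditions

The generator produces: ports on a quasi-uniform latitude scatter
(temperature decreasing with |latitude|, salinity on a longitude gradient,
Gaussian jitter of 1 unit on both), ecoregions as contiguous port-index
blocks nested in realms with chain adjacency, one evaluation region per
ecoregion; a typed fleet with lognormal tonnage around per-type scales; and
trajectories from a first-order base chain (uniform by default) with
planted dependencies: when a ship's recent history matches a planted
context exactly, the planted next port is emitted with the boost
probability (0.9 in the reference conditions). Dates use whole days, stays
uniform on 1–14 days, speeds uniform on 250–550 km/day.

Reference corpora (fixed once, used by the acceptance suite):

- *memoryless*: 20 ports, 6 ecoregions, 3333 ships × 3 voyages (≈10⁴
  voyages). The thin per-ship records mirror a short observation window and
  keep chance recurrence of 2-step contexts near the support threshold's
  floor; a first-order process should then yield almost no higher-order
  rules (<1% pooled over seeds).
- *planted*: 50 ports, 10 ecoregions, 12 500 ships × 4 voyages (5·10⁴
  voyages), 5 second-order + 2 third-order planted rules at boost 0.9.
  Each third-order rule ships with a second-order helper (counted among the
  five) that makes its context recur. Planted chains are sampled among
  environmentally similar (|ΔT| ≤ 3 °C, |ΔS| ≤ 8 ppt), pairwise
  cross-ecoregion port sequences, so every leg of a planted pathway carries
  comparable, non-zero risk and the dependency is recoverable in principle.
  The expected recovery set is the planted rules plus the second-order
  suffixes induced by third-order plants (extraction is stepwise, and those
  suffixes are genuinely predictive in the generated traffic).

End-to-end truth: the generating process moves species along first-order
legs always, and along multi-leg pathways exactly where dependencies are
planted; the true port risk is therefore the collapse of the network wired
from the true rule set (all first-order pairs plus planted rules at exact
pathway risks). Observations are min-max-transformed true region risks
(noiseless for the ordering test; truncated Gaussian noise and rounding to
counts otherwise). Passing these tests shows the pipeline recovers the
structure its own model class generates — it does not validate the
biological parameterization against field data, and the generator makes no
attempt at realistic traffic statistics (no port-call power laws, no
seasonal structure, no fleet routing).

## Numerical choices

Probability unions run in log1p/expm1 space; any term ≥ 1 short-circuits
to 1. Single-term unions return the term bit-exactly. Establishment uses
direct `exp`; underflow to 0 at extreme mismatch is acceptable and treated
as genuine zero risk. Min-max normalization of a constant vector returns
zeros with a log flag rather than NaNs. Betweenness ties are resolved by
the shortest-path counts of Dijkstra on exact float lengths. The map
equation guards `0·log 0 = 0`. Cluster ids are relabeled densely in
first-appearance order so equal seeds serialize identically.

## Known limitations

- Ballast risk uses total estimated discharge for every leg; partial
  discharge en route is not tracked, which inflates long-pathway ballast
  risk.
- The biofouling survival decay at realistic velocities suppresses most
  biofouling risk; conclusions should rest on relative, not absolute,
  values.
- The extraction significance test is risk-based (relative by default,
  absolute available); a frequency-divergence criterion in the style of
  variable-order network inference is a natural third variant behind the
  same interface, not yet implemented.
- The clustering optimizer is greedy; on large graphs with weak structure
  it may return locally optimal partitions (mitigated by restarts).
- Region evaluation assumes every scored port maps to exactly one region
  and regions are compared only after per-model scaling.
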