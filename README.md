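# sfhon — species-flow networks for ship-borne invasion risk

`sfhon` models the spread of aquatic nonindigenous species (NIS) through a
shipping network via its two main vectors — **ballast water** and **hull
biofouling** — and asks whether spread follows the first-order Markov
assumption (risk depends only on the last port) or exhibits *higher-order*
pathways: ships that take on ballast or fouling in port *C* and release it
two or three calls later. It is aimed at invasion ecologists and biosecurity
analysts who have port-call records, port environmental data and marine
biogeography, and want port-, region- or realm-level risk estimates that
account for recurring multi-leg transfer patterns.

## The model

For an ordered port pair *(i, j)* and one vector, the spread risk is the
product of three probabilities:

```
P(spread)_ij = P(nonindigenous)_ij · P(establish)_ij · P(intro)_ij
```

- **P(nonindigenous)** ∈ {0, 1}: 0 when the ports share the same or a
  neighboring marine ecoregion (shared native species pool), else 1.
- **P(establish)** = α·exp(−½[(ΔT/δ_T)² + (ΔS/δ_S)²]) — a Gaussian
  environmental-similarity kernel on the temperature and salinity
  differences (α = 1.5·10⁻⁴, δ_T = 2 °C, δ_S = 10 ppt).
- **P(intro)** = 1 − ∏_v (1 − p⁽ᵛ⁾) — the union over all voyages *v* from
  *i* to *j* of per-voyage introduction probabilities:
  - biofouling: `A(type) · (β₁d³ − β₂d² + β₃d) · e^(−γ·velocity)` —
    antifouling share of the ship type, a climate-zone cubic in the days
    *d* spent at the source port, and en-route survival;
  - ballast: `ρ · (1 − e^(−λD)) · e^(−μΔt)` — discharge-volume saturation
    and in-tank mortality over the voyage duration.

A pathway S = {p₁ … p_k} is scored by the same union over its consecutive
edges, `P_S = 1 − ∏(1 − p_ij)`. From risk-weighted ship trajectories the
package extracts **dependency rules** (context → next port): a context is
extended one step back into the past whenever the extended pathway recurs
at least `min_support` times and raises the pathway risk by more than a
relative `threshold`. Wiring the rules yields the species-flow higher-order
network (SF-HON), whose nodes are ports annotated with visiting history
(`p2|p0,p1`); the first-order network (SF-FON) and an unfiltered All-Paths
baseline are built for comparison. On top of the graphs the package provides
network statistics, map-equation flow clustering with multi-cluster port
membership, realm-level flow matrices, ship-type risk summaries, and
region-level validation (MSE against normalized first-introduction counts,
paired t-tests between models).

## Worked example

A fully synthetic world with planted higher-order dependencies (the library
equivalent of `sfhon synth --planted`):

```python
from sfhon import pipeline

corpus = pipeline.planted_corpus(seed=1)           # 50 ports, 50k voyages
rules, hon, pair_df = pipeline.build_hon(corpus, "ballast")
print(len(pair_df), "port pairs,", len(rules), "rules,",
      sum(r.order >= 2 for r in rules), "higher-order")
for r in rules:
    if r.order >= 2:
        print("|".join(r.context), "->", r.next,
              f"support={r.support} p={r.probability:.3e}")
        break

res = pipeline.evaluate_three_models(corpus, "ballast", seed=1)
print(res["mse"])
```

prints

```
2450 port pairs, 2459 rules, 10 higher-order
P003|P048 -> P010 support=11 p=6.995e-05
{'SF-FON': 0.009847..., 'SF-HON': 0.002373..., 'All-Paths': 0.007162...}
```

The rule line reads: for ships that visited P048 before P003, the risk of
spreading species onward to P010 along that pathway is 7.0·10⁻⁵ — a
dependency the first-order network cannot represent. In the model
comparison the higher-order network attains the lowest region-level MSE;
the All-Paths baseline (which chains risk along entire trajectories without
a significance filter) over-predicts, here with a mean signed error of
+0.038 on the min-max scale.

The same pipeline is scriptable from the shell via the `sfhon` CLI
(`synth`, `pair-risk`, `build-fon`, `build-allpaths`, `build-hon`, `stats`,
`cluster`, `evaluate`, `compare`; see `sfhon --help`).

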