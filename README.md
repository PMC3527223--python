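# synapcap

**Storage capacity and memory lifetime of a single neuron under online
(palimpsest) synaptic plasticity.**

Experiments show that synaptic plasticity is weight-dependent: strong
synapses are harder to potentiate, while the relative amount of depression is
roughly weight-independent. Such *soft-bound* plasticity automatically
constrains synaptic weights. `synapcap` quantifies what this weight
dependence does to information storage, comparing the prototypical soft-bound
rule against *hard-bound* plasticity (constant updates with the weight
clipped to `[0, 1]`) in an online recognition task, by Monte-Carlo simulation
and by Fokker-Planck theory of the weight distribution. It is aimed at
computational neuroscientists studying synaptic memory models.

## The model

A neuron with `N` plastic synapses receives one random binary pattern
`x ∈ {−1, +1}^N` (or `{0, 1}^N` at coding density `f`) per time step and
outputs the weighted sum `y = Σᵢ xᵢ wᵢ`, optionally minus a feed-forward
inhibitory term `g Σᵢ xᵢ`. Every presentation potentiates high-input
synapses and depresses low-input ones:

| rule       | potentiation        | depression          | bounds |
|------------|---------------------|---------------------|--------|
| hard       | `w → w + a₊`        | `w → w − a₋`        | clip [0, 1] |
| soft       | `w → w + c_p`       | `w → (1 − c_d) w`   | intrinsic |
| power-law  | `w → w + a(1−w)^μ`  | `w → w − a w^μ`     | clip [0, 1] |
| log-normal | `w → w e^{c_p}`     | `w → w (w/w_ref)^{−c_d}` | intrinsic |

Learning never stops: each new pattern overwrites older traces (the
palimpsest property). The memory of a pattern of age `t` is summarized by
the signal-to-noise ratio of the output to that pattern against lures,

    S(t) = (μ₁(t) − μ₀)² / (½ (σ₁²(t) + σ₀²)),

and the recognition information per pattern is
`I(S) = 1 − H_b(Φ(−√S/2))` bits. Two scalar performance measures resolve
the trade-off between strong initial memories and slow forgetting:

* **information per synapse** — `Σ_t I(S(t)) / N`, maximized by small
  updates; in the small-update limit the soft rule reaches
  `1/(4π ln 2) ≈ 0.115` bits/synapse, about 18% above the hard rule
  (whose decay follows a reflecting-diffusion eigenmode series);
* **memory lifetime** — the number of recent patterns with `S(t) ≥ θ`
  (θ = 30 by convention); optimized over the update size the soft rule gives
  `N/(eθ)` and the hard rule ~20% less.

All closed forms are cross-validated against an exact discrete-state master
equation of the weight distribution, which also powers a deterministic
capacity pipeline and a numerical optimizer over polynomial update rules.

## Worked example

```python
from synapcap.rules import make_soft_rule
from synapcap.simulator import SimConfig, run_online, log_age_grid
from synapcap import metrics, theory

rule = make_soft_rule(c_p=0.005, c_d=0.01)
cfg = SimConfig(n_synapses=1000, n_patterns=100_000, seed=1,
                age_grid=log_age_grid(400, 40))
stats, weights = run_online(cfg, rule)
curve = metrics.snr_curve_from_stats(stats)
S0, tau = metrics.fit_exponential(curve, floor=0.5)
print(f"fitted S0  = {S0:.2f}   (theory: N c_d = 10)")
print(f"fitted tau = {tau:.1f}  (theory: 1/c_d = 100)")
print(f"mean weight = {weights.mean():.3f}   (theory: c_p/c_d = 0.5)")
print(f"lifetime at theta=5: {metrics.memory_lifetime(curve, 5.0)} patterns")
print(f"soft capacity  = {theory.soft_info_capacity():.4f} bits/synapse")
print(f"hard capacity  = {theory.hard_info_capacity():.4f} bits/synapse")
print(f"improvement    = {theory.capacity_improvement():.1f} %")
```

prints

```
fitted S0  = 10.00   (theory: N c_d = 10)
fitted tau = 99.3  (theory: 1/c_d = 100)
mean weight = 0.499   (theory: c_p/c_d = 0.5)
lifetime at theta=5: 69 patterns
soft capacity  = 0.1148 bits/synapse
hard capacity  = 0.0968 bits/synapse
improvement    = 18.6 %
```

The simulated SNR decays exponentially with the predicted initial strength
`N c_d` and time constant `1/c_d`; 69 of the most recent patterns are stored
above SNR 5; and the closed-form capacities show the ~18% soft-bound
advantage.

A command-line interface wraps the same machinery:

```
synapcap simulate --config run.yaml --out results/
synapcap report   --config run.yaml --out results/
synapcap theory | lifetime | optimize ...
```

with a YAML/JSON config such as

```yaml
command: simulate
rule: {family: soft, c_p: 0.005, c_d: 0.01}
sim: {n_synapses: 1000, n_patterns: 100000}
seed: 1
```

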