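# Methods

## Model and task

A single neuron receives `N` plastic synapses. Time is discrete: one pattern
presentation per step. Pattern elements are i.i.d. binary, either ±1 or 0/1,
with the high level occurring at coding density `f` (default ½). A high
input potentiates its synapse and a low input depresses it, independently of
the post-synaptic output; learning is online and never stops, so the weight
distribution is assumed to sit at its stochastic equilibrium and every
stored pattern is gradually overwritten by later ones (palimpsest memory).

Recognition is a binary discrimination: probe the neuron with a previously
presented pattern of age `t` or with a fresh lure, threshold the output, and
ask how much information the response carries about the pattern's novelty.
Because the output sums many inputs it is close to Gaussian whatever the
weight distribution, so the separation is captured by the SNR
`S(t) = (μ₁−μ₀)²/(½(σ₁²+σ₀²))`. With the threshold midway between the two
class means, either class is misclassified with probability
`ε = Φ(−√S/2)`, giving `I(S) = 1 − H_b(ε)` bits per pattern, linear near
zero with slope `I'(0) = 1/(4π ln 2)` and saturating at 1 bit. This
convention for the SNR denominator (the mean of the two variances) is pinned
by the anchor that an error rate of 0.36% corresponds to `S ≈ 29 ≈ 30`.

Both performance measures reduce the SNR-vs-age curve to one number:

* **Information per synapse**: `Σ_t I(S(t))/N` over integer ages. Because
  `I` saturates, large updates waste capacity: with exponential decay at
  fixed area `S₀τ`, initial SNR 10 reaches only ~78% of the small-update
  maximum (`capacity_fraction`).
* **Memory lifetime**: the number of ages with `S(t) ≥ θ`, default `θ = 30`
  (the error rate a recurrent network can tolerate per neuron).

## Fokker-Planck theory

A rule with event magnitudes `pot(w)`, `dep(w)` applied with probabilities
`f`, `1−f` induces per-step drift `A(w) = f·pot − (1−f)·dep` and diffusion
`B(w) = f·pot² + (1−f)·dep²`. For small updates the weight distribution
`P(w,t)` obeys the standard diffusion limit.

**Soft rule** (`pot = c_p`, `dep = c_d w`, dense ±1 inputs): an
Ornstein-Uhlenbeck process. Equilibrium Gaussian with mean `c_p/c_d`,
variance `c_p²/c_d`; after a plasticity event the displaced distribution is
transported rigidly back (the perturbation obeys a transport equation, so
the shape is preserved) with mean relaxation rate `c_d/2`. Since the SNR is
quadratic in the mean perturbation it decays at rate `c_d`:
`S(t) = N c_d e^{−c_d t}`. The area under the SNR curve is `N` for every
`c_d`, hence the small-update capacity `I'(0) ≈ 0.1148` bits/synapse,
independent of the parameter values. Any rule with constant-sign linear
drift and locally constant diffusion maps onto this case, which is why the
log-normal (exponentiated soft) and power-law (`μ = 1`) variants store the
same amount.

**Balanced hard rule** (`pot = dep = a`, clip [0, 1]): pure diffusion
`D = a²/2` with zero-flux (reflecting) boundaries and uniform equilibrium
(variance 1/12). A potentiation event piles a bump of probability against
the upper bound and leaves a dip at the lower one; approximating both by
boundary deltas and expanding in the cosine eigenmodes that implement the
reflecting boundaries (the mirror-charge construction) gives

    Δμ(t) = Σ_{k odd} (8a/π²k²) · exp(−(a²/2)π²k²t),

a sum of exponentials whose early part decays faster than any single mode.
Integrating `S(t) = 12NΔμ(t)²` over age yields the capacity
`I'(0)·12·(128/π⁶)·Σ_{k,l odd} 1/(k²l²(k²+l²)) ≈ 0.0968` bits/synapse —
about 18.6% below the soft rule. The double sum is truncated at 199 odd
modes (truncation error far below the comparison tolerances; the `k=l=1`
term alone captures ~95%).

**Lifetimes.** Maximizing the threshold-crossing time over the update size:
soft `L* = N/(eθ)` at `c_d* = eθ/N`; hard (lowest eigenmode only)
`L* = (768/π⁶)·N/(eθ)`, a deficit of `1 − 768/π⁶ ≈ 20.1%`. The full-series
lifetime optimizer (extra positive modes) does slightly better than lowest
order but stays below the soft optimum.

**Imbalanced hard rule** (`pot = a(1+β)`, `dep = a(1−β)`): constant drift
`v = aβ`, diffusion `D = a²(1+β²)/2` (the `(1+β²)` factor is kept rather
than approximated away). Equilibrium `P∞ ∝ e^{vw/D}`; perturbations relax
through Sturm-Liouville modes `u_n = e^{vw/2D}[cos nπw + (v/2Dnπ) sin nπw]`
with rates `λ_n = v²/4D + Dn²π²`, so any imbalance speeds up forgetting.
Expansion coefficients are fixed by requiring the `t = 0` series to
reproduce the imposed initial perturbation (rigid shift of `P∞` plus
boundary pile-up, `c_n = a_event ∫ψ_n'P∞/‖φ_n‖²` with the adjoint modes
`ψ_n = e^{−vw/D}u_n`); potentiation and depression probes are averaged for
the signal. Defaults: 100 modes, quadrature on 2000 grid points, ages up to
`20/λ₁`. The information is maximal at `β = 0` and symmetric in `β`.

## Master-equation oracle

Every closed form is checked against an exact discrete-state master
equation: the weight axis is binned (default 200 bins; bounded rules use
their clip interval, unbounded rules an automatic ±8σ window around the
drift zero), and each step moves every bin's mass through the rule's clipped
potentiation/depression maps with probabilities `f`/`1−f`, splitting
displaced mass linearly between the two neighbouring target bins.
Probability is conserved to 1e-12 per step (violations abort); target
positions within 1e-9 of a bin centre are snapped to it. The stationary
distribution is obtained by a direct linear solve of `(T − I)p = 0` with a
normalization row (minimal-norm least squares for degenerate chains).

Two numerical properties matter when interpreting oracle comparisons:

* The linear mass split is exact for the first moment but adds `O(h²)`
  artificial diffusion when an update spans few bins, inflating the
  stationary variance and deflating the SNR. Mean-decay comparisons are
  therefore tight at any resolution, while variance-sensitive quantities
  (small-update capacities) use finer grids (~1000 bins, update ≥ several
  bin widths).
* The exact clipped jump process is not the diffusion limit: its stationary
  law keeps ripples with period equal to the update size (wavelength-`a`
  structure is invariant under ±`a` jumps) and boundary layers of width
  `a`, and its slow eigenvalues carry `O(a)` corrections. Uniformity checks
  are made after coarse-graining over one update length; decay-curve
  comparisons are normalized to the initial perturbation, under which the
  mirror-charge series agrees with the oracle to better than 1% for
  `a ≤ 0.02` (the `t = 0` point alone carries the `O(a/2)` clip shortfall
  of the boundary-delta idealization and is compared from `t = 1`).

The same pipeline, run deterministically (stationary state → one
potentiation and one depression event → evolved mean perturbations →
`S(t) = N·signal²/Var∞` → information sum), is `capacity_discrete`, the
objective of the polynomial-rule optimizer. Its evolution stops once the
SNR is negligible; if the decay is slow the tail is added analytically from
an exponential fit to the late signal (single-mode regime). A Nelder-Mead
simplex with random restarts (default 8; bounded coefficient box |c| ≤ 1,
negative-magnitude rules rejected by penalty) searches the six coefficients
of second-order polynomial update magnitudes. No polynomial rule exceeds
the soft-bound small-update capacity; from coarse starts the optimizer can
recover a few percent of saturation and discretization loss, which is why
comparisons are made against the closed-form supremum `1/(4π ln 2)` rather
than a finite-resolution soft evaluation.

## Simulation engine

`run_online` keeps a ring buffer of the last `max(age_grid)` patterns.
After a warm-up (equilibrium initial weights plus buffer filling), each step
trains on a fresh pattern, then probes the neuron with the stored pattern at
every monitored age and with one fresh, never-reused lure, accumulating
means and variances by Welford updates. Lure statistics are pooled across
ages (a lure is new by definition). Initial weights come from the known
closed forms (uniform for balanced hard, Gaussian for soft, log-normal for
the exponentiated rule, all under dense ±1 inputs) or otherwise from
simulated relaxation over at least `20/rate` presentations, with the rate
taken from the drift derivative at the equilibrium point. The default age
grid is logarithmic with ≤ 64 points (dense grids are configurable);
per-age statistics are unbiased either way. Identical config + seed gives
bit-identical results.

Feed-forward inhibition subtracts `g Σᵢxᵢ` from the output. Two regimes
differ in a way that matters:

* `g` tracking the current mean weight (the default, equivalent to using
  zero-mean effective weights to rounding error) cancels both the
  mean-weight term *and* the mean-input term of the lure variance, and
  yields optimal capacity even for 0/1 inputs at density ½.
* `g` fixed at the equilibrium mean weight cancels only the mean-weight
  term; with 0/1 inputs at density ½ the surviving mean-input variance
  halves the capacity relative to ±1 inputs, recovering it only as the code
  becomes sparse (`f → 0`). With 0/1 inputs the plasticity is rebalanced
  (`pot × (1−f)`, `dep × f`) so the equilibrium mean weight is preserved.

What the simulations emulate — and do not. Patterns are uncorrelated and
presented exactly once each; there is no input noise, no spiking dynamics,
no post-synaptic dependence of plasticity, and synapses are continuous and
independent. Passing tests therefore validate the storage theory under its
own assumptions; they say nothing about correlated natural stimuli,
discrete-state synapses, or recurrent-network error propagation.

## Numerical choices and problem sizes

* Eigen series: 199 odd modes (hard), 100 modes (imbalanced); truncation
  tails are orders below the comparison tolerances except the `t = 0`
  perturbation sum, which converges only as `1/K` (0.2% at K = 199).
* `info_per_synapse` interpolates `ln S` linearly in age (exact for
  exponential decay) on integer ages, and extrapolates an exponential tail
  beyond the last monitored age; a tail contributing > 1% of the total
  raises an error instead of silently truncating.
* Exponential fits are log-linear least squares above a caller-supplied
  noise floor (ages with SNR below ~5 Monte-Carlo standard errors should be
  excluded); residuals are available to expose the hard rule's systematic
  lack of fit.
* The lifetime grid optimizer scores the continuous threshold-crossing time
  so the optimum is not hidden by integer-count plateaus; the user-facing
  `memory_lifetime` remains the integer count.
* Default sizes follow the convention of `N = 1000` for lifetime
  calculations and `N = 100` for information measures (the scaling in `N`
  being trivial). The test suite runs simulations of 10⁴–2×10⁵
  presentations and master-equation grids of 200–1000 bins, sizes chosen so
  Monte-Carlo error sits well inside the asserted tolerances on a desktop
  machine.

## Known limitations

* The log-normal rule's depression is signed (below the reference weight a
  depression event raises the weight): it is the exact exponentiation of
  the soft rule, and the general non-negativity of update magnitudes does
  not apply to it.
* Small-update closed forms degrade for updates comparable to the
  equilibrium spread (√c_d ≳ 0.5 triggers a warning); at matched initial
  SNR of 100 the hard rule's exact jump process realizes a lower S(0) than
  the continuum formula `12Na²` suggests, and calibrations at large updates
  should use the master-equation oracle.
* Soft-bound rules whose drift has no linear term are not implemented; the
  theory module covers them only insofar as they map onto the OU case.
* Class priors other than ½ and ROC-style analyses are out of scope; the
  empirical information estimator supports equiprobable classes only.
* The imbalanced-plasticity peak width is reported empirically; the
  conjectured scale `|β| ≲ πa` is a reconstruction, not a derived result.
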