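"""Numerical rule optimization on the discretized master equation.

The deterministic capacity pipeline (:func:`capacity_discrete`) replaces the
Monte-Carlo simulator with the exact discrete-state weight-distribution
dynamics, so a derivative-free optimizer can search update-rule parameter
space without noise.  It is used to ask whether any second-order polynomial
update rule can beat the soft-bound rule (it cannot, beyond tolerance), and
to maximize the memory lifetime over the update size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from . import theory
from .metrics import INFO_SLOPE0, info_from_snr
from .rules import PlasticityRule, make_polynomial_rule

__all__ = [
    "OptResult",
    "capacity_discrete",
    "optimize_polynomial",
    "optimize_update_for_lifetime",
]


@dataclass
class OptResult:
    best_params: dict
    best_value: float
    trace: list = field(default_factory=list)

    def __post_init__(self):
        if self.trace:
            vals = [v for _, v in self.trace]
            if abs(self.best_value - max(vals)) > 1e-12:
                raise ValueError("best_value must equal the maximum of the trace")


def capacity_discrete(
    rule: PlasticityRule,
    bins: int = 200,
    n_synapses: int = 100,
    f: float = 0.5,
    levels: str = "pm1",
    domain=None,
    max_steps: int = 200_000,
    drift_tol: float = 1e-9,
) -> float:
    """Information per synapse from the deterministic master-equation pipeline.

    Procedure: find the stationary weight distribution; apply one potentiation
    and one depression event to it; evolve both perturbed distributions,
    recording the mean-weight perturbations dmu+-(t); convert the
    probe-averaged signal to an SNR against the stationary lure variance; and
    sum the information over integer ages.  With +/-1 inputs the probe weights
    potentiated synapses by +1 (probability f) and depressed ones by -1; with
    0/1 inputs only the potentiated (high-input) synapses are probed and the
    lure variance carries the input second moment f.

    The evolution stops once the SNR is negligible; if the decay is too slow
    the remaining tail is added analytically from an exponential fit to the
    recorded signal (the late decay is single-mode exponential).
    """
    centers, t_pot, t_dep, t_all = theory.build_transition(rule, f, bins, domain)
    p_inf = theory.stationary_distribution(t_all)
    resid = float(np.abs(t_all @ p_inf - p_inf).sum())
    if resid > 1e-8:
        raise RuntimeError(f"stationary solve failed (residual {resid:.1e})")
    mu_inf = float(centers @ p_inf)
    drift = abs(float(centers @ (t_all @ p_inf)) - mu_inf)
    if drift > max(drift_tol, 1e-12 * abs(mu_inf)):
        raise RuntimeError(f"start is not stationary (residual drift {drift:.1e})")
    var_inf = float(centers**2 @ p_inf - mu_inf**2)

    if levels == "pm1":
        ex2 = 1.0 if f == 0.5 else (4 * f * (1 - f) + (2 * f - 1) ** 2)
    elif levels == "binary01":
        ex2 = f
    else:
        raise ValueError("levels must be 'pm1' or 'binary01'")

    p_plus = t_pot @ p_inf
    p_minus = t_dep @ p_inf
    sig0 = _signal(centers, p_plus, p_minus, mu_inf, f, levels)
    if sig0 <= 0:
        return 0.0
    snr_floor = 1e-12
    signals = [sig0]
    chunk = 256
    while True:
        for _ in range(chunk):
            p_plus = t_all @ p_plus
            p_minus = t_all @ p_minus
            signals.append(_signal(centers, p_plus, p_minus, mu_inf, f, levels))
        s_now = n_synapses * signals[-1] ** 2 / (var_inf * ex2)
        if s_now < snr_floor or len(signals) > max_steps:
            break

    sig = np.array(signals)
    snr = n_synapses * sig**2 / (var_inf * ex2)
    total = float(info_from_snr(snr).sum())
    if snr[-1] >= snr_floor:
        # analytic tail from the asymptotic exponential decay of the signal
        tail_fit = np.polyfit(np.arange(len(sig))[-64:], np.log(np.abs(sig[-64:])), 1)
        rate = -2.0 * tail_fit[0]  # SNR decays twice as fast as the signal
        if rate > 0:
            total += INFO_SLOPE0 * float(snr[-1]) * np.exp(-rate) / -np.expm1(-rate)
    return total / n_synapses


def _signal(centers, p_plus, p_minus, mu_inf, f, levels):
    dmu_p = float(centers @ p_plus) - mu_inf
    dmu_m = float(centers @ p_minus) - mu_inf
    if levels == "pm1":
        return f * dmu_p - (1 - f) * dmu_m
    return f * dmu_p


def optimize_polynomial(
    bins: int = 200,
    n_synapses: int = 100,
    start: Optional[Sequence[float]] = None,
    n_restarts: int = 8,
    maxiter: int = 400,
    tol: float = 1e-4,
    seed: int = 0,
    f: float = 0.5,
) -> OptResult:
    """Search second-order polynomial update rules for maximal capacity.

    The six coefficients (p0, p1, p2) for potentiation and (d0, d1, d2) for
    depression parameterize magnitudes p0 + p1 w + p2 w^2 (and likewise d) on
    [0, 1].  A Nelder-Mead simplex with random restarts maximizes
    :func:`capacity_discrete`; coefficient sets producing a negative magnitude
    anywhere in [0, 1], or outside the box |coef| <= 1, are rejected through a
    penalty.  ``start`` defaults to the soft rule's coefficients.
    """
    rng = np.random.default_rng(seed)
    if start is None:
        start = (0.01, 0.0, 0.0, 0.0, 0.02, 0.0)
    start = np.asarray(start, float)
    trace: list = []
    if _penalized(start, bins, n_synapses, f, trace) <= 0:
        raise ValueError("start coefficients yield an infeasible or degenerate rule")

    best_x, best_v = None, -np.inf
    for restart in range(n_restarts):
        x0 = start if restart == 0 else start * np.exp(rng.normal(0, 0.3, 6)) + rng.normal(0, 0.002, 6)
        res = minimize(
            lambda x: -_penalized(x, bins, n_synapses, f, trace),
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": tol, "xatol": 1e-5},
        )
        if -res.fun > best_v:
            best_v, best_x = -res.fun, res.x
    names = ("p0", "p1", "p2", "d0", "d1", "d2")
    return OptResult(
        best_params=dict(zip(names, (float(v) for v in best_x))),
        best_value=float(best_v),
        trace=trace,
    )


def _feasible(x):
    if np.any(np.abs(x) > 1.0):
        return None
    try:
        return make_polynomial_rule(x[:3], x[3:])
    except ValueError:
        return None


def _penalized(x, bins, n_synapses, f, trace):
    rule = _feasible(np.asarray(x, float))
    if rule is None:
        val = -1.0
    else:
        try:
            val = capacity_discrete(rule, bins=bins, n_synapses=n_synapses, f=f)
        except (RuntimeError, np.linalg.LinAlgError):
            val = -1.0
    trace.append((tuple(float(v) for v in x), val))
    return val


def optimize_update_for_lifetime(
    rule_family: str,
    n_synapses: int,
    theta: float,
    grid: Sequence[float],
    n_modes: int = 199,
) -> OptResult:
    """Maximize the memory lifetime over the update size along a grid.

    For the soft family the grid values are depression fractions ``c_d`` and
    the lifetime is the continuous threshold-crossing time of
    S(t) = N c_d exp(-c_d t); for the hard family they are update sizes ``a``
    with the full eigenmode series for the SNR decay.  Too small an update
    never reaches the threshold (lifetime zero); too large an update decays
    too fast.
    """
    grid = np.asarray(grid, float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid must contain positive update sizes")
    trace = []
    for u in grid:
        if rule_family == "soft":
            s0 = n_synapses * u
            life = np.log(s0 / theta) / u if s0 > theta else 0.0
        elif rule_family == "hard":
            life = theory._hard_series_lifetime(u, n_synapses, theta, n_modes)
        else:
            raise ValueError("rule_family must be 'soft' or 'hard'")
        trace.append((float(u), float(life)))
    best_u, best_v = max(trace, key=lambda kv: kv[1])
    key = "c_d" if rule_family == "soft" else "a"
    return OptResult(best_params={key: best_u}, best_value=best_v, trace=trace)
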