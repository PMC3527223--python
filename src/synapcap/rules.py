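"""Synaptic plasticity rule family.

A plasticity rule is defined by the absolute weight change it applies on a
potentiation event and on a depression event, each a function of the current
weight, plus optional hard clipping bounds.  The two prototypes are

* the *hard-bound* rule: constant updates ``+a_plus`` / ``-a_minus`` with the
  weight clipped to ``[0, 1]``, and
* the *soft-bound* rule: constant potentiation ``+c_p`` and multiplicative
  depression ``-c_d * w``, which is intrinsically bounded and needs no clip.

Variants (log-normal, power-law, general polynomial, imbalanced,
density-rebalanced) are all expressed through the same interface so that the
simulator and the Fokker-Planck machinery treat them uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

__all__ = [
    "PlasticityRule",
    "make_hard_rule",
    "make_soft_rule",
    "make_powerlaw_rule",
    "make_lognormal_rule",
    "make_polynomial_rule",
    "make_imbalanced_hard_rule",
    "sparse_balance",
    "apply_update",
    "rule_to_dict",
    "rule_from_dict",
]


@dataclass(frozen=True)
class PlasticityRule:
    """A weight-dependent update rule for a single synapse.

    Attributes
    ----------
    name:
        Family label (``"hard"``, ``"soft"``, ...).
    pot_delta, dep_delta:
        Vectorized callables mapping weight(s) to the absolute update applied
        on a potentiation / depression event.  The new weight is
        ``w + pot_delta(w)`` or ``w - dep_delta(w)``, clipped if bounds are
        set.  For most rules both deltas are non-negative everywhere in the
        domain; the log-normal rule's depression is signed (it relaxes the
        log-weight towards its reference, so it can increase a weight below
        the reference).
    w_min, w_max:
        Clipping bounds, or ``None`` for intrinsically bounded rules.
    params:
        The constructor parameters, kept for serialization and for the
        closed-form theory.
    """

    name: str
    pot_delta: Callable[[np.ndarray], np.ndarray]
    dep_delta: Callable[[np.ndarray], np.ndarray]
    w_min: Optional[float] = None
    w_max: Optional[float] = None
    params: Mapping[str, float] = field(default_factory=dict)

    @property
    def bounded(self) -> bool:
        return self.w_min is not None or self.w_max is not None

    def clip(self, w: np.ndarray) -> np.ndarray:
        if not self.bounded:
            return w
        lo = -np.inf if self.w_min is None else self.w_min
        hi = np.inf if self.w_max is None else self.w_max
        return np.clip(w, lo, hi)

    def potentiate(self, w):
        return self.clip(w + self.pot_delta(w))

    def depress(self, w):
        return self.clip(w - self.dep_delta(w))


def make_hard_rule(a_plus: float, a_minus: float) -> PlasticityRule:
    """Constant-magnitude updates with the weight clipped to [0, 1].

    Potentiation maps ``w -> min(w + a_plus, 1)``; depression maps
    ``w -> max(w - a_minus, 0)``.  With ``a_plus == a_minus`` (balanced) and
    dense random inputs the stationary weight distribution is uniform.
    """
    if a_plus <= 0 or a_minus <= 0:
        raise ValueError("hard rule requires positive update magnitudes")
    return PlasticityRule(
        name="hard",
        pot_delta=lambda w: np.full_like(np.asarray(w, float), a_plus),
        dep_delta=lambda w: np.full_like(np.asarray(w, float), a_minus),
        w_min=0.0,
        w_max=1.0,
        params={"a_plus": float(a_plus), "a_minus": float(a_minus)},
    )


def make_soft_rule(c_p: float, c_d: float) -> PlasticityRule:
    """Weight-independent potentiation, depression proportional to the weight.

    Potentiation: ``w -> w + c_p``; depression: ``w -> (1 - c_d) * w``.  No
    bounds are needed: depression can never flip the sign of a non-negative
    weight for ``0 < c_d < 1``, and the multiplicative pull-back bounds growth.
    For small updates the stationary distribution is a narrow Gaussian with
    mean ``c_p / c_d`` and variance ``c_p**2 / c_d``.
    """
    if c_p <= 0:
        raise ValueError("c_p must be positive")
    if not 0 < c_d < 1:
        raise ValueError("c_d must lie in (0, 1); c_d >= 1 could flip the sign")
    return PlasticityRule(
        name="soft",
        pot_delta=lambda w: np.full_like(np.asarray(w, float), c_p),
        dep_delta=lambda w: c_d * np.asarray(w, float),
        params={"c_p": float(c_p), "c_d": float(c_d)},
    )


def make_powerlaw_rule(a: float, mu: float) -> PlasticityRule:
    """Power-law interpolation between hard- and soft-bound behaviour.

    Potentiation magnitude ``a * (1 - w)**mu``, depression ``a * w**mu``,
    clipped to [0, 1].  ``mu = 0`` reproduces the balanced hard rule exactly;
    ``mu = 1`` is a soft rule (linear weight dependence) very similar to,
    though not identical with, :func:`make_soft_rule`.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if mu < 0:
        raise ValueError("mu must be non-negative")

    def pot(w):
        w = np.asarray(w, float)
        return a * np.clip(1.0 - w, 0.0, None) ** mu

    def dep(w):
        w = np.asarray(w, float)
        return a * np.clip(w, 0.0, None) ** mu

    return PlasticityRule(
        name="powerlaw",
        pot_delta=pot,
        dep_delta=dep,
        w_min=0.0,
        w_max=1.0,
        params={"a": float(a), "mu": float(mu)},
    )


def make_lognormal_rule(c_p: float, c_d: float, w_ref: float = 1.0) -> PlasticityRule:
    """Exponentiated soft rule: an Ornstein-Uhlenbeck process in ``ln w``.

    With ``v = ln(w / w_ref)`` the dynamics are exactly the soft rule on
    ``v``: potentiation ``v -> v + c_p`` (``w -> w * exp(c_p)``), depression
    ``v -> (1 - c_d) * v`` (``w -> w * (w / w_ref)**(-c_d)``).  For small
    updates the stationary weight distribution is log-normal with
    ``E[ln w] = c_p / c_d + ln(w_ref)`` and ``Var[ln w] = c_p**2 / c_d``.
    Weights stay strictly positive; no clipping.  The depression delta is
    signed: below ``w_ref`` depression pushes the weight up towards the
    reference, which is what keeps the log-weight mean-reverting.
    """
    if c_p <= 0:
        raise ValueError("c_p must be positive")
    if not 0 < c_d < 1:
        raise ValueError("c_d must lie in (0, 1)")
    if w_ref <= 0:
        raise ValueError("w_ref must be positive")
    gain = np.expm1(c_p)

    def pot(w):
        w = np.asarray(w, float)
        _check_positive(w)
        return w * gain

    def dep(w):
        w = np.asarray(w, float)
        _check_positive(w)
        return w - w * (w / w_ref) ** (-c_d)

    return PlasticityRule(
        name="lognormal",
        pot_delta=pot,
        dep_delta=dep,
        params={"c_p": float(c_p), "c_d": float(c_d), "w_ref": float(w_ref)},
    )


def _check_positive(w: np.ndarray) -> None:
    if np.any(np.asarray(w) <= 0):
        raise ValueError("log-normal rule is defined for strictly positive weights")


def make_polynomial_rule(
    pot_coeffs, dep_coeffs, w_min: float = 0.0, w_max: float = 1.0
) -> PlasticityRule:
    """General second-order polynomial update magnitudes on [w_min, w_max].

    ``pot_delta(w) = p0 + p1*w + p2*w**2`` and likewise for depression.  Both
    magnitudes must be non-negative over the whole domain; coefficient sets
    violating this are rejected.  The soft and hard rules are special cases:
    ``pot=(c_p,0,0), dep=(0,c_d,0)`` and ``pot=(a,0,0), dep=(a,0,0)``.
    """
    p = tuple(float(c) for c in pot_coeffs)
    d = tuple(float(c) for c in dep_coeffs)
    if len(p) != 3 or len(d) != 3:
        raise ValueError("expected three coefficients per polynomial")
    grid = np.linspace(w_min, w_max, 2001)
    for coeffs, label in ((p, "potentiation"), (d, "depression")):
        vals = coeffs[0] + coeffs[1] * grid + coeffs[2] * grid**2
        if np.any(vals < -1e-12):
            raise ValueError(f"{label} magnitude is negative inside the domain")

    def pot(w):
        w = np.asarray(w, float)
        return p[0] + p[1] * w + p[2] * w**2

    def dep(w):
        w = np.asarray(w, float)
        return d[0] + d[1] * w + d[2] * w**2

    return PlasticityRule(
        name="polynomial",
        pot_delta=pot,
        dep_delta=dep,
        w_min=float(w_min),
        w_max=float(w_max),
        params={"pot_coeffs": p, "dep_coeffs": d, "w_min": float(w_min), "w_max": float(w_max)},
    )


def make_imbalanced_hard_rule(a: float, beta: float) -> PlasticityRule:
    """Hard-bound rule with tilted event sizes.

    Potentiation magnitude ``a * (1 + beta)``, depression ``a * (1 - beta)``,
    clipped to [0, 1].  ``beta = 0`` recovers the balanced hard rule; the
    interior drift per presentation (dense +/-1 inputs) is ``a * beta``.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if abs(beta) > 1:
        raise ValueError("beta must lie in [-1, 1]")
    ap = a * (1.0 + beta)
    am = a * (1.0 - beta)
    return PlasticityRule(
        name="imbalanced_hard",
        pot_delta=lambda w: np.full_like(np.asarray(w, float), ap),
        dep_delta=lambda w: np.full_like(np.asarray(w, float), am),
        w_min=0.0,
        w_max=1.0,
        params={"a": float(a), "beta": float(beta)},
    )


def sparse_balance(rule: PlasticityRule, f: float) -> PlasticityRule:
    """Rescale a rule so potentiation and depression balance at coding density f.

    With 0/1 inputs at density ``f`` a synapse is potentiated with probability
    ``f`` and depressed with probability ``1 - f``.  Scaling the potentiation
    magnitude by ``(1 - f)`` and the depression magnitude by ``f`` keeps
    ``f * pot_delta = (1 - f) * dep_delta`` wherever the unscaled drifts
    balanced, so the equilibrium mean weight is preserved.  At ``f = 1/2`` the
    original rule is recovered up to a global factor of 1/2.
    """
    if not 0 < f < 1:
        raise ValueError("coding density f must lie in (0, 1)")
    base_pot, base_dep = rule.pot_delta, rule.dep_delta
    return PlasticityRule(
        name=f"{rule.name}_sparse",
        pot_delta=lambda w: (1.0 - f) * base_pot(w),
        dep_delta=lambda w: f * base_dep(w),
        w_min=rule.w_min,
        w_max=rule.w_max,
        params={**dict(rule.params), "f": float(f), "base_family": rule.name},
    )


def apply_update(rule: PlasticityRule, w, potentiating: bool):
    """Apply a single plasticity event and return the clipped new weight."""
    w = np.asarray(w, float)
    if rule.w_min is not None and np.any(w < rule.w_min - 1e-12):
        raise ValueError("weight below rule domain")
    if rule.w_max is not None and np.any(w > rule.w_max + 1e-12):
        raise ValueError("weight above rule domain")
    return rule.potentiate(w) if potentiating else rule.depress(w)


# --- serialization ---------------------------------------------------------

_FACTORIES = {
    "hard": make_hard_rule,
    "soft": make_soft_rule,
    "powerlaw": make_powerlaw_rule,
    "lognormal": make_lognormal_rule,
    "polynomial": make_polynomial_rule,
    "imbalanced_hard": make_imbalanced_hard_rule,
}

_SIGNATURES = {
    "hard": ("a_plus", "a_minus"),
    "soft": ("c_p", "c_d"),
    "powerlaw": ("a", "mu"),
    "lognormal": ("c_p", "c_d", "w_ref"),
    "polynomial": ("pot_coeffs", "dep_coeffs", "w_min", "w_max"),
    "imbalanced_hard": ("a", "beta"),
}


def rule_to_dict(rule: PlasticityRule) -> dict:
    """Serialize a rule as a ``{family, params}`` record (JSON/YAML-safe)."""
    params = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in rule.params.items()
    }
    if rule.name.endswith("_sparse"):
        return {"family": rule.name.removesuffix("_sparse"), "params": params, "sparse_f": params.pop("f")}
    return {"family": rule.name, "params": params}


def rule_from_dict(record: Mapping) -> PlasticityRule:
    """Reconstruct a rule from :func:`rule_to_dict` output. Lossless round-trip."""
    family = record["family"]
    if family not in _FACTORIES:
        raise ValueError(f"unknown rule family {family!r}")
    params = dict(record.get("params", {}))
    params.pop("base_family", None)
    kwargs = {k: params[k] for k in _SIGNATURES[family] if k in params}
    rule = _FACTORIES[family](**kwargs)
    if "sparse_f" in record:
        rule = sparse_balance(rule, float(record["sparse_f"]))
    return rule
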