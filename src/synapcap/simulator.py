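"""Online palimpsest learning of a single neuron.

A neuron with ``N`` plastic synapses is shown one random binary pattern per
time step.  Each presentation updates every synapse (high input potentiates,
low input depresses) and thereby gradually overwrites the traces of all
earlier patterns.  The simulator tracks, as a function of pattern age, the
mean and variance of the neuron's output to previously stored patterns and to
fresh lures; these summary statistics are everything the downstream
information and lifetime measures need.

Statistics are accumulated online (Welford) on a configurable grid of
monitored ages, using a ring buffer of the most recent patterns, so memory
use is independent of the run length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .rules import PlasticityRule
from . import theory

__all__ = [
    "InputModel",
    "SimConfig",
    "AgeStats",
    "log_age_grid",
    "generate_pattern",
    "neuron_output",
    "train_step",
    "burn_in_weights",
    "run_online",
]


@dataclass(frozen=True)
class InputModel:
    """Binary input statistics: levels ``pm1`` (+1/-1) or ``binary01`` (1/0),
    with the high level occurring at coding density ``f``."""

    levels: str = "pm1"
    density: float = 0.5

    def __post_init__(self):
        if self.levels not in ("pm1", "binary01"):
            raise ValueError("levels must be 'pm1' or 'binary01'")
        if not 0 < self.density < 1:
            raise ValueError("coding density must lie in (0, 1)")

    @property
    def mean(self) -> float:
        f = self.density
        return 2 * f - 1 if self.levels == "pm1" else f

    @property
    def var(self) -> float:
        f = self.density
        return 4 * f * (1 - f) if self.levels == "pm1" else f * (1 - f)


def log_age_grid(max_age: int, n: int = 48) -> np.ndarray:
    """Roughly log-spaced integer ages from 0 to max_age inclusive."""
    if max_age < 1:
        return np.array([0])
    pts = np.unique(np.round(np.geomspace(1, max_age, n - 1)).astype(int))
    return np.concatenate(([0], pts))


@dataclass
class SimConfig:
    n_synapses: int
    n_patterns: int
    input_model: InputModel = field(default_factory=InputModel)
    inhibition: str = "zero_mean"
    inhibitory_weight: Optional[float] = None  # None => track mean weight
    seed: int = 0
    age_grid: Optional[np.ndarray] = None
    burn_in: int = 0

    def __post_init__(self):
        if self.n_synapses < 1:
            raise ValueError("need at least one synapse")
        if self.inhibition not in ("none", "feedforward", "zero_mean"):
            raise ValueError("inhibition must be none|feedforward|zero_mean")
        if self.age_grid is None:
            self.age_grid = log_age_grid(min(self.n_patterns // 4, 1000))
        self.age_grid = np.asarray(self.age_grid, dtype=int)
        if self.age_grid[0] != 0 or np.any(np.diff(self.age_grid) <= 0):
            raise ValueError("age_grid must be sorted, unique and start at 0")
        if self.n_patterns <= self.burn_in + int(self.age_grid[-1]):
            raise ValueError("n_patterns must exceed burn_in + max(age_grid)")


@dataclass
class AgeStats:
    """Per-age output statistics for stored patterns plus pooled lure stats.

    ``var_*`` are unbiased sample variances.  Lure statistics are pooled over
    all ages: a lure is new by definition, so its output distribution does
    not depend on the age grid.
    """

    ages: np.ndarray
    n_pattern: np.ndarray
    mean_pattern: np.ndarray
    var_pattern: np.ndarray
    n_lure: int
    mean_lure: float
    var_lure: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "n_eval": self.n_pattern,
                "mean_pattern": self.mean_pattern,
                "var_pattern": self.var_pattern,
                "mean_lure": self.mean_lure,
                "var_lure": self.var_lure,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AgeStats":
        return cls(
            ages=df["age"].to_numpy(int),
            n_pattern=df["n_eval"].to_numpy(int),
            mean_pattern=df["mean_pattern"].to_numpy(float),
            var_pattern=df["var_pattern"].to_numpy(float),
            n_lure=int(df["n_eval"].iloc[0]),
            mean_lure=float(df["mean_lure"].iloc[0]),
            var_lure=float(df["var_lure"].iloc[0]),
        )


def generate_pattern(input_model: InputModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an i.i.d. binary pattern of length ``n``."""
    high = rng.random(n) < input_model.density
    if input_model.levels == "pm1":
        return np.where(high, 1.0, -1.0)
    return high.astype(float)


def neuron_output(weights, pattern, inhibition: str = "none", g: float = 0.0) -> float:
    """Weighted input sum, optionally with feed-forward inhibition.

    ``feedforward`` subtracts ``g`` times the unweighted input sum (an
    inhibitory partner neuron seeing the same pattern); ``zero_mean`` uses
    effective weights ``w - mean(w)``, which is algebraically the same as
    feed-forward inhibition with ``g`` tracking the mean weight.
    """
    weights = np.asarray(weights, float)
    pattern = np.asarray(pattern, float)
    if weights.shape != pattern.shape:
        raise ValueError("weights and pattern must have the same length")
    if inhibition == "none":
        return float(pattern @ weights)
    if inhibition == "feedforward":
        return float(pattern @ weights - g * pattern.sum())
    if inhibition == "zero_mean":
        return float(pattern @ (weights - weights.mean()))
    raise ValueError(f"unknown inhibition mode {inhibition!r}")


def train_step(weights, pattern, rule: PlasticityRule) -> np.ndarray:
    """One presentation: potentiate high-input synapses, depress the rest."""
    weights = np.asarray(weights, float)
    high = np.asarray(pattern) > 0
    return np.where(high, rule.potentiate(weights), rule.depress(weights))


def burn_in_weights(
    cfg: SimConfig, rule: PlasticityRule, rng: np.random.Generator
) -> np.ndarray:
    """Draw initial weights from (an approximation of) the stationary law.

    Closed forms are used where known -- uniform for the balanced hard rule,
    Gaussian for the soft rule, log-normal for the exponentiated soft rule --
    all under dense +/-1 inputs.  Otherwise the equilibrium is reached by
    simulating at least ``20 / relaxation-rate`` random presentations.
    """
    n = cfg.n_synapses
    f = cfg.input_model.density
    p = dict(rule.params)
    dense = cfg.input_model.levels == "pm1" and f == 0.5
    if dense and rule.name == "hard" and p["a_plus"] == p["a_minus"]:
        return rng.uniform(0.0, 1.0, n)
    if dense and rule.name == "soft":
        w = rng.normal(p["c_p"] / p["c_d"], np.sqrt(p["c_p"] ** 2 / p["c_d"]), n)
        return np.clip(w, 0.0, None)
    if dense and rule.name == "lognormal":
        mu = p["c_p"] / p["c_d"] + np.log(p["w_ref"])
        return np.exp(rng.normal(mu, np.sqrt(p["c_p"] ** 2 / p["c_d"]), n))
    # generic route: relax by simulation from the drift zero (or mid-domain)
    pot_prob = f  # high input potentiates
    dd = theory.drift_diffusion(rule, pot_prob)
    w0, rate = theory.equilibrium_point(dd)
    steps = int(max(10_000, np.ceil(20.0 / max(rate, 1e-6))))
    w = np.full(n, w0)
    for _ in range(steps):
        x = generate_pattern(cfg.input_model, n, rng)
        w = train_step(w, x, rule)
    return w


def run_online(cfg: SimConfig, rule: PlasticityRule):
    """Present ``cfg.n_patterns`` patterns online and collect output statistics.

    After an initial warm-up (burn-in plus filling the pattern ring buffer)
    each step trains on a fresh pattern and then probes the neuron with the
    stored pattern at every monitored age and with one fresh lure, updating
    running means and variances.  Returns ``(AgeStats, final_weights)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_synapses
    ages = cfg.age_grid
    max_age = int(ages[-1])
    n_ages = len(ages)
    im = cfg.input_model

    w = np.asarray(burn_in_weights(cfg, rule, rng), float)

    buf = np.zeros((max_age + 1, n))
    count = 0
    mean_p = np.zeros(n_ages)
    m2_p = np.zeros(n_ages)
    mean_l = 0.0
    m2_l = 0.0
    warmup = cfg.burn_in + max_age
    density = im.density
    pm1 = im.levels == "pm1"
    mode = cfg.inhibition
    g_fixed = cfg.inhibitory_weight

    for t in range(cfg.n_patterns):
        high = rng.random(n) < density
        x = np.where(high, 1.0, -1.0) if pm1 else high.astype(float)
        w = np.where(high, rule.potentiate(w), rule.depress(w))
        buf[t % (max_age + 1)] = x

        if t < warmup:
            continue

        if mode == "zero_mean":
            weff = w - w.mean()
            rows = buf[(t - ages) % (max_age + 1)]
            y = rows @ weff
            lure_high = rng.random(n) < density
            lure = np.where(lure_high, 1.0, -1.0) if pm1 else lure_high.astype(float)
            y_l = lure @ weff
        else:
            g = (w.mean() if g_fixed is None else g_fixed) if mode == "feedforward" else 0.0
            rows = buf[(t - ages) % (max_age + 1)]
            y = rows @ w
            lure_high = rng.random(n) < density
            lure = np.where(lure_high, 1.0, -1.0) if pm1 else lure_high.astype(float)
            y_l = lure @ w
            if mode == "feedforward":
                y -= g * rows.sum(axis=1)
                y_l -= g * lure.sum()

        count += 1
        d = y - mean_p
        mean_p += d / count
        m2_p += d * (y - mean_p)
        d_l = y_l - mean_l
        mean_l += d_l / count
        m2_l += d_l * (y_l - mean_l)

    if count < 2:
        raise ValueError("not enough evaluations; increase n_patterns")
    return (
        AgeStats(
            ages=ages.copy(),
            n_pattern=np.full(n_ages, count),
            mean_pattern=mean_p,
            var_pattern=m2_p / (count - 1),
            n_lure=count,
            mean_lure=mean_l,
            var_lure=m2_l / (count - 1),
        ),
        w,
    )
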