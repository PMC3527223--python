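"""Performance measures: SNR, recognition information, memory lifetime.

The recognition task is a binary discrimination between the neuron's output
to a previously learned pattern and to a lure.  Both output distributions are
close to Gaussian (the neuron sums many inputs), so the separation is
summarized by a signal-to-noise ratio

    S = (mu1 - mu0)^2 / ((var1 + var0) / 2)

and the mutual information between the thresholded output and the class label
follows as I(S) = 1 - H_b(Phi(-sqrt(S)/2)) bits, with Phi the standard normal
CDF and H_b the binary entropy.  Summing I over all stored pattern ages and
dividing by the synapse count gives the information per synapse; counting the
ages whose SNR exceeds a threshold gives the memory lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr, ndtri

__all__ = [
    "SNRCurve",
    "CapacityResult",
    "INFO_SLOPE0",
    "snr",
    "snr_curve_from_stats",
    "error_rate",
    "snr_for_error_rate",
    "info_from_snr",
    "info_empirical",
    "info_per_synapse",
    "memory_lifetime",
    "fit_exponential",
    "capacity_fraction",
]

#: Small-SNR slope of the information curve, dI/dS at S=0, in bits:
#: 1 / (4 pi ln 2).  This is also the information capacity per synapse of the
#: soft-bound rule in the small-update limit.
INFO_SLOPE0 = 1.0 / (4.0 * np.pi * np.log(2.0))


@dataclass
class SNRCurve:
    """SNR sampled on a sorted grid of pattern ages."""

    ages: np.ndarray
    snr: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.snr = np.asarray(self.snr, float)
        if self.ages.shape != self.snr.shape:
            raise ValueError("ages and snr must have the same length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.snr < 0):
            raise ValueError("snr values must be non-negative")


@dataclass
class CapacityResult:
    info_per_synapse: float
    lifetime: float
    fitted_S0: float
    fitted_tau: float

    def to_dict(self) -> dict:
        return {
            "info_per_synapse": self.info_per_synapse,
            "lifetime": self.lifetime,
            "fitted_S0": self.fitted_S0,
            "fitted_tau": self.fitted_tau,
        }


def snr(mu1, var1, mu0, var0):
    """Signal-to-noise ratio between pattern and lure output distributions."""
    mu1, var1 = np.asarray(mu1, float), np.asarray(var1, float)
    mu0, var0 = np.asarray(mu0, float), np.asarray(var0, float)
    if np.any(var1 < 0) or np.any(var0 < 0):
        raise ValueError("variances must be non-negative")
    denom = 0.5 * (var1 + var0)
    if np.any(denom <= 0):
        raise ValueError("at least one variance must be positive")
    return (mu1 - mu0) ** 2 / denom


def snr_curve_from_stats(stats) -> SNRCurve:
    """Build the per-age SNR curve from simulator :class:`AgeStats`."""
    s = snr(stats.mean_pattern, stats.var_pattern, stats.mean_lure, stats.var_lure)
    return SNRCurve(ages=np.asarray(stats.ages), snr=np.atleast_1d(s))


def error_rate(S):
    """Misclassification probability at the optimal (midpoint) threshold.

    For two equal-variance Gaussians separated by SNR ``S`` the threshold
    halfway between the means misclassifies either class with probability
    ``Phi(-sqrt(S)/2)``.
    """
    S = np.asarray(S, float)
    if np.any(S < 0):
        raise ValueError("SNR must be non-negative")
    return ndtr(-np.sqrt(S) / 2.0)


def snr_for_error_rate(eps: float) -> float:
    """Inverse of :func:`error_rate`: the SNR yielding error probability eps."""
    if not 0 < eps < 0.5:
        raise ValueError("error rate must lie in (0, 0.5)")
    return float((2.0 * ndtri(eps)) ** 2)


def _binary_entropy(p):
    p = np.asarray(p, float)
    out = np.zeros_like(p)
    inner = (p > 0) & (p < 1)
    q = p[inner]
    out[inner] = -(q * np.log2(q) + (1 - q) * np.log2(1 - q))
    return out


def info_from_snr(S):
    """Mutual information (bits) of the recognition task at SNR ``S``.

    Monotone, concave, I(0) = 0, I(inf) = 1 bit; for small S it is linear
    with slope :data:`INFO_SLOPE0`.
    """
    scalar = np.isscalar(S)
    eps = error_rate(np.atleast_1d(S))
    out = 1.0 - _binary_entropy(eps)
    return float(out[0]) if scalar else out


def info_empirical(pattern_outputs, lure_outputs, threshold: float) -> float:
    """Plug-in mutual information from raw outputs, no Gaussian assumption.

    Classes are equiprobable; the response is the output thresholded at
    ``threshold``.  Computed from the empirical hit and false-alarm rates.
    """
    pat = np.asarray(pattern_outputs, float)
    lur = np.asarray(lure_outputs, float)
    if pat.size == 0 or lur.size == 0:
        raise ValueError("both sample sets must be non-empty")
    hit = np.mean(pat > threshold)
    fa = np.mean(lur > threshold)
    marg = 0.5 * (hit + fa)
    i = _binary_entropy(np.array([marg]))[0] - 0.5 * (
        _binary_entropy(np.array([hit]))[0] + _binary_entropy(np.array([fa]))[0]
    )
    return float(max(i, 0.0))


def _interp_log_snr(curve: SNRCurve):
    """Interpolate ln S linearly in age on the integer ages 0..last.

    Exact for exponential decay.  Ages where the curve is zero contribute
    S = 0.  Returns (integer ages, S values).
    """
    ages = np.asarray(curve.ages, float)
    t = np.arange(0, int(round(ages[-1])) + 1)
    pos = curve.snr > 0
    if pos.sum() == 0:
        return t, np.zeros_like(t, dtype=float)
    logs = np.interp(t, ages[pos], np.log(curve.snr[pos]))
    s = np.exp(logs)
    # zero out integer ages flanked by zero-valued grid points
    if not pos.all():
        zero_ages = ages[~pos]
        for za in zero_ages:
            s[np.abs(t - za) < 0.5] = 0.0
    return t, s


def _tail_exponential(curve: SNRCurve, n_fit: int = 8):
    """Fit an exponential to the last decaying stretch for tail extrapolation."""
    pos = curve.snr > 0
    if pos.sum() < 3:
        return None
    ages = np.asarray(curve.ages, float)[pos][-n_fit:]
    vals = curve.snr[pos][-n_fit:]
    if len(ages) < 3:
        return None
    slope, intercept = np.polyfit(ages, np.log(vals), 1)
    if slope >= 0:
        return None
    return float(np.exp(intercept)), float(-1.0 / slope)


def info_per_synapse(curve: SNRCurve, n_synapses: int, tail_tol: float = 0.01) -> float:
    """Total stored information per synapse, in bits.

    Sums I(S(t)) over integer pattern ages, interpolating the SNR on the
    monitored grid and extrapolating an exponential tail beyond the last
    monitored age.  If the extrapolated tail would contribute more than
    ``tail_tol`` of the total, the curve is considered truncated and an
    error is raised.
    """
    t, s = _interp_log_snr(curve)
    total = float(info_from_snr(s).sum())
    if total == 0.0:
        return 0.0
    tail = _tail_exponential(curve)
    tail_sum = 0.0
    if tail is not None:
        s0, tau = tail
        t_last = float(curve.ages[-1])
        s_next = s0 * np.exp(-(t_last + 1) / tau)
        # sum the extrapolated exponential until negligible
        n_terms = int(min(np.ceil(tau * np.log(max(s_next, 1e-300) / 1e-13)), 2e6))
        if n_terms > 0 and s_next > 1e-13:
            ts = np.arange(n_terms)
            tail_sum = float(info_from_snr(s_next * np.exp(-ts / tau)).sum())
    if tail_sum > tail_tol * (total + tail_sum):
        raise ValueError(
            "SNR curve is truncated: extrapolated tail contributes "
            f"{100 * tail_sum / (total + tail_sum):.1f}% of the information; "
            "extend the age grid"
        )
    return (total + tail_sum) / n_synapses


def memory_lifetime(curve: SNRCurve, theta: float) -> int:
    """Number of pattern ages stored with SNR at or above ``theta``."""
    if theta <= 0:
        raise ValueError("threshold must be positive")
    t, s = _interp_log_snr(curve)
    return int(np.count_nonzero(s >= theta))


def fit_exponential(curve: SNRCurve, floor: float = 0.0, full: bool = False):
    """Log-linear least-squares fit S(t) ~ S0 * exp(-t / tau).

    Ages with SNR at or below ``floor`` (e.g. below the Monte-Carlo noise
    level) are excluded.  With ``full=True`` the residuals of ln S are also
    returned so systematic lack of fit (non-exponential decay) can be
    inspected.
    """
    mask = curve.snr > max(floor, 0.0)
    if mask.sum() < 3:
        raise ValueError("need at least three ages above the noise floor")
    ages = np.asarray(curve.ages, float)[mask]
    logs = np.log(curve.snr[mask])
    slope, intercept = np.polyfit(ages, logs, 1)
    if slope >= 0:
        raise ValueError("curve does not decay; cannot fit an exponential")
    s0, tau = float(np.exp(intercept)), float(-1.0 / slope)
    if full:
        resid = logs - (intercept + slope * ages)
        return s0, tau, resid
    return s0, tau


def capacity_fraction(S0: float) -> float:
    """Fraction of the small-update information capacity achieved at initial
    SNR ``S0``, for exponential SNR decay at fixed area under the curve.

    f(S0) = [integral_0^S0 I(s)/s ds] / (S0 * I'(0)); decreases from 1 at
    S0 -> 0 because the information saturates at high SNR.
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")

    def integrand(s):
        return info_from_snr(s) / s if s > 0 else INFO_SLOPE0

    val, _ = quad(integrand, 0.0, S0, limit=200)
    return float(val / (S0 * INFO_SLOPE0))
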