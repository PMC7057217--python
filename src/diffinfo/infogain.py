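"""Per-reflection information gain (KL divergence) for intensity data.

The information gained by measuring one normalized intensity is the
Kullback-Leibler divergence of the posterior distribution of the true
intensity from its Wilson prior.  Via Bayes' theorem this is evaluated as the
posterior-weighted average of ``log[p(Z_O | Z) / p(Z_O)]``, which is better
conditioned than the direct posterior/prior ratio.

Acentric reflections admit a closed form: the posterior is a normal
distribution with location ``Z_O - sigma_z**2`` and scale ``sigma_z``
truncated to ``Z >= 0``, so the KL divergence reduces to truncated-normal
moments and the log observed density, all expressible with erfc/erfcx.  The
erfcx branch is taken where the erfc form would suffer 0/0 underflow.

Centric reflections are integrated numerically over the amplitude
``E = Z**0.5`` (the change of variable removes the prior's singularity at
zero), with the observed density supplied by the scaled parabolic cylinder
closed form.  A direct quadrature oracle over ``Z`` using only numerically
convolved densities is shipped for verification of both paths.

Units: nats for the natural logarithm; bits are nats / ln 2.  Bits are the
default reporting unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy import special as sps

from .distributions import (
    NormalizedObservation,
    log_obs_density,
    obs_density_numeric,
    wilson_prior_e,
    wilson_prior_z,
)

__all__ = [
    "InfoResult",
    "info_gain",
    "info_gain_acentric",
    "info_gain_centric",
    "info_gain_numeric",
    "expected_info_gain",
    "sigma_for_info",
    "sigma_for_expected_info",
]

LN2 = math.log(2.0)
_SQRT2 = math.sqrt(2.0)
_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class InfoResult:
    """Information gain of one measurement, carried in both units."""

    nats: float

    @property
    def bits(self) -> float:
        return self.nats / LN2


def _check_sigma(sigma_z: float) -> float:
    sigma_z = float(sigma_z)
    if not (sigma_z > 0.0) or not math.isfinite(sigma_z):
        raise ValueError(f"sigma_z must be positive and finite, got {sigma_z!r}")
    return sigma_z


def info_gain_acentric_nats(z_obs, sigma_z):
    """Vectorized acentric KL divergence in nats (closed form).

    The posterior is a truncated normal on [0, inf) with location
    ``mu = Z_O - sigma**2`` and scale ``sigma``; writing its hazard
    ``lam = phi(alpha) / (1 - Phi(alpha))`` at ``alpha = -mu/sigma``, the KL
    divergence is

        -0.5*log(2*pi*sigma^2) - (var + (mean - Z_O)^2) / (2*sigma^2) - log p(Z_O)

    with the truncated-normal mean/variance and the closed-form observed
    density.  Both ``lam`` and ``log p(Z_O)`` switch between erfc and erfcx
    forms at X = alpha/sqrt(2) = 0 for stability.
    """
    z = np.asarray(z_obs, dtype=float)
    s = np.asarray(sigma_z, dtype=float)
    z, s = np.broadcast_arrays(z, s)
    x = (s * s - z) / (s * _SQRT2)
    pos = x >= 0.0
    xp = np.where(pos, x, 0.0)
    xn = np.where(pos, 0.0, x)
    with np.errstate(over="ignore", under="ignore"):
        lam = np.where(
            pos,
            np.sqrt(2.0 / np.pi) / sps.erfcx(xp),
            np.sqrt(2.0 / np.pi) * np.exp(-xn * xn) / sps.erfc(xn),
        )
        log_erfc_term = np.where(pos, np.log(sps.erfcx(xp)), np.log(sps.erfc(xn)) + xn * xn)
    alpha = _SQRT2 * x
    mean = z - s * s + s * lam
    var = s * s * (1.0 + alpha * lam - lam * lam)
    log_p = np.log(0.5) + log_erfc_term - z * z / (2.0 * s * s)
    nats = -0.5 * np.log(2.0 * np.pi * s * s) - (var + (mean - z) ** 2) / (2.0 * s * s) - log_p
    # ultra-weak limit: the closed form cancels ~s^2-scale terms, so beyond
    # s ~ 100 the roundoff exceeds the true O(s^-4) value; switch to the
    # exponential-tilt expansion D_KL ~ Var_prior[(2 Z_O z - z^2)/(2 s^2)]/2
    weak = s > 100.0 * (1.0 + np.abs(z) / 4.0)
    if np.any(weak):
        tilt = (4.0 * z * z - 16.0 * z + 20.0) / (8.0 * s**4)
        nats = np.where(weak, tilt, nats)
    return np.maximum(nats, 0.0)


def info_gain_acentric(z_obs: float, sigma_z: float) -> InfoResult:
    """Analytic information gain of one acentric intensity observation."""
    sigma_z = _check_sigma(sigma_z)
    return InfoResult(float(info_gain_acentric_nats(float(z_obs), sigma_z)))


def _upper_e(z_obs: float, sigma_z: float) -> float:
    return max(6.0, math.sqrt(max(z_obs, 0.0) + 10.0 * sigma_z) + 6.0)


def _quad_points_e(z_obs: float, sigma_z: float, upper: float):
    # breakpoints around the (possibly very narrow) likelihood peak at
    # E = sqrt(Z_O), so adaptive quadrature cannot step over it
    pts = sorted({math.sqrt(max(z_obs + k * sigma_z, 0.0)) for k in (-8.0, -3.0, 0.0, 3.0, 8.0)})
    pts = [p for p in pts if 0.0 < p < upper]
    return pts or None


def info_gain_centric_nats(z_obs: float, sigma_z: float) -> float:
    """Centric KL divergence in nats by adaptive quadrature over E."""
    z_o, s = float(z_obs), float(sigma_z)
    obs = NormalizedObservation(z_o, s, centric=True)
    log_p = log_obs_density(obs)
    upper = _upper_e(z_o, s)
    pts = _quad_points_e(z_o, s, upper)

    def joint(e):
        log_like = -0.5 * ((z_o - e * e) / s) ** 2 - math.log(s * _SQRT_2PI)
        return wilson_prior_e(e, centric=True) * math.exp(log_like), log_like

    def f_norm(e):
        return joint(e)[0]

    def f_kl(e):
        w, log_like = joint(e)
        return 0.0 if w == 0.0 else w * (log_like - log_p)

    # relative tolerance: the unnormalized posterior mass can be far below
    # any fixed absolute scale for improbable observations
    kw = dict(epsabs=1e-280, epsrel=1e-10, limit=400, points=pts)
    norm, norm_err = integrate.quad(f_norm, 0.0, upper, **kw)
    if not (norm > 0.0) or not math.isfinite(norm):
        raise ArithmeticError(
            f"centric information quadrature failed to converge (norm={norm!r}, "
            f"err={norm_err!r}) at z_obs={z_o}, sigma_z={s}"
        )
    val, _ = integrate.quad(f_kl, 0.0, upper, **kw)
    return max(val / norm, 0.0)


def info_gain_centric(z_obs: float, sigma_z: float) -> InfoResult:
    """Information gain of one centric intensity observation (numeric)."""
    sigma_z = _check_sigma(sigma_z)
    return InfoResult(info_gain_centric_nats(z_obs, sigma_z))


def info_gain(z_obs: float, sigma_z: float, centric: bool = False) -> InfoResult:
    """Information gain of one observation, dispatching on centricity."""
    if centric:
        return info_gain_centric(z_obs, sigma_z)
    return info_gain_acentric(z_obs, sigma_z)


def info_gain_numeric(obs: NormalizedObservation, cutoff_scale: float = 1.0) -> InfoResult:
    """Reference implementation: direct quadrature of the KL integral over Z.

    Uses only numerically convolved densities (no closed forms), so it is an
    independent oracle for both analytic paths.  ``cutoff_scale`` multiplies
    the integration cutoff; the result should be invariant to doubling it.
    """
    z_o, s = obs.z_obs, _check_sigma(obs.sigma_z)
    p_obs = obs_density_numeric(obs)
    if not (p_obs > 0.0):
        raise ArithmeticError(
            f"observed-intensity density underflows at z_obs={z_o}, sigma_z={s}; "
            "the KL quadrature is not representable in double precision there"
        )
    # the posterior is confined jointly by the Gaussian (z_o +- 12 s) and the
    # prior tail (exp(-z) or exp(-z/2)), whichever cuts off first
    prior_reach = 90.0 if obs.centric else 50.0
    upper = (max(z_o, 0.0) + min(12.0 * s + 20.0, prior_reach)) * cutoff_scale
    norm = 1.0 / (s * _SQRT_2PI)

    def f(z):
        like = norm * math.exp(-0.5 * ((z_o - z) / s) ** 2)
        w = wilson_prior_z(z, obs.centric) * like / p_obs
        return 0.0 if w == 0.0 else w * math.log(like / p_obs)

    pts = sorted({max(z_o + k * s, 0.0) for k in (-8.0, -3.0, 0.0, 3.0, 8.0)})
    pieces = [(0.0, min(1.0, upper)), (min(1.0, upper), upper)] if obs.centric else [(0.0, upper)]
    total = 0.0
    for lo, hi in pieces:
        if hi > lo:
            inner = [p for p in pts if lo < p < hi] or None
            val, _ = integrate.quad(f, lo, hi, epsabs=1e-12, limit=400, points=inner)
            total += val
    return InfoResult(max(total, 0.0))


def expected_info_gain(sigma_z: float, centric: bool = False) -> InfoResult:
    """Expected information gain at fixed ``sigma_z``, before observing.

    Averages the per-observation KL divergence over the distribution of
    observed normalized intensities at that standard deviation.  The average
    runs over non-negative observed intensities (the convention under which
    the published expected-information thresholds and the I/sigma
    correspondences were tabulated): sub-zero net intensities contribute
    zero to the average, without renormalization.  Monotone decreasing in
    ``sigma_z``.
    """
    s = _check_sigma(sigma_z)
    if s > 1e3:
        # below ~4e-7 bits the KL integrand sits at cancellation noise;
        # the expected gain scales as 1/sigma^2 in this regime
        ref = expected_info_gain(1e3, centric).nats
        return InfoResult(ref * (1e3 / s) ** 2)
    if centric:
        def f(z_o):
            obs = NormalizedObservation(z_o, s, centric=True)
            return math.exp(log_obs_density(obs)) * info_gain_centric_nats(z_o, s)
    else:
        def f(z_o):
            obs = NormalizedObservation(z_o, s, centric=False)
            return math.exp(log_obs_density(obs)) * float(info_gain_acentric_nats(z_o, s))

    # integrate in u = Z_O / sigma so the density varies on a unit scale for
    # any sigma; the prior tail adds the 40/s term to the cutoff
    upper_u = 12.0 + 40.0 / s
    val = 0.0
    edges = sorted({0.0, 1.0, 4.0, 8.0, min(12.0, upper_u), upper_u})
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            piece, _ = integrate.quad(lambda u: s * f(s * u), lo, hi,
                                      epsabs=1e-11, limit=500)
            val += piece
    return InfoResult(max(val, 0.0))


def _invert_monotone(fun, target: float, rel_tol: float = 1e-6,
                     lo: float = 1e-4, hi: float = 1e4) -> float:
    """Solve fun(sigma) = target for sigma, fun monotone decreasing."""
    if not (target > 0.0):
        raise ValueError("target information must be positive")
    log_lo, log_hi = math.log(lo), math.log(hi)
    f = lambda ls: fun(math.exp(ls)) - target
    f_lo, f_hi = f(log_lo), f(log_hi)
    if f_lo * f_hi > 0.0:
        raise ValueError(
            f"target of {target:g} bits is not bracketed by sigma_z in "
            f"[{math.exp(log_lo):g}, {math.exp(log_hi):g}]"
        )
    root = optimize.brentq(f, log_lo, log_hi, xtol=rel_tol * 0.1, rtol=8.9e-16)
    return math.exp(root)


def sigma_for_info(z_obs: float, target_bits: float, centric: bool = False) -> float:
    """The sigma_z at which one observation of ``z_obs`` conveys ``target_bits``."""
    return _invert_monotone(lambda s: info_gain(z_obs, s, centric).bits, target_bits)


def sigma_for_expected_info(target_bits: float, centric: bool = False) -> float:
    """The sigma_z at which the expected information gain equals ``target_bits``.

    This is the inversion behind expected-information thresholding: a bits
    threshold maps to a single normalized standard deviation.
    """
    # beyond sigma_z ~ 1e3 the expected gain is below 1e-7 bits and the
    # KL integrand is at the level of floating-point cancellation noise
    return _invert_monotone(lambda s: expected_info_gain(s, centric).bits,
                            target_bits, lo=1e-3, hi=1e3)
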