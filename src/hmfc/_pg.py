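"""Pólya-gamma random variate generation.

The Bernoulli likelihood ``y ~ Bern(sigmoid(psi))`` becomes conditionally
Gaussian in ``psi`` after augmenting each trial with ``omega ~ PG(1, psi)``.
Only the shape-1 case is needed here (one Bernoulli observation per trial),
so we implement the exact alternating-series rejection sampler of Devroye
for the Jacobi-type density J*(1, z), using the identity

    PG(1, c)  =  J*(1, c/2) / 4.

The sampler mixes a truncated inverse-Gaussian proposal on (0, t] with a
truncated exponential on (t, inf), t = 0.64, and accepts by evaluating the
partial sums of the alternating series expansion of the density. Expected
number of proposals is < 1.1 uniformly in c.

A truncated sum-of-gammas generator (the defining infinite series of the
PG law cut at a finite number of terms) is kept as a cross-check and as a
fallback; it is approximate, with a small negative bias that shrinks like
1/n_terms.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg", "sample_pg1", "sample_pg1_gamma_sum"]

_TRUNC = 0.64
_HALF_PI2 = math.pi * math.pi / 8.0


@njit(cache=True)
def _log_ndtr(x):
    """log of the standard normal CDF, stable far into the left tail."""
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    # asymptotic expansion: Phi(x) ~ phi(x)/|x| * (1 - 1/x^2 + 3/x^4)
    x2 = x * x
    return (
        -0.5 * x2
        - 0.5 * math.log(2.0 * math.pi)
        - math.log(-x)
        + math.log1p(-1.0 / x2 + 3.0 / (x2 * x2))
    )


@njit(cache=True)
def _mass_right(z):
    """P(proposal taken from the exponential region (t, inf)) for J*(1,z)."""
    fz = _HALF_PI2 + 0.5 * z * z
    t = _TRUNC
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_ndtr(b)
    xa = x0 + z + _log_ndtr(a)
    # log(q/p) with q the inverse-Gaussian mass, p the exponential mass
    m = max(xb, xa)
    log_qdivp = math.log(4.0 / math.pi) + m + math.log(
        math.exp(xb - m) + math.exp(xa - m)
    )
    # p/(p+q) = sigmoid(-log(q/p))
    if log_qdivp > 35.0:
        return math.exp(-log_qdivp)
    return 1.0 / (1.0 + math.exp(log_qdivp))


@njit(cache=True)
def _a_coef(n, x):
    """n-th term of the alternating series for the J*(1, z) density."""
    npt = n + 0.5
    if x > _TRUNC:
        return math.pi * npt * math.exp(-0.5 * npt * npt * math.pi * math.pi * x)
    return (
        math.pi
        * npt
        * math.pow(2.0 / (math.pi * x), 1.5)
        * math.exp(-2.0 * npt * npt / x)
    )


@njit(cache=True)
def _rtigauss(z, gen):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    t = _TRUNC
    if z < 1.0 / t:
        # mu > t: rejection from the truncated Levy density with exp tilt
        while True:
            while True:
                e1 = gen.exponential(1.0)
                e2 = gen.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if gen.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = gen.standard_normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
                4.0 * mu * y + mu * mu * y * y
            )
            if gen.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _pg1_draw(c, gen):
    """One exact draw from PG(1, c)."""
    z = 0.5 * abs(c)
    fz = _HALF_PI2 + 0.5 * z * z
    p_right = _mass_right(z)
    while True:
        if gen.random() < p_right:
            x = _TRUNC + gen.exponential(1.0) / fz
        else:
            x = _rtigauss(z, gen)
        # squeeze by partial sums of the alternating series
        s = _a_coef(0, x)
        y = gen.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def sample_pg1(c, gen):
    """Vector of exact PG(1, c_j) draws, one per element of ``c``."""
    out = np.empty(c.shape[0])
    for j in range(c.shape[0]):
        out[j] = _pg1_draw(c[j], gen)
    return out


def sample_pg(b, c, rng):
    """One draw from PG(b, c) for positive integer shape ``b``.

    PG(b, c) is the b-fold convolution of PG(1, c); only small integer
    shapes are supported (the sampler itself needs just b = 1).
    """
    if not np.isfinite(b) or b <= 0:
        raise ValueError(f"PG shape parameter must be positive, got {b}")
    if b != int(b):
        raise NotImplementedError("PG(b, c) with non-integer b is not supported")
    if not np.isfinite(c):
        raise ValueError("PG tilt parameter must be finite")
    total = 0.0
    for _ in range(int(b)):
        total += _pg1_draw(float(c), rng)
    return total


def sample_pg1_gamma_sum(c, rng, n_terms=200):
    """Approximate PG(1, c) draws from the truncated sum-of-gammas series.

    omega = (1/2 pi^2) * sum_k g_k / ((k - 1/2)^2 + c^2 / (4 pi^2)),
    g_k ~ Exp(1).  Used as an independent cross-check of the exact sampler.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    k = np.arange(1, n_terms + 1)
    denom = (k - 0.5) ** 2 + (c[:, None] / (2.0 * math.pi)) ** 2
    g = rng.standard_exponential(size=(c.shape[0], n_terms))
    return (g / denom).sum(axis=1) / (2.0 * math.pi**2)
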