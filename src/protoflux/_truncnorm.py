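"""Numerically hardened univariate truncated-Gaussian moments and sampling.

Expectation propagation repeatedly needs the mean and variance of
``N(m, s^2)`` restricted to ``[lo, hi]`` under truncations that can sit a
dozen standard deviations into a tail; the naive phi/Phi ratios underflow
there.  Tail cases are therefore rewritten through the scaled complementary
error function ``erfcx``, and near-flat cavities (``s`` much wider than the
box) fall back to the exact uniform limit.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfcx, ndtr, ndtri

_C = 1.0 / np.sqrt(2.0 * np.pi)
_SQRT2 = np.sqrt(2.0)


def _tail_ratios(a, b):
    """R1 = (phi(a)-phi(b))/Z and R2 = (a phi(a)-b phi(b))/Z for 0 <= a < b.

    Works entirely in erfcx-scaled space so that a, b >> 1 is safe;
    ``b`` may be +inf.
    """
    ea = erfcx(a / _SQRT2)
    with np.errstate(over="ignore", invalid="ignore"):
        delta = np.exp((a * a - b * b) / 2.0)  # <= 1
    finite_b = np.isfinite(b)
    eb = np.where(finite_b, erfcx(np.where(finite_b, b, 0.0) / _SQRT2), 0.0)
    delta = np.where(finite_b, delta, 0.0)
    denom = ea - eb * delta
    r1 = 2.0 * _C * (1.0 - delta) / denom
    r2 = 2.0 * _C * (a - b * delta) / denom
    # b -> inf: the b-terms vanish
    r2 = np.where(finite_b, r2, 2.0 * _C * a / denom)
    return r1, r2


def _central_ratios(a, b):
    z = ndtr(b) - ndtr(a)
    pa = _C * np.exp(-0.5 * a * a)
    pb = np.where(np.isfinite(b), _C * np.exp(-0.5 * np.minimum(b, 38.0) ** 2), 0.0)
    apa = a * pa
    bpb = np.where(np.isfinite(b), b * pb, 0.0)
    return (pa - pb) / z, (apa - bpb) / z


def truncnorm_moments(m, s, lo, hi):
    """Mean and variance of N(m, s^2) truncated to [lo, hi], vectorized.

    Handles degenerate widths (returns the point mass), near-flat cavities
    (uniform limit) and deep-tail truncations.  All inputs broadcast.
    """
    m, s, lo, hi = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (m, s, lo, hi)))
    mean = np.empty(m.shape)
    var = np.empty(m.shape)

    width = hi - lo
    point = width <= 0
    flat = (~point) & (width / np.where(s > 0, s, np.inf) < 1e-6)
    rest = ~(point | flat)

    mean[point] = lo[point]
    var[point] = 0.0
    mean[flat] = 0.5 * (lo[flat] + hi[flat])
    var[flat] = width[flat] ** 2 / 12.0

    if np.any(rest):
        mr, sr, lor, hir = m[rest], s[rest], lo[rest], hi[rest]
        a = (lor - mr) / sr
        b = (hir - mr) / sr
        r1 = np.empty(a.shape)
        r2 = np.empty(a.shape)

        right = a >= 0
        left = b <= 0
        mid = ~(right | left)
        if np.any(right):
            r1[right], r2[right] = _tail_ratios(a[right], b[right])
        if np.any(left):
            # mirror: X in [a,b] <-> -X in [-b,-a]
            t1, t2 = _tail_ratios(-b[left], -a[left])
            r1[left] = -t1
            r2[left] = t2
        if np.any(mid):
            r1[mid], r2[mid] = _central_ratios(a[mid], b[mid])

        mu = mr + sr * r1
        v = sr**2 * (1.0 + r2 - r1**2)
        # clamp float noise: the truncated mean/variance are bounded by the box
        mu = np.clip(mu, lor, hir)
        v = np.clip(v, 1e-300, (hir - lor) ** 2 / 4.0)
        mean[rest] = mu
        var[rest] = v
    return mean, var


def truncnorm_rvs(rng, m, s, lo, hi):
    """Draw one truncated-normal variate per broadcast element.

    Inverse-CDF sampling carried out on whichever tail keeps the CDF
    values well away from saturation; exact for the central case.
    """
    m, s, lo, hi = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (m, s, lo, hi)))
    out = np.empty(m.shape)
    u = rng.random(m.shape)

    degenerate = (hi - lo <= 0) | (s <= 0)
    if np.any(degenerate):
        out[degenerate] = np.clip(m[degenerate], lo[degenerate], hi[degenerate])
    ok = ~degenerate
    if np.any(ok):
        a = (lo[ok] - m[ok]) / s[ok]
        b = (hi[ok] - m[ok]) / s[ok]
        uu = u[ok]
        x = np.empty(a.shape)
        mirror = a + b > 0  # mass sits to the right; work on the negated axis
        if np.any(mirror):
            am, bm = -b[mirror], -a[mirror]
            p0 = ndtr(am)
            p1 = ndtr(bm)
            x[mirror] = -ndtri(p0 + (1.0 - uu[mirror]) * (p1 - p0))
        direct = ~mirror
        if np.any(direct):
            p0 = ndtr(a[direct])
            p1 = ndtr(b[direct])
            x[direct] = ndtri(p0 + uu[direct] * (p1 - p0))
        x = np.clip(x, a, b)
        out[ok] = m[ok] + s[ok] * x
    return out
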