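"""Independent brute-force oracles used by the test suite.

These are deliberately naive transcriptions (scalar loops, closed forms,
full enumeration) kept separate from the package implementation so the
two routes stay independent.
"""

from __future__ import annotations

import math

import numpy as np


def enrichment_oracle(h, l, require_both=True):
    """Scalar-loop transcription of the raw-enrichment log-ratio."""
    h = [float(v) for v in h]
    l = [float(v) for v in l]
    th = sum(0.5 + v for v in h)
    tl = sum(0.5 + v for v in l)
    out = []
    for hi, li in zip(h, l):
        if (require_both and not (hi > 0 and li > 0)) \
                or sum(h) == 0 or sum(l) == 0:
            out.append(float("nan"))
        else:
            out.append(math.log((0.5 + hi) / th) - math.log((0.5 + li) / tl))
    return out


def poisson_se_oracle(ch, cl, th, tl):
    return math.sqrt(1 / (ch + 0.5) + 1 / (cl + 0.5)
                     + 1 / (th + 0.5) + 1 / (tl + 0.5))


def control_oracle(scores):
    n = len(scores)
    mu = sum(scores) / n
    var = sum((s - mu) ** 2 for s in scores) / (n - 1)
    return mu, math.sqrt(var)


def combine_oracle(z, se, n_iter=50):
    """Replicate combination: scalar REML Fisher scoring plus the printed
    sqrt(M + SE^2) weights."""
    z = [float(v) for v in z]
    s2 = [float(v) ** 2 for v in se]
    n = len(z)
    if n == 1:
        return z[0], [1.0], 0.0
    mean = sum(z) / n
    m = max(0.0, sum((v - mean) ** 2 for v in z) / (n - 1)
            - sum(s2) / n)
    for _ in range(n_iter):
        v = [s + m for s in s2]
        w = [1 / vi for vi in v]
        sw = sum(w)
        theta = sum(wi * zi for wi, zi in zip(w, z)) / sw
        sc = 0.5 * (sum(wi ** 2 * (zi - theta) ** 2
                        for wi, zi in zip(w, z))
                    - sw + sum(wi ** 2 for wi in w) / sw)
        info = 0.5 * (sum(wi ** 2 for wi in w)
                      - 2 * sum(wi ** 3 for wi in w) / sw
                      + (sum(wi ** 2 for wi in w) / sw) ** 2)
        if info <= 0:
            break
        m = max(0.0, m + sc / info)
    wts = [math.sqrt(s + m) for s in s2]
    tot = sum(wts)
    wts = [wv / tot for wv in wts]
    return sum(wi * zi for wi, zi in zip(wts, z)), wts, m


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full enumeration of tables at fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_fact(k):
        return math.lgamma(k + 1)

    def prob(x):
        # hypergeometric P(a = x) at the fixed margins
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return math.exp(
            log_fact(r1) - log_fact(x) - log_fact(r1 - x)
            + log_fact(r2) - log_fact(c1 - x) - log_fact(r2 - (c1 - x))
            - (log_fact(n) - log_fact(c1) - log_fact(n - c1)))

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def anm_msf_oracle(coords, cutoff=15.0, gamma=1.0):
    """Mean-square fluctuations via an independently assembled Hessian and
    numpy's pinv (no eigendecomposition bookkeeping shared with the
    implementation)."""
    x = np.asarray(coords, dtype=float)
    n = len(x)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = x[j] - x[i]
            r2 = float(d @ d)
            if r2 > cutoff ** 2:
                continue
            blk = gamma * np.outer(d, d) / r2
            hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = -blk
            hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] += blk
    cov = np.linalg.pinv(hess, rcond=1e-10, hermitian=True)
    msf = np.array([np.trace(cov[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                    for i in range(n)])
    return msf / msf.mean()
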