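"""Exact contingency statistics shared by the methylation, expression and
enrichment callers.

For small tables the two-sided Fisher p-value and the hypergeometric upper
tail are computed with big-integer arithmetic (sums of binomial-coefficient
products over a common denominator), so the returned floats are exact up to a
single rounding.  Larger tables fall back to log-space hypergeometric mass
with a relative tie tolerance, which is the regime where counts are library
totals rather than read depths.

The negative-binomial exact test is the double-tail test of the kind used for
two-group RNA-seq comparisons with a common dispersion: condition on the sum
of the two pooled counts, with each pooled count modelled as NB with shape
``n_reps / dispersion``.  At dispersion zero it reduces to the conditioned
binomial (equivalently hypergeometric) test.
"""
from __future__ import annotations

from math import comb

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, nbinom

#: tables with grand total at or below this use exact integer arithmetic
EXACT_TOTAL = 500

_TIE_REL = 1e-12


def fisher_exact_two_sided(m1: int, u1: int, m2: int, u2: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[m1, u1], [m2, u2]].

    The two-sided mass is the sum of probabilities, over all tables with the
    observed margins, of the tables whose probability does not exceed that of
    the observed one.
    """
    m1, u1, m2, u2 = int(m1), int(u1), int(m2), int(u2)
    if min(m1, u1, m2, u2) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = m1 + u1, m2 + u2
    n = r1 + r2
    c1 = m1 + m2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    if n <= EXACT_TOTAL:
        return _fisher_int(m1, r1, r2, c1)
    return _fisher_float(m1, r1, r2, c1)


def _fisher_int(m1: int, r1: int, r2: int, c1: int) -> float:
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    obs = comb(r1, m1) * comb(r2, c1 - m1)
    acc = 0
    for k in range(lo, hi + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            acc += w
    p = acc / comb(r1 + r2, c1)
    return min(1.0, p)


def _fisher_float(m1: int, r1: int, r2: int, c1: int) -> float:
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    k = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(k, n, c1, r1)
    log_obs = hypergeom.logpmf(m1, n, c1, r1)
    mask = logp <= log_obs + np.log1p(_TIE_REL)
    p = float(np.exp(logsumexp(logp[mask])))
    return min(1.0, p)


def hypergeom_sf(k: int, total: int, marked: int, drawn: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(total, marked, drawn)."""
    k, total, marked, drawn = int(k), int(total), int(marked), int(drawn)
    if not (0 <= marked <= total and 0 <= drawn <= total):
        raise ValueError("invalid hypergeometric parameters")
    hi = min(marked, drawn)
    if k <= max(0, drawn - (total - marked)):
        return 1.0
    if k > hi:
        return 0.0
    if total <= EXACT_TOTAL:
        acc = sum(comb(marked, j) * comb(total - marked, drawn - j) for j in range(k, hi + 1))
        return min(1.0, acc / comb(total, drawn))
    return min(1.0, float(hypergeom.sf(k - 1, total, marked, drawn)))


def nb_exact_test(y1: int, y2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided exact test for equality of per-replicate NB means.

    ``y1``/``y2`` are counts pooled over ``n1``/``n2`` replicates (already
    adjusted to a common library size).  ``dispersion`` is the NB dispersion
    phi (variance = mu + phi * mu^2 per replicate); phi = 0 falls back to the
    conditioned binomial test, i.e. Fisher on the 2x2 count split.
    """
    y1, y2 = int(y1), int(y2)
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    s = y1 + y2
    if s == 0:
        return 1.0
    if dispersion <= 0:
        # conditioned on the total, Y1 ~ Binomial(s, n1/(n1+n2))
        return _binom_two_sided(y1, s, n1 / (n1 + n2))
    r1 = n1 / dispersion
    r2 = n2 / dispersion
    lam = s / (n1 + n2)
    mu1, mu2 = n1 * lam, n2 * lam
    k = np.arange(s + 1)
    lp = nbinom.logpmf(k, r1, r1 / (r1 + mu1)) + nbinom.logpmf(s - k, r2, r2 / (r2 + mu2))
    tot = logsumexp(lp)
    mask = lp <= lp[y1] + np.log1p(_TIE_REL)
    return min(1.0, float(np.exp(logsumexp(lp[mask]) - tot)))


def _binom_two_sided(y1: int, s: int, prob: float) -> float:
    from scipy.stats import binom

    k = np.arange(s + 1)
    lp = binom.logpmf(k, s, prob)
    mask = lp <= lp[y1] + np.log1p(_TIE_REL)
    return min(1.0, float(np.exp(logsumexp(lp[mask]))))
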