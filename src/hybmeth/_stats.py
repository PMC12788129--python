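"""Vectorized exact tests used across the pipeline.

The two-sided Fisher exact test follows the minimum-likelihood rule (sum
the probabilities of all tables, under the hypergeometric null with fixed
margins, that are no more probable than the observed one, with a 1+1e-7
relative tolerance) — the convention of both R's fisher.test and
scipy.stats.fisher_exact, against which these implementations are
oracle-tested.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

_REL_TOL = 1.0 + 1e-7


def fisher_exact_vec(mc_a: np.ndarray, tot_a: np.ndarray,
                     mc_b: np.ndarray, tot_b: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p for many 2x2 tables [[mc_a, ua], [mc_b, ub]].

    Vectorized over tables by looping over the (short) hypergeometric
    support: suited to read-depth-scale counts.
    """
    mc_a = np.asarray(mc_a, dtype=np.int64)
    mc_b = np.asarray(mc_b, dtype=np.int64)
    tot_a = np.asarray(tot_a, dtype=np.int64)
    tot_b = np.asarray(tot_b, dtype=np.int64)
    N = tot_a + tot_b
    K = mc_a + mc_b  # methylated margin
    n = tot_a        # sample-a margin
    kmin = np.maximum(0, K - tot_b)
    kmax = np.minimum(K, n)
    width = int((kmax - kmin).max()) + 1 if len(mc_a) else 0

    # log pmf of hypergeom at k: C(K,k) C(N-K,n-k) / C(N,n)
    def logpmf(k):
        with np.errstate(invalid="ignore"):
            val = (gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
                   + gammaln(N - K + 1) - gammaln(n - k + 1)
                   - gammaln(N - K - (n - k) + 1)
                   - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))
        return val

    p_obs = np.exp(logpmf(mc_a))
    total = np.zeros(len(mc_a))
    for off in range(width):
        k = kmin + off
        valid = k <= kmax
        pk = np.where(valid, np.exp(logpmf(np.minimum(k, kmax))), 0.0)
        total += np.where(valid & (pk <= p_obs * _REL_TOL), pk, 0.0)
    return np.minimum(total, 1.0)


def fisher_exact_pair(mc_a: int, uc_a: int, mc_b: int, uc_b: int) -> float:
    """Scalar two-sided Fisher exact p on the 2x2 table [[mc_a, uc_a], [mc_b, uc_b]]."""
    if mc_a + uc_a == 0 or mc_b + uc_b == 0:
        raise ValueError("each sample needs total >= 1")
    return float(fisher_exact_vec(
        np.array([mc_a]), np.array([mc_a + uc_a]),
        np.array([mc_b]), np.array([mc_b + uc_b]))[0])


def binom_greater_pvals(mc: np.ndarray, total: np.ndarray, rate: float) -> np.ndarray:
    """One-sided binomial P(X >= mc | total, rate), vectorized.

    The methylated-site caller: small p means more methylated reads than
    bisulfite conversion failure alone explains.
    """
    mc = np.asarray(mc, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    return binom.sf(mc - 1, total, rate)


def nb_exact_test_vec(x1: np.ndarray, x2: np.ndarray, dispersion: float) -> np.ndarray:
    """Exact conditional negative-binomial test of x1 vs x2 with common dispersion.

    Under the null both counts share mean mu = (x1+x2)/2 and the given
    dispersion phi (var = mu + phi mu^2).  Conditional on the pair total n,
    the two-sided p sums P(k, n-k) over all splits k whose joint probability
    does not exceed the observed one (min-likelihood rule).  phi = 0 reduces
    to the binomial(n, 1/2) split.  Returns p = 1 where n = 0.
    """
    x1 = np.asarray(x1, dtype=np.int64)
    x2 = np.asarray(x2, dtype=np.int64)
    n = x1 + x2
    pvals = np.ones(len(x1))
    todo = np.flatnonzero(n > 0)
    if len(todo) == 0:
        return pvals
    nmax = int(n[todo].max())
    k = np.arange(nmax + 1)

    for i in todo:
        ni = int(n[i])
        kk = k[: ni + 1]
        if dispersion <= 0:
            logjoint = (gammaln(ni + 1) - gammaln(kk + 1) - gammaln(ni - kk + 1)
                        + ni * np.log(0.5))
        else:
            r = 1.0 / dispersion
            logp = gammaln(kk + r) - gammaln(kk + 1) - gammaln(r)
            logjoint = logp + logp[::-1]  # + constant terms, cancel in comparison
            logjoint = logjoint - logjoint.max()
        joint = np.exp(logjoint)
        joint = joint / joint.sum()
        p_obs = joint[int(x1[i])]
        pvals[i] = min(1.0, float(joint[joint <= p_obs * _REL_TOL].sum()))
    return pvals
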