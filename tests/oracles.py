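"""Independent oracles used by the tests.

Everything here is written from first principles (exhaustive search,
enumeration, Monte Carlo, closed forms) and deliberately avoids calling the
package's own estimators, so agreement between the two is evidence rather
than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def conditional_loglik(counts: np.ndarray, totals: np.ndarray, r: np.ndarray,
                       norm: np.ndarray | None = None) -> float:
    """Multinomial log-likelihood of the counts across timepoints.

    Conditioning on the gene's total read count gives cell probabilities
    proportional to ``totals * r / Z``; this is the textbook multinomial
    pmf written out with ``lgamma``.
    """
    c = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    z = np.ones_like(c) if norm is None else np.asarray(norm, dtype=float)
    w = n * np.asarray(r, dtype=float) / z
    q = w / w.sum()
    const = math.lgamma(c.sum() + 1) - sum(math.lgamma(x + 1) for x in c)
    return const + float(np.sum(c * np.log(np.clip(q, 1e-300, None))))


def brute_force_trajectory_fit(
    times: np.ndarray,
    counts: np.ndarray,
    totals: np.ndarray,
    t_step: float = 0.02,
    d_step: float = 0.005,
    d_max: float = 5.0,
    norm: np.ndarray | None = None,
) -> dict:
    """Exhaustive (T, delta) grid search for the three trajectory models.

    Returns the best log-likelihood per model; the overabundance search is a
    full two-parameter scan, so its maximum lower-bounds the true MLE to
    grid resolution.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    z = np.ones_like(c) if norm is None else np.asarray(norm, dtype=float)
    const = math.lgamma(c.sum() + 1) - sum(math.lgamma(x + 1) for x in c)

    def ll_of(r_mat: np.ndarray) -> np.ndarray:
        w = n * r_mat / z
        q = w / w.sum(axis=1, keepdims=True)
        return const + np.sum(c * np.log(np.clip(q, 1e-300, None)), axis=1)

    ll_ne = float(ll_of(np.ones((1, t.size)))[0])

    deltas = np.arange(0.0, d_max + d_step / 2, d_step)
    ll_s_all = ll_of(np.exp(-np.outer(deltas, t)))
    i_s = int(np.argmax(ll_s_all))
    ll_s, d_s = float(ll_s_all[i_s]), float(deltas[i_s])

    T_grid = np.arange(0.0, t[-1] + t_step / 2, t_step)
    best = (-np.inf, 0.0, 0.0)
    for T in T_grid:
        shifted = np.clip(t - T, 0.0, None)
        ll_all = ll_of(np.exp(-np.outer(deltas, shifted)))
        j = int(np.argmax(ll_all))
        if ll_all[j] > best[0]:
            best = (float(ll_all[j]), float(T), float(deltas[j]))
    ll_o, T_hat, d_o = best
    return {
        "ll_no_effect": ll_ne,
        "ll_sufficiency": max(ll_s, ll_ne),
        "ll_overabundance": max(ll_o, ll_s, ll_ne),
        "delta_sufficiency": d_s,
        "T": T_hat,
        "delta": d_o,
    }


def ks_two_sample_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and exact permutation p-value (no ties).

    Enumerates every assignment of the pooled values to the two samples and
    counts assignments whose D is at least the observed one.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("exact enumeration oracle assumes distinct values")

    def stat(a: np.ndarray, b: np.ndarray) -> float:
        grid = np.sort(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
        fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
        return float(np.max(np.abs(fa - fb)))

    d_obs = stat(x, y)
    n = x.size
    idx = range(pooled.size)
    count = total = 0
    for pick in itertools.combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(pick)] = True
        d = stat(pooled[mask], pooled[~mask])
        count += d >= d_obs - 1e-12
        total += 1
    return d_obs, count / total


def mc_gamma_below(mu: float, o: float, n: int = 10_000_000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo fraction of gamma(shape=mu) draws below mu/o, with its SE."""
    rng = np.random.default_rng(seed)
    draws = rng.gamma(shape=mu, scale=1.0, size=n)
    p = float(np.mean(draws < mu / o))
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    return p, se


def gamma_tail_integer_shape(k: int, x: float) -> float:
    """Closed-form regularized lower incomplete gamma for integer shape k.

    P(k, x) = 1 - exp(-x) * sum_{j<k} x^j / j!
    """
    s = sum(x**j / math.factorial(j) for j in range(k))
    return 1.0 - math.exp(-x) * s


def grid_optimal_overabundance(mu: float, epsilon: float, dlog: float = 1e-3) -> tuple[float, float]:
    """Dense-grid maximizer of (1 - eps*o) * (1 - P_a) in log10 o."""
    from scipy.special import gammainc

    logs = np.arange(0.0, math.log10(1.0 / epsilon) + dlog / 2, dlog)
    o = 10.0**logs
    f = (1.0 - epsilon * o) * (1.0 - gammainc(mu, mu / o))
    i = int(np.argmax(f))
    return float(o[i]), float(f[i])
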