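"""Robustness-load trade-off (RLTO): optimal overabundance versus transcription.

Expression noise is modelled as a gamma-distributed protein level whose shape
parameter equals the message number ``mu_m`` (the bursty-expression limit, in
which the squared coefficient of variation is ``1/mu_m``).  With endogenous
mean expression ``o`` times the arrest threshold, the probability that a cell
falls below threshold in a cell cycle is the regularized lower incomplete
gamma function at ``(mu_m, mu_m/o)`` — scale-free, depending only on
``(mu_m, o)``.

Fitness trades the metabolic load of expression against the risk of growth
arrest::

    F(o) = (1 - epsilon * o) * (1 - P_a(mu_m, o))

where ``epsilon`` is the relative cost per unit of threshold-level
expression and the second factor is the per-cycle non-arrest probability.
The landscape is highly asymmetric: for low-expression genes the marginal
load of more protein is tiny compared with the risk of arresting essential
processes, so the optimum ``o*`` sits far above 1 and grows rapidly as
``mu_m`` falls, while high-expression (low-noise, high-cost) genes sit near
``o* = 1``.  The exact fitness functional of the published model is not
reproduced here; this module is a reconstruction with the same structure,
and its quantitative claims are bounds and monotonicity properties rather
than exact values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "RLTOParams",
    "RLTOPrediction",
    "arrest_probability",
    "expected_fitness",
    "optimal_overabundance",
    "overabundance_floor",
]


@dataclass(frozen=True)
class RLTOParams:
    """Parameters of the trade-off for a single gene.

    mu_m
        message number (mRNA per cell cycle); sets the noise (CV^2 = 1/mu_m).
    epsilon
        relative metabolic cost per unit of threshold-level expression;
        default 1e-4, a low-expression essential gene's share of the
        proteome.  The prediction is nearly insensitive to it.
    o_grid
        optional candidate overabundances for the coarse search.
    """

    mu_m: float
    epsilon: float = 1e-4
    o_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu_m) and self.mu_m > 0):
            raise ValueError("mu_m must be a positive message number")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.o_grid is not None:
            g = np.asarray(self.o_grid, dtype=float)
            if np.any(g < 1.0) or np.any(np.diff(g) <= 0):
                raise ValueError("o_grid must be increasing and >= 1")


@dataclass
class RLTOPrediction:
    """Optimal overabundance along a message-number grid."""

    mu_m_grid: np.ndarray
    o_star: np.ndarray
    f_max: np.ndarray
    mu_m_min: float
    epsilon: float
    n_local_maxima: np.ndarray = field(default=None)


def arrest_probability(mu_m, o):
    """Per-cycle probability that expression falls below the arrest threshold.

    A gamma level with shape ``mu_m`` and mean ``mu_m * s`` (any scale s)
    falls below the threshold ``mu_m * s / o`` with probability
    ``gammainc(mu_m, mu_m / o)`` — the scale cancels, so the result depends
    only on ``(mu_m, o)`` and is decreasing in both.
    """
    mu = np.asarray(mu_m, dtype=float)
    oo = np.asarray(o, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu_m must be positive")
    if np.any(oo < 1.0):
        raise ValueError("o must be >= 1")
    out = special.gammainc(mu, mu / oo)
    return float(out) if np.isscalar(mu_m) and np.isscalar(o) else out


def expected_fitness(mu_m, o, epsilon: float = 1e-4):
    """Relative fitness F(o) = (1 - epsilon*o) * (1 - P_a(mu_m, o)).

    The product of the metabolic-load term and the per-cycle survival
    (non-arrest) term; F <= 1, and F <= 0 once the load epsilon*o reaches 1
    (valid, not an error).
    """
    pa = arrest_probability(mu_m, o)
    return (1.0 - epsilon * np.asarray(o, dtype=float)) * (1.0 - pa)


def _maximize_fitness(mu: float, epsilon: float, n_coarse: int = 600) -> tuple[float, float, int]:
    """(o_star, F_max, n_local_maxima) by log-grid search + golden refinement."""
    lo, hi = 0.0, math.log10(1.0 / epsilon)
    grid = np.logspace(lo, hi, n_coarse)
    f = expected_fitness(mu, grid, epsilon)
    i = int(np.argmax(f))
    d = np.diff(f)
    n_max = int(np.sum((d[:-1] > 0) & (d[1:] < 0)))
    if i == 0:
        lo_x, hi_x = lo, math.log10(grid[1])
    elif i == n_coarse - 1:
        lo_x, hi_x = math.log10(grid[-2]), hi
    else:
        lo_x, hi_x = math.log10(grid[i - 1]), math.log10(grid[i + 1])
    res = optimize.minimize_scalar(
        lambda x: -expected_fitness(mu, 10.0**x, epsilon),
        bounds=(lo_x, hi_x), method="bounded", options={"xatol": 1e-7},
    )
    cands = [(10.0**res.x, -res.fun), (float(grid[i]), float(f[i])), (1.0, float(expected_fitness(mu, 1.0, epsilon)))]
    o_star, f_max = max(cands, key=lambda c: c[1])
    return float(o_star), float(f_max), n_max


def optimal_overabundance(mu_m_grid, epsilon: float = 1e-4) -> RLTOPrediction:
    """Optimal overabundance o*(mu_m) along a grid of message numbers.

    ``o*`` maximizes F over o in [1, 1/epsilon] per grid point (coarse log
    grid plus golden-section refinement; unimodality is checked, and the
    global maximum is taken with a warning when the coarse grid shows more
    than one local maximum).

    ``mu_m_min`` is the smallest admissible transcription level: the
    smallest grid point at which (a) the optimal strategy sustains the
    lineage — a division yields on average more than one proliferating
    daughter, ``2 * F(o*) > 1`` — and (b) expression can be robust at all,
    i.e. the cell-to-cell variation of the gamma noise model does not exceed
    the mean level (CV <= 1, the one-message threshold).
    """
    mu_grid = np.asarray(mu_m_grid, dtype=float)
    if mu_grid.ndim != 1 or np.any(np.diff(mu_grid) <= 0) or np.any(mu_grid <= 0):
        raise ValueError("mu_m_grid must be a positive, strictly increasing vector")
    o_star = np.empty_like(mu_grid)
    f_max = np.empty_like(mu_grid)
    n_loc = np.empty_like(mu_grid, dtype=int)
    for i, mu in enumerate(mu_grid):
        o_star[i], f_max[i], n_loc[i] = _maximize_fitness(float(mu), epsilon)
    if np.any(n_loc > 1):
        warnings.warn("fitness not unimodal on the coarse grid for some mu_m; global maximum used")

    mean, var = stats.gamma(a=mu_grid).stats(moments="mv")
    cv = np.sqrt(np.asarray(var)) / np.asarray(mean)
    admissible = (2.0 * f_max > 1.0) & (cv <= 1.0)
    mu_m_min = float(mu_grid[admissible][0]) if admissible.any() else float("inf")
    return RLTOPrediction(mu_m_grid=mu_grid, o_star=o_star, f_max=f_max,
                          mu_m_min=mu_m_min, epsilon=epsilon, n_local_maxima=n_loc)


def overabundance_floor(
    mu_range: tuple[float, float] = (1.0, 2.0),
    eps_range: tuple[float, float] = (1e-6, 1e-3),
    n_mu: int = 5,
    n_eps: int = 7,
) -> float:
    """Minimum optimal overabundance over the lowest admissible expression.

    Scans mu_m over ``mu_range`` (the one-message neighbourhood) and epsilon
    over ``eps_range`` and returns the smallest o*; the model's claim is
    that even this floor exceeds a tenfold excess.
    """
    mus = np.linspace(mu_range[0], mu_range[1], n_mu)
    epss = np.logspace(math.log10(eps_range[0]), math.log10(eps_range[1]), n_eps)
    floor = math.inf
    for eps in epss:
        pred = optimal_overabundance(mus, epsilon=float(eps))
        floor = min(floor, float(pred.o_star.min()))
    return floor
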