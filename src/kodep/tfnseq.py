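"""Genome-wide depletion-trajectory classification and arrest-time inference.

Each mutant's relative-abundance trajectory is compared under three nested
growth models for the expected relative abundance r(t):

no effect
    ``r(t) = 1`` (0 free parameters);
sufficiency
    ``r(t) = exp(-delta * t)``, ``delta >= 0`` (1 parameter): growth slows
    immediately after the knockout, so the endogenous level is at threshold;
overabundance
    ``r(t) = 1`` for ``t < T`` then ``exp(-delta * (t - T))`` (2 parameters):
    wild-type growth until the diluted protein reaches threshold at the
    arrest time T.

Counts at each timepoint are binomial given the library total, with expected
fraction ``f0 * r(t) / Z(t)`` where Z(t) is a library-wide normalization
(the pooled library keeps growing while mutants drop out, so raw fractions of
unaffected genes drift upward).  Z is estimated from genes called no-effect
in a first pass and all genes are refit in a second pass
(:func:`fit_library`).

Model choice uses two successive null-hypothesis tests: the no-effect null
against the overabundance alternative, then the sufficiency null against
overabundance, both with boundary-corrected chi-squared reference
distributions.  The arrest time maps to overabundance through
``o = exp(k0 * T)``; ``k0`` must be supplied (relative abundances carry no
absolute rate information).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "AbundanceTrajectory",
    "ModelFits",
    "MutantCall",
    "relative_abundance",
    "fit_models",
    "select_model",
    "overabundance",
    "halving_time",
    "fit_library",
    "replicate_error",
    "class_fractions",
]

LN10 = math.log(10.0)

MODELS = ("no_effect", "sufficiency", "overabundance")


@dataclass
class AbundanceTrajectory:
    """Per-gene read counts and library-fraction trajectory."""

    gene_id: str
    times: np.ndarray
    counts: np.ndarray
    totals: np.ndarray
    norm: np.ndarray | None = None  # library normalization Z(t); None = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        if not (self.times.shape == self.counts.shape == self.totals.shape):
            raise ValueError(f"{self.gene_id}: times/counts/totals shape mismatch")
        if self.times[0] != 0.0:
            raise ValueError(f"{self.gene_id}: trajectory must start at t = 0")
        if np.any(self.counts > self.totals):
            raise ValueError(f"{self.gene_id}: counts exceed totals")
        if np.any(self.totals <= 0):
            raise ValueError(f"{self.gene_id}: non-positive library total")
        if self.counts[0] <= 0:
            raise ValueError(f"{self.gene_id}: zero count at t = 0")

    @property
    def f0(self) -> float:
        return float(self.counts[0] / self.totals[0])

    @property
    def rel_abundance(self) -> np.ndarray:
        """Fraction-of-library trajectory normalized to its t = 0 value."""
        frac = self.counts / self.totals
        return frac / frac[0]

    @property
    def rel_corrected(self) -> np.ndarray:
        """Relative abundance corrected by the library normalization Z(t)."""
        r = self.rel_abundance
        return r if self.norm is None else r * self.norm


@dataclass
class ModelFits:
    gene_id: str
    ll_no_effect: float
    ll_sufficiency: float
    ll_overabundance: float
    delta_sufficiency: float
    delta_overabundance: float
    T_overabundance: float
    t_last: float
    converged: bool = True


@dataclass
class MutantCall:
    gene_id: str
    model: str
    p_no_effect: float
    p_sufficiency: float
    T_hat: float | None = None
    log10_o: float | None = None
    delta: float | None = None
    halving_time: float | None = None
    censored: bool = False


def _parse_time_columns(columns) -> np.ndarray:
    times = []
    for c in columns:
        s = str(c)
        if s.startswith("t="):
            s = s[2:]
        times.append(float(s))
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise ValueError("count-matrix time columns are not strictly increasing")
    return t


def relative_abundance(
    counts: pd.DataFrame,
    min_count0: int = 20,
    totals: np.ndarray | None = None,
) -> tuple[list[AbundanceTrajectory], pd.DataFrame]:
    """Build per-gene trajectories from a count matrix.

    Columns are timepoints (hours, optionally prefixed ``t=``); totals
    default to column sums.  Genes whose t = 0 count falls below
    ``min_count0`` are dropped and reported, never silently.
    Returns ``(trajectories, dropped)``.
    """
    times = _parse_time_columns(counts.columns)
    if times[0] != 0.0:
        raise ValueError("count matrix must include a t = 0 column")
    mat = counts.to_numpy(dtype=np.int64)
    tot = mat.sum(axis=0) if totals is None else np.asarray(totals, dtype=np.int64)
    if np.any(tot <= 0):
        raise ValueError("library totals must be positive at every timepoint")
    trajs: list[AbundanceTrajectory] = []
    dropped = []
    for gid, row in zip(counts.index, mat):
        if row[0] < min_count0:
            dropped.append({"gene_id": gid, "reason": f"count(0) = {row[0]} < {min_count0}", "count0": int(row[0])})
            continue
        trajs.append(AbundanceTrajectory(str(gid), times, row, tot))
    return trajs, pd.DataFrame(dropped, columns=["gene_id", "reason", "count0"])


def _make_loglik(traj: AbundanceTrajectory):
    """Trajectory-shape log-likelihood as a function of r(t).

    Counts are binomial per timepoint with expected fraction
    ``f0 * r(t) / Z(t)``, but the initial fraction f0 is a nuisance: its
    sampling noise at t = 0 would otherwise masquerade as a coherent shift
    of the whole trajectory.  Conditioning on the gene's total read count
    removes f0 exactly (the conditional distribution across timepoints is
    multinomial with weights ``totals * r / Z``), leaving the stated
    0/1/2 free parameters for the three models.
    """
    c = traj.counts.astype(float)
    n = traj.totals.astype(float)
    const = gammaln(c.sum() + 1) - float(np.sum(gammaln(c + 1)))
    z = np.ones_like(c) if traj.norm is None else np.asarray(traj.norm, dtype=float)
    weight = n / z

    def loglik(r: np.ndarray) -> float:
        w = np.clip(weight * r, 1e-300, None)
        q = w / w.sum()
        return float(const + np.sum(c * np.log(q)))

    return loglik


def fit_models(
    traj: AbundanceTrajectory,
    delta_max: float = 20.0,
    coarse_step: float = 0.2,
    t_resolution: float = 0.01,
) -> ModelFits:
    """Maximum-likelihood fits of the three nested trajectory models.

    The arrest time T is profiled on a coarse grid over the sampled window
    and refined to ``t_resolution`` (0.01 h); the decay rate delta is
    maximized numerically at each T.  Candidate inclusion of the nested
    special cases (delta = 0; T = 0) guarantees the likelihood ordering
    ``no_effect <= sufficiency <= overabundance``.
    """
    t = traj.times
    if t.size < 3:
        raise ValueError(f"{traj.gene_id}: need >= 3 timepoints to fit trajectory models")
    loglik = _make_loglik(traj)
    ones = np.ones_like(t)
    ll_ne = loglik(ones)

    converged = True

    def best_delta(shifted: np.ndarray) -> tuple[float, float]:
        """(delta_hat, loglik) for r = exp(-delta * shifted), delta >= 0."""
        nonlocal converged

        def neg(d: float) -> float:
            return -loglik(np.exp(-d * shifted))

        res = optimize.minimize_scalar(neg, bounds=(0.0, delta_max), method="bounded",
                                       options={"xatol": 1e-6})
        if not res.success:
            converged = False
        cand = [(0.0, ll_ne if shifted is t else loglik(ones)), (float(res.x), float(-res.fun))]
        return max(cand, key=lambda x: x[1])

    d_s, ll_s = best_delta(t)
    ll_s = max(ll_s, ll_ne)

    t_last = float(t[-1])
    coarse = np.arange(0.0, t_last + coarse_step, coarse_step)
    coarse = coarse[coarse <= t_last]

    def profile(T: float) -> tuple[float, float]:
        return best_delta(np.clip(t - T, 0.0, None))

    results = {float(T): profile(float(T)) for T in coarse}
    T_best = max(results, key=lambda T: results[T][1])
    fine = np.arange(max(0.0, T_best - coarse_step), min(t_last, T_best + coarse_step) + t_resolution / 2, t_resolution)
    for T in fine:
        results[float(T)] = profile(float(T))
    # nested candidates: T = 0 reduces to sufficiency
    results[0.0] = max(results.get(0.0, (d_s, ll_s)), (d_s, ll_s), key=lambda x: x[1])
    T_hat = max(results, key=lambda T: results[T][1])
    d_o, ll_o = results[T_hat]
    ll_o = max(ll_o, ll_s)
    return ModelFits(
        gene_id=traj.gene_id,
        ll_no_effect=ll_ne,
        ll_sufficiency=ll_s,
        ll_overabundance=ll_o,
        delta_sufficiency=d_s,
        delta_overabundance=d_o,
        T_overabundance=float(T_hat),
        t_last=t_last,
        converged=converged,
    )


def _p_boundary_mix(lr: float, dfs: tuple[int, ...], weights: tuple[float, ...]) -> float:
    if lr <= 0:
        return 1.0
    p = 0.0
    for df, w in zip(dfs, weights):
        p += w * (stats.chi2.sf(lr, df) if df > 0 else 0.0)
    return float(min(p, 1.0))


def select_model(
    fits: ModelFits,
    alpha1: float = 1e-4,
    alpha2: float = 1e-4,
    k0: float | None = None,
    traj: AbundanceTrajectory | None = None,
    t_resolution: float = 0.01,
) -> MutantCall:
    """Two successive likelihood-ratio tests.

    Test 1 rejects the no-effect null against the (best, nested-most-general)
    overabundance alternative; if retained the gene is no-effect.  Test 2
    rejects the sufficiency null against overabundance.  P-values use
    boundary-corrected chi-squared mixtures: (1/2, 1/2) on 1 and 2 df for
    test 1 (conservative relative to the chi-bar-squared weights), and
    (1/2, 1/2) on 0 and 1 df for test 2 where T sits on its boundary.
    Arrest times at the end of the sampled window are censored lower bounds.
    """
    if not fits.converged:
        return MutantCall(fits.gene_id, "unclassifiable", np.nan, np.nan)
    lr1 = 2.0 * (fits.ll_overabundance - fits.ll_no_effect)
    p1 = _p_boundary_mix(lr1, (1, 2), (0.5, 0.5))
    lr2 = 2.0 * (fits.ll_overabundance - fits.ll_sufficiency)
    p2 = _p_boundary_mix(lr2, (0, 1), (0.5, 0.5))
    ht = halving_time(traj) if traj is not None else None
    if p1 > alpha1:
        return MutantCall(fits.gene_id, "no_effect", p1, p2, halving_time=ht)
    if p2 <= alpha2:
        censored = fits.T_overabundance >= fits.t_last - t_resolution
        log10_o = None
        if k0 is not None:
            log10_o = k0 * fits.T_overabundance / LN10
        return MutantCall(
            fits.gene_id, "overabundance", p1, p2,
            T_hat=fits.T_overabundance, log10_o=log10_o,
            delta=fits.delta_overabundance, halving_time=ht, censored=censored,
        )
    return MutantCall(fits.gene_id, "sufficiency", p1, p2, T_hat=0.0, log10_o=0.0,
                      delta=fits.delta_sufficiency, halving_time=ht)


def overabundance(call: MutantCall, k0: float | None) -> float:
    """Overabundance o = exp(k0 * T) of a classified mutant."""
    if call.model not in ("overabundance", "sufficiency"):
        raise ValueError("overabundance is defined only for sufficiency/overabundance calls")
    if call.model == "sufficiency":
        return 1.0
    if k0 is None:
        raise ValueError("k0 is required: relative abundances cannot identify the absolute growth rate")
    return math.exp(k0 * call.T_hat)


def halving_time(traj: AbundanceTrajectory) -> float | None:
    """First time the (normalization-corrected) relative abundance crosses 0.5.

    Log-linear interpolation between the straddling timepoints; ``None`` when
    the trajectory never falls below one half.
    """
    r = traj.rel_corrected
    t = traj.times
    below = np.flatnonzero(r < 0.5)
    if below.size == 0:
        return None
    j = int(below[0])
    if j == 0:
        return float(t[0])
    r0, r1 = r[j - 1], r[j]
    if r0 <= 0.5:
        return float(t[j - 1])
    w = (math.log(r0) - math.log(0.5)) / (math.log(r0) - math.log(max(r1, 1e-12)))
    return float(t[j - 1] + w * (t[j] - t[j - 1]))


@dataclass
class LibraryResult:
    calls: pd.DataFrame
    dropped: pd.DataFrame
    norm: np.ndarray
    trajectories: list[AbundanceTrajectory] = field(default_factory=list)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out


def fit_library(
    counts: pd.DataFrame,
    k0: float,
    alpha1: float = 1e-4,
    alpha2: float = 1e-4,
    min_count0: int = 20,
    multiple_testing: str | None = None,
    **fit_kw,
) -> LibraryResult:
    """Classify every gene of a count matrix (two-pass library normalization).

    Pass 1 fits all genes without normalization; genes retained as no-effect
    define the library normalization ``Z(t)`` (inverse median of their
    observed relative abundance).  Pass 2 refits everything against
    ``f0 * r(t) / Z(t)`` and makes the final calls.  ``multiple_testing="bh"``
    applies a Benjamini-Hochberg adjustment to the stage-1 p-values across
    the library before thresholding.
    """
    if k0 is None or not np.isfinite(k0) or k0 <= 0:
        raise ValueError("k0 (wild-type growth rate) is a required positive input")
    trajs, dropped = relative_abundance(counts, min_count0=min_count0)
    if not trajs:
        raise ValueError("no gene passed the t = 0 count minimum")
    pass1 = [select_model(fit_models(tr, **fit_kw), alpha1, alpha2, k0=k0) for tr in trajs]
    flat = [tr for tr, call in zip(trajs, pass1) if call.model == "no_effect"]
    if flat:
        rel = np.vstack([tr.rel_abundance for tr in flat])
        norm = 1.0 / np.median(rel, axis=0)
        norm[0] = 1.0
    else:
        warnings.warn("no no-effect genes found; skipping library normalization (Z = 1)")
        norm = np.ones(trajs[0].times.size)
    for tr in trajs:
        tr.norm = norm
    fits = [fit_models(tr, **fit_kw) for tr in trajs]
    calls = [select_model(f, alpha1, alpha2, k0=k0, traj=tr) for f, tr in zip(fits, trajs)]
    if multiple_testing == "bh":
        p1 = _bh_adjust(np.array([c.p_no_effect for c in calls]))
        calls = [
            select_model(f, alpha1, alpha2, k0=k0, traj=tr) if padj <= alpha1
            else MutantCall(f.gene_id, "no_effect", float(padj), c.p_sufficiency,
                            halving_time=c.halving_time)
            for f, tr, c, padj in zip(fits, trajs, calls, p1)
        ]
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "model": c.model,
                "p_no_effect": c.p_no_effect,
                "p_sufficiency": c.p_sufficiency,
                "T_hat": c.T_hat,
                "halving_time": c.halving_time,
                "log10_o": c.log10_o,
                "delta": c.delta,
                "censored": c.censored,
            }
        )
    return LibraryResult(calls=pd.DataFrame(rows).set_index("gene_id"), dropped=dropped,
                         norm=norm, trajectories=trajs)


def class_fractions(calls: pd.DataFrame, essential: pd.Series | None = None) -> dict:
    """Fraction of genes per trajectory class, optionally split by essentiality."""
    def frac(df: pd.DataFrame) -> dict:
        n = len(df)
        return {m: float((df["model"] == m).sum() / n) if n else np.nan for m in MODELS}

    out = {"all": frac(calls), "n": len(calls)}
    if essential is not None:
        ess = essential.reindex(calls.index).astype(bool)
        out["essential"] = frac(calls[ess])
        out["nonessential"] = frac(calls[~ess])
        # among essential genes, the sufficiency/overabundance split
        ess_called = calls[ess & calls["model"].isin(["sufficiency", "overabundance"])]
        n_e = len(ess_called)
        if n_e:
            out["essential_split"] = {
                "overabundance": float((ess_called["model"] == "overabundance").sum() / n_e),
                "sufficiency": float((ess_called["model"] == "sufficiency").sum() / n_e),
            }
    return out


def replicate_error(calls_by_replicate: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-gene mean and spread of log10 overabundance across replicates.

    Genes missing from a replicate or discordant in class are flagged, never
    imputed.  Requires >= 2 replicates.
    """
    if len(calls_by_replicate) < 2:
        raise ValueError("replicate_error requires >= 2 replicates")
    all_genes = sorted(set().union(*[set(df.index) for df in calls_by_replicate]))
    rows = []
    for g in all_genes:
        models, log_os = [], []
        present = 0
        for df in calls_by_replicate:
            if g not in df.index:
                continue
            present += 1
            models.append(df.loc[g, "model"])
            lo = df.loc[g, "log10_o"]
            if lo is not None and not pd.isna(lo):
                log_os.append(float(lo))
        missing = present < len(calls_by_replicate)
        discordant = len(set(models)) > 1
        mean = float(np.mean(log_os)) if log_os else np.nan
        sd = float(np.std(log_os, ddof=1)) if len(log_os) > 1 else (0.0 if log_os else np.nan)
        rows.append(
            {
                "gene_id": g,
                "n_replicates": present,
                "model": models[0] if not discordant and models else "discordant" if discordant else "missing",
                "log10_o_mean": mean,
                "log10_o_sd": sd,
                "class_discordant": discordant,
                "missing_in_replicate": missing,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
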