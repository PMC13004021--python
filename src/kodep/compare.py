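"""Genome-wide synthesis: message numbers, trends, subgroup statistics.

Combines the per-gene overabundance calls with RNA-seq-derived message
numbers, extracts the transcription-versus-overabundance trend with two
complementary binning schemes, compares gene subgroups to the full essential
set with two-sample Kolmogorov-Smirnov tests, and reports the two headline
statistics (median overabundance and expression-weighted mean overabundance)
whose contrast reflects the expression dependence of overabundance.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "message_number",
    "merge_records",
    "trend_bins",
    "group_test",
    "summary_stats",
    "kde_overlay",
]


def message_number(counts: pd.Series, m_total: float) -> pd.Series:
    """Messages per gene per cell cycle from RNA-seq counts.

    ``mu_m_hat = (count_g / sum counts) * M_total`` where ``M_total`` is the
    total number of mRNA produced per cell cycle (a calibration input; the
    estimates conserve it exactly).
    """
    if m_total <= 0:
        raise ValueError("M_total must be positive")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total RNA-seq counts")
    return counts / total * float(m_total)


def merge_records(
    calls: pd.DataFrame,
    mu_m_hat: pd.Series,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Merge calls, message numbers and annotation into gene records.

    Genes called sufficiency enter the overabundance distributions at o = 1
    exactly; no-effect genes carry no overabundance.  ``groups`` is a
    comma-separated label set from the annotation table.
    """
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    rec = calls.copy()
    rec["mu_m_hat"] = mu_m_hat.reindex(rec.index)
    rec["essential"] = ann["essential"].reindex(rec.index).astype("boolean")
    rec["groups"] = ann["groups"].reindex(rec.index).fillna("")
    rec["o"] = 10.0 ** rec["log10_o"].astype(float)
    return rec


def trend_bins(
    mu_m: np.ndarray,
    o: np.ndarray,
    method: str = "quantile",
    n_bins: int = 10,
    bins_per_decade: int = 4,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned medians of the (mu_m, o) cloud with bootstrap intervals.

    ``quantile`` uses equal-count bins in the rank of mu_m; ``log_width``
    uses equal-width bins in log10 mu_m (``bins_per_decade`` per decade,
    empty bins dropped with a warning).  Each bin reports the median mu_m,
    median o and a 95% bootstrap interval on the median o.
    """
    mu_m = np.asarray(mu_m, dtype=float)
    o = np.asarray(o, dtype=float)
    if mu_m.size != o.size or mu_m.size < 2:
        raise ValueError("need matched (mu_m, o) samples, at least two bins' worth")
    rng = np.random.default_rng(seed)
    if method == "quantile":
        order = np.argsort(mu_m, kind="stable")
        groups = np.array_split(order, min(n_bins, mu_m.size))
    elif method == "log_width":
        lo = math.floor(np.log10(mu_m.min()) * bins_per_decade) / bins_per_decade
        hi = math.ceil(np.log10(mu_m.max()) * bins_per_decade) / bins_per_decade
        edges = np.arange(lo, hi + 0.5 / bins_per_decade, 1.0 / bins_per_decade)
        which = np.clip(np.digitize(np.log10(mu_m), edges) - 1, 0, len(edges) - 2)
        groups = [np.flatnonzero(which == b) for b in range(len(edges) - 1)]
        n_empty = sum(1 for g in groups if g.size == 0)
        if n_empty:
            warnings.warn(f"{n_empty} empty log-width bin(s) dropped")
        groups = [g for g in groups if g.size > 0]
    else:
        raise ValueError(f"unknown binning method {method!r}")
    rows = []
    for b, idx in enumerate(groups):
        if idx.size == 0:
            continue
        o_bin = o[idx]
        med = float(np.median(o_bin))
        if idx.size > 1:
            boots = np.median(o_bin[rng.integers(0, idx.size, size=(n_boot, idx.size))], axis=1)
            lo_ci, hi_ci = (float(x) for x in np.percentile(boots, [2.5, 97.5]))
        else:
            lo_ci = hi_ci = med
        rows.append(
            {
                "bin": b,
                "n": int(idx.size),
                "mu_m_median": float(np.median(mu_m[idx])),
                "o_median": med,
                "o_ci_lo": lo_ci,
                "o_ci_hi": hi_ci,
            }
        )
    return pd.DataFrame(rows)


def group_test(group_o: np.ndarray, reference_o: np.ndarray) -> dict:
    """Two-sample KS comparison of a gene subgroup against a reference set.

    The test is run on log10 overabundances (the statistic is invariant to
    the monotone transform; the log scale is the display convention).
    Small samples use the exact null distribution.  Returns the KS statistic
    D, the p-value and the group median in fold units.
    """
    g = np.log10(np.asarray(group_o, dtype=float))
    r = np.log10(np.asarray(reference_o, dtype=float))
    if g.size < 3 or r.size < 3:
        raise ValueError("each sample must contain at least 3 genes")
    method = "exact" if max(g.size, r.size) <= 25 else "auto"
    res = stats.ks_2samp(g, r, method=method)
    return {
        "n": int(g.size),
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "median_fold": float(np.median(np.asarray(group_o, dtype=float))),
    }


def summary_stats(records: pd.DataFrame) -> dict:
    """Headline overabundance statistics over the gene records.

    * median overabundance over essential genes with calls (sufficiency
      genes enter at o = 1);
    * mean overabundance weighted by expression level (w = mu_m_hat), the
      metabolic-load view;
    * class fractions among essential and nonessential genes.

    A large median alongside a near-unity weighted mean is the signature of
    expression-dependent overabundance: low-expression genes carry large
    excess but contribute little to the load.
    """
    ess = records[(records["essential"] == True) & records["o"].notna()]  # noqa: E712
    if len(ess) == 0:
        raise ValueError("no essential gene with an overabundance value")
    o = ess["o"].to_numpy(dtype=float)
    w = ess["mu_m_hat"].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        w = np.ones_like(o)
    out = {
        "n_essential": int(len(ess)),
        "median_o": float(np.median(o)),
        "weighted_mean_o": float(np.sum(w * o) / np.sum(w)),
    }
    for label, mask in (("essential", records["essential"] == True),  # noqa: E712
                        ("nonessential", records["essential"] == False)):  # noqa: E712
        sub = records[mask]
        n = len(sub)
        out[f"class_fractions_{label}"] = {
            m: float((sub["model"] == m).sum() / n) if n else np.nan
            for m in ("no_effect", "sufficiency", "overabundance")
        }
    return out


def kde_overlay(mu_m: np.ndarray, o: np.ndarray, grid_size: int = 101, pad: float = 0.5) -> dict:
    """2-D kernel density of the (log10 mu_m, log10 o) cloud for figures.

    Scott's plug-in bandwidth; the returned density is evaluated on a
    regular grid padded ``pad`` decades beyond the data range and integrates
    to ~1 over it.
    """
    x = np.log10(np.asarray(mu_m, dtype=float))
    y = np.log10(np.asarray(o, dtype=float))
    if x.size < 10:
        raise ValueError("need at least 10 points for a density estimate")
    jitter = 0.0
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.linalg.matrix_rank(np.cov(np.vstack([x, y]))) < 2:
        jitter = 1e-6  # degenerate clouds: regularize the covariance
    rng = np.random.default_rng(0)
    kde = stats.gaussian_kde(np.vstack([x + jitter * rng.standard_normal(x.size),
                                        y + jitter * rng.standard_normal(y.size)]))
    gx = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    gy = np.linspace(y.min() - pad, y.max() + pad, grid_size)
    xx, yy = np.meshgrid(gx, gy)
    z = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return {"log10_mu_m": gx, "log10_o": gy, "density": z}
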