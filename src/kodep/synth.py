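"""Synthetic knockout-depletion data with the statistical structure the
analysis assumes.

Three generators cover the pipeline inputs:

* :func:`simulate_tfnseq` — pooled insertion-library count matrices.  Mutant
  *i* grows at the wild-type rate ``k0`` until its arrest time ``T_i`` (set by
  its true overabundance through ``T = ln(o)/k0``), then at the residual rate;
  sequencing reads are drawn multinomially over genes at fixed depth at each
  timepoint.
* :func:`simulate_microcolony` — single-cell dilution dynamics.  The
  progenitor starts at concentration ``o_true`` times the arrest threshold;
  cells grow exponentially in area, divide on area doubling, partition the
  (conserved) protein amount between daughters, and arrest sharply once their
  concentration falls below the threshold.
* :func:`simulate_rnaseq` — multinomial RNA-seq reads proportional to each
  gene's message number, for message-number estimation.

:func:`simulate_genome` builds a whole synthetic genome whose essential genes
follow the optimal-overabundance curve, including the four anchor genes
(dnaA, dnaN, ftsN, murA) at their measured transcription levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .singlecell import CellTrack, LineageTree

__all__ = [
    "SimConfig",
    "TrueGene",
    "ANCHOR_GENES",
    "expected_cell_number",
    "simulate_tfnseq",
    "simulate_microcolony",
    "simulate_rnaseq",
    "simulate_genome",
    "annotation_table",
    "truth_table",
]

LN2 = math.log(2.0)
LN10 = math.log(10.0)

CLASSES = ("no_effect", "sufficiency", "overabundance")


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation conditions.

    k0
        wild-type growth rate (1/h); the fastest A. baylyi-like doubling of
        ~40 min corresponds to k0 ~ 1/h, the default.
    timepoints
        library sampling schedule in hours; fractions every 2 h by default.
    depth
        sequencing reads per timepoint.
    partition_cv
        coefficient of variation of the division split fraction.
    residual_rate
        post-arrest growth rate as a fraction of k0 (sharp but not perfectly
        degenerate arrest).
    frame_interval_h
        imaging frame interval; 2 min by default.
    abundance_sigma
        ln-scale spread of initial library abundances (insertion libraries
        are never perfectly uniform).
    overdispersion
        reserved for a future beta-binomial read-noise knob; must stay 0.
    """

    k0: float = 1.0
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    depth: int = 1_000_000
    n_genes: int = 200
    seed: int = 0
    partition_cv: float = 0.05
    residual_rate: float = 0.05
    frame_interval_h: float = 1.0 / 30.0
    abundance_sigma: float = 0.5
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k0) and self.k0 > 0):
            raise ValueError("k0 must be a finite positive rate")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1 read per timepoint")
        if not 0.0 <= self.partition_cv < 0.5:
            raise ValueError("partition_cv must lie in [0, 0.5)")
        if not 0.0 <= self.residual_rate < 1.0:
            raise ValueError("residual_rate must lie in [0, 1)")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")
        if self.overdispersion != 0.0:
            raise ValueError("overdispersion is reserved and must be 0 in this version")


@dataclass(frozen=True)
class TrueGene:
    """Ground-truth gene record used by all generators."""

    gene_id: str
    essential: bool
    class_true: str
    log10_o_true: float = 0.0
    mu_m: float = 10.0

    def __post_init__(self) -> None:
        if self.class_true not in CLASSES:
            raise ValueError(f"class_true must be one of {CLASSES}")
        if not np.isfinite(self.log10_o_true) or self.log10_o_true < 0:
            raise ValueError("log10_o_true must be finite and >= 0")
        if self.class_true == "no_effect" and self.essential:
            raise ValueError("a no-effect gene cannot be essential")
        if self.class_true == "sufficiency" and self.log10_o_true != 0.0:
            raise ValueError("sufficiency genes have o = 1 (log10_o_true = 0)")
        if not np.isfinite(self.mu_m) or self.mu_m <= 0:
            raise ValueError("mu_m must be a positive message number")

    def arrest_time(self, k0: float) -> float:
        """T = ln(o)/k0; 0 for sufficiency, +inf for no-effect genes."""
        if self.class_true == "no_effect":
            return math.inf
        if self.class_true == "sufficiency":
            return 0.0
        return self.log10_o_true * LN10 / k0


#: Imaging/sequencing anchor genes with their measured transcription levels
#: (mRNA molecules per cell cycle) and library-based log10 overabundances.
ANCHOR_GENES = (
    TrueGene("dnaA", True, "sufficiency", 0.0, 30.0),
    TrueGene("dnaN", True, "overabundance", 1.5, 49.0),
    TrueGene("ftsN", True, "overabundance", 2.6, 20.0),
    TrueGene("murA", True, "overabundance", 0.7, 26.0),
)


def expected_cell_number(truth: list[TrueGene], cfg: SimConfig, t: float) -> np.ndarray:
    """Expected cell number per mutant at time t (unit initial abundance)."""
    out = np.empty(len(truth))
    for i, g in enumerate(truth):
        ti = g.arrest_time(cfg.k0)
        grown = min(t, ti)
        out[i] = math.exp(cfg.k0 * grown + cfg.residual_rate * cfg.k0 * max(0.0, t - ti))
    return out


def simulate_tfnseq(
    truth: list[TrueGene],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate an insertion-library count matrix (genes x timepoints).

    Reads at each timepoint are multinomial over genes with probabilities
    proportional to the expected cell numbers; initial abundances are
    log-normal with ln-sd ``cfg.abundance_sigma``.  Column labels are the
    sampling times in hours.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    times = np.asarray(cfg.timepoints, dtype=float)
    n0 = np.exp(rng.normal(0.0, cfg.abundance_sigma, size=len(truth))) if cfg.abundance_sigma > 0 else np.ones(len(truth))
    counts = np.zeros((len(truth), times.size), dtype=np.int64)
    for j, t in enumerate(times):
        n = n0 * expected_cell_number(truth, cfg, float(t))
        p = n / n.sum()
        counts[:, j] = rng.multinomial(cfg.depth, p)
    return pd.DataFrame(counts, index=[g.gene_id for g in truth], columns=times)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0.0:
        return min(max(mean, lo), hi)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    return min(max(mean, lo), hi)


def simulate_microcolony(
    o_true: float,
    k0: float,
    cfg: SimConfig,
    t_max: float,
    rng: np.random.Generator | None = None,
) -> LineageTree:
    """Simulate one knockout-depletion microcolony as a lineage tree.

    The arrest threshold concentration is the unit of concentration and the
    progenitor area the unit of area, so the progenitor starts at
    concentration ``o_true``.  Cells grow exponentially in area at ``k0``
    while their concentration exceeds 1, divide when their area doubles
    (protein split between daughters proportionally to a noisy area split,
    conserving the total amount exactly), and grow at
    ``cfg.residual_rate * k0`` once diluted below threshold.  Tracks are
    sampled on the fixed frame grid ``cfg.frame_interval_h``.
    """
    if o_true < 1.0:
        raise ValueError("o_true must be >= 1 (endogenous level at or above threshold)")
    if not np.isfinite(k0) or k0 <= 0:
        raise ValueError("k0 must be a finite positive rate")
    dt = cfg.frame_interval_h
    if t_max < dt:
        raise ValueError("t_max shorter than one frame interval")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    c_a = 1.0
    a0 = 1.0
    tracks: dict[str, CellTrack] = {}
    edges: list[tuple[str, str]] = []
    # cell record: (id, parent, t_birth, birth area, protein amount)
    queue: list[tuple[str, str | None, float, float, float]] = [("c0", None, 0.0, a0, o_true * c_a * a0)]
    serial = 0
    while queue:
        cid, parent, t0, ab, w = queue.pop()
        conc0 = w / ab
        t_div = t0 + LN2 / k0
        # area at which concentration hits the threshold: a = w / c_a
        t_thr = t0 + math.log(w / (c_a * ab)) / k0 if conc0 > c_a else t0
        arrested = conc0 <= c_a * (1.0 + 1e-12)
        divides = (not arrested) and (t_div <= t_thr + 1e-12) and (t_div <= t_max)
        t_arrest = None
        if arrested:
            t_arrest = t0
        elif not divides and t_thr <= t_max:
            t_arrest = t_thr

        t_end = t_div if divides else t_max
        # frame ownership: [t0, t_div) for dividers, [t0, t_max] for leaves
        i_first = int(math.ceil(t0 / dt - 1e-9))
        i_last = int(math.floor(t_end / dt + (1e-9 if not divides else -1e-9)))
        frames = np.arange(i_first, i_last + 1)
        times = frames * dt
        if times.size == 0:
            times = np.array([t0])
        areas = np.empty_like(times)
        for i, t in enumerate(times):
            if t_arrest is not None and t >= t_arrest:
                a_arr = ab * math.exp(k0 * (t_arrest - t0))
                areas[i] = a_arr * math.exp(cfg.residual_rate * k0 * (t - t_arrest))
            else:
                areas[i] = ab * math.exp(k0 * (t - t0))
        fluor = np.full_like(times, w)
        tracks[cid] = CellTrack(cid, parent, times, areas, fluor=fluor,
                                arrested=t_arrest is not None, t_arrest=t_arrest)
        if parent is not None:
            edges.append((parent, cid))
        if divides:
            a_div = 2.0 * ab
            f_area = _trunc_normal(rng, 0.5, 0.5 * cfg.partition_cv, 0.2, 0.8)
            f_prot = _trunc_normal(rng, f_area, 0.5 * cfg.partition_cv, 0.02, 0.98)
            serial += 1
            d1 = f"c{serial}"
            serial += 1
            d2 = f"c{serial}"
            queue.append((d1, cid, t_div, f_area * a_div, f_prot * w))
            queue.append((d2, cid, t_div, (1.0 - f_area) * a_div, (1.0 - f_prot) * w))
    return LineageTree(progenitor_id="c0", tracks=tracks, edges=edges)


def simulate_rnaseq(
    truth: list[TrueGene],
    total_reads: int,
    seed: int = 0,
) -> pd.Series:
    """Multinomial RNA-seq counts proportional to each gene's message number."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not truth:
        raise ValueError("truth must be non-empty")
    mu = np.array([g.mu_m for g in truth], dtype=float)
    if mu.sum() <= 0:
        raise ValueError("all message numbers are zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(total_reads), mu / mu.sum())
    return pd.Series(counts, index=[g.gene_id for g in truth], name="count")


def simulate_genome(
    n_genes: int = 200,
    seed: int = 0,
    frac_essential: float = 0.3,
    frac_overabundant: float = 0.69,
    frac_nonessential_defect: float = 0.10,
    mu_log_mean: float = math.log(10.0),
    mu_log_sigma: float = 1.5,
    o_noise_sigma: float = 0.3,
    epsilon: float = 1e-4,
    include_anchors: bool = True,
) -> list[TrueGene]:
    """Draw a synthetic genome whose essential genes sit near the optimal
    overabundance curve.

    Message numbers are log-normal (median 10 messages/cycle, ~2 decades of
    spread).  Each essential gene gets a candidate ``log10 o = log10
    o*(mu_m)`` plus log-normal scatter of ``o_noise_sigma`` decades; the
    lowest-candidate fraction ``1 - frac_overabundant`` — the highly
    expressed genes whose optimum sits near unity — is the sufficiency
    class (o = 1), the remainder keep their candidate as overabundance.
    Expression level and class are therefore anti-correlated, as the
    trade-off itself dictates: a gene's excess is undetectable precisely
    when its optimal excess is small.  Overabundance values are floored at
    twofold so the two classes stay operationally distinct.  Nonessential
    genes are no-effect except a ``frac_nonessential_defect`` fraction with
    an immediate mild growth defect (modelled as sufficiency-class
    dynamics).
    """
    from .rlto import optimal_overabundance

    rng = np.random.default_rng(seed)
    genes: list[TrueGene] = []
    if include_anchors:
        genes.extend(ANCHOR_GENES)
    n_rest = n_genes - len(genes)
    if n_rest < 0:
        raise ValueError("n_genes smaller than the anchor set")
    n_ess_total = int(round(frac_essential * n_genes))
    n_ess = max(0, n_ess_total - len(genes))

    mu_all = np.exp(rng.normal(mu_log_mean, mu_log_sigma, size=n_rest))
    ess_mu = mu_all[:n_ess]
    if n_ess:
        pred = optimal_overabundance(np.sort(np.unique(np.clip(ess_mu, 0.3, None))), epsilon=epsilon)
        log10_o_cand = np.array(
            [
                math.log10(float(np.interp(max(float(mu), 0.3), pred.mu_m_grid, pred.o_star)))
                for mu in ess_mu
            ]
        ) + rng.normal(0.0, o_noise_sigma, size=n_ess)
        n_suff = int(round((1.0 - frac_overabundant) * n_ess))
        # sufficiency = the n_suff genes with the smallest candidate excess
        suff_idx = set(np.argsort(log10_o_cand, kind="stable")[:n_suff].tolist())
    for i in range(n_ess):
        mu = float(ess_mu[i])
        if i in suff_idx:
            genes.append(TrueGene(f"ess{i:04d}", True, "sufficiency", 0.0, mu))
        else:
            log10_o = max(float(log10_o_cand[i]), math.log10(2.0))
            genes.append(TrueGene(f"ess{i:04d}", True, "overabundance", log10_o, mu))
    for i, mu in enumerate(mu_all[n_ess:]):
        if rng.random() < frac_nonessential_defect:
            genes.append(TrueGene(f"non{i:04d}", False, "sufficiency", 0.0, float(mu)))
        else:
            genes.append(TrueGene(f"non{i:04d}", False, "no_effect", 0.0, float(mu)))
    return genes


_GROUPS = ("autoregulatory", "highly_regulated", "unregulated", "atpase", "enzyme", "dna_binding")


def annotation_table(truth: list[TrueGene], seed: int = 0) -> pd.DataFrame:
    """Gene annotation table (essentiality plus random category labels).

    Category membership is plumbing for the group-statistics stage; real
    analyses supply a curated table with the same columns.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in truth:
        groups = [lbl for lbl in _GROUPS if g.essential and rng.random() < 0.15]
        rows.append({"gene_id": g.gene_id, "essential": g.essential, "groups": ",".join(groups)})
    return pd.DataFrame(rows)


def truth_table(truth: list[TrueGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in truth],
            "essential": [g.essential for g in truth],
            "class_true": [g.class_true for g in truth],
            "log10_o_true": [g.log10_o_true for g in truth],
            "mu_m": [g.mu_m for g in truth],
        }
    )
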