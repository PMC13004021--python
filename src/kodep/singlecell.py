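"""Single-cell reconstruction of growth rate, concentration and overabundance.

A knockout-depletion microcolony is observed as a set of cell tracks (area,
optionally total fluorescence, versus time) linked by parentage.  Because
target-protein synthesis stops at the knockout, the protein pool of the
progenitor is only diluted by growth: the relative concentration over the
whole colony obeys ``C(t)/C0 = V0/V(t)`` with ``V`` the total progeny area.
Pairing that dilution coordinate with the single-cell areal growth rate
``k(t) = d ln A / dt`` traces out the fitness landscape, and the location of
the growth-arrest threshold gives the protein overabundance
``o = C0 / C_A``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "CellTrack",
    "LineageTree",
    "FitnessLandscape",
    "ArrestEstimate",
    "areal_growth_rate",
    "relative_concentration",
    "fitness_landscape",
    "arrest_time",
    "progenitor_spread",
]


@dataclass
class CellTrack:
    """Area (and optional fluorescence) time series for one cell.

    ``fluor`` is the total fluorescence of the cell (a protein-amount proxy),
    not a concentration; divide by ``areas`` for concentration.  ``t_arrest``
    is generator ground truth and is ``None`` for real data.
    """

    cell_id: str
    parent_id: str | None
    times: np.ndarray
    areas: np.ndarray
    fluor: np.ndarray | None = None
    arrested: bool = False
    t_arrest: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.fluor is not None:
            self.fluor = np.asarray(self.fluor, dtype=float)
            if self.fluor.shape != self.times.shape:
                raise ValueError(f"cell {self.cell_id}: fluor/times length mismatch")
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError(f"cell {self.cell_id}: empty track")
        if self.areas.shape != self.times.shape:
            raise ValueError(f"cell {self.cell_id}: areas/times length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"cell {self.cell_id}: times not strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


@dataclass
class LineageTree:
    """A single microcolony: one progenitor and its progeny tracks."""

    progenitor_id: str
    tracks: dict[str, CellTrack]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.progenitor_id not in self.tracks:
            raise ValueError("progenitor track missing from tree")
        g = nx.DiGraph()
        g.add_nodes_from(self.tracks)
        g.add_edges_from(self.edges)
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if roots != [self.progenitor_id] and set(roots) != {self.progenitor_id}:
            raise ValueError(f"tree must have the single root {self.progenitor_id!r}, got roots {roots}")
        if any(g.in_degree(n) > 1 for n in g.nodes):
            raise ValueError("a cell has more than one parent")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("lineage graph contains a cycle")
        for parent, child in self.edges:
            p, c = self.tracks[parent], self.tracks[child]
            if c.times[0] < p.times[-1] - 1e-9:
                raise ValueError(f"cell {child} starts before its parent {parent} ends")

    def children(self, cell_id: str) -> list[str]:
        return [c for p, c in self.edges if p == cell_id]

    def frame_grid(self) -> np.ndarray:
        """Sorted union of all observation times (duplicates merged)."""
        t = np.sort(np.concatenate([tr.times for tr in self.tracks.values()]))
        keep = np.ones(t.size, dtype=bool)
        keep[1:] = np.diff(t) > 1e-9
        return t[keep]

    def total_area(self) -> tuple[np.ndarray, np.ndarray]:
        """(grid, V) with V the summed area of cells alive at each grid time."""
        grid = self.frame_grid()
        v = np.zeros_like(grid)
        n = np.zeros_like(grid)
        for tr in self.tracks.values():
            idx = np.searchsorted(grid, tr.times[0] - 1e-9)
            sl = slice(idx, idx + tr.n_frames)
            if not np.allclose(grid[sl], tr.times, atol=1e-8):
                # tracks on a ragged grid: accumulate frame by frame
                for t_i, a_i in zip(tr.times, tr.areas):
                    j = int(np.argmin(np.abs(grid - t_i)))
                    v[j] += a_i
                    n[j] += 1
                continue
            v[sl] += tr.areas
            n[sl] += 1
        if np.any(n == 0):
            bad = grid[n == 0]
            raise ValueError(f"no progeny exists at frame time(s) {bad[:3]}...")
        return grid, v

    def cell_count(self) -> tuple[np.ndarray, np.ndarray]:
        grid = self.frame_grid()
        n = np.zeros_like(grid)
        for tr in self.tracks.values():
            n += (grid >= tr.times[0] - 1e-9) & (grid <= tr.times[-1] + 1e-9)
        return grid, n


@dataclass
class FitnessLandscape:
    """Paired (relative concentration, growth rate) samples with threshold fit."""

    rel_conc: np.ndarray
    growth_rate: np.ndarray
    arrest_conc: float
    o_hat: float
    censored: bool
    k_plateau: float
    k_floor: float
    plateau_slope: float = np.nan
    plateau_slope_se: float = np.nan

    def to_sidecar(self) -> dict:
        return {
            "o_hat": self.o_hat,
            "arrest_conc": self.arrest_conc,
            "censored": self.censored,
            "k_plateau": self.k_plateau,
            "k_floor": self.k_floor,
        }


@dataclass
class ArrestEstimate:
    metric: str
    t_arrest: float
    o: float
    k0_est: float


def _window_slope(t: np.ndarray, y: np.ndarray, i: int, window: int) -> float:
    half = window // 2
    lo = max(0, i - half)
    hi = min(t.size, i + half + 1)
    if hi - lo < max(2, window - half):  # one-sided window at the ends
        hi = min(t.size, lo + window)
        lo = max(0, hi - window)
    tt, yy = t[lo:hi], y[lo:hi]
    tm, ym = tt.mean(), yy.mean()
    denom = np.sum((tt - tm) ** 2)
    return float(np.sum((tt - tm) * (yy - ym)) / denom)


def areal_growth_rate(track: CellTrack, window: int = 5) -> np.ndarray:
    """Areal growth rate k(t) = d ln A/dt by windowed least squares.

    The slope of a centred least-squares line through ln A(t) is returned at
    every frame; endpoints fall back to one-sided windows of the same width.
    Exactly exponential tracks give the exact rate (to round-off).
    """
    if window < 3:
        raise ValueError("window must be >= 3 frames")
    if track.n_frames < window:
        raise ValueError(f"cell {track.cell_id}: track has {track.n_frames} < window={window} points")
    bad = np.flatnonzero(track.areas <= 0)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"cell {track.cell_id}: non-positive area at frame {i} (t={track.times[i]:g})"
        )
    ln_a = np.log(track.areas)
    return np.array([_window_slope(track.times, ln_a, i, window) for i in range(track.n_frames)])


def relative_concentration(tree: LineageTree, ref_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Dilution-model relative concentration C(t)/C0 = V0/V(t).

    ``V(t)`` is the total progeny area on the colony frame grid and ``V0`` the
    progenitor area at the knockout reference frame (first frame by default;
    ``ref_index`` moves it when the knockout predates the first image).
    Returns ``(grid_times, C/C0)``.
    """
    grid, v = tree.total_area()
    prog = tree.tracks[tree.progenitor_id]
    if not 0 <= ref_index < prog.n_frames:
        raise ValueError("ref_index outside the progenitor track")
    v0 = prog.areas[ref_index]
    return grid, v0 / v


def _smoothed_log_slope(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    ln_y = np.log(y)
    return np.array([_window_slope(t, ln_y, i, window) for i in range(t.size)])


def _plateau_rate(rate: np.ndarray) -> float:
    """Pre-arrest plateau estimate: median of the near-maximal rate values."""
    top = rate >= 0.75 * rate.max()
    return float(np.median(rate[top])) if top.any() else float(np.median(rate))


def fitness_landscape(tree: LineageTree, window: int = 5, min_segment: int | None = None) -> FitnessLandscape:
    """Reconstruct the threshold fitness landscape of one microcolony.

    Every cell-frame growth rate is paired with the colony-level dilution
    coordinate C/C0 at that frame.  A two-level changepoint model (plateau
    above the arrest concentration, floor below it) is fitted by least squares
    over the changepoint grid; the overabundance estimate is
    ``o_hat = C0/C_A = 1/arrest_conc``.

    When no rate change is detectable the result is censored: colonies that
    grew are reported with the dilution lower bound ``o_hat >= V(t_max)/V0``;
    colonies that never achieved a single doubling are treated as arrested at
    the start (``o_hat = 1``).
    """
    grid, relc = relative_concentration(tree)
    pairs_c, pairs_k = [], []
    for tr in tree.tracks.values():
        if tr.n_frames < window:
            continue
        k = areal_growth_rate(tr, window=window)
        idx = np.searchsorted(grid, tr.times[0] - 1e-9)
        pairs_c.append(relc[idx : idx + tr.n_frames])
        pairs_k.append(k)
    rc = np.concatenate(pairs_c)
    kk = np.concatenate(pairs_k)
    order = np.argsort(rc)
    rc_s, kk_s = rc[order], kk[order]
    n = rc_s.size
    min_seg = max(window, 5) if min_segment is None else min_segment

    # least-squares two-mean changepoint via prefix sums
    cs = np.cumsum(kk_s)
    cs2 = np.cumsum(kk_s**2)
    best = (np.inf, None)
    for s in range(min_seg, n - min_seg + 1):
        lo_ss = cs2[s - 1] - cs[s - 1] ** 2 / s
        hi_n = n - s
        hi_sum = cs[-1] - cs[s - 1]
        hi_ss = (cs2[-1] - cs2[s - 1]) - hi_sum**2 / hi_n
        sse = lo_ss + hi_ss
        if sse < best[0]:
            best = (sse, s)
    grid_v0_vmax = float((tree.total_area()[1][-1]) / tree.tracks[tree.progenitor_id].areas[0])

    detected = False
    if best[1] is not None:
        s = best[1]
        k_lo = float(kk_s[:s].mean())
        k_hi = float(kk_s[s:].mean())
        c_hat = float(0.5 * (rc_s[s - 1] + rc_s[s]))
        detected = k_hi > 0 and k_lo < 0.5 * k_hi and c_hat < 1.0
    if detected:
        # plateau flatness is assessed away from the transition band: the
        # windowed rate estimates within ~half a window of an arrest mix
        # pre- and post-arrest growth, and asynchronous arrests place some
        # of those frames just above the fitted threshold
        hi_mask = rc_s >= 1.5 * c_hat
        slope = se = np.nan
        if np.unique(rc_s[hi_mask]).size > 2:
            fit = stats.linregress(rc_s[hi_mask], kk_s[hi_mask])
            slope, se = float(fit.slope), float(fit.stderr)
        return FitnessLandscape(
            rel_conc=rc, growth_rate=kk, arrest_conc=c_hat, o_hat=1.0 / c_hat,
            censored=False, k_plateau=k_hi, k_floor=k_lo,
            plateau_slope=slope, plateau_slope_se=se,
        )
    # no detectable rate change
    if grid_v0_vmax >= 2.0:  # still growing at the end of the movie
        return FitnessLandscape(
            rel_conc=rc, growth_rate=kk, arrest_conc=1.0 / grid_v0_vmax,
            o_hat=grid_v0_vmax, censored=True,
            k_plateau=float(kk.mean()), k_floor=np.nan,
        )
    # never achieved a doubling: arrested from the start
    return FitnessLandscape(
        rel_conc=rc, growth_rate=kk, arrest_conc=1.0, o_hat=1.0, censored=False,
        k_plateau=float(kk.mean()), k_floor=float(kk.mean()),
    )


def arrest_time(
    tree: LineageTree,
    metric: str = "elongation",
    frac: float = 0.5,
    window: int = 5,
    persist: int = 3,
    k0: float | None = None,
) -> ArrestEstimate:
    """Arrest time of a microcolony by elongation or septation.

    elongation
        first time the smoothed total-area log-slope falls below
        ``frac * k0`` and stays below for ``persist`` frames;
    septation
        the same criterion applied to the cell-count log-slope.  Because the
        count series is a staircase (slope zero between division events), the
        count slope is measured over a trailing window of one generation
        (ln 2 / k0) and the window lag is subtracted from the crossing time;
        a colony whose divisions stop while elongation continues therefore
        shows septation arrest before elongation arrest.

    ``k0`` defaults to the per-colony pre-arrest plateau of the total-area
    rate, keeping the imaging branch independent of the sequencing config.
    Both metrics report the dilution overabundance ``o = V(t_A)/V0``.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    grid, v = tree.total_area()
    if grid.size < window:
        raise ValueError("colony observed for fewer frames than the smoothing window")
    area_rate = _smoothed_log_slope(grid, v, window)
    k0_est = float(k0) if k0 is not None else _plateau_rate(area_rate)

    lag = 0.0
    if metric == "elongation":
        rate = area_rate
    elif metric == "septation":
        if len(tree.edges) == 0:
            raise ValueError("septation metric requires division events, but the tree has none")
        _, counts = tree.cell_count()
        gen = math.log(2.0) / k0_est
        dt = float(np.median(np.diff(grid)))
        k = max(1, int(round(gen / dt)))
        ln_n = np.log(counts)
        rate = np.full(grid.size, np.nan)
        rate[k:] = (ln_n[k:] - ln_n[:-k]) / (grid[k:] - grid[:-k])
        rate[:k] = rate[k] if grid.size > k else np.nan
        lag = k * dt
    else:
        raise ValueError(f"unknown arrest metric {metric!r}")

    below = rate < frac * k0_est
    idx = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= persist:
            idx = i - persist + 1
            break
    if idx is None:
        raise ValueError(f"no {metric} arrest detected (rate never stays below frac*k0)")
    t_a = max(float(grid[0]), float(grid[idx]) - lag)
    j = int(np.argmin(np.abs(grid - t_a)))
    v0 = tree.tracks[tree.progenitor_id].areas[0]
    return ArrestEstimate(metric=metric, t_arrest=float(grid[j]), o=float(v[j] / v0), k0_est=k0_est)


def progenitor_spread(trees: list[LineageTree], metric: str = "elongation", **kw) -> dict:
    """Arrest-time spread between distinct progenitor cells.

    Errors on imaging-based overabundances are reported as the variance
    between arrest times of independent progenitors.
    """
    ests = [arrest_time(t, metric=metric, **kw) for t in trees]
    log_o = np.log10([e.o for e in ests])
    return {
        "n_progenitors": len(ests),
        "log10_o_mean": float(np.mean(log_o)),
        "log10_o_sd": float(np.std(log_o, ddof=1)) if len(ests) > 1 else 0.0,
        "t_arrest": [e.t_arrest for e in ests],
    }


def write_landscape(fl: FitnessLandscape, path: str | Path) -> None:
    """Write the (rel_conc, k) table as TSV plus a JSON sidecar of estimates."""
    path = Path(path)
    import pandas as pd

    pd.DataFrame({"rel_conc": fl.rel_conc, "k": fl.growth_rate}).to_csv(path, sep="\t", index=False)
    path.with_suffix(".json").write_text(json.dumps(fl.to_sidecar(), indent=2, sort_keys=True))
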