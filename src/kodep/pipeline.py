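"""End-to-end pipeline: synthetic library -> trajectory calls -> genome-wide
synthesis -> optimality overlay, with a reproducibility manifest.

The demo mode generates every input itself (two library replicates, RNA-seq,
annotation), so the whole analysis runs from a single config file with no
external data.  All randomness is funnelled through per-stage seeds derived
from the one config seed; rerunning an identical config byte-identically
reproduces the manifest and outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, compare, io, rlto, synth, tfnseq

__all__ = ["PipelineError", "default_config", "run_pipeline", "validate_tables"]

REQUIRED_KEYS = ("k0", "M_total", "alpha1", "alpha2", "seed")


class PipelineError(ValueError):
    """Configuration or stage failure; carries the stage/key name."""


def default_config() -> dict:
    """Demo configuration (synthetic end-to-end run)."""
    return {
        "mode": "demo",
        "seed": 0,
        "n_genes": 200,
        "depth": 200_000,
        "timepoints": [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
        "k0": 1.0,
        "residual_rate": 0.05,
        "partition_cv": 0.05,
        "n_replicates": 2,
        "M_total": 4000.0,
        "total_reads": 2_000_000,
        "alpha1": 1e-4,
        "alpha2": 1e-4,
        "min_count0": 20,
        "epsilon": 1e-4,
        "mu_grid": [0.3, 1000.0, 60],
        "quantile_bins": 10,
        "bins_per_decade": 4,
        "frac_essential": 0.3,
        "frac_overabundant": 0.69,
    }


def _require(cfg: dict) -> None:
    for key in REQUIRED_KEYS:
        if key not in cfg:
            raise PipelineError(f"config missing required key: {key}")


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the full knockout-depletion analysis and write a report bundle.

    Stages: synthetic genome + library/RNA-seq generation (demo mode),
    per-replicate trajectory classification, replicate merging, genome-wide
    synthesis (message numbers, trends, subgroup tests, summary statistics,
    density grid) and the optimal-overabundance curve.  Returns the manifest
    dict; every table is written as TSV under ``outdir``.
    """
    _require(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dict(default_config(), **config)
    seed = int(cfg["seed"])
    k0 = float(cfg["k0"])

    # --- stage: synth ---------------------------------------------------
    try:
        truth = synth.simulate_genome(
            n_genes=int(cfg["n_genes"]), seed=seed,
            frac_essential=float(cfg["frac_essential"]),
            frac_overabundant=float(cfg["frac_overabundant"]),
            epsilon=float(cfg["epsilon"]),
        )
        truth_df = synth.truth_table(truth).set_index("gene_id")
        annotation = synth.annotation_table(truth, seed=seed + 1)
        rep_counts = []
        for r in range(int(cfg["n_replicates"])):
            sim_cfg = synth.SimConfig(
                k0=k0, timepoints=tuple(float(t) for t in cfg["timepoints"]),
                depth=int(cfg["depth"]), n_genes=int(cfg["n_genes"]),
                seed=seed + 10 + r, partition_cv=float(cfg["partition_cv"]),
                residual_rate=float(cfg["residual_rate"]),
            )
            counts = synth.simulate_tfnseq(truth, sim_cfg)
            io.write_counts(counts, outdir / f"counts_rep{r + 1}.tsv")
            rep_counts.append(counts)
        rna = synth.simulate_rnaseq(truth, int(cfg["total_reads"]), seed=seed + 50)
        rna.rename_axis("gene_id").to_frame().to_csv(outdir / "rnaseq.tsv", sep="\t")
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        truth_df.to_csv(outdir / "truth_synthetic.tsv", sep="\t")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage synth failed: {exc}") from exc

    # --- stage: tfnseq --------------------------------------------------
    try:
        results = []
        for r, counts in enumerate(rep_counts):
            res = tfnseq.fit_library(
                counts, k0=k0, alpha1=float(cfg["alpha1"]), alpha2=float(cfg["alpha2"]),
                min_count0=int(cfg["min_count0"]),
            )
            res.calls.to_csv(outdir / f"calls_rep{r + 1}.tsv", sep="\t")
            res.dropped.to_csv(outdir / f"dropped_rep{r + 1}.tsv", sep="\t", index=False)
            results.append(res)
        if len(results) >= 2:
            merged = tfnseq.replicate_error([r.calls for r in results])
            merged.to_csv(outdir / "calls.tsv", sep="\t")
        else:
            results[0].calls.to_csv(outdir / "calls.tsv", sep="\t")
        fractions = tfnseq.class_fractions(results[0].calls, essential=truth_df["essential"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage tfnseq failed: {exc}") from exc

    # --- stage: compare -------------------------------------------------
    try:
        mu_hat = compare.message_number(rna, float(cfg["M_total"]))
        rep1 = results[0].calls
        records = compare.merge_records(rep1, mu_hat, annotation)
        records.to_csv(outdir / "records.tsv", sep="\t")
        called = records[records["o"].notna() & (records["essential"] == True)]  # noqa: E712
        trends = {}
        for method, fname in (("quantile", "trend_quantile.tsv"), ("log_width", "trend_logwidth.tsv")):
            tb = compare.trend_bins(
                called["mu_m_hat"].to_numpy(), called["o"].to_numpy(), method=method,
                n_bins=int(cfg["quantile_bins"]), bins_per_decade=int(cfg["bins_per_decade"]),
                seed=seed + 60,
            )
            tb.to_csv(outdir / fname, sep="\t", index=False)
            trends[method] = tb
        group_rows = []
        ref = called["o"].to_numpy()
        labels = sorted({g for gs in called["groups"] for g in str(gs).split(",") if g})
        for lbl in labels:
            sub = called[called["groups"].str.contains(lbl, regex=False)]["o"].to_numpy()
            if sub.size >= 3:
                res = compare.group_test(sub, ref)
                group_rows.append({"group": lbl, **res})
        pd.DataFrame(group_rows).to_csv(outdir / "group_stats.tsv", sep="\t", index=False)
        summary = compare.summary_stats(records)
        kde = compare.kde_overlay(called["mu_m_hat"].to_numpy(), called["o"].to_numpy())
        pd.DataFrame(kde["density"], index=kde["log10_o"], columns=kde["log10_mu_m"]).to_csv(
            outdir / "kde_grid.tsv", sep="\t"
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage compare failed: {exc}") from exc

    # --- stage: rlto ----------------------------------------------------
    try:
        lo, hi, n = cfg["mu_grid"]
        mu_grid = np.logspace(np.log10(float(lo)), np.log10(float(hi)), int(n))
        pred = rlto.optimal_overabundance(mu_grid, epsilon=float(cfg["epsilon"]))
        pd.DataFrame({"mu_m": pred.mu_m_grid, "o_star": pred.o_star, "F_max": pred.f_max}).to_csv(
            outdir / "rlto_curve.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage rlto failed: {exc}") from exc

    summary_all = {
        "summary": summary,
        "class_fractions": fractions,
        "rlto_mu_m_min": pred.mu_m_min,
        "n_dropped": int(sum(len(r.dropped) for r in results)),
    }
    (outdir / "summary.json").write_text(json.dumps(summary_all, indent=2, sort_keys=True))

    manifest = {
        "package": "kodep",
        "version": __version__,
        "config": cfg,
        "config_sha256": _hash_config(cfg),
        "seeds": {"genome": seed, "annotation": seed + 1,
                  "replicates": [seed + 10 + r for r in range(int(cfg["n_replicates"]))],
                  "rnaseq": seed + 50, "bootstrap": seed + 60},
        "thresholds": {"alpha1": cfg["alpha1"], "alpha2": cfg["alpha2"],
                       "min_count0": cfg["min_count0"], "epsilon": cfg["epsilon"]},
        "outputs": sorted(p.name for p in outdir.iterdir() if p.suffix in (".tsv", ".json") and p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _check_counts(path: Path, diags: list) -> None:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        diags.append({"table": path.name, "row": 0, "column": df.columns[0],
                      "message": "first column must be gene_id"})
        return
    times = []
    for c in df.columns[1:]:
        try:
            times.append(float(str(c).removeprefix("t=")))
        except ValueError:
            diags.append({"table": path.name, "row": 0, "column": c,
                          "message": f"malformed time column header {c!r}"})
            return
    if any(b <= a for a, b in zip(times, times[1:])):
        diags.append({"table": path.name, "row": 0, "column": "*",
                      "message": "time columns not strictly increasing"})
    mat = df.iloc[:, 1:]
    neg = np.argwhere(mat.to_numpy() < 0)
    if neg.size:
        r, c = neg[0]
        diags.append({"table": path.name, "row": int(r) + 1, "column": mat.columns[c],
                      "message": "negative count"})


def _check_tracks(path: Path, diags: list) -> None:
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "parent_id", "frame", "time_h", "area"}
    missing = required - set(df.columns)
    if missing:
        diags.append({"table": path.name, "row": 0, "column": ",".join(sorted(missing)),
                      "message": "missing required column(s)"})
        return
    bad_area = df.index[df["area"] <= 0]
    for i in bad_area[:5]:
        diags.append({"table": path.name, "row": int(i) + 1, "column": "area",
                      "message": f"non-positive area for cell {df.loc[i, 'cell_id']}"})
    for cid, sub in df.groupby("cell_id"):
        t = sub.sort_values("frame")["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            diags.append({"table": path.name, "row": int(sub.index[0]) + 1, "column": "time_h",
                          "message": f"times not strictly increasing for cell {cid}"})


def validate_tables(paths: dict[str, str | Path]) -> list[dict]:
    """Schema/monotonicity/invariant diagnostics for pipeline input tables.

    ``paths`` maps table kind (``counts``, ``tracks``, ``annotation``) to a
    file path.  Returns machine-readable diagnostics (empty when all tables
    are well formed); missing files raise.
    """
    diags: list[dict] = []
    for kind, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        if kind.startswith("counts"):
            _check_counts(p, diags)
        elif kind.startswith("tracks"):
            _check_tracks(p, diags)
        elif kind.startswith("annotation"):
            df = pd.read_csv(p, sep="\t")
            for col in ("gene_id", "essential"):
                if col not in df.columns:
                    diags.append({"table": p.name, "row": 0, "column": col,
                                  "message": "missing required column"})
        else:
            diags.append({"table": p.name, "row": 0, "column": "*",
                          "message": f"unknown table kind {kind!r}"})
    return diags
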