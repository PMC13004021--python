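"""Readers and writers for the pipeline's tab-separated interchange formats.

Count matrices: first column ``gene_id``, remaining columns ``t=<hours>``;
replicates live in separate files suffixed ``_rep<k>``.  Track tables:
``cell_id, parent_id, frame, time_h, area, fluor_total, arrested`` with an
empty parent for the progenitor.  Configuration is a single declarative
YAML file of ``key: value`` pairs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .singlecell import CellTrack, LineageTree

__all__ = [
    "write_counts",
    "read_counts",
    "write_tracks",
    "read_tracks",
    "read_config",
    "write_config",
]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.columns = [f"t={float(c):g}" for c in counts.columns]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.columns = [float(str(c).removeprefix("t=")) for c in df.columns]
    return df


def write_tracks(tree: LineageTree, path: str | Path) -> None:
    rows = []
    for cid in sorted(tree.tracks):
        tr = tree.tracks[cid]
        for i, (t, a) in enumerate(zip(tr.times, tr.areas)):
            rows.append(
                {
                    "cell_id": cid,
                    "parent_id": tr.parent_id if tr.parent_id is not None else "",
                    "frame": i,
                    "time_h": t,
                    "area": a,
                    "fluor_total": tr.fluor[i] if tr.fluor is not None else "",
                    "arrested": int(tr.arrested),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tracks(path: str | Path) -> LineageTree:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "parent_id": str})
    df["parent_id"] = df["parent_id"].fillna("")
    tracks: dict[str, CellTrack] = {}
    edges = []
    root = None
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        parent = sub["parent_id"].iloc[0] or None
        fluor = None
        if "fluor_total" in sub.columns and not sub["fluor_total"].isna().all():
            fluor = sub["fluor_total"].to_numpy(dtype=float)
        arrested = bool(sub["arrested"].iloc[0]) if "arrested" in sub.columns else False
        tracks[cid] = CellTrack(cid, parent, sub["time_h"].to_numpy(dtype=float),
                                sub["area"].to_numpy(dtype=float), fluor=fluor, arrested=arrested)
        if parent is None:
            root = cid
        else:
            edges.append((parent, cid))
    if root is None:
        raise ValueError(f"{path}: no progenitor (cell with empty parent_id) found")
    return LineageTree(progenitor_id=root, tracks=tracks, edges=edges)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of key: value pairs")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
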