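"""Clustering statistic on complex-position snapshots, and sweep heatmaps.

Clustering is quantified as the percentage of complexes having at least one
other complex strictly closer than a distance threshold (default 3 µm), and
the fold change of that percentage between the post-addition snapshot and
the final snapshot of a run.  Because "percentage of short-distance
complexes" can also be read per-pair, the per-pair percentage is computed
and reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import GridError, MissingSnapshotError
from .sim.record import SimRecord

DEFAULT_THRESHOLD_UM = 3.0


def pairwise_distances(positions) -> np.ndarray:
    """Symmetric Euclidean distance matrix of a set of 2-D points."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 1 or pos.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array with n >= 1, got shape {pos.shape}")
    if pos.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pos))


def short_distance_percentage(
    positions, threshold: float = DEFAULT_THRESHOLD_UM, per_pair: bool = False
) -> float:
    """Percentage of complexes with a neighbor strictly closer than ``threshold``.

    With ``per_pair=True``, instead the percentage of unordered pairs at
    distance < threshold.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = pairwise_distances(pos)
    if per_pair:
        iu = np.triu_indices(len(pos), k=1)
        return 100.0 * float(np.mean(d[iu] < threshold))
    np.fill_diagonal(d, np.inf)
    return 100.0 * float(np.mean(np.min(d, axis=1) < threshold))


@dataclass
class ClusteringSummary:
    """Short-distance percentages at the start/end snapshots and their ratio."""

    threshold: float
    t_start: float
    t_end: float
    pct_short_t_start: float
    pct_short_t_end: float
    fold_change: float              # nan when undefined
    undefined: bool = False         # True when pct_short_t_start == 0
    pct_pair_t_start: float = float("nan")
    pct_pair_t_end: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "threshold_um": self.threshold,
            "t_start_s": self.t_start,
            "t_end_s": self.t_end,
            "pct_short_t_start": self.pct_short_t_start,
            "pct_short_t_end": self.pct_short_t_end,
            "fold_change": self.fold_change,
            "undefined": self.undefined,
            "pct_pair_t_start": self.pct_pair_t_start,
            "pct_pair_t_end": self.pct_pair_t_end,
        }


def clustering_fold_change(
    record: SimRecord, threshold: float = DEFAULT_THRESHOLD_UM
) -> ClusteringSummary:
    """Fold change of the short-distance percentage between the post-addition
    and final snapshots of a run."""
    t_start = record.config.t_bundle
    t_end = record.config.t_total
    start = record.snapshot_at(t_start)
    end = record.snapshot_at(t_end)
    if len(start) < 2 or len(end) < 2:
        raise MissingSnapshotError(t_start if len(start) < 2 else t_end)
    p0 = short_distance_percentage(start, threshold)
    p1 = short_distance_percentage(end, threshold)
    undefined = p0 == 0.0
    return ClusteringSummary(
        threshold=threshold,
        t_start=t_start,
        t_end=t_end,
        pct_short_t_start=p0,
        pct_short_t_end=p1,
        fold_change=float("nan") if undefined else p1 / p0,
        undefined=undefined,
        pct_pair_t_start=short_distance_percentage(start, threshold, per_pair=True),
        pct_pair_t_end=short_distance_percentage(end, threshold, per_pair=True),
    )


@dataclass
class HeatmapGrid:
    """Mean fold change per (row, column) cell of a two-axis parameter sweep."""

    row_param: str
    col_param: str
    row_values: np.ndarray
    col_values: np.ndarray
    mean_fold_change: np.ndarray    # (n_rows, n_cols)
    n_replicates: np.ndarray        # (n_rows, n_cols) int
    record_ids: dict = field(default_factory=dict)  # (i, j) -> list of cell indices

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rv in enumerate(self.row_values):
            for j, cv in enumerate(self.col_values):
                rows.append(
                    {
                        self.row_param: rv,
                        self.col_param: cv,
                        "mean_fold_change": self.mean_fold_change[i, j],
                        "n_replicates": int(self.n_replicates[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path, render: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "heatmap.csv", index=False)
        if render:
            render_heatmap(self, out / "heatmap.png")


def build_heatmap(
    records: list[SimRecord],
    row_param: str,
    col_param: str,
    threshold: float = DEFAULT_THRESHOLD_UM,
) -> HeatmapGrid:
    """Aggregate tagged sweep records into a rectangular heatmap grid.

    Every record must carry ``row_param`` and ``col_param`` in its
    provenance; replicates (identical cell coordinates) are averaged.
    Undefined fold changes (zero baseline) are dropped from cell means.
    """
    if not records:
        raise GridError("no records supplied")
    for rec in records:
        for p in (row_param, col_param):
            if p not in rec.provenance:
                raise GridError(f"record missing provenance key {p!r}")
    row_values = np.array(sorted({rec.provenance[row_param] for rec in records}))
    col_values = np.array(sorted({rec.provenance[col_param] for rec in records}))
    shape = (len(row_values), len(col_values))
    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    ids: dict = {}
    for rec in records:
        i = int(np.searchsorted(row_values, rec.provenance[row_param]))
        j = int(np.searchsorted(col_values, rec.provenance[col_param]))
        summary = clustering_fold_change(rec, threshold)
        ids.setdefault((i, j), []).append(rec.provenance.get("cell_index", -1))
        if not summary.undefined:
            sums[i, j] += summary.fold_change
            counts[i, j] += 1
    missing = [
        (row_values[i], col_values[j])
        for i in range(shape[0])
        for j in range(shape[1])
        if (i, j) not in ids
    ]
    if missing:
        raise GridError(f"incomplete grid; missing cells: {missing}")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HeatmapGrid(
        row_param=row_param,
        col_param=col_param,
        row_values=row_values,
        col_values=col_values,
        mean_fold_change=means,
        n_replicates=counts,
        record_ids=ids,
    )


def render_heatmap(grid: HeatmapGrid, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid.mean_fold_change, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(grid.col_values)), [f"{v:g}" for v in grid.col_values])
    ax.set_yticks(range(len(grid.row_values)), [f"{v:g}" for v in grid.row_values])
    ax.set_xlabel(grid.col_param)
    ax.set_ylabel(grid.row_param)
    fig.colorbar(im, ax=ax, label="mean fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summaries_to_csv(
    records: list[SimRecord], path: str | Path, threshold: float = DEFAULT_THRESHOLD_UM
) -> pd.DataFrame:
    """One clustering summary row per record, written to ``clustering.csv``."""
    rows = []
    for rec in records:
        d = clustering_fold_change(rec, threshold).to_dict()
        d.update({f"prov_{k}": v for k, v in rec.provenance.items()})
        rows.append(d)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def positions_from_csv(path: str | Path, time_s: float | None = None) -> np.ndarray:
    """Read an (n, 2) position set from a snapshots-style CSV.

    Accepts any CSV with ``x_um, y_um`` columns, optionally filtered by a
    ``time_s`` column.
    """
    df = pd.read_csv(path)
    if time_s is not None and "time_s" in df.columns:
        df = df[np.isclose(df["time_s"], time_s)]
    return df[["x_um", "y_um"]].to_numpy()
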