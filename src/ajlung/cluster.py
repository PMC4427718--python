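"""Two-way hierarchical clustering and heatmap reporting.

The study's figures cluster features and samples with complete-linkage
agglomeration on Euclidean (or squared-Euclidean) distances after
centering each feature by its mean across tumor samples, and render the
result with a color scale symmetric around zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

_METRICS = {"euclidean": "euclidean", "squared-euclidean": "sqeuclidean"}


def center_rows_by_tumor_mean(m: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Subtract from each row its mean over tumor-labelled columns."""
    sheet = sheet.set_index("sample_id")
    tumor = [c for c in m.columns if sheet.loc[c, "tissue"] == "T"]
    if not tumor:
        raise ValueError("no tumor samples to center on")
    return m.sub(m[tumor].mean(axis=1), axis=0)


@dataclass
class ClusterResult:
    """Merge histories and leaf orders of a two-way clustering."""

    matrix: pd.DataFrame
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list
    col_order: list

    @property
    def ordered(self) -> pd.DataFrame:
        """The input matrix in dendrogram leaf order."""
        return self.matrix.loc[self.row_order, self.col_order]


def hierarchical_cluster(
    m: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
    cluster_rows: bool = True,
    cluster_cols: bool = True,
) -> ClusterResult:
    """Two-way agglomerative clustering of a feature-by-sample matrix.

    ``metric`` is ``"euclidean"`` or ``"squared-euclidean"``; the
    default linkage is complete agglomeration.  Distances are computed
    on rows (features) and on columns (samples) independently.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if np.isnan(m.to_numpy(dtype=float)).any():
        raise ValueError("matrix contains NaN")

    def _link(vals: np.ndarray):
        if vals.shape[0] < 2:
            return None, list(range(vals.shape[0]))
        Z = linkage(pdist(vals, metric=_METRICS[metric]), method=method)
        return Z, list(leaves_list(Z))

    row_Z, row_idx = (None, list(range(m.shape[0])))
    col_Z, col_idx = (None, list(range(m.shape[1])))
    if cluster_rows:
        row_Z, row_idx = _link(m.to_numpy(dtype=float))
    if cluster_cols:
        col_Z, col_idx = _link(m.to_numpy(dtype=float).T)
    return ClusterResult(
        matrix=m,
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=[m.index[i] for i in row_idx],
        col_order=[m.columns[i] for i in col_idx],
    )


def render_heatmap(
    cluster: ClusterResult,
    path: str | Path,
    annotations: pd.Series | None = None,
    cmap: str = "RdBu_r",
) -> tuple[Path, Path]:
    """Write a heatmap image and the leaf-ordered matrix TSV.

    The color scale is symmetric about zero (the centering convention of
    the study's figures).  ``annotations``, if given, is a per-column
    label series drawn above the heatmap.  Returns the image path and
    the TSV path (same stem, ``.tsv`` suffix).
    """
    path = Path(path)
    ordered = cluster.ordered
    vmax = float(np.abs(ordered.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.18 * ordered.shape[1]), max(3, 0.08 * ordered.shape[0]))
    )
    ax.imshow(
        ordered.to_numpy(dtype=float),
        aspect="auto",
        cmap=cmap,
        vmin=-vmax,
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    if annotations is not None:
        labels = annotations.reindex(ordered.columns)
        ax.set_title(" ".join(str(v) for v in labels), fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    tsv_path = path.with_suffix(".tsv")
    ordered.to_csv(tsv_path, sep="\t", float_format="%.6f")
    return path, tsv_path
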