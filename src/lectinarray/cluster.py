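"""Hierarchical clustering and heatmap export of NFI profiles.

Rows (lectins) are standardized so each heatmap cell shows expression
relative to the rest of its row (red high / green low / black middle),
then rows and columns are clustered agglomeratively.  Defaults are
Pearson-correlation distance (1 - r) with average linkage — the
customary configuration for expression heatmaps; both are configurable
and recorded alongside the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = ["ClusterResult", "ClusterError", "row_standardize", "hcluster", "to_newick", "plot_heatmap"]

DISTANCES = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "single")


class ClusterError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Dendrograms and leaf orders for a clustered matrix."""

    matrix: pd.DataFrame  # row-standardized values, original order
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    params: dict = field(default_factory=dict)

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]

    def row_newick(self) -> str:
        return to_newick(self.row_linkage, list(self.matrix.index))

    def col_newick(self) -> str:
        if self.col_linkage is None:
            raise ClusterError("columns were not clustered")
        return to_newick(self.col_linkage, list(self.matrix.columns))


def row_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each row at 0 and scale to unit sample SD.

    Constant rows (SD = 0) become all zeros rather than NaN so they stay
    plottable and clusterable.
    """
    if matrix.shape[1] < 2:
        raise ClusterError("row standardization needs >= 2 columns")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    out = matrix.sub(mean, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return out


def _distance_vector(values: np.ndarray, metric: str) -> np.ndarray:
    d = pdist(values, metric=metric)
    if metric == "correlation":
        # rows with zero variance have undefined correlation; treat them
        # as maximally uninformative (distance 1 = uncorrelated)
        d = np.where(np.isnan(d), 1.0, d)
    return d


def hcluster(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
    standardize: bool = True,
    cluster_columns: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of rows (and optionally columns).

    Tie-breaking is deterministic in input order (inherited from the
    linkage algorithm).  Requires >= 2 rows.
    """
    if distance not in DISTANCES:
        raise ClusterError(f"distance must be one of {DISTANCES}, got {distance!r}")
    if linkage not in LINKAGES:
        raise ClusterError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if matrix.shape[0] < 2:
        raise ClusterError("clustering needs >= 2 rows")
    std = row_standardize(matrix) if standardize else matrix.copy()

    row_link = hierarchy.linkage(_distance_vector(std.to_numpy(), distance), method=linkage)
    row_order = [std.index[i] for i in hierarchy.leaves_list(row_link)]

    col_link = None
    col_order = list(std.columns)
    if cluster_columns and std.shape[1] >= 2:
        col_link = hierarchy.linkage(
            _distance_vector(std.to_numpy().T, distance), method=linkage
        )
        col_order = [std.columns[i] for i in hierarchy.leaves_list(col_link)]

    return ClusterResult(
        matrix=std,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        params={"distance": distance, "linkage": linkage, "standardize": standardize},
    )


def to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage dendrogram as a Newick string.

    Branch lengths are differences of merge heights, so root-to-leaf
    path lengths reproduce the merge heights (ultrametric rendering).
    """
    tree = hierarchy.to_tree(linkage_matrix)

    def escape(label: str) -> str:
        return label.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "").replace(":", "")

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{escape(labels[node.id])}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def plot_heatmap(result: ClusterResult, path=None):
    """Render the clustered, row-standardized matrix as a heatmap.

    Color scale is symmetric about 0 (standardized values).  Returns the
    matplotlib figure; writes to *path* when given.  Import of matplotlib
    is deferred so headless pipelines without plotting stay light.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    data = result.ordered
    vmax = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    red_black_green = LinearSegmentedColormap.from_list(
        "red_black_green", ["#00B000", "#000000", "#E00000"]
    )
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.45 * data.shape[1] + 2), max(4.0, 0.22 * data.shape[0] + 1))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=red_black_green, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="row-standardized NFI")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
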