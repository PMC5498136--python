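"""DEG selection, hierarchical-clustering heatmap and PCA.

Differentially expressed genes are defined by an absolute log2 fold-change
threshold in at least one contrast (there are no replicates, so no
test-based calling).  The DEG fold-change matrix is clustered
agglomeratively (Euclidean distance, complete linkage — the heatmap.2
defaults) and normalized counts of untouched + cryoinjured samples are
decomposed by PCA on log2(x+1), samples as observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .normalize import FoldChangeMatrix, contrast_label

logger = logging.getLogger("crossheart")

__all__ = [
    "DendrogramResult",
    "PCAResult",
    "select_degs",
    "cluster_heatmap",
    "run_pca",
    "discordant_clusters",
]


def select_degs(
    fc: FoldChangeMatrix,
    abs_log2fc_threshold: float = 2.0,
    scope: Optional[Sequence] = None,
    strict: bool = False,
) -> list:
    """Ortholog pairs with |log2 FC| >= threshold in >=1 contrast in scope.

    ``scope`` is a subset of contrast tuples or column labels (default: all
    contrasts).  ``strict=True`` uses > instead of >= at the boundary.
    """
    if abs_log2fc_threshold < 0:
        raise ValueError("threshold must be >= 0")
    if scope is None:
        cols = list(fc.values.columns)
    else:
        cols = [
            c if isinstance(c, str) else contrast_label(*c) for c in scope
        ]
        missing = set(cols) - set(fc.values.columns)
        if missing:
            raise ValueError(f"unknown contrasts in scope: {sorted(missing)}")
    if not cols:
        raise ValueError("empty contrast scope")
    absfc = fc.values[cols].abs()
    hit = (absfc > abs_log2fc_threshold) if strict else (
        absfc >= abs_log2fc_threshold
    )
    selected = list(fc.values.index[hit.any(axis=1)])
    logger.info("select_degs: %d/%d pairs at |FC|%s%g",
                len(selected), len(fc.values), ">" if strict else ">=",
                abs_log2fc_threshold)
    return selected


@dataclass
class DendrogramResult:
    """Agglomerative merge tree over matrix rows.

    ``linkage_matrix`` is the scipy (n-1) x 4 encoding; ``leaf_order`` the
    dendrogram's left-to-right row ids.
    """

    linkage_matrix: np.ndarray
    leaf_order: list
    row_ids: list
    metric: str
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Partition the rows into k flat clusters (labels 1..k)."""
        labels = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return pd.Series(labels, index=self.row_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick string with row ids as leaf labels and merge heights as
        branch lengths."""
        n = len(self.row_ids)
        Z = self.linkage_matrix

        def height(node: int) -> float:
            return 0.0 if node < n else Z[node - n, 2]

        def render(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.row_ids[node]}:{parent_h:.6g}"
            h = Z[node - n, 2]
            left = render(int(Z[node - n, 0]), h - height(int(Z[node - n, 0])))
            right = render(int(Z[node - n, 1]), h - height(int(Z[node - n, 1])))
            return f"({left},{right}):{parent_h - h:.6g}"

        root = n + len(Z) - 1
        if n == 1:
            return f"{self.row_ids[0]};"
        h = Z[-1, 2]
        left = render(int(Z[-1, 0]), h - height(int(Z[-1, 0])))
        right = render(int(Z[-1, 1]), h - height(int(Z[-1, 1])))
        return f"({left},{right});"


def cluster_heatmap(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
    render_to: Optional[str] = None,
    vlim: Optional[float] = None,
) -> DendrogramResult:
    """Cluster matrix rows agglomeratively; optionally render a heatmap PNG.

    Deterministic: scipy's linkage breaks distance ties by merging the
    lowest-index pair first.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    vals = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = matrix.index[~np.isfinite(vals).all(axis=1)][0]
        raise ValueError(f"non-finite values in row {bad!r}")
    Z = hierarchy.linkage(pdist(vals, metric=metric), method=linkage)
    leaves = hierarchy.leaves_list(Z)
    result = DendrogramResult(
        linkage_matrix=Z,
        leaf_order=[matrix.index[i] for i in leaves],
        row_ids=list(matrix.index),
        metric=metric,
        linkage=linkage,
    )
    if render_to is not None:
        _render_heatmap(matrix, result, render_to, vlim=vlim)
    return result


def _render_heatmap(matrix, dendro, path, vlim=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.loc[dendro.leaf_order]
    if vlim is None:
        vlim = float(np.abs(ordered.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * matrix.shape[1]), 6)
    )
    im = ax.imshow(
        ordered.to_numpy(), aspect="auto", cmap="RdBu_r",
        vmin=-vlim, vmax=vlim, interpolation="nearest",
    )
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(ordered)} genes (clustered)")
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class PCAResult:
    """SVD-based principal components of gene-centered expression; samples
    are observations."""

    scores: pd.DataFrame         # samples x components
    loadings: pd.DataFrame       # genes x components
    variance_explained: np.ndarray  # fraction per component

    def __post_init__(self):
        ve = self.variance_explained
        if (ve < -1e-12).any() or (ve > 1 + 1e-9).any():
            raise ValueError("variance fractions out of [0, 1]")
        if ve.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


def run_pca(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    conditions: Sequence[str] = ("untouched", "cryoinjured"),
    transform: str = "log2p1",
    n_components: Optional[int] = None,
) -> PCAResult:
    """PCA of normalized counts restricted to the given conditions.

    ``transform='log2p1'`` applies log2(x+1) before per-gene centering
    (the field-standard variance stabilization for count PCA);
    ``transform='raw'`` uses the normalized counts directly.
    """
    keep = list(samples.index[samples["condition"].isin(conditions)])
    keep = [s for s in keep if s in normalized.columns]
    if len(keep) < 2:
        raise ValueError("need at least 2 samples after condition restriction")
    X = normalized[keep].to_numpy(dtype=float).T  # samples x genes
    if transform == "log2p1":
        X = np.log2(X + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("constant matrix: zero total variance")
    max_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_components or max_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=keep, columns=pcs),
        loadings=pd.DataFrame(
            pca.components_.T, index=normalized.index, columns=pcs
        ),
        variance_explained=pca.explained_variance_ratio_,
    )


def discordant_clusters(
    fc: FoldChangeMatrix,
    dendro: DendrogramResult,
    k: int = 4,
    matched_times: Sequence[float] = (6.0, 48.0, 72.0),
    condition: str = "cryoinjured",
) -> pd.DataFrame:
    """Rank dendrogram clusters by cross-species discordance.

    Cuts the tree at k clusters and scores each by
    |mean FC_A - mean FC_B| averaged over matched cryoinjury time points —
    a quantitative stand-in for the visual identification of discordant
    gene blocks on a clustered fold-change heatmap.
    """
    labels = dendro.cut(k)
    species = sorted({c[0] for c in fc.contrasts})
    if len(species) != 2:
        raise ValueError("expected exactly two species among contrasts")
    sa, sb = species
    rows = []
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        diffs = []
        for t in matched_times:
            ca = contrast_label(sa, condition, float(t))
            cb = contrast_label(sb, condition, float(t))
            if ca not in fc.values.columns or cb not in fc.values.columns:
                continue
            diffs.append(
                abs(
                    fc.values.loc[members, ca].mean()
                    - fc.values.loc[members, cb].mean()
                )
            )
        if not diffs:
            raise ValueError("no matched time points present in contrasts")
        rows.append(
            {"cluster": cl, "n_genes": len(members),
             "discordance": float(np.mean(diffs))}
        )
    out = pd.DataFrame(rows).sort_values(
        "discordance", ascending=False, kind="stable"
    )
    return out.reset_index(drop=True)
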