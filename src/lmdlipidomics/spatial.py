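"""Spatial heterogeneity analysis of ROI lipidomes.

Assembles ROI x species mol% matrices, z-score normalizes per species,
clusters hierarchically with Euclidean distance and Ward linkage (the
MetaboAnalyst-style heatmap configuration), and exports per-species spatial
maps over the ROI geometries.  Replicate ROIs (successive sections) are
clustered individually so the dendrogram displays section-to-section
reproducibility alongside regional structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantify import QuantifiedLipidome, lipidome_matrix
from .simulate import ROISpec

__all__ = [
    "ROIMatrix",
    "build_roi_matrix",
    "zscore_normalize",
    "ClusterResult",
    "ward_cluster",
    "cut_clusters",
    "to_newick",
    "spatial_map",
    "plot_heatmap",
]


@dataclass
class ROIMatrix:
    """ROI-replicate rows x species mol% columns, with ROI metadata."""

    values: pd.DataFrame
    meta: pd.DataFrame  # index sample_id; roi_id, region, centroid_x/y, area_um2

    def __post_init__(self):
        if self.values.isna().all(axis=0).any():
            raise ValueError("matrix contains all-missing species columns")


def build_roi_matrix(
    lipidomes: Sequence[QuantifiedLipidome],
    rois: Mapping[str, ROISpec],
) -> ROIMatrix:
    """Assemble the clustering input from quantified ROI replicates."""
    if not lipidomes:
        raise ValueError("no lipidomes given")
    values = lipidome_matrix(lipidomes, value="mol_percent")
    values = values.loc[:, ~values.isna().all(axis=0)]
    meta = pd.DataFrame(
        {
            "roi_id": [rois[q.sample_id].roi_id for q in lipidomes],
            "region": [rois[q.sample_id].region for q in lipidomes],
            "centroid_x": [rois[q.sample_id].centroid[0] for q in lipidomes],
            "centroid_y": [rois[q.sample_id].centroid[1] for q in lipidomes],
            "area_um2": [rois[q.sample_id].area_um2 for q in lipidomes],
        },
        index=[q.sample_id for q in lipidomes],
    )
    return ROIMatrix(values, meta)


def zscore_normalize(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-species (column-wise) z-scores: mean 0, SD 1.

    Zero-variance columns carry no contrast and are dropped with a warning;
    an all-constant matrix is an error.
    """
    sd = matrix.std(axis=0, ddof=ddof)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant) == len(matrix.columns):
        raise ValueError("all species columns have zero variance")
    if len(constant):
        warnings.warn(f"dropping {len(constant)} zero-variance species columns")
    kept = matrix.drop(columns=constant)
    return (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=ddof)


@dataclass
class ClusterResult:
    """Ward/Euclidean clustering of an ROI lipidome matrix."""

    zscores: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    cophenetic: np.ndarray
    sample_ids: list[str]

    def linkage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "n_leaves"]
        )


def ward_cluster(matrix: ROIMatrix | pd.DataFrame, zscore: bool = True) -> ClusterResult:
    """Agglomerative clustering, Euclidean distance / Ward linkage.

    Operates on the z-scored matrix (matching heatmaps whose color code shows
    normalized values).  Merge order for tied distances follows the original
    row order, so results are deterministic for a given input.
    """
    values = matrix.values if isinstance(matrix, ROIMatrix) else matrix
    if len(values) < 2:
        raise ValueError("need at least two rows to cluster")
    z = zscore_normalize(values) if zscore else values
    dist = pdist(z.to_numpy(), metric="euclidean")
    link = hierarchy.linkage(dist, method="ward")
    leaves = hierarchy.leaves_list(link)
    coph = hierarchy.cophenet(link)
    ids = list(z.index)
    return ClusterResult(z, link, [ids[i] for i in leaves], coph, ids)


def cut_clusters(result: ClusterResult, k: int) -> pd.Series:
    """Flat partition into k clusters (labels indexed by sample id)."""
    labels = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=result.sample_ids, name="cluster")


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string (leaf names are sample ids)."""
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(result.linkage, result.sample_ids)
    return str(tree)


def spatial_map(
    lipidomes: Sequence[QuantifiedLipidome],
    rois: Mapping[str, ROISpec],
    species: Sequence[str],
) -> pd.DataFrame:
    """Per-ROI mean +/- SD mol% of selected species, joined to ROI geometry.

    The SD runs over successive-section replicates of each ROI.  Unknown
    species raise a KeyError.
    """
    if not lipidomes:
        raise ValueError("no lipidomes given")
    values = lipidome_matrix(lipidomes, value="mol_percent")
    missing = [s for s in species if s not in values.columns]
    if missing:
        raise KeyError(f"species not quantified in any ROI: {missing}")
    rows = []
    roi_of = {sid: rois[sid] for sid in values.index}
    by_roi: dict[int, list[str]] = {}
    for sid, roi in roi_of.items():
        by_roi.setdefault(roi.roi_id, []).append(sid)
    for roi_id, sids in sorted(by_roi.items()):
        roi = roi_of[sids[0]]
        sub = values.loc[sids, list(species)]
        for sp in species:
            rows.append(
                {
                    "roi_id": roi_id,
                    "region": roi.region,
                    "centroid_x": roi.centroid[0],
                    "centroid_y": roi.centroid[1],
                    "area_um2": roi.area_um2,
                    "species": sp,
                    "mean_mol_percent": float(sub[sp].mean()),
                    "sd_mol_percent": float(sub[sp].std(ddof=1))
                    if len(sids) > 1
                    else 0.0,
                    "n": len(sids),
                }
            )
    return pd.DataFrame(rows)


def plot_heatmap(result: ClusterResult, path=None, **clustermap_kwargs):
    """Clustered heatmap of the z-scored matrix (rows follow the dendrogram)."""
    import seaborn as sns

    clustermap_kwargs.setdefault("cmap", "RdBu_r")
    clustermap_kwargs.setdefault("center", 0.0)
    grid = sns.clustermap(
        result.zscores,
        row_linkage=result.linkage,
        col_cluster=True,
        **clustermap_kwargs,
    )
    if path is not None:
        grid.savefig(path, dpi=150)
    return grid
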