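"""Skeletonization and branch decomposition of mitochondrial clusters.

Each cluster is thinned to a 1-px-wide topological skeleton. Skeleton
pixels are classified by their 8-neighbour count: exactly one neighbour
is an end point, three or more a junction point. A branch is the piece of
skeleton between two end points, two junctions, or one of each; an
isolated single-pixel skeleton is one degenerate branch of length 0 with
one end point. Junction pixels that touch each other are merged into a
single junction node for counting, since thinning produces small junction
clumps.

The isolated-mitochondria mask re-partitions each cluster's pixels by a
watershed seeded at the branch labels, so the pixel support of the
isolated mask equals that of the cluster mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage import morphology, segmentation as skseg

from .imgio import LabelMask

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SkeletonGraph:
    """Per-field skeleton decomposition.

    ``branch_labels`` assigns every non-junction skeleton pixel its branch
    id (junction pixels are 0 there but flagged in ``junction_points``).
    ``branches`` is one row per branch: branch id, cluster, cell and
    geodesic length (axial steps count 1, diagonal steps sqrt(2)).
    """

    skeleton: np.ndarray
    end_points: np.ndarray
    junction_points: np.ndarray
    branch_labels: np.ndarray
    branches: pd.DataFrame
    #: merged 8-connected junction clumps, one row per junction node
    junction_nodes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def per_cell_counts(self) -> pd.DataFrame:
        """End-point, junction-node and branch counts per cell."""
        cells = sorted(
            set(self.branches["cell"]).union(
                self.junction_nodes["cell"] if len(self.junction_nodes) else []
            )
        )
        rows = []
        for cell in cells:
            b = self.branches[self.branches["cell"] == cell]
            j = (
                self.junction_nodes[self.junction_nodes["cell"] == cell]
                if len(self.junction_nodes)
                else self.junction_nodes
            )
            rows.append(
                {
                    "cell": cell,
                    "n_branches": int(len(b)),
                    "n_end_points": int(b["n_end_points"].sum()),
                    "n_junction_nodes": int(len(j)),
                    "total_length": float(b["length"].sum()),
                }
            )
        return pd.DataFrame(rows, columns=["cell", "n_branches", "n_end_points", "n_junction_nodes", "total_length"])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    counts = ndi.convolve(skel.astype(np.uint8), _EIGHT, mode="constant")
    return np.where(skel, counts - 1, 0)


def _branch_lengths(branch_labels: np.ndarray, n_branches: int) -> np.ndarray:
    """Geodesic length per branch via a minimum spanning forest.

    Edges connect 8-adjacent pixels of the same branch with weight 1
    (axial) or sqrt(2) (diagonal); the MST of the disconnected graph is
    the spanning forest whose per-branch total weight is the path length.
    """
    lengths = np.zeros(n_branches + 1)
    coords = np.nonzero(branch_labels > 0)
    n_px = coords[0].size
    if n_px == 0:
        return lengths
    idx_img = np.full(branch_labels.shape, -1, dtype=np.int64)
    idx_img[coords] = np.arange(n_px)
    rows_i, cols_j, weights = [], [], []
    for dr, dc, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        r1, c1 = coords
        r2 = r1 + dr
        c2 = c1 + dc
        ok = (r2 >= 0) & (r2 < branch_labels.shape[0]) & (c2 >= 0) & (c2 < branch_labels.shape[1])
        r1, c1, r2, c2 = r1[ok], c1[ok], r2[ok], c2[ok]
        dst = idx_img[r2, c2]
        same = (dst >= 0) & (branch_labels[r1, c1] == branch_labels[r2, c2])
        src = idx_img[r1[same], c1[same]]
        rows_i.append(src)
        cols_j.append(dst[same])
        weights.append(np.full(src.size, w))
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    w = np.concatenate(weights)
    if i.size == 0:
        return lengths
    graph = coo_matrix((w, (i, j)), shape=(n_px, n_px))
    mst = minimum_spanning_tree(graph).tocoo()
    if mst.nnz:
        edge_branch = branch_labels[coords[0][mst.row], coords[1][mst.row]]
        np.add.at(lengths, edge_branch, mst.data)
    return lengths


def skeletonize_clusters(clusters: LabelMask, cluster_to_cell: dict | None = None) -> SkeletonGraph:
    """Thin clusters to skeletons and decompose them into branches.

    Branch ids are globally unique within the field; the ``branches``
    table carries the owning cluster and cell so per-cell summaries are a
    group-by away.
    """
    support = clusters.labels > 0
    skel = morphology.skeletonize(support)
    nb = _neighbor_counts(skel)
    end_points = skel & (nb <= 1)  # includes isolated single-pixel skeletons
    junction_px = skel & (nb >= 3)

    branch_support = skel & ~junction_px
    branch_labels, n_branches = ndi.label(branch_support, structure=_EIGHT)

    cluster_to_cell = cluster_to_cell or {}
    branch_ids = np.arange(1, n_branches + 1)
    if n_branches:
        cluster_of_branch = ndi.maximum(clusters.labels, labels=branch_labels, index=branch_ids)
        ends_per_branch = ndi.sum_labels(end_points.astype(np.int64), labels=branch_labels, index=branch_ids)
        lengths = _branch_lengths(branch_labels, n_branches)[1:]
        branches = pd.DataFrame(
            {
                "branch": branch_ids,
                "cluster": np.asarray(cluster_of_branch, dtype=int),
                "n_end_points": np.asarray(ends_per_branch, dtype=int),
                "length": lengths,
            }
        )
    else:
        branches = pd.DataFrame(columns=["branch", "cluster", "n_end_points", "length"])
    branches["cell"] = branches["cluster"].map(lambda c: cluster_to_cell.get(int(c), 0)) if len(branches) else []

    junction_nodes_img, n_nodes = ndi.label(junction_px, structure=_EIGHT)
    if n_nodes:
        node_ids = np.arange(1, n_nodes + 1)
        cluster_of_node = ndi.maximum(clusters.labels, labels=junction_nodes_img, index=node_ids)
        junction_nodes = pd.DataFrame(
            {"node": node_ids, "cluster": np.asarray(cluster_of_node, dtype=int)}
        )
        junction_nodes["cell"] = junction_nodes["cluster"].map(
            lambda c: cluster_to_cell.get(int(c), 0)
        )
    else:
        junction_nodes = pd.DataFrame(columns=["node", "cluster", "cell"])

    return SkeletonGraph(
        skeleton=skel,
        end_points=end_points,
        junction_points=junction_px,
        branch_labels=branch_labels.astype(np.int32),
        branches=branches,
        junction_nodes=junction_nodes,
    )


def segment_isolated_mito(clusters: LabelMask, graph: SkeletonGraph) -> tuple[LabelMask, dict]:
    """Re-partition cluster pixels among skeleton branches by watershed.

    Every cluster pixel is assigned to exactly one branch by flooding the
    distance-to-skeleton relief from the branch seeds, confined to the
    cluster support, so pixel support is conserved exactly. Clusters whose
    skeleton consists only of junction pixels (no branch seed) are kept
    whole under a fresh label.
    """
    support = clusters.labels > 0
    seeds = graph.branch_labels
    dist = ndi.distance_transform_edt(seeds == 0)
    iso = skseg.watershed(dist, markers=seeds, mask=support)
    leftover = support & (iso == 0)
    if leftover.any():
        extra, n_extra = ndi.label(leftover, structure=_EIGHT)
        iso = np.where(leftover, extra + int(iso.max()), iso)
    branch_to_mito = {int(b): int(b) for b in graph.branches["branch"]} if len(graph.branches) else {}
    return LabelMask(labels=iso.astype(np.int32), kind="isolated_mito"), branch_to_mito
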