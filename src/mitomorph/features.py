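"""The 31 per-cell morphological descriptors and their aggregation.

Features are computed on five masks (cell, mitochondrial clusters,
skeleton, isolated mitochondria, nuclei) plus the raw intensity channels,
then aggregated to one record per cell: area and length features are
*summed* over the cell's objects, every other per-object feature is
*averaged*, counts are object counts, and the fractal dimensions are
computed once per cell on the union of its cluster pixels.

All geometry is in pixels. Missing values (e.g. a cell without any
detected mitochondria) propagate as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

#: Canonical feature order of the per-cell CSV.
FEATURE_NAMES = [
    # cellular parameters (cell mask + cell channel)
    "Cell_Area",
    "Cell_MeanIntensity",
    "Cell_MaxIntensity",
    "Cell_Perimeter",
    "Cell_Compaction",
    "Cell_Roundness",
    # mitochondrial cluster parameters (cluster mask + red channel)
    "MitoCluster_Fractal2",
    "MitoCluster_Fractal8",
    "MitoCluster_Fractal32",
    "MitoCluster_Count",
    "MitoCluster_Area",
    "MitoCluster_Elongation",
    "MitoCluster_Compaction",
    "MitoCluster_Roundness",
    "MitoCluster_EulerNumber",
    "Mito_MeanIntensity",
    "Mito_MaxIntensity",
    "MitoCluster_Perimeter",
    "MitoCluster_Solidity",
    # skeletonized parameters
    "Skel_Width",
    "Skel_Length",
    "Skel_BranchPointsCount",
    "Skel_EndPointsCount",
    "Skel_BranchPointsEndPointsRatio",
    # isolated mitochondria parameters
    "Mito_Compaction",
    "Mito_Elongation",
    "Mito_Roundness",
    "Mito_Length",
    # localization parameters (skeleton + cell + nuclei masks)
    "DistToMembrane",
    "DistToNuclei",
    "RatioDistMemb0Nucl1",
]

#: Features aggregated by summation over a cell's objects; all other
#: per-object features are averaged.
SUMMED_FEATURES = {"MitoCluster_Area", "Skel_Length", "Mito_Length"}


@dataclass
class CellFeatureRecord:
    """Identifiers plus the 31 descriptors for one cell."""

    condition: str
    field_id: str
    cell_id: int
    features: dict

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.features]
        extra = [n for n in self.features if n not in FEATURE_NAMES]
        if missing or extra:
            raise ValueError(f"feature schema mismatch: missing={missing} extra={extra}")

    def as_row(self) -> dict:
        row = {"condition": self.condition, "field_id": self.field_id, "cell_id": self.cell_id}
        row.update({n: self.features[n] for n in FEATURE_NAMES})
        return row


def records_to_frame(records) -> pd.DataFrame:
    from .imgio import ID_COLUMNS

    if len(records) == 0:
        return pd.DataFrame(columns=ID_COLUMNS + FEATURE_NAMES)
    return pd.DataFrame([r.as_row() for r in records], columns=ID_COLUMNS + FEATURE_NAMES)


# ---------------------------------------------------------------------------
# shape descriptors
# ---------------------------------------------------------------------------


def _descriptors_from_regionprops(rp, *, literal_roundness: bool = False) -> dict:
    area = float(rp.area)
    if area <= 1:
        # degenerate single-pixel region
        return {
            "area": area,
            "perimeter": 1.0,
            "compaction": 1.0,
            "elongation": 1.0,
            "roundness": 1.0,
            "euler": int(rp.euler_number),
            "solidity": 1.0,
        }
    perimeter = max(float(rp.perimeter), 1.0)
    # moment-equivalent ellipse axes, floored at one pixel width so that
    # 1-px-wide lines stay finite
    major = max(float(rp.axis_major_length), 1.0)
    minor = max(float(rp.axis_minor_length), 1.0)
    eq_diam = math.sqrt(4.0 * area / math.pi)
    if literal_roundness:
        # the verbatim printed formula, sqrt(4*Area/pi)/(Perimeter/4*pi),
        # read with left-to-right precedence: (perimeter / 4) * pi
        roundness = eq_diam / (perimeter / 4.0 * math.pi)
    else:
        roundness = eq_diam / (perimeter / math.pi)
    hull_perimeter = measure.perimeter(rp.image_convex)
    return {
        "area": area,
        "perimeter": perimeter,
        "compaction": minor / major,
        "elongation": major / minor,
        "roundness": roundness,
        "euler": int(rp.euler_number),
        "solidity": float(hull_perimeter) / perimeter,
    }


def shape_descriptors(object_mask: np.ndarray, *, literal_roundness: bool = False) -> dict:
    """Shape descriptors of a single binary region.

    Returns area (px), perimeter (px), compaction (minor/major ellipse
    axis, in (0, 1]), elongation (major/minor, >= 1), roundness
    (equivalent diameter / (perimeter / pi); 1 for a perfect circle),
    Euler number (#components - #holes) and solidity (convex-hull
    perimeter / object perimeter).
    """
    mask = np.asarray(object_mask).astype(bool)
    if not mask.any():
        raise ValueError("shape_descriptors requires a nonempty region")
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    return _descriptors_from_regionprops(rp, literal_roundness=literal_roundness)


# ---------------------------------------------------------------------------
# box-counting fractal dimension
# ---------------------------------------------------------------------------


@dataclass
class BoxCountProfile:
    """Box-counting profile of a binary mask padded to a 2^P square.

    ``box_sizes[i] = 2**i`` for i in 0..P; ``counts[i]`` is the number of
    boxes of that size containing at least one nonzero pixel; ``fd`` is the
    per-scale fractal dimension -gradient(log N)/gradient(log R) with
    central differences in the interior and one-sided at the ends.
    """

    padded_side: int
    box_sizes: np.ndarray
    counts: np.ndarray
    fd: np.ndarray

    def fd_at_box_size(self, size: int) -> float:
        idx = np.nonzero(self.box_sizes == size)[0]
        return float(self.fd[idx[0]]) if idx.size else float("nan")


def box_count_profile(mask: np.ndarray) -> BoxCountProfile | None:
    """Box-count a binary mask at dyadic box sizes 1, 2, ..., 2^P.

    P is the smallest integer such that the largest mask dimension fits
    in 2^P (a 320x200 mask pads to 512x512); the mask is zero-padded to
    that square. Returns None for an empty mask.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return None
    p = max(0, int(math.ceil(math.log2(max(mask.shape)))))
    side = 2**p
    padded = np.zeros((side, side), dtype=bool)
    padded[: mask.shape[0], : mask.shape[1]] = mask

    sizes = 2 ** np.arange(p + 1)
    counts = np.empty(p + 1, dtype=np.int64)
    current = padded
    for i in range(p + 1):
        counts[i] = int(current.sum())
        if i < p:
            h, w = current.shape
            current = current.reshape(h // 2, 2, w // 2, 2).any(axis=(1, 3))

    log_n = np.log(counts.astype(float))
    log_r = np.log(sizes.astype(float))
    if p == 0:
        fd = np.zeros(1)
    else:
        fd = -np.gradient(log_n, log_r)
    return BoxCountProfile(padded_side=side, box_sizes=sizes, counts=counts, fd=fd)


def box_count_fd(mask: np.ndarray) -> tuple[float, float, float]:
    """Fractal-dimension triplet at box sizes 4, 16 and 64 pixels.

    Returns (Fractal2, Fractal8, Fractal32); values whose box size exceeds
    the padded image are NaN, as is everything for an empty mask.
    """
    profile = box_count_profile(mask)
    if profile is None:
        return (float("nan"),) * 3
    return (
        profile.fd_at_box_size(4),
        profile.fd_at_box_size(16),
        profile.fd_at_box_size(64),
    )


# ---------------------------------------------------------------------------
# skeleton and localization features
# ---------------------------------------------------------------------------


def skeleton_features(
    total_branch_length: float,
    n_branch_points: int,
    n_end_points: int,
    total_cluster_area: float,
) -> dict:
    """Per-cell skeleton summary.

    Width is the mean tubule width proxy: total cluster area divided by
    total skeleton length (length floored at 1 px for degenerate
    point skeletons). The branch-point ratio B/(B+E) is 0 when B+E = 0.
    """
    length = float(total_branch_length)
    b, e = int(n_branch_points), int(n_end_points)
    ratio = b / (b + e) if (b + e) > 0 else 0.0
    width = float(total_cluster_area) / max(length, 1.0)
    return {
        "Skel_Width": width,
        "Skel_Length": length,
        "Skel_BranchPointsCount": float(b),
        "Skel_EndPointsCount": float(e),
        "Skel_BranchPointsEndPointsRatio": ratio,
    }


def localization_features(
    skeleton_mask: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
) -> dict:
    """Mean distances from skeleton pixels to the cell and nucleus borders.

    For each skeleton pixel of a cell: Euclidean distance to the nearest
    non-cell pixel (membrane) and to the nearest nucleus pixel. The ratio
    DistToNuclei/(DistToMembrane + DistToNuclei) is computed per pixel and
    then averaged, so a pixel hugging the nucleus scores ~0 and one on the
    cell boundary scores ~1.
    """
    skel = np.asarray(skeleton_mask).astype(bool)
    if not skel.any():
        return {
            "DistToMembrane": float("nan"),
            "DistToNuclei": float("nan"),
            "RatioDistMemb0Nucl1": float("nan"),
        }
    dist_membrane = ndi.distance_transform_edt(np.asarray(cell_mask).astype(bool))
    dist_nucleus = ndi.distance_transform_edt(~np.asarray(nucleus_mask).astype(bool))
    dm = dist_membrane[skel]
    dn = dist_nucleus[skel]
    denom = dm + dn
    ratio = np.where(denom > 0, dn / np.where(denom > 0, denom, 1.0), 0.5)
    return {
        "DistToMembrane": float(dm.mean()),
        "DistToNuclei": float(dn.mean()),
        "RatioDistMemb0Nucl1": float(ratio.mean()),
    }


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_objects(per_object: pd.DataFrame, feature_names: list[str]) -> dict:
    """Aggregate per-object features to one value per feature.

    Features named in :data:`SUMMED_FEATURES` are summed across objects;
    all others are arithmetic means. An empty frame yields NaNs.
    """
    out = {}
    for name in feature_names:
        if per_object.empty or name not in per_object:
            out[name] = float("nan")
        elif name in SUMMED_FEATURES:
            out[name] = float(per_object[name].sum())
        else:
            out[name] = float(per_object[name].mean())
    return out
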