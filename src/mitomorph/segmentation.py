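"""Five-stage segmentation: nuclei, cells, mitochondrial clusters.

The stages follow the fixed recipe of the original tool:

* nuclei — difference-of-Gaussians band-pass (sigma 3/12), threshold at
  the median of the filtered image, small-object removal (< 2000 px),
  hole filling, 3-px disk dilation, watershed separation of touching
  nuclei, removal of border-touching objects;
* cells — watershed on the negated membrane channel with nucleus
  interiors forced to the global minimum so each nucleus seeds one
  catchment, iterative aggregation of residual catchments into the
  neighbouring cell with the dimmest shared boundary, then exclusion of
  pixels below a user-settable intensity floor;
* mitochondrial clusters — band-pass (sigma 1/4), threshold at
  mean + 1 SD of the filtered channel, removal of objects < 10 px,
  intersection with the cell foreground and per-cell labeling.

Everything is deterministic: no random number generator is used anywhere
in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation as skseg
from skimage.filters import threshold_otsu

from .imgio import LabelMask, compact_relabel


@dataclass
class SegmentationParams:
    """Tunable thresholds and scales of the three thresholding stages.

    Defaults are the recipe's published values; ``cell_intensity_floor``
    has no published default and falls back to an Otsu threshold of the
    membrane channel when left as None.
    """

    nuclei_sigma_lo: float = 3.0
    nuclei_sigma_hi: float = 12.0
    nuclei_min_area_px: int = 2000
    nuclei_dilate_radius_px: int = 3
    cell_intensity_floor: float | None = None
    mito_sigma_lo: float = 1.0
    mito_sigma_hi: float = 4.0
    mito_threshold_k_sd: float = 1.0
    mito_min_area_px: int = 10
    #: skimage connectivity for component labeling/border tests (2 = 8-conn)
    label_connectivity: int = 2
    #: skimage connectivity for watershed flooding (1 = 4-conn ridges)
    watershed_connectivity: int = 1

    def __post_init__(self) -> None:
        if not self.nuclei_sigma_lo < self.nuclei_sigma_hi:
            raise ValueError("nuclei_sigma_lo must be < nuclei_sigma_hi")
        if not self.mito_sigma_lo < self.mito_sigma_hi:
            raise ValueError("mito_sigma_lo must be < mito_sigma_hi")
        for name in ("nuclei_min_area_px", "nuclei_dilate_radius_px", "mito_min_area_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SegmentationResult:
    """Nuclei, cell and cluster masks sharing one label space.

    Cell k contains nucleus k; every cluster lies inside exactly one cell
    and ``cluster_to_cell`` maps each cluster label to it.
    """

    nuclei: LabelMask
    cells: LabelMask
    clusters: LabelMask
    cluster_to_cell: dict = field(default_factory=dict)


def bandpass(channel: np.ndarray, sigma_lo: float, sigma_hi: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass with reflective boundaries.

    Subtracting the wide blur removes slowly varying background; the
    narrow blur removes sharp noise. The response is ~zero on flat
    regions, so median/SD thresholds of the filtered image are anchored
    near zero.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError(f"bandpass expects a 2D image, got ndim={channel.ndim}")
    if not sigma_lo < sigma_hi:
        raise ValueError("sigma_lo must be < sigma_hi")
    lo = ndi.gaussian_filter(channel, sigma_lo, mode="reflect")
    hi = ndi.gaussian_filter(channel, sigma_hi, mode="reflect")
    return lo - hi


def _split_touching(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Watershed separation of touching objects in a binary mask.

    Relief is the (smoothed) Euclidean distance transform with minima
    imposed at its regional maxima — the standard touching-nuclei recipe.
    """
    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, 2.0)
    # h-maxima suppression: shallow ridge maxima of one elongated object
    # merge into a single seed, while the deep dip between two touching
    # objects keeps their seeds separate
    peaks = morphology.h_maxima(smooth, 2.0, footprint=np.ones((3, 3))) > 0
    peaks &= mask
    markers, _ = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    if markers.max() == 0:
        labeled, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        return labeled
    return skseg.watershed(
        -smooth, markers=markers, mask=mask, connectivity=params.watershed_connectivity
    )


def segment_nuclei(nuclei_channel: np.ndarray, params: SegmentationParams | None = None) -> LabelMask:
    """Segment nuclei from the blue channel.

    Pipeline order is fixed: band-pass -> threshold strictly above the
    median of the filtered image -> remove components below the minimum
    area -> fill holes -> dilate by a disk -> watershed-split touching
    objects -> drop anything touching the image border -> compact
    relabeling. An empty mask is a valid result.
    """
    params = params or SegmentationParams()
    filtered = bandpass(nuclei_channel, params.nuclei_sigma_lo, params.nuclei_sigma_hi)
    channel = np.asarray(nuclei_channel)
    if np.issubdtype(channel.dtype, np.integer) or not np.mod(channel, 1).any():
        # integer-count input: quantize the band-passed response to whole
        # counts (integer image arithmetic), so sub-count background
        # fluctuations cannot straddle the median threshold
        filtered = np.round(filtered)
    mask = filtered > np.median(filtered)
    mask = morphology.remove_small_objects(
        mask, max_size=params.nuclei_min_area_px - 1, connectivity=params.label_connectivity
    )
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.dilation(mask, morphology.disk(params.nuclei_dilate_radius_px))
    labels = _split_touching(mask, params)
    labels = skseg.clear_border(labels)
    return LabelMask(labels=compact_relabel(labels), kind="nuclei")


def _quantization_step(relief: np.ndarray) -> float:
    values = np.unique(relief)
    if values.size < 2:
        return 1.0
    return float(np.min(np.diff(values)))


def _merge_residual_regions(
    ws: np.ndarray, assign: np.ndarray, intensity: np.ndarray
) -> np.ndarray:
    """Iteratively absorb unassigned watershed regions into labeled cells.

    In each pass every residual region touching at least one labeled cell
    joins the neighbour whose shared boundary has the lowest mean channel
    intensity (ties broken by lower cell label); passes repeat until no
    residual region touches a labeled cell. Fully deterministic.
    """
    n_regions = int(ws.max())
    while True:
        cell_of_px = assign[ws]
        pairs_r = []
        pairs_c = []
        weights = []
        # 4-neighbourhood boundary pairs between residual and assigned pixels
        for axis in (0, 1):
            if axis == 0:
                a_sl, b_sl = (slice(None, -1), slice(None)), (slice(1, None), slice(None))
            else:
                a_sl, b_sl = (slice(None), slice(None, -1)), (slice(None), slice(1, None))
            wa, wb = ws[a_sl], ws[b_sl]
            ca, cb = cell_of_px[a_sl], cell_of_px[b_sl]
            ia, ib = intensity[a_sl], intensity[b_sl]
            # residual on side a, assigned on side b
            m = (ca == 0) & (cb > 0)
            pairs_r.append(wa[m]); pairs_c.append(cb[m]); weights.append((ia[m] + ib[m]) / 2.0)
            # residual on side b, assigned on side a
            m = (cb == 0) & (ca > 0)
            pairs_r.append(wb[m]); pairs_c.append(ca[m]); weights.append((ia[m] + ib[m]) / 2.0)
        r = np.concatenate(pairs_r)
        if r.size == 0:
            break
        c = np.concatenate(pairs_c)
        w = np.concatenate(weights)
        # mean boundary intensity per (residual region, candidate cell)
        code = r.astype(np.int64) * (int(assign.max()) + 1) + c
        uniq, inv = np.unique(code, return_inverse=True)
        sums = np.bincount(inv, weights=w)
        counts = np.bincount(inv)
        means = sums / counts
        ur = uniq // (int(assign.max()) + 1)
        uc = uniq % (int(assign.max()) + 1)
        # choose, per residual region, the candidate with the lowest mean
        # boundary intensity; ties -> lower cell label (lexsort order)
        order = np.lexsort((uc, means, ur))
        ur_o, uc_o = ur[order], uc[order]
        first = np.ones(ur_o.size, dtype=bool)
        first[1:] = ur_o[1:] != ur_o[:-1]
        new_assign = assign.copy()
        new_assign[ur_o[first]] = uc_o[first]
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        if n_regions and (assign[1:] > 0).all():
            break
    return assign


def segment_cells(
    cell_channel: np.ndarray, nuclei: LabelMask, params: SegmentationParams | None = None
) -> LabelMask:
    """Extend nucleus labels to whole cells using the membrane channel.

    Watershed floods the negated membrane intensity; nucleus interiors are
    forced to the global minimum minus one quantization step so each
    nucleus seeds exactly one catchment. Catchments overlapping a nucleus
    take its label; the rest are absorbed iteratively along their dimmest
    boundaries. Finally, pixels dimmer than the intensity floor (Otsu of
    the channel if unset) are returned to background, except inside
    nuclei: a cell always keeps its seeding nucleus.
    """
    params = params or SegmentationParams()
    channel = np.asarray(cell_channel, dtype=np.float64)
    if channel.shape != nuclei.labels.shape:
        raise ValueError("cell channel and nuclei mask shapes differ")
    relief = -channel
    nuc = nuclei.labels
    inside = nuc > 0
    if inside.any():
        relief = relief.copy()
        relief[inside] = relief.min() - _quantization_step(relief)
    ws = skseg.watershed(relief, connectivity=params.watershed_connectivity)

    # catchments overlapping a nucleus inherit its label
    n_ws = int(ws.max())
    assign = np.zeros(n_ws + 1, dtype=np.int32)
    if inside.any():
        # each nucleus is one flat global-minimum plateau => one catchment;
        # take the nucleus label seen in each catchment
        overlap = ndi.maximum(nuc, labels=ws, index=np.arange(1, n_ws + 1))
        assign[1:] = np.asarray(overlap, dtype=np.int32)
        assign = _merge_residual_regions(ws, assign, channel)
    labels = assign[ws]

    floor = params.cell_intensity_floor
    if floor is None:
        floor = float(threshold_otsu(channel)) if np.ptp(channel) > 0 else float("-inf")
    labels[(channel < floor) & ~inside] = 0
    return LabelMask(labels=labels.astype(np.int32), kind="cells")


def segment_mito_clusters(
    mito_channel: np.ndarray, cells: LabelMask, params: SegmentationParams | None = None
) -> tuple[LabelMask, dict]:
    """Segment mitochondrial clusters and assign each to its cell.

    Band-pass (sigma 1/4) -> keep pixels above mean + k*SD of the filtered
    image -> drop components below the minimum area -> intersect with the
    cell foreground; components straddling two cells are split per cell
    before labeling. Returns the cluster mask and a cluster -> cell map.
    """
    params = params or SegmentationParams()
    channel = np.asarray(mito_channel, dtype=np.float64)
    if channel.shape != cells.labels.shape:
        raise ValueError("mito channel and cells mask shapes differ")
    filtered = bandpass(channel, params.mito_sigma_lo, params.mito_sigma_hi)
    threshold = filtered.mean() + params.mito_threshold_k_sd * filtered.std()
    mask = filtered > threshold
    mask = morphology.remove_small_objects(
        mask, max_size=params.mito_min_area_px - 1, connectivity=params.label_connectivity
    )
    mask &= cells.labels > 0
    comps, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    # split straddling components per cell: composite (component, cell) code
    n_cells = int(cells.labels.max())
    code = np.where(mask, comps.astype(np.int64) * (n_cells + 1) + cells.labels, 0)
    labels = compact_relabel(code)
    cluster_ids = np.unique(labels)
    cluster_ids = cluster_ids[cluster_ids > 0]
    cluster_to_cell = {}
    if cluster_ids.size:
        owner = ndi.maximum(cells.labels, labels=labels, index=cluster_ids)
        cluster_to_cell = {int(k): int(v) for k, v in zip(cluster_ids, owner)}
    return LabelMask(labels=labels.astype(np.int32), kind="clusters"), cluster_to_cell


def segment_field(
    field, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Run the nuclei -> cells -> clusters cascade on one field."""
    params = params or SegmentationParams()
    nuclei = segment_nuclei(field.nuclei_channel, params)
    cells = segment_cells(field.cell_channel, nuclei, params)
    clusters, cluster_to_cell = segment_mito_clusters(field.mito_channel, cells, params)
    for mask in (nuclei, cells, clusters):
        mask.parent_field = field.field_id
    return SegmentationResult(
        nuclei=nuclei, cells=cells, clusters=clusters, cluster_to_cell=cluster_to_cell
    )
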