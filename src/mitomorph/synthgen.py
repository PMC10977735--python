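"""Synthetic three-channel fluorescence fields with ground truth.

Emulates flat cultured cells imaged in 2D: each cell is a smooth blob
with one elliptical nucleus and a cytoplasmic network of curvilinear
mitochondrial tubules drawn as radially-constrained persistent random
walks. Three phenotype knobs control the network:

* ``fragmentation`` (0..1) — trades a few long, occasionally branched
  tubules for many short grains at constant total tubule length;
* ``swelling`` (0..1) — multiplies the tubule width;
* ``perinuclear_bias`` (0..1) — pulls tubule placement toward the
  nucleus.

Channels are rendered by rasterization, Gaussian PSF blur and
Poisson-like shot noise on a 16-bit-like intensity scale. A fixed seed
gives bit-identical output; all stochastic choices are drawn from a
single generator in a fixed order.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw, morphology

from .imgio import FieldImage, LabelMask, DEFAULT_PIXEL_SIZE_UM

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SynthParams:
    """Generator knobs and scene geometry (all lengths in pixels)."""

    n_cells: int = 4
    image_side: int = 768
    fragmentation: float = 0.3
    swelling: float = 0.0
    perinuclear_bias: float = 0.2
    noise_level: float = 1.0
    psf_sigma: float = 1.0
    seed: int = 0
    # scene geometry: sized for a 60x/0.108 um px acquisition, where a
    # fibroblast nucleus spans ~15 um (r ~ 70 px) and a compact cell
    # footprint ~30-35 um (r ~ 150 px)
    cell_radius_px: float = 150.0
    nucleus_radius_px: float = 70.0
    #: total tubule centre-line length budget per cell
    mito_total_length_px: float = 1200.0
    # rendered intensities (counts) over a near-black background, as in
    # an acquisition optimized to minimize background signal
    nuclei_fg: float = 3000.0
    nuclei_bg: float = 20.0
    cell_fg: float = 1500.0
    cell_bg: float = 40.0
    mito_fg: float = 4000.0
    mito_bg: float = 20.0

    def __post_init__(self) -> None:
        for name in ("fragmentation", "swelling", "perinuclear_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def tubule_half_width_px(self) -> float:
        """Half-width of the tubule cross-section (width = 2r + 1).

        Spans ~0.3 um (thin tubule) to ~1 um (swollen) at the default
        pixel size; continuous so swelling series have no tied levels.
        """
        return 1.0 + 3.0 * self.swelling

    @property
    def n_tubules_per_cell(self) -> int:
        return int(round(5 + self.fragmentation * 75))


@dataclass
class GroundTruth:
    """True label masks plus per-cell truth values.

    ``per_cell`` columns: cell, true_mito_count (components of the true
    mask), true_end_points / true_branch_points (from the thinned true
    mask), true_width (drawn tubule width, px), true_dist_to_nucleus
    (mean distance of true mito pixels to the nucleus, px).
    """

    nuclei: LabelMask
    cells: LabelMask
    mito: LabelMask
    per_cell: pd.DataFrame = field(default_factory=pd.DataFrame)


def _cell_blob(center, radius, rng, shape):
    """Smooth star-convex blob: Fourier-perturbed radius polygon."""
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    r = np.full_like(theta, radius)
    for k in range(2, 6):
        amp = 0.05 * radius * rng.normal() / math.sqrt(k)
        phase = rng.uniform(0, 2 * np.pi)
        r = r + amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.6 * radius, 1.15 * radius)
    rr, cc = draw.polygon(center[0] + r * np.sin(theta), center[1] + r * np.cos(theta), shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _nucleus(center, radius, rng, shape):
    a = radius * rng.uniform(0.95, 1.1)
    b = radius * rng.uniform(0.85, 1.0)
    rot = rng.uniform(0, np.pi)
    rr, cc = draw.ellipse(center[0], center[1], a, b, shape=shape, rotation=rot)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _walk(rng, start, heading, n_steps, center, target_radius, allowed):
    """Radially-constrained persistent random walk inside ``allowed``.

    The heading diffuses slowly and is steered so the path orbits the
    cell centre near its launch radius, mimicking tubules arcing around
    the nucleus; steps leaving the allowed region trigger a turn.
    """
    pts = [start]
    pos = np.array(start, dtype=float)
    h, w = allowed.shape
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.12)
        # radial correction: steer back toward the launch radius
        d = pos - center
        r = np.hypot(*d)
        if r > 1e-6:
            radial_angle = math.atan2(d[0], d[1])
            err = (r - target_radius) / max(target_radius, 1.0)
            # rotate heading away from outward radial direction when too
            # far out, toward it when too far in
            outward = radial_angle
            delta = (heading - outward + np.pi) % (2 * np.pi) - np.pi
            heading -= 0.25 * err * np.sign(np.cos(delta)) * abs(np.cos(delta))
        step = np.array([math.sin(heading), math.cos(heading)])
        nxt = pos + step
        ri, ci = int(round(nxt[0])), int(round(nxt[1]))
        if not (0 <= ri < h and 0 <= ci < w) or not allowed[ri, ci]:
            heading += rng.choice((-1.0, 1.0)) * (np.pi / 2 + rng.uniform(0, np.pi / 4))
            continue
        pos = nxt
        pts.append((ri, ci))
    return pts, heading


def _render(mask, fg, bg, psf_sigma, noise_level, rng):
    img = np.where(mask, fg, 0.0) + bg
    if psf_sigma > 0:
        img = ndi.gaussian_filter(img, psf_sigma)
    if noise_level > 0:
        scale = noise_level * noise_level
        img = rng.poisson(img / scale).astype(np.float64) * scale
    return np.clip(img, 0, None)


def generate_field(params: SynthParams) -> tuple[FieldImage, GroundTruth]:
    """Generate one field and its ground truth.

    Cells are placed on a jittered grid; raises if ``n_cells`` cannot fit
    in the frame at the configured cell radius.
    """
    rng = np.random.default_rng(params.seed)
    side = params.image_side
    shape = (side, side)
    grid = math.ceil(math.sqrt(params.n_cells))
    spacing = side / grid
    if spacing < 2.2 * params.cell_radius_px:
        raise ValueError(
            f"n_cells={params.n_cells} too large for image_side={side} at "
            f"cell_radius_px={params.cell_radius_px}"
        )

    cell_labels = np.zeros(shape, dtype=np.int32)
    nuc_labels = np.zeros(shape, dtype=np.int32)
    mito_union = np.zeros(shape, dtype=bool)
    wr = params.tubule_half_width_px
    wi = int(math.ceil(wr))
    n_tub = params.n_tubules_per_cell
    tub_len = max(int(round(params.mito_total_length_px / n_tub)), 2 * wi + 2)
    path_px = np.zeros(shape, dtype=bool)

    centers = []
    k = 0
    for gy in range(grid):
        for gx in range(grid):
            if k >= params.n_cells:
                break
            cy = (gy + 0.5) * spacing + rng.uniform(-0.04, 0.04) * spacing
            cx = (gx + 0.5) * spacing + rng.uniform(-0.04, 0.04) * spacing
            centers.append((cy, cx))
            k += 1

    for idx, center in enumerate(centers, start=1):
        cell = _cell_blob(center, params.cell_radius_px, rng, shape) & (cell_labels == 0)
        nuc = _nucleus(center, params.nucleus_radius_px, rng, shape) & cell
        cell_labels[cell] = idx
        nuc_labels[nuc] = idx

        # tubules live in the cytoplasm, clear of the nucleus and the
        # cell edge by the tubule half-width (morphology on the cell's
        # bounding box only)
        rows = np.nonzero(cell.any(axis=1))[0]
        cols = np.nonzero(cell.any(axis=0))[0]
        m = wi + 3
        win = (
            slice(max(rows[0] - m, 0), min(rows[-1] + m + 1, side)),
            slice(max(cols[0] - m, 0), min(cols[-1] + m + 1, side)),
        )
        allowed = np.zeros(shape, dtype=bool)
        allowed[win] = morphology.erosion(cell[win], morphology.disk(wi + 1)) & ~morphology.dilation(
            nuc[win], morphology.disk(wi + 2)
        )
        r_in = params.nucleus_radius_px + wr + 4
        r_out = max(r_in + 5.0, 0.88 * params.cell_radius_px - wr)
        ctr = np.array(center)
        for _ in range(n_tub):
            # mixture model of perinuclear recruitment: a fraction
            # ``perinuclear_bias`` of tubules orbits in the inner band
            # next to the nucleus, the rest anywhere in the cytoplasm
            if rng.uniform() < params.perinuclear_bias:
                r0 = r_in + 0.15 * (r_out - r_in) * rng.uniform()
            else:
                r0 = r_in + (r_out - r_in) * rng.uniform()
            theta0 = rng.uniform(0, 2 * np.pi)
            start = ctr + r0 * np.array([math.sin(theta0), math.cos(theta0)])
            ri, ci = int(round(start[0])), int(round(start[1]))
            # nudge the launch point into the allowed region
            tries = 0
            while not (0 <= ri < side and 0 <= ci < side and allowed[ri, ci]) and tries < 20:
                theta0 = rng.uniform(0, 2 * np.pi)
                start = ctr + r0 * np.array([math.sin(theta0), math.cos(theta0)])
                ri, ci = int(round(start[0])), int(round(start[1]))
                tries += 1
            if tries >= 20:
                continue
            heading = theta0 + rng.choice((-1.0, 1.0)) * np.pi / 2  # tangential launch
            pts, heading = _walk(rng, (ri, ci), heading, tub_len, ctr, r0, allowed)
            for p in pts:
                path_px[p] = True
            # occasional side branch on long tubules; branching propensity
            # decays continuously as the network fragments
            if len(pts) > 10 and rng.uniform() < 0.3 * (1.0 - params.fragmentation):
                mid = pts[len(pts) // 2]
                bpts, _ = _walk(
                    rng, mid, heading + rng.choice((-1.0, 1.0)) * np.pi / 3,
                    max(4, tub_len // 3), ctr, r0, allowed,
                )
                for p in bpts:
                    path_px[p] = True

    # inflate centre lines to tubes of continuous half-width wr so the
    # tube cross-section tracks the swelling knob without quantization
    tubes = ndi.distance_transform_edt(~path_px) <= wr
    tubes &= (cell_labels > 0) & (nuc_labels == 0)
    mito_union = tubes

    field = FieldImage(
        nuclei_channel=_render(nuc_labels > 0, params.nuclei_fg, params.nuclei_bg,
                               params.psf_sigma, params.noise_level, rng),
        cell_channel=_render(cell_labels > 0, params.cell_fg, params.cell_bg,
                             params.psf_sigma, params.noise_level, rng),
        mito_channel=_render(mito_union, params.mito_fg, params.mito_bg,
                             params.psf_sigma, params.noise_level, rng),
        pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
        field_id=f"synth_seed{params.seed}",
        condition="synthetic",
    )

    mito_comp, _ = ndi.label(mito_union, structure=_EIGHT)
    truth = GroundTruth(
        nuclei=LabelMask(nuc_labels, kind="nuclei", parent_field=field.field_id),
        cells=LabelMask(cell_labels, kind="cells", parent_field=field.field_id),
        mito=LabelMask(mito_comp.astype(np.int32), kind="clusters", parent_field=field.field_id),
        per_cell=_per_cell_truth(cell_labels, nuc_labels, mito_union, 2 * wr + 1),
    )
    return field, truth


def _per_cell_truth(cell_labels, nuc_labels, mito_union, width) -> pd.DataFrame:
    skel = morphology.skeletonize(mito_union)
    nb = ndi.convolve(skel.astype(np.uint8), _EIGHT, mode="constant")
    nb = np.where(skel, nb - 1, 0)
    ends = skel & (nb <= 1)
    junction_nodes, _ = ndi.label(skel & (nb >= 3), structure=_EIGHT)
    dist_nuc = ndi.distance_transform_edt(nuc_labels == 0)
    rows = []
    for cell in range(1, int(cell_labels.max()) + 1):
        inside = cell_labels == cell
        comp, n_comp = ndi.label(mito_union & inside, structure=_EIGHT)
        junc_ids = np.unique(junction_nodes[inside])
        rows.append(
            {
                "cell": cell,
                "true_mito_count": int(n_comp),
                "true_end_points": int((ends & inside).sum()),
                "true_branch_points": int((junc_ids > 0).sum()),
                "true_width": float(width),
                "true_dist_to_nucleus": float(dist_nuc[mito_union & inside].mean())
                if (mito_union & inside).any()
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def phenotype_series(
    base: SynthParams, knob: str, values
) -> list[tuple[SynthParams, FieldImage, GroundTruth]]:
    """Generate fields differing only in one knob (shared seed).

    Mirrors a dose series: the same scene layout is re-rendered at each
    knob value.
    """
    if knob not in {f.name for f in dataclasses.fields(SynthParams)}:
        raise ValueError(f"unknown knob {knob!r}")
    out = []
    for v in values:
        params = dataclasses.replace(base, **{knob: v})
        fld, truth = generate_field(params)
        fld.condition = f"{knob}={v}"
        out.append((params, fld, truth))
    return out
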