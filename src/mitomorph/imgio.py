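"""Image, label-mask and feature-table I/O.

Defines the on-disk contract of the pipeline: one single-plane grayscale
TIFF per channel on input; lossless integer label TIFFs for the five mask
kinds and an RFC-4180 CSV (one row per cell, fixed header order) on output.

Conventions: row-major arrays, origin top-left, 0-based indices; all
geometry is in pixels, with micrometre conversions applied only in
reporting via ``pixel_size_um``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: The five label-mask kinds produced by the pipeline.
MASK_KINDS = ("nuclei", "cells", "clusters", "skeleton_branches", "isolated_mito")

#: Identifier columns preceding the feature columns in every cell table.
ID_COLUMNS = ["condition", "field_id", "cell_id"]

#: Default physical pixel size (60x objective, 1x zoom) in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.108333

CHANNEL_ROLES = ("nuclei", "cell", "mito")


@dataclass
class FieldImage:
    """One microscope field: three aligned 2D intensity channels.

    Channels are bound to dye roles explicitly (blue = nuclei stain,
    green = plasma-membrane stain, red = mitochondrial stain), never
    inferred from filenames or pixel statistics.
    """

    nuclei_channel: np.ndarray
    cell_channel: np.ndarray
    mito_channel: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    field_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        chans = {}
        for name in ("nuclei_channel", "cell_channel", "mito_channel"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 2:
                raise ValueError(f"{name} must be a single-plane 2D array, got ndim={arr.ndim}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"{name} contains negative intensities")
            chans[name] = arr
            setattr(self, name, arr)
        shapes = {a.shape for a in chans.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei_channel.shape


@dataclass
class LabelMask:
    """2D integer label image: 0 = background, k > 0 = object k.

    Labeling is compact: every value in ``1..K`` is present.
    """

    labels: np.ndarray
    kind: str
    parent_field: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("labels must be 2D")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if arr.size and arr.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}; expected one of {MASK_KINDS}")
        self.labels = arr

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def is_compact(self) -> bool:
        present = np.unique(self.labels)
        present = present[present > 0]
        return bool(np.array_equal(present, np.arange(1, present.size + 1)))


def compact_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel an integer image so nonzero labels are 1..K without gaps.

    Preserves the relative order of the original label values.
    """
    labels = np.asarray(labels)
    values = np.unique(labels)
    values = values[values > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[values] = np.arange(1, values.size + 1, dtype=np.int32)
    return lut[labels]


def _read_single_plane_tiff(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"channel file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise ValueError(
                f"{path} has {len(tf.pages)} pages; multi-page TIFFs (z-stacks, "
                "stitched composites) are not supported — supply one single-plane "
                "grayscale TIFF per channel"
            )
        arr = tf.pages[0].asarray()
    if arr.ndim != 2:
        raise ValueError(
            f"{path} is not single-channel grayscale (shape {arr.shape}); "
            "RGB/multichannel TIFFs are rejected"
        )
    return arr


def read_field(
    paths_per_channel: Mapping[str, str | os.PathLike],
    *,
    condition: str = "",
    field_id: str = "",
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> FieldImage:
    """Load one field from three single-plane TIFF files.

    Parameters
    ----------
    paths_per_channel
        Mapping with keys ``"nuclei"``, ``"cell"``, ``"mito"`` giving the
        file path of each dye channel. Roles are declared, never guessed.
    """
    missing = set(CHANNEL_ROLES) - set(paths_per_channel)
    if missing:
        raise ValueError(f"missing channel role(s): {sorted(missing)}")
    arrays = {role: _read_single_plane_tiff(paths_per_channel[role]) for role in CHANNEL_ROLES}
    return FieldImage(
        nuclei_channel=arrays["nuclei"],
        cell_channel=arrays["cell"],
        mito_channel=arrays["mito"],
        pixel_size_um=pixel_size_um,
        field_id=field_id,
        condition=condition,
    )


def _label_dtype(max_label: int) -> np.dtype:
    return np.dtype(np.uint16) if max_label <= np.iinfo(np.uint16).max else np.dtype(np.uint32)


def write_masks(masks: Sequence[LabelMask], out_dir: str | os.PathLike) -> list[Path]:
    """Write label masks as lossless integer TIFFs, one file per mask.

    The mask kind (and parent field id, when set) is encoded in the file
    name. Reading the file back reproduces the labels bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for mask in masks:
        stem = f"{mask.parent_field}_{mask.kind}" if mask.parent_field else mask.kind
        path = out_dir / f"{stem}.tif"
        data = mask.labels.astype(_label_dtype(mask.n_objects))
        tifffile.imwrite(path, data)
        paths.append(path)
    return paths


def read_mask(path: str | os.PathLike, kind: str, parent_field: str = "") -> LabelMask:
    arr = tifffile.imread(path)
    return LabelMask(labels=arr.astype(np.int32), kind=kind, parent_field=parent_field)


def write_cell_table(records: pd.DataFrame, out_path: str | os.PathLike) -> Path:
    """Write the per-cell feature table as CSV: one row per cell.

    Column order is fixed: identifier columns then the 31 feature names in
    their canonical order. Raises if the frame does not carry the full
    schema.
    """
    from .features import FEATURE_NAMES  # deferred: features imports nothing from imgio

    out_path = Path(out_path)
    columns = ID_COLUMNS + FEATURE_NAMES
    missing = [c for c in columns if c not in records.columns]
    if missing:
        raise ValueError(f"cell table is missing columns: {missing}")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    records.loc[:, columns].to_csv(out_path, index=False, lineterminator="\r\n")
    return out_path


def read_cell_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    from .features import FEATURE_NAMES

    missing = [c for c in ID_COLUMNS + FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"cell table at {path} is missing columns: {missing}")
    return df
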