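"""End-to-end orchestration: segment a field, extract the 31 features,
batch-process folders deterministically, and compare conditions.

Each field is processed independently (per-field parallelism only), so
outputs are identical regardless of worker count or scheduling.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import ndimage as ndi

from . import __version__
from .features import (
    FEATURE_NAMES,
    CellFeatureRecord,
    _descriptors_from_regionprops,
    aggregate_objects,
    box_count_fd,
    localization_features,
    records_to_frame,
    skeleton_features,
)
from .imgio import FieldImage, read_field, write_cell_table, write_masks
from .segmentation import SegmentationParams, SegmentationResult, segment_field
from .skeleton import SkeletonGraph, segment_isolated_mito, skeletonize_clusters

from skimage import measure

log = logging.getLogger("mitomorph")


# ---------------------------------------------------------------------------
# per-field analysis
# ---------------------------------------------------------------------------


def _regionprops_table(label_img, intensity=None):
    return measure.regionprops(label_img, intensity_image=intensity)


def extract_features(
    field: FieldImage,
    seg: SegmentationResult,
    graph: SkeletonGraph,
    isolated,
    *,
    literal_roundness: bool = False,
) -> pd.DataFrame:
    """Assemble the 31-descriptor record for every cell of a field."""
    cells = seg.cells.labels
    nuclei = seg.nuclei.labels
    clusters = seg.clusters.labels
    cluster_to_cell = seg.cluster_to_cell

    # per-cluster object features (cluster mask + red channel)
    cluster_rows = []
    for rp in _regionprops_table(clusters, field.mito_channel):
        d = _descriptors_from_regionprops(rp, literal_roundness=literal_roundness)
        cluster_rows.append(
            {
                "cluster": rp.label,
                "cell": cluster_to_cell.get(rp.label, 0),
                "MitoCluster_Area": d["area"],
                "MitoCluster_Perimeter": d["perimeter"],
                "MitoCluster_Compaction": d["compaction"],
                "MitoCluster_Elongation": d["elongation"],
                "MitoCluster_Roundness": d["roundness"],
                "MitoCluster_EulerNumber": d["euler"],
                "MitoCluster_Solidity": d["solidity"],
                "_intensity_sum": float(rp.image_intensity[rp.image].sum()),
                "_intensity_max": float(rp.intensity_max),
            }
        )
    cluster_df = pd.DataFrame(cluster_rows)

    # per-isolated-mitochondrion object features
    iso_rows = []
    branch_lengths = (
        dict(zip(graph.branches["branch"].astype(int), graph.branches["length"]))
        if len(graph.branches)
        else {}
    )
    iso_labels = isolated.labels
    if iso_labels.max() > 0:
        owner_cell = {}
        ids = np.unique(iso_labels)
        ids = ids[ids > 0]
        owners = ndi.maximum(cells, labels=iso_labels, index=ids)
        owner_cell = dict(zip(ids.astype(int), np.asarray(owners, dtype=int)))
        for rp in _regionprops_table(iso_labels):
            d = _descriptors_from_regionprops(rp, literal_roundness=literal_roundness)
            iso_rows.append(
                {
                    "mito": rp.label,
                    "cell": owner_cell.get(rp.label, 0),
                    "Mito_Compaction": d["compaction"],
                    "Mito_Elongation": d["elongation"],
                    "Mito_Roundness": d["roundness"],
                    "Mito_Length": float(branch_lengths.get(rp.label, 0.0)),
                }
            )
    iso_df = pd.DataFrame(iso_rows)

    skel_counts = graph.per_cell_counts().set_index("cell") if len(graph.branches) else pd.DataFrame()

    records = []
    for rp in _regionprops_table(cells, field.cell_channel):
        cell_id = rp.label
        d = _descriptors_from_regionprops(rp, literal_roundness=literal_roundness)
        feats = {
            "Cell_Area": d["area"],
            "Cell_MeanIntensity": float(rp.intensity_mean),
            "Cell_MaxIntensity": float(rp.intensity_max),
            "Cell_Perimeter": d["perimeter"],
            "Cell_Compaction": d["compaction"],
            "Cell_Roundness": d["roundness"],
        }

        cl = cluster_df[cluster_df["cell"] == cell_id] if len(cluster_df) else cluster_df
        cluster_feature_names = [
            "MitoCluster_Area",
            "MitoCluster_Perimeter",
            "MitoCluster_Compaction",
            "MitoCluster_Elongation",
            "MitoCluster_Roundness",
            "MitoCluster_EulerNumber",
            "MitoCluster_Solidity",
        ]
        feats.update(aggregate_objects(cl, cluster_feature_names))
        feats["MitoCluster_Count"] = float(len(cl))
        if len(cl):
            total_area = cl["MitoCluster_Area"].sum()
            feats["Mito_MeanIntensity"] = float(cl["_intensity_sum"].sum() / total_area)
            feats["Mito_MaxIntensity"] = float(cl["_intensity_max"].mean())
        else:
            feats["Mito_MeanIntensity"] = float("nan")
            feats["Mito_MaxIntensity"] = float("nan")

        # fractal profile on the cell's cluster union, cropped to the
        # cell's bounding box (C is the per-cell mitochondria mask)
        r0, c0, r1, c1 = rp.bbox
        union = ((clusters > 0) & (cells == cell_id))[r0:r1, c0:c1]
        f2, f8, f32 = box_count_fd(union)
        feats["MitoCluster_Fractal2"] = f2
        feats["MitoCluster_Fractal8"] = f8
        feats["MitoCluster_Fractal32"] = f32

        if cell_id in getattr(skel_counts, "index", []):
            row = skel_counts.loc[cell_id]
            total_area = float(cl["MitoCluster_Area"].sum()) if len(cl) else 0.0
            feats.update(
                skeleton_features(
                    row["total_length"], int(row["n_junction_nodes"]), int(row["n_end_points"]), total_area
                )
            )
        else:
            feats.update(
                {
                    "Skel_Width": float("nan"),
                    "Skel_Length": float("nan"),
                    "Skel_BranchPointsCount": float("nan"),
                    "Skel_EndPointsCount": float("nan"),
                    "Skel_BranchPointsEndPointsRatio": float("nan"),
                }
            )

        it = iso_df[iso_df["cell"] == cell_id] if len(iso_df) else iso_df
        feats.update(
            aggregate_objects(it, ["Mito_Compaction", "Mito_Elongation", "Mito_Roundness", "Mito_Length"])
        )

        # localization distances only need the cell's neighbourhood
        pr0, pc0 = max(r0 - 1, 0), max(c0 - 1, 0)
        pr1, pc1 = min(r1 + 1, cells.shape[0]), min(c1 + 1, cells.shape[1])
        win = (slice(pr0, pr1), slice(pc0, pc1))
        cell_win = cells[win] == cell_id
        feats.update(
            localization_features(
                graph.skeleton[win] & cell_win, cell_win, nuclei[win] == cell_id
            )
        )

        records.append(
            CellFeatureRecord(
                condition=field.condition, field_id=field.field_id, cell_id=int(cell_id), features=feats
            )
        )
    return records_to_frame(records)


def process_field(
    field: FieldImage, params: SegmentationParams | None = None
) -> tuple[dict, pd.DataFrame]:
    """Segment one field end-to-end and extract per-cell features.

    Returns the five label masks (keyed by kind) and the feature table.
    """
    params = params or SegmentationParams()
    seg = segment_field(field, params)
    graph = skeletonize_clusters(seg.clusters, seg.cluster_to_cell)
    isolated, _ = segment_isolated_mito(seg.clusters, graph)
    isolated.parent_field = field.field_id
    from .imgio import LabelMask

    skeleton_mask = LabelMask(
        labels=graph.branch_labels, kind="skeleton_branches", parent_field=field.field_id
    )
    table = extract_features(field, seg, graph, isolated)
    masks = {
        "nuclei": seg.nuclei,
        "cells": seg.cells,
        "clusters": seg.clusters,
        "skeleton_branches": skeleton_mask,
        "isolated_mito": isolated,
    }
    log.info(
        "field %s: %d cells, %d clusters", field.field_id, seg.cells.n_objects, seg.clusters.n_objects
    )
    return masks, table


# ---------------------------------------------------------------------------
# batch runs
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Folder-level run configuration, serializable to YAML."""

    input_dir: str
    output_dir: str
    channel_patterns: dict = dc_field(
        default_factory=lambda: {"nuclei": "*_nuclei.tif", "cell": "*_cell.tif", "mito": "*_mito.tif"}
    )
    condition: str = ""
    pixel_size_um: float = 0.108333
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    n_workers: int = 1
    write_mask_files: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)


def discover_fields(config: RunConfig) -> list[dict]:
    """Match channel files per field by shared stem across role patterns.

    The part of the filename matched by the pattern's ``*`` is the field
    id; a field needs all three roles present.
    """
    root = Path(config.input_dir)
    per_role = {}
    for role, pattern in config.channel_patterns.items():
        prefix, _, suffix = pattern.partition("*")
        matches = {}
        for path in sorted(root.glob(pattern)):
            stem = path.name[len(prefix) : len(path.name) - len(suffix)]
            matches[stem] = path
        per_role[role] = matches
    stems = sorted(set.intersection(*(set(m) for m in per_role.values()))) if per_role else []
    if not stems:
        raise FileNotFoundError(
            f"no complete fields found under {root} with patterns {config.channel_patterns}"
        )
    return [
        {"field_id": stem, "paths": {role: per_role[role][stem] for role in per_role}}
        for stem in stems
    ]


def _process_one(entry: dict, config: RunConfig):
    try:
        fld = read_field(
            entry["paths"],
            condition=config.condition,
            field_id=entry["field_id"],
            pixel_size_um=config.pixel_size_um,
        )
        masks, table = process_field(fld, config.segmentation)
        return entry["field_id"], masks, table, None
    except Exception as exc:  # per-field failures are recorded, never silent
        return entry["field_id"], None, None, f"{type(exc).__name__}: {exc}"


def run_pipeline(config: RunConfig) -> dict:
    """Process every field of a folder; write masks, CSV and a manifest.

    Returns the manifest dict. Outputs are bit-identical for any
    ``n_workers``: fields are independent and results are assembled in
    sorted field order.
    """
    entries = discover_fields(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.n_workers > 1:
        results = Parallel(n_jobs=config.n_workers)(
            delayed(_process_one)(e, config) for e in entries
        )
    else:
        results = [_process_one(e, config) for e in entries]
    results.sort(key=lambda r: r[0])

    tables = []
    failures = {}
    per_field_cells = {}
    for field_id, masks, table, error in results:
        if error is not None:
            failures[field_id] = error
            log.error("field %s failed: %s", field_id, error)
            continue
        tables.append(table)
        per_field_cells[field_id] = int(len(table))
        if config.write_mask_files:
            write_masks(list(masks.values()), out_dir / "masks")

    from .features import FEATURE_NAMES as _names
    from .imgio import ID_COLUMNS

    combined = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=ID_COLUMNS + _names)
    )
    csv_path = write_cell_table(combined, out_dir / "cell_features.csv")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_fields": len(entries),
        "per_field_cells": per_field_cells,
        "failures": failures,
        "csv": str(csv_path),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


def compare_conditions(
    tables: dict[str, pd.DataFrame],
    reference: str,
    out_dir: str | Path | None = None,
):
    """Normalize condition means, test significance, classify and plot.

    ``tables`` maps condition name to a per-cell feature table. Returns
    (profiles, tiers, sigils); when ``out_dir`` is given, also writes the
    spider plot (SVG), the sigil JSON and the stats CSV.
    """
    from .morphospace import classify_sigil, normalize_profiles, render_spider, significance_tiers

    if reference not in tables:
        raise ValueError(f"reference condition {reference!r} not among {sorted(tables)}")
    schemas = {tuple(sorted(set(t.columns) & set(FEATURE_NAMES))) for t in tables.values()}
    if len(schemas) != 1 or len(next(iter(schemas))) != len(FEATURE_NAMES):
        raise ValueError("condition tables have mismatching feature schemas")

    means = pd.DataFrame({cond: t[FEATURE_NAMES].mean() for cond, t in tables.items()}).T
    profiles = normalize_profiles(means, reference)
    tiers = {
        cond: significance_tiers(tables[reference], t, FEATURE_NAMES)
        for cond, t in tables.items()
        if cond != reference
    }
    sigils = {cond: classify_sigil(tiers[cond]) for cond in tiers}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        render_spider(profiles, tiers, out_dir / "mitospider.svg", reference=reference)
        with open(out_dir / "sigils.json", "w") as fh:
            json.dump({c: s.to_dict() for c, s in sigils.items()}, fh, indent=2)
        stats = pd.concat(
            {c: t.assign(condition=c) for c, t in tiers.items()}, ignore_index=True
        )
        stats.to_csv(out_dir / "stats.csv", index=False)
    return profiles, tiers, sigils
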