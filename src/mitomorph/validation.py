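"""Ground-truth validation utilities on synthetic fields.

These helpers back the package's self-validation: they run the full
measurement pipeline over synthetic phenotype series and against the
generator's ground truth, returning tidy frames from which recovery
errors and dose-response monotonicity are computed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import process_field
from .segmentation import SegmentationParams
from .synthgen import SynthParams, generate_field


def phenotype_response(
    knob: str,
    values,
    base: SynthParams | None = None,
    n_fields_per_level: int = 5,
    seed: int = 0,
    seg_params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Measure per-cell features over a synthetic dose series.

    For each knob value, ``n_fields_per_level`` fields are generated
    (seeds derived from ``seed`` and the field index so that the same
    scene layouts recur at every level) and processed end-to-end.
    Returns the concatenated per-cell feature tables with ``level`` and
    ``field_seed`` columns.
    """
    base = base or SynthParams()
    tables = []
    for value in values:
        for i in range(n_fields_per_level):
            params = dataclasses.replace(base, **{knob: value}, seed=seed + i)
            fld, _ = generate_field(params)
            fld.condition = f"{knob}={value}"
            _, table = process_field(fld, seg_params)
            table = table.assign(level=value, field_seed=params.seed)
            tables.append(table)
    return pd.concat(tables, ignore_index=True)


def level_spearman(per_cell: pd.DataFrame, feature: str) -> float:
    """Spearman correlation between knob level and the per-level feature mean."""
    means = per_cell.groupby("level")[feature].mean()
    rho, _ = stats.spearmanr(means.index.to_numpy(), means.to_numpy())
    return float(rho)


def recovery_metrics(
    n_fields: int = 3, seed: int = 0, base: SynthParams | None = None
) -> pd.DataFrame:
    """Pipeline-on-truth recovery on noiseless, lightly blurred fields.

    Matches each true cell to the recovered cell of maximal overlap and
    reports per-cell IoUs and relative errors of the cluster count and
    skeleton end-point count against the generator's ground truth.
    """
    base = base or SynthParams()
    base = dataclasses.replace(base, noise_level=0.0, psf_sigma=0.5)
    rows = []
    for i in range(n_fields):
        params = dataclasses.replace(base, seed=seed + i)
        fld, truth = generate_field(params)
        masks, table = process_field(fld)
        rn = masks["nuclei"].labels
        rc = masks["cells"].labels
        for k in range(1, truth.cells.n_objects + 1):
            tn = truth.nuclei.labels == k
            tc = truth.cells.labels == k
            ln = int(np.bincount(rn[tn]).argmax()) if tn.any() else 0
            lc = int(np.bincount(rc[tc]).argmax()) if tc.any() else 0
            if ln == 0 or lc == 0 or not (table.cell_id == lc).any():
                rows.append({"field_seed": params.seed, "cell": k, "matched": False})
                continue
            meas = table[table.cell_id == lc].iloc[0]
            tr = truth.per_cell[truth.per_cell.cell == k].iloc[0]
            nuc_iou = float((tn & (rn == ln)).sum() / (tn | (rn == ln)).sum())
            cell_iou = float((tc & (rc == lc)).sum() / (tc | (rc == lc)).sum())
            rows.append(
                {
                    "field_seed": params.seed,
                    "cell": k,
                    "matched": True,
                    "nucleus_iou": nuc_iou,
                    "cell_iou": cell_iou,
                    "true_count": float(tr.true_mito_count),
                    "measured_count": float(meas.MitoCluster_Count),
                    "count_rel_err": abs(meas.MitoCluster_Count - tr.true_mito_count)
                    / tr.true_mito_count,
                    "true_ends": float(tr.true_end_points),
                    "measured_ends": float(meas.Skel_EndPointsCount),
                    "ends_rel_err": abs(meas.Skel_EndPointsCount - tr.true_end_points)
                    / tr.true_end_points,
                }
            )
    return pd.DataFrame(rows)


def pixel_conservation(seed: int = 0, base: SynthParams | None = None) -> tuple[int, int]:
    """Support sizes (clusters, isolated) on one synthetic field.

    The isolated-mitochondria re-segmentation must conserve the cluster
    support pixel-exactly.
    """
    from .segmentation import segment_field
    from .skeleton import segment_isolated_mito, skeletonize_clusters

    base = base or SynthParams()
    params = dataclasses.replace(base, seed=seed)
    fld, _ = generate_field(params)
    seg = segment_field(fld)
    graph = skeletonize_clusters(seg.clusters, seg.cluster_to_cell)
    isolated, _ = segment_isolated_mito(seg.clusters, graph)
    return int((seg.clusters.labels > 0).sum()), int((isolated.labels > 0).sum())
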