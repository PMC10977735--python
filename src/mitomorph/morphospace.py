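"""Condition-level morphospace: normalized spider profiles, significance
tiers and rule-based sigil classification.

Per-condition feature means Vp are min-max normalized across the
conditions being compared, Vn = (Vp - Vmin)/(Vmax - Vmin), and drawn on a
radar ("spider") chart whose axes follow five ontology groups
(Abundance, Shape, Connectivity, Size, Density & Texture). Each
non-reference condition gets per-feature two-sample t-tests against the
reference; p-value tiers (* < 0.05, ** < 0.01, *** < 0.001) are encoded
as circles of three sizes at the feature vertices. The signature of
significant feature changes is then classified into a three-axis sigil
code: mitochondrial state (M1-M7), localization (I1-I3) and cell shape
(C1-C6), with M1/I1/C1 the no-change reference codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

#: Ontology group per feature, used only for spider-axis ordering.
FEATURE_GROUPS = {
    "Abundance": [
        "MitoCluster_Count",
        "Mito_MeanIntensity",
        "Mito_MaxIntensity",
        "Cell_MeanIntensity",
        "Cell_MaxIntensity",
    ],
    "Shape": [
        "Cell_Compaction",
        "Cell_Roundness",
        "MitoCluster_Compaction",
        "MitoCluster_Elongation",
        "MitoCluster_Roundness",
        "Mito_Compaction",
        "Mito_Elongation",
        "Mito_Roundness",
    ],
    "Connectivity": [
        "Skel_BranchPointsCount",
        "Skel_EndPointsCount",
        "Skel_BranchPointsEndPointsRatio",
        "MitoCluster_EulerNumber",
        "Skel_Width",
    ],
    "Size": [
        "Cell_Area",
        "Cell_Perimeter",
        "MitoCluster_Area",
        "MitoCluster_Perimeter",
        "Skel_Length",
        "Mito_Length",
    ],
    "Density & Texture": [
        "MitoCluster_Fractal2",
        "MitoCluster_Fractal8",
        "MitoCluster_Fractal32",
        "MitoCluster_Solidity",
        "DistToMembrane",
        "DistToNuclei",
        "RatioDistMemb0Nucl1",
    ],
}

#: Spider-axis feature order: the five groups concatenated.
SPIDER_ORDER = [f for group in FEATURE_GROUPS.values() for f in group]
assert sorted(SPIDER_ORDER) == sorted(FEATURE_NAMES)

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_tier(p: float) -> str:
    """Map a p-value to its significance tier (ns, *, ** or ***)."""
    if np.isnan(p):
        return "ns"
    for threshold, tier in TIER_THRESHOLDS:
        if p < threshold:
            return tier
    return "ns"


@dataclass
class SpiderProfile:
    """Min-max normalized condition profiles over the 31 features.

    ``vp`` and ``vn`` are condition x feature frames; ``degenerate``
    flags features whose means were identical across all conditions
    (their Vn is pinned to 0.5).
    """

    vp: pd.DataFrame
    vn: pd.DataFrame
    reference: str
    degenerate: list = field(default_factory=list)


def normalize_profiles(condition_means: pd.DataFrame, reference: str) -> SpiderProfile:
    """Normalize per-condition feature means to [0, 1].

    Vmin/Vmax are taken per feature over the condition means being
    compared. Features with Vmax = Vmin get Vn = 0.5 everywhere and are
    flagged degenerate.
    """
    if reference not in condition_means.index:
        raise ValueError(f"reference {reference!r} not among conditions {list(condition_means.index)}")
    if len(condition_means) < 2:
        raise ValueError("normalization needs at least two conditions")
    vmin = condition_means.min(axis=0)
    vmax = condition_means.max(axis=0)
    span = vmax - vmin
    degenerate = list(span.index[(span == 0) | span.isna()])
    safe = span.replace(0, np.nan)
    vn = (condition_means - vmin) / safe
    vn[degenerate] = 0.5
    return SpiderProfile(vp=condition_means, vn=vn, reference=reference, degenerate=degenerate)


def significance_tiers(
    reference_cells: pd.DataFrame,
    condition_cells: pd.DataFrame,
    features: list[str] | None = None,
    *,
    experiment_col: str | None = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-feature two-sample t-test of a condition against the reference.

    The statistical unit defaults to the cell; when ``experiment_col``
    names a replicate column, cells are first averaged per experiment and
    n becomes the number of independent experiments. Welch's unequal-
    variance test is the default; set ``welch=False`` for Student's.

    Returns one row per feature: p_value, tier, direction (sign of the
    condition mean minus the reference mean).
    """
    features = features or FEATURE_NAMES
    if experiment_col is not None:
        reference_cells = reference_cells.groupby(experiment_col)[features].mean()
        condition_cells = condition_cells.groupby(experiment_col)[features].mean()
    rows = []
    for feat in features:
        a = np.asarray(reference_cells[feat].dropna(), dtype=float)
        b = np.asarray(condition_cells[feat].dropna(), dtype=float)
        direction = float(np.sign(b.mean() - a.mean())) if a.size and b.size else 0.0
        if a.size < 2 or b.size < 2:
            p = float("nan")
        elif a.std() == 0 and b.std() == 0:
            # zero-variance fast path: exact equality decides
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        rows.append({"feature": feat, "p_value": p, "tier": p_to_tier(p), "direction": direction})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sigil classification
# ---------------------------------------------------------------------------


@dataclass
class SigilCode:
    """Three-axis morphospace code with a rule-firing trace."""

    mito_state: list
    localization: str
    cell_shape: list
    conflicts: list = field(default_factory=list)
    trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mito_state": self.mito_state,
            "localization": self.localization,
            "cell_shape": self.cell_shape,
            "conflicts": self.conflicts,
            "trace": self.trace,
        }


def _sig(tiers: pd.DataFrame, feature: str, direction: int) -> bool:
    row = tiers.loc[tiers["feature"] == feature]
    if row.empty:
        return False
    return bool((row["tier"].iloc[0] != "ns") and (row["direction"].iloc[0] == direction))


def classify_sigil(tiers: pd.DataFrame) -> SigilCode:
    """Rule-based mapping from significant feature changes to a sigil.

    A pure function of per-feature (direction, tier) pairs: with no
    significant change on an axis the reference code (M1/I1/C1) is
    emitted; several rules may fire on the mito and cell axes (composite
    states), which is reported with a conflict flag.
    """
    up, down = 1, -1
    s = lambda f, d: _sig(tiers, f, d)

    mito = []
    trace = {}
    rounder = (
        s("Mito_Roundness", up)
        or s("Mito_Compaction", up)
        or s("MitoCluster_Roundness", up)
        or s("MitoCluster_Compaction", up)
    )
    if s("MitoCluster_Count", down) and s("Mito_Length", up):
        mito.append("M2")  # fusion: fewer, longer mitochondria
        trace["M2"] = "MitoCluster_Count down, Mito_Length up"
    if s("Skel_BranchPointsCount", up) and s("Skel_Length", up):
        mito.append("M3")  # branching
        trace["M3"] = "Skel_BranchPointsCount up, Skel_Length up"
    if s("MitoCluster_Compaction", up) and s("MitoCluster_Area", down) and not s("MitoCluster_Count", up):
        mito.append("M4")  # compaction without fission
        trace["M4"] = "MitoCluster_Compaction up, MitoCluster_Area down, count not up"
    if s("Skel_Length", down) and s("Skel_BranchPointsCount", down) and s("MitoCluster_Solidity", up):
        mito.append("M5")  # dislocation
        trace["M5"] = "Skel_Length down, branch points down, cluster solidity up"
    if s("MitoCluster_Count", up) and s("Mito_Length", down) and rounder:
        mito.append("M6")  # total or partial fission
        trace["M6"] = "MitoCluster_Count up, Mito_Length down, roundness/compaction up"
    if s("Skel_Width", up):
        mito.append("M7")  # total or partial swelling
        trace["M7"] = "Skel_Width up"
    if not mito:
        mito = ["M1"]

    to_nucleus = s("DistToNuclei", down)
    to_membrane = s("DistToMembrane", down)
    if to_nucleus and to_membrane:
        # both shrink (e.g. overall retraction); the ratio decides
        localization = "I3" if _sig(tiers, "RatioDistMemb0Nucl1", down) else "I2"
        conflicts = ["localization: both distances decreased"]
        trace["I"] = "both distances down; RatioDistMemb0Nucl1 decides"
    elif to_nucleus:
        localization, conflicts = "I3", []
        trace["I3"] = "DistToNuclei down"
    elif to_membrane:
        localization, conflicts = "I2", []
        trace["I2"] = "DistToMembrane down"
    else:
        localization, conflicts = "I1", []

    cell = []
    if s("Cell_Area", down):
        cell.append("C2")  # retraction
        trace["C2"] = "Cell_Area down"
    if s("Cell_Area", up):
        cell.append("C3")  # spreading
        trace["C3"] = "Cell_Area up"
    if s("Cell_Compaction", up) or s("Cell_Roundness", up):
        cell.append("C4")  # cell compaction
        trace["C4"] = "Cell_Compaction/Cell_Roundness up"
    if s("Cell_Perimeter", up) and not s("Cell_Area", up):
        cell.append("C5")  # star-like
        trace["C5"] = "Cell_Perimeter up without Cell_Area up"
    if s("Cell_MeanIntensity", up) or s("Cell_MeanIntensity", down):
        cell.append("C6")  # membrane-stain intensity shift
        trace["C6"] = "Cell_MeanIntensity changed"
    if not cell:
        cell = ["C1"]

    if len(mito) > 1:
        conflicts.append(f"mito axis composite: {mito}")
    if len(cell) > 1:
        conflicts.append(f"cell axis composite: {cell}")
    return SigilCode(
        mito_state=mito, localization=localization, cell_shape=cell, conflicts=conflicts, trace=trace
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_TIER_RADIUS = {"*": 3.0, "**": 6.0, "***": 9.0}


def render_spider(
    profiles: SpiderProfile,
    tiers: dict[str, pd.DataFrame] | None,
    out_path,
    *,
    reference: str | None = None,
) -> None:
    """Radar chart of normalized profiles with significance circles.

    The reference condition is drawn as a circle (display convention);
    other conditions as polylines over the 31 axes, ordered by the five
    ontology groups. Significant features get a circle glyph at the
    vertex whose size encodes the tier.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reference = reference or profiles.reference
    order = [f for f in SPIDER_ORDER if f in profiles.vn.columns]
    n = len(order)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(9, 9))
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    # reference baseline circle
    ax.plot(
        np.linspace(0, 2 * np.pi, 200),
        np.full(200, 0.5),
        color="green",
        lw=2,
        label=f"{reference} (reference)",
    )
    for cond in profiles.vn.index:
        if cond == reference:
            continue
        vals = profiles.vn.loc[cond, order].to_numpy(dtype=float)
        closed = np.concatenate([vals, vals[:1]])
        ang = np.concatenate([angles, angles[:1]])
        ax.plot(ang, closed, lw=1.5, ls="--", label=str(cond))
        if tiers and cond in tiers:
            t = tiers[cond].set_index("feature")
            for a, f, v in zip(angles, order, vals):
                tier = t.loc[f, "tier"] if f in t.index else "ns"
                if tier in _TIER_RADIUS:
                    ax.plot(a, v, "o", ms=_TIER_RADIUS[tier], mfc="none", mec="black")
    ax.set_xticks(angles)
    ax.set_xticklabels(order, fontsize=6)
    ax.set_ylim(-0.05, 1.1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
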