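"""Atlas-space quantification of classified signal.

Once a probability map sits on the atlas grid, every annotated region's
signal is summarized two ways — the summed probability mass of its voxels
and the count of voxels at or above a segmentation threshold (default 5% of
the 8-bit range) — and normalized per region volume to a density in units
per mm^3.  Quantities are reported per hemisphere, rolled up through the
region ontology, and assembled into sample x region heat-map tables.

Both the mass and the count readouts are carried through every table so
either convention can be compared downstream.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ProbabilityMap
from .register import AtlasBundle

logger = logging.getLogger("stptquant")

__all__ = [
    "DEFAULT_THRESHOLD_FRACTION",
    "quantify_regions",
    "aggregate_hierarchy",
    "split_hemispheres",
    "compute_density",
    "build_heatmap_matrix",
    "render_heatmap",
    "QUANT_COLUMNS",
]

#: default segmentation threshold: 5% of the 8-bit range
DEFAULT_THRESHOLD_FRACTION = 0.05

QUANT_COLUMNS = [
    "sample_id",
    "label",
    "region_id",
    "acronym",
    "hemisphere",
    "summed_signal",
    "voxel_count",
    "region_voxels",
    "volume_mm3",
    "signal_density",
    "count_density",
]


def split_hemispheres(atlas: AtlasBundle) -> np.ndarray:
    """Per-voxel hemisphere assignment from the atlas midline.

    Returns an int8 volume with 0 = left, 1 = right.  A voxel center whose
    left-right coordinate equals the midline is assigned left (documented
    tie rule).
    """
    n_cols = atlas.labels.shape[2]
    if not (0 <= atlas.midline <= n_cols - 1):
        raise ValueError(
            f"midline {atlas.midline} lies outside the volume (0..{n_cols - 1})"
        )
    cols = np.arange(n_cols)
    right = cols > atlas.midline  # ties (==) go left
    out = np.zeros(atlas.labels.shape, dtype=np.int8)
    out[:, :, right] = 1
    return out


def compute_density(quantity: float, region_volume_mm3: float) -> float:
    """Signal per mm^3; region volume comes from the atlas label volume
    itself (voxel count x voxel volume), never a published table."""
    if region_volume_mm3 <= 0:
        raise ValueError("region volume must be positive")
    return quantity / region_volume_mm3


def _per_region_table(
    p: np.ndarray,
    labels: np.ndarray,
    hemi_mask: np.ndarray,
    threshold_fraction: float,
    voxel_volume_mm3: float,
    region_ids: np.ndarray,
    hemisphere: str,
) -> pd.DataFrame:
    sel_labels = labels[hemi_mask]
    sel_p = p[hemi_mask]
    nbins = int(region_ids.max()) + 1 if region_ids.size else 1
    summed = np.bincount(sel_labels, weights=sel_p, minlength=nbins)
    above = sel_p >= threshold_fraction
    counts = np.bincount(sel_labels[above], minlength=nbins)
    voxels = np.bincount(sel_labels, minlength=nbins)
    return pd.DataFrame(
        {
            "region_id": region_ids,
            "hemisphere": hemisphere,
            "summed_signal": summed[region_ids],
            "voxel_count": counts[region_ids].astype(int),
            "region_voxels": voxels[region_ids].astype(int),
            "volume_mm3": voxels[region_ids] * voxel_volume_mm3,
        }
    )


def quantify_regions(
    prob: ProbabilityMap,
    atlas: AtlasBundle,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Leaf-level region quantification of one probability map.

    For every label ID present in the atlas label volume (leaf assignment),
    each hemisphere and bilaterally: ``summed_signal`` = sum of v/255 over
    member voxels, ``voxel_count`` = number of voxels with v/255 >= the
    threshold fraction.  Background (ID 0, outside brain) is reported as its
    own row so that total mass is conserved and checkable.
    """
    if prob.values.shape != atlas.labels.shape:
        raise ValueError(
            f"probability grid {prob.values.shape} != atlas grid {atlas.labels.shape}"
        )
    if not (0.0 <= threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must lie in [0, 1]")
    p = prob.probabilities
    labels = atlas.labels
    hemi = split_hemispheres(atlas)
    region_ids = np.unique(labels)
    vox_mm3 = atlas.voxel_volume_mm3
    parts = [
        _per_region_table(
            p, labels, hemi == 0, threshold_fraction, vox_mm3, region_ids, "left"
        ),
        _per_region_table(
            p, labels, hemi == 1, threshold_fraction, vox_mm3, region_ids, "right"
        ),
    ]
    both = parts[0].drop(columns="hemisphere").set_index("region_id") + parts[
        1
    ].drop(columns="hemisphere").set_index("region_id")
    both = both.reset_index()
    both["hemisphere"] = "both"
    df = pd.concat(parts + [both], ignore_index=True)
    acronyms = {r.id: r.acronym for r in atlas.ontology}
    acronyms[0] = "background"
    df["acronym"] = df["region_id"].map(acronyms)
    df["sample_id"] = sample_id
    df["label"] = prob.label_name
    df = _add_densities(df)
    return df[QUANT_COLUMNS]


def _add_densities(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["signal_density"] = np.where(
            df["volume_mm3"] > 0, df["summed_signal"] / df["volume_mm3"], np.nan
        )
        df["count_density"] = np.where(
            df["volume_mm3"] > 0, df["voxel_count"] / df["volume_mm3"], np.nan
        )
    n_zero = int((df["volume_mm3"] <= 0).sum())
    if n_zero:
        logger.warning("%d zero-volume region rows have no density", n_zero)
    return df


def aggregate_hierarchy(leaf_matrix: pd.DataFrame, atlas: AtlasBundle) -> pd.DataFrame:
    """Roll leaf-level quantities up the region ontology.

    Each region's quantities are its directly assigned voxels' quantities
    plus the sum over all descendants; volumes aggregate identically.  The
    background row (ID 0) is outside the tree and passes through unchanged.
    Raises on a cyclic ontology.
    """
    children = atlas.children_map()
    # topological order by depth-first traversal from the root, cycle-checked
    order: list[int] = []
    state: dict[int, int] = {}

    def visit(rid: int) -> None:
        if state.get(rid) == 1:
            raise ValueError("cycle detected in ontology")
        if state.get(rid) == 2:
            return
        state[rid] = 1
        for ch in children.get(rid, []):
            visit(ch)
        state[rid] = 2
        order.append(rid)

    visit(atlas.root.id)
    if len(order) != len(atlas.ontology):
        raise ValueError("ontology contains nodes unreachable from the root")

    value_cols = ["summed_signal", "voxel_count", "region_voxels", "volume_mm3"]
    out_parts = []
    for (sample_id, label, hemi), grp in leaf_matrix.groupby(
        ["sample_id", "label", "hemisphere"], sort=False
    ):
        direct = {
            int(rid): row[value_cols].to_numpy(dtype=np.float64)
            for rid, row in grp.set_index("region_id").iterrows()
        }
        totals: dict[int, np.ndarray] = {}
        for rid in order:  # children visited before parents
            acc = direct.get(rid, np.zeros(len(value_cols)))
            acc = acc + sum(
                (totals[ch] for ch in children.get(rid, [])), np.zeros(len(value_cols))
            )
            totals[rid] = acc
        rows = []
        for r in atlas.ontology:
            vals = totals[r.id]
            rows.append(
                dict(
                    sample_id=sample_id,
                    label=label,
                    region_id=r.id,
                    acronym=r.acronym,
                    hemisphere=hemi,
                    summed_signal=vals[0],
                    voxel_count=int(round(vals[1])),
                    region_voxels=int(round(vals[2])),
                    volume_mm3=vals[3],
                )
            )
        if 0 in direct:
            vals = direct[0]
            rows.append(
                dict(
                    sample_id=sample_id,
                    label=label,
                    region_id=0,
                    acronym="background",
                    hemisphere=hemi,
                    summed_signal=vals[0],
                    voxel_count=int(round(vals[1])),
                    region_voxels=int(round(vals[2])),
                    volume_mm3=vals[3],
                )
            )
        out_parts.append(pd.DataFrame(rows))
    out = pd.concat(out_parts, ignore_index=True)
    out = _add_densities(out)
    return out[QUANT_COLUMNS]


def build_heatmap_matrix(
    matrices: Sequence[pd.DataFrame],
    region_acronyms: Sequence[str],
    atlas: AtlasBundle,
    value: str = "count_density",
) -> dict[tuple[str, str], pd.DataFrame]:
    """Dense samples x regions density tables, one per (label, hemisphere).

    Row order follows the input sample order and column order the requested
    acronym order; a region absent from a sample's matrix becomes 0, not
    missing.  Unknown acronyms raise, naming the offenders.
    """
    known = {r.acronym for r in atlas.ontology} | {"background"}
    bad = [a for a in region_acronyms if a not in known]
    if bad:
        raise KeyError(f"unknown region acronyms: {bad}")
    all_rows = pd.concat(matrices, ignore_index=True)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    sample_order = list(dict.fromkeys(all_rows["sample_id"]))
    for (label, hemi), grp in all_rows.groupby(["label", "hemisphere"], sort=False):
        pivot = grp.pivot_table(
            index="sample_id", columns="acronym", values=value, aggfunc="first"
        )
        table = pivot.reindex(index=sample_order, columns=list(region_acronyms))
        tables[(label, hemi)] = table.fillna(0.0)
    return tables


def render_heatmap(
    table: pd.DataFrame, path: str | Path, title: str = "", cmap: str = "inferno"
) -> Path:
    """Write a color-mapped figure of a heat-map table (regions on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(3, 0.5 * len(table.index) + 2), max(3, 0.22 * len(table.columns)))
    )
    data = table.to_numpy().T  # regions x samples
    im = ax.imshow(data, aspect="auto", cmap=cmap)
    ax.set_yticks(range(len(table.columns)), table.columns, fontsize=6)
    ax.set_xticks(range(len(table.index)), table.index, rotation=90, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="density (per mm$^3$)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
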