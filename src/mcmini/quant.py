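"""Single-cell quantification: the Spatial Feature Table.

Given segmentation label masks and a multichannel mosaic, computes per-cell
mean marker intensities per compartment (nucleus / cytoplasm / whole cell)
and morphology metrics on the primary compartment, and writes the result as
a CSV — the per-cell table (Level 4 data) that downstream spatial analysis
consumes, analogous to an scRNA-seq count table.

Column dialect: ``CellID``, then ``<marker>_<compartment>`` intensity columns
(compartment suffixes ``nucleus`` / ``cyto`` / ``cell``), then morphology
columns (``area``, ``centroid_y``, ``centroid_x``, ``eccentricity``,
``solidity``, ``extent``, ``orientation``, ``equivalent_diameter``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops_table

from .containers import LabelMask, MosaicImage

__all__ = ["quantify", "write_feature_table", "read_feature_table", "MORPHOLOGY_COLUMNS"]

_SUFFIX = {"nucleus": "nucleus", "cytoplasm": "cyto", "cell": "cell"}

MORPHOLOGY_COLUMNS = [
    "area",
    "centroid_y",
    "centroid_x",
    "eccentricity",
    "solidity",
    "extent",
    "orientation",
    "equivalent_diameter",
]


def quantify(
    label_masks: dict[str, LabelMask],
    mosaic: MosaicImage,
    channels: list[str] | None = None,
    primary: str = "nucleus",
) -> pd.DataFrame:
    """Build the Spatial Feature Table from label masks and a channel stack.

    Parameters
    ----------
    label_masks:
        Mapping of compartment name (``nucleus``, ``cytoplasm``, ``cell``) to
        its mask.  Cytoplasm/cell labels must be a subset of the nucleus (or
        primary) labels: the same integer refers to the same cell.
    mosaic:
        The multichannel image to quantify.
    channels:
        Channel names to quantify; defaults to all mosaic channels.
    primary:
        Compartment whose mask defines the cell set and morphology.
    """
    if primary not in label_masks:
        raise ValueError(f"primary compartment {primary!r} missing from masks")
    channels = list(channels) if channels is not None else list(mosaic.channel_names)
    H, W = mosaic.shape
    for name, mask in label_masks.items():
        if mask.labels.shape != (H, W):
            raise ValueError(f"mask {name!r} shape {mask.labels.shape} != mosaic {H}x{W}")

    prim = label_masks[primary].labels
    ids = np.unique(prim[prim > 0])
    primary_set = set(ids.tolist())
    for name, mask in label_masks.items():
        extra = mask.label_set() - primary_set
        if extra:
            raise ValueError(
                f"labels {sorted(extra)[:5]} present in {name!r} but absent from "
                f"the primary ({primary!r}) mask: label correspondence violated"
            )

    table = pd.DataFrame({"CellID": ids.astype(np.int64)})
    for comp, mask in label_masks.items():
        suffix = _SUFFIX.get(comp, comp)
        present = np.unique(mask.labels[mask.labels > 0])
        pos = {lab: i for i, lab in enumerate(present)}
        for ch in channels:
            plane = mosaic.channel(ch)
            means = ndimage.mean(plane, labels=mask.labels, index=present)
            col = np.full(len(ids), np.nan)
            for i, lab in enumerate(ids):
                if lab in pos:
                    col[i] = means[pos[lab]]
            table[f"{ch}_{suffix}"] = col

    props = regionprops_table(
        prim,
        properties=(
            "label",
            "area",
            "centroid",
            "eccentricity",
            "solidity",
            "extent",
            "orientation",
            "equivalent_diameter",
        ),
    )
    morph = pd.DataFrame(props).rename(
        columns={
            "label": "CellID",
            "centroid-0": "centroid_y",
            "centroid-1": "centroid_x",
        }
    )
    table = table.merge(morph, on="CellID", how="left")
    return table.sort_values("CellID", ignore_index=True)


def write_feature_table(table: pd.DataFrame, path: str | Path, allow_empty: bool = False) -> Path:
    """Write the feature table as CSV (round-trips at 9 significant digits)."""
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.10g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
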