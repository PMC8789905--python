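"""Per-cell intensity quantification for live-imaging readouts.

Cells are nuclear labels plus a dilated cytoplasmic ring; reported
statistics are the nuclear, cytoplasmic and whole-cell (union) means per
channel and the nuclear:cytoplasmic ratio — the standard proxy for
Smad2/3 pathway activity.  Time courses are averaged hierarchically:
cells within a field of view first, then across fields, matching how
biological replicates (fields) are treated statistically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .prep import LabelImage

__all__ = ["per_cell_intensity", "nc_ratio", "field_mean_timeseries"]

#: reported when a ratio denominator is zero
RATIO_SENTINEL = float("nan")


def per_cell_intensity(
    nuclear_labels: LabelImage,
    cyto_labels: LabelImage,
    channels: dict[str, np.ndarray],
    t_h: float = 0.0,
    field: str = "field0",
) -> pd.DataFrame:
    """Per-cell means over nucleus, cytoplasmic ring and whole cell.

    ``cyto_labels`` must come from :func:`~nodalrelay.prep.dilate_labels`
    on ``nuclear_labels`` so ids match; the ring is the dilated label
    minus the nucleus.  Returns one row per cell with columns
    ``{channel}_nuc|cyto|cell`` and ``{channel}_nc_ratio``; an empty label
    set yields an empty frame.
    """
    nuc = nuclear_labels.labels
    cyto = cyto_labels.labels
    if nuc.shape != cyto.shape:
        raise ValueError("label images differ in shape")
    ids_n = set(np.unique(nuc)) - {0}
    ids_c = set(np.unique(cyto)) - {0}
    if ids_n != ids_c:
        raise ValueError(
            "nuclear and cytoplasmic label ids disagree; cyto_labels must be "
            "dilated from the same nuclear segmentation"
        )
    ids = np.array(sorted(ids_n), int)
    if len(ids) == 0:
        return pd.DataFrame()

    ring = np.where(nuc > 0, 0, cyto)
    centroids = nuclear_labels.centroids_um()
    rows: dict[str, np.ndarray] = {
        "cell_id": ids,
        "t_h": np.full(len(ids), t_h),
        "field": np.full(len(ids), field, dtype=object),
        "x_um": centroids[:, 0],
        "y_um": centroids[:, 1],
    }
    for name, img in channels.items():
        img = np.asarray(img, float)
        nuc_mean = ndimage.mean(img, labels=nuc, index=ids)
        nuc_area = ndimage.sum_labels(np.ones_like(img), labels=nuc, index=ids)
        ring_area = ndimage.sum_labels(np.ones_like(img), labels=ring, index=ids)
        ring_sum = ndimage.sum_labels(img, labels=ring, index=ids)
        with np.errstate(invalid="ignore", divide="ignore"):
            ring_mean = np.where(ring_area > 0, ring_sum / np.maximum(ring_area, 1),
                                 np.nan)
        cell_mean = (nuc_mean * nuc_area + np.nan_to_num(ring_sum)) \
            / (nuc_area + ring_area)
        rows[f"{name}_nuc"] = nuc_mean
        rows[f"{name}_cyto"] = ring_mean
        rows[f"{name}_cell"] = cell_mean
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[f"{name}_nc_ratio"] = np.where(
                ring_mean > 0, nuc_mean / ring_mean, RATIO_SENTINEL
            )
    return pd.DataFrame(rows)


def nc_ratio(record: pd.Series | dict, channel: str) -> float:
    """Nuclear / cytoplasmic mean for one cell record.

    Zero or negative cytoplasmic mean yields NaN (flagged sentinel), never
    an exception mid-pipeline.
    """
    nuc = float(record[f"{channel}_nuc"])
    cyto = float(record[f"{channel}_cyto"])
    if not cyto > 0:
        return RATIO_SENTINEL
    return nuc / cyto


def field_mean_timeseries(
    records: pd.DataFrame,
    value_column: str,
) -> pd.DataFrame:
    """Hierarchical time series: cells -> field mean -> across-field mean.

    Cell-level values are first averaged within each (field, t) group,
    then the per-time mean and SEM are taken across fields — so fields
    with many cells do not dominate (the pooled mean would differ whenever
    cell counts are unequal).  Fewer than two fields at a time point gives
    a NaN SEM.
    """
    if value_column not in records.columns:
        raise KeyError(f"no column {value_column!r} in records")
    per_field = (
        records.groupby(["t_h", "field"], sort=True)[value_column]
        .mean()
        .reset_index()
    )
    out = (
        per_field.groupby("t_h")[value_column]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v))
             if len(v) > 1 else np.nan, n_fields="count")
        .reset_index()
    )
    return out
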