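"""Probe-level expression QC: filtering, replicate collapse, normalization.

The filtering rules mirror standard one-color array practice: a probe is
dropped when it is non-detectable in more than half of the arrays of *both*
groups, or when any single platform flag fires on more than three quarters of
all arrays. Replicate probes are collapsed by median, then arrays are quantile
normalized and log2 transformed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FLAG_NAMES, RawExpression, ValidationError


def filter_probes(
    raw: RawExpression, detect_frac: float = 0.5, flag_frac: float = 0.75
) -> pd.Index:
    """Return the probe ids retained by the detectability and flag rules.

    A probe is removed iff
      * its non-detectable fraction exceeds ``detect_frac`` in the control
        arrays AND in the case arrays (both strictly greater), or
      * any one flag condition fires in strictly more than ``flag_frac`` of
        all arrays.
    Input order is preserved. Requires both groups to be present.
    """
    group = raw.sample_group
    for g in ("case", "control"):
        if not (group == g).any():
            raise ValidationError(
                f"detectability rule undefined: no {g} arrays present"
            )
    nondet = ~raw.detectable
    frac_by_group = {
        g: nondet.loc[:, group[group == g].index].mean(axis=1)
        for g in ("case", "control")
    }
    undetectable = (frac_by_group["case"] > detect_frac) & (
        frac_by_group["control"] > detect_frac
    )
    flagged = pd.Series(False, index=raw.values.index)
    for name in FLAG_NAMES:
        flagged |= raw.flags[name].mean(axis=1) > flag_frac
    keep = ~(undetectable | flagged)
    return raw.values.index[keep.to_numpy()]


def collapse_replicates(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a probe id to their per-sample median.

    Non-replicated rows pass through unchanged; the output keeps the order of
    first appearance.
    """
    if not values.index.has_duplicates:
        return values.copy()
    order = values.index.unique()
    collapsed = values.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def quantile_normalize_log2(values: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across sample columns, then log2.

    Each column's rank r is mapped to the mean across columns of the r-th
    smallest values; tied entries within a column receive the mean of the
    normalized values of their tied ranks. All inputs must be positive.
    """
    arr = values.to_numpy(dtype=float)
    if not (arr > 0).all():
        raise ValidationError("quantile_normalize_log2 requires strictly positive values")
    n_rows, n_cols = arr.shape
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(n_cols):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_rows)
        assigned[order] = mean_sorted
        # average over tie blocks so equal inputs get equal outputs
        sorted_col = col[order]
        start = 0
        for stop in range(1, n_rows + 1):
            if stop == n_rows or sorted_col[stop] != sorted_col[start]:
                if stop - start > 1:
                    assigned[order[start:stop]] = mean_sorted[start:stop].mean()
                start = stop
        out[:, j] = assigned
    return pd.DataFrame(np.log2(out), index=values.index, columns=values.columns)


def detect_outlier_arrays(values: pd.DataFrame, k: float = 3.0) -> pd.Index:
    """Flag arrays by inter-array distance, a simple heuristic for hybridization
    failures: distance(i, j) = 1 - Pearson r of the arrays' log2 intensities,
    and an array is an outlier when its mean distance to all others exceeds
    median + k * MAD over arrays.
    """
    if values.shape[1] < 3:
        raise ValidationError("outlier detection needs at least 3 arrays")
    arr = values.to_numpy(dtype=float)
    if not (arr > 0).all():
        raise ValidationError("outlier detection expects positive raw intensities")
    log_arr = np.log2(arr)
    corr = np.corrcoef(log_arr, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, np.nan)
    mean_dist = np.nanmean(dist, axis=1)
    med = np.median(mean_dist)
    mad = np.median(np.abs(mean_dist - med))
    cutoff = med + k * mad
    return values.columns[mean_dist > cutoff]


def normalize_expression(
    raw: RawExpression,
    detect_frac: float = 0.5,
    flag_frac: float = 0.75,
    outlier_k: float | None = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Full expression QC: outlier-array removal (optional), probe filtering,
    replicate collapse, quantile normalization + log2.

    Returns the normalized probes x samples matrix and a stage-count log.
    """
    log: dict = {
        "n_arrays_in": raw.values.shape[1],
        "n_probe_rows_in": raw.values.shape[0],
        "n_probes_in": raw.values.index.nunique(),
    }
    values, flags, detectable, group = raw.values, raw.flags, raw.detectable, raw.sample_group
    if outlier_k is not None:
        outliers = detect_outlier_arrays(values, k=outlier_k)
        log["outlier_arrays"] = list(outliers)
        if len(outliers):
            keep_cols = values.columns.difference(outliers, sort=False)
            values = values[keep_cols]
            flags = {n: t[keep_cols] for n, t in flags.items()}
            detectable = detectable[keep_cols]
            group = group[keep_cols]
    else:
        log["outlier_arrays"] = None
    log["n_arrays_retained"] = values.shape[1]

    filtered = RawExpression(values, flags, detectable, group)
    kept = filter_probes(filtered, detect_frac=detect_frac, flag_frac=flag_frac)
    mask = values.index.isin(kept)
    log["n_probe_rows_retained"] = int(mask.sum())
    log["n_probes_removed"] = int(values.index.nunique() - kept.nunique())

    collapsed = collapse_replicates(values.loc[mask])
    log["n_probes_retained"] = collapsed.shape[0]
    normalized = quantile_normalize_log2(collapsed)
    return normalized, log
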