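"""Preprocessing of expression matrices: log2, quantile normalization, replicate averaging.

The pipeline accepts matrices that are already array-normalized; quantile
normalization is the default cross-sample normalization otherwise. Replicate
averaging collapses samples sharing (cultivar, tissue_group, stage_label)
into one meta-expression column per group, ordered developmentally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)


def log2_transform(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Replace each linear intensity v by log2(max(v, floor)).

    The floor (default 1.0, i.e. log2 floor of 0) prevents -inf on
    non-positive or near-zero intensities without distorting mid-range
    signal.
    """
    if floor <= 0:
        if np.nanmin(matrix.values) <= 0:
            raise ValidationError(
                "non-positive intensities present and floor <= 0; "
                "log2 transform undefined"
            )
    clamped = np.maximum(matrix.values, floor)
    return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids),
                            np.log2(clamped))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto a common reference distribution.

    The reference is the row-wise mean of per-column sorted values; each
    column is then remapped rank-for-rank onto it, so all columns share an
    identical sorted value multiset. Tied values within a column receive
    the mean of the reference values at their tied ranks, preserving
    within-column rank order.
    """
    if matrix.has_missing():
        raise ValidationError("quantile normalization requires an NA-free matrix")
    n_probes, n_samples = matrix.shape
    if n_samples < 2:
        logger.info("quantile_normalize: single sample, returned unchanged")
        return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids),
                                matrix.values.copy())
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n_probes)
        mapped[order] = reference
        # ties: average the reference values assigned to equal inputs
        s = pd.Series(mapped)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids), out)


def average_replicates(matrix: ExpressionMatrix, metadata: SampleMetadata,
                       group_key: tuple[str, ...] = ("cultivar", "tissue_group", "stage_label"),
                       ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Average replicate samples into one column per sample group.

    Groups are defined by ``group_key`` over the metadata; output columns are
    ordered by (cultivar, tissue_group, stage_order) so downstream scoring
    and display follow the developmental series, not alphabetical labels.

    Returns the averaged matrix together with a per-group metadata table
    (one row per output column, carrying cultivar, tissue_group,
    stage_label, stage_order, is_late_pollen and n_replicates).
    """
    meta = metadata.for_samples(matrix.sample_ids)
    if meta.empty:
        raise ValidationError("no samples to average")
    frame = matrix.to_frame()
    key_frame = meta.set_index("sample_id").loc[matrix.sample_ids]
    groups = key_frame.groupby(list(group_key), sort=False)

    records = []
    for key, members in groups:
        flags = set(members["is_late_pollen"])
        if len(flags) > 1:
            raise ValidationError(
                f"group {key} mixes late-pollen and non-late samples")
        records.append({
            "group_id": "|".join(str(k) for k in key),
            "cultivar": members["cultivar"].iloc[0],
            "tissue_group": members["tissue_group"].iloc[0],
            "stage_label": members["stage_label"].iloc[0],
            "stage_order": int(members["stage_order"].iloc[0]),
            "is_late_pollen": bool(members["is_late_pollen"].iloc[0]),
            "n_replicates": len(members),
            "members": list(members.index),
        })
    group_meta = pd.DataFrame(records).sort_values(
        ["cultivar", "tissue_group", "stage_order"], kind="stable"
    ).reset_index(drop=True)

    cols = {}
    for rec in group_meta.itertuples(index=False):
        cols[rec.group_id] = frame[list(rec.members)].mean(axis=1)
    averaged = pd.DataFrame(cols, index=frame.index)
    group_meta = group_meta.drop(columns="members")
    return ExpressionMatrix.from_frame(averaged), group_meta
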