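"""From raw aligned feature table to normalized and binarized matrices.

The canonical order is: remove blank-associated features, normalize each
sample to its total ion current, merge replicate cultures per isolate,
then binarize presence/absence. :func:`preprocess_pipeline` runs the
whole sequence.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import FeatureTable, IncidenceMatrix
from .errors import EmptySampleError, MalformedTableError
from .io import check_samples_covered

logger = logging.getLogger(__name__)

__all__ = [
    "blank_filter",
    "tic_normalize",
    "merge_replicates",
    "binarize",
    "preprocess_pipeline",
]


def blank_filter(
    table: FeatureTable,
    metadata: pd.DataFrame,
    mode: str = "strict",
    fold: float = 3.0,
) -> FeatureTable:
    """Remove features attributable to blanks and drop blank columns.

    In ``strict`` mode (the default) any feature with nonzero abundance
    in any blank is removed entirely — the categorical rule. In ``fold``
    mode a feature is rescued when its maximum culture abundance exceeds
    ``fold`` times its maximum blank abundance. With no blanks present
    the table is returned unchanged with a warning.
    """
    check_samples_covered(table, metadata)
    meta = metadata.loc[table.samples]
    blank_cols = meta.index[meta["is_blank"]]
    if len(blank_cols) == 0:
        warnings.warn("no blank samples present; blank filter is a no-op", stacklevel=2)
        return table.copy()
    culture_cols = meta.index[~meta["is_blank"]]
    blank_max = table.abundances[blank_cols].max(axis=1)
    if mode == "strict":
        keep = blank_max == 0
    elif mode == "fold":
        if fold <= 0:
            raise ValueError("fold must be positive")
        culture_max = table.abundances[list(culture_cols)].max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            keep = (blank_max == 0) | (culture_max >= fold * blank_max)
    else:
        raise ValueError(f"unknown blank filter mode {mode!r}")
    removed = int((~keep).sum())
    logger.info("blank filter removed %d features", removed)
    return FeatureTable(
        table.abundances.loc[keep, list(culture_cols)],
        table.mz.loc[keep],
        table.rt.loc[keep],
    )


def tic_normalize(table: FeatureTable) -> FeatureTable:
    """Divide every sample's abundances by its total ion current.

    After normalization every column sums to one. An all-zero sample
    column raises :class:`~npdiv.errors.EmptySampleError`.
    """
    totals = table.abundances.sum(axis=0)
    empty = totals.index[totals == 0]
    if len(empty):
        raise EmptySampleError(f"samples with zero total abundance: {list(empty)[:5]}")
    return FeatureTable(table.abundances / totals, table.mz.copy(), table.rt.copy())


def merge_replicates(
    table: FeatureTable,
    metadata: pd.DataFrame,
    mode: str = "mean",
) -> FeatureTable:
    """Collapse replicate culture columns into one column per isolate.

    ``mean`` averages (TIC-normalized) abundances, preserving
    quantitative structure and column sums; ``union`` takes per-feature
    maxima, which only preserves presence/absence. Isolates listed in
    the metadata but with no retained replicate columns are logged and
    dropped.
    """
    check_samples_covered(table, metadata)
    meta = metadata.loc[table.samples]
    if meta["is_blank"].any():
        raise MalformedTableError("merge_replicates expects blanks to be filtered first")
    isolate_of = meta["isolate_id"]
    if mode == "mean":
        merged = table.abundances.T.groupby(isolate_of).mean().T
    elif mode == "union":
        merged = table.abundances.T.groupby(isolate_of).max().T
    else:
        raise ValueError(f"unknown merge mode {mode!r}")
    all_isolates = metadata.loc[~metadata["is_blank"], "isolate_id"].unique()
    dropped = sorted(set(all_isolates) - set(merged.columns))
    if dropped:
        logger.warning("isolates with zero retained replicates dropped: %s", dropped)
    # keep first-appearance isolate order for determinism
    order = pd.unique(isolate_of)
    merged = merged[[iso for iso in order if iso in merged.columns]]
    return FeatureTable(merged, table.mz.copy(), table.rt.copy())


def binarize(
    table: FeatureTable,
    threshold: float = 0.0,
    groups: pd.Series | None = None,
) -> IncidenceMatrix:
    """Threshold abundances into an incidence matrix.

    Presence means abundance strictly above ``threshold`` (default 0:
    any detected peak counts). All-zero feature rows are dropped with
    their count logged. ``groups`` optionally labels each isolate column
    (clade or cluster).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    presence = (table.abundances > threshold).astype(np.int8)
    nonzero = presence.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("binarize dropped %d all-zero feature rows", n_dropped)
    return IncidenceMatrix(presence.loc[nonzero], groups)


def isolate_groups(metadata: pd.DataFrame, column: str = "clade") -> pd.Series:
    """Per-isolate group labels (e.g. clade) from per-sample metadata."""
    meta = metadata.loc[~metadata["is_blank"]]
    groups = meta.groupby("isolate_id")[column].first()
    groups.name = column
    return groups


def preprocess_pipeline(
    table: FeatureTable,
    metadata: pd.DataFrame,
    blank_mode: str = "strict",
    fold: float = 3.0,
    merge_mode: str = "mean",
    threshold: float = 0.0,
    group_column: str = "clade",
) -> tuple[FeatureTable, IncidenceMatrix]:
    """blank_filter -> tic_normalize -> merge_replicates -> binarize.

    Returns the isolate-level normalized table and the incidence matrix
    labeled with ``group_column``.
    """
    filtered = blank_filter(table, metadata, mode=blank_mode, fold=fold)
    normalized = tic_normalize(filtered)
    merged = merge_replicates(normalized, metadata, mode=merge_mode)
    groups = isolate_groups(metadata, group_column)
    incidence = binarize(merged, threshold=threshold, groups=groups)
    return merged, incidence
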