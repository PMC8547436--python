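"""Core in-memory containers shared across the pipeline.

A :class:`FeatureTable` is the features x samples abundance matrix exported
by an LC-MS alignment tool, together with per-feature m/z and retention
time. An :class:`IncidenceMatrix` is the binarized presence of items
(features or scaffolds) per isolate, the form consumed by all
accumulation, richness and Venn analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MalformedTableError

__all__ = ["FeatureTable", "IncidenceMatrix"]


@dataclass
class FeatureTable:
    """Features x samples abundance matrix with feature metadata.

    Parameters
    ----------
    abundances
        Nonnegative peak areas, indexed by feature ID, one column per
        sample (replicate culture or blank) or per isolate after
        replicate merging.
    mz
        Mass-to-charge ratio (Da) per feature, aligned to ``abundances``.
    rt
        Retention time (min) per feature, aligned to ``abundances``.
    """

    abundances: pd.DataFrame
    mz: pd.Series
    rt: pd.Series

    def __post_init__(self) -> None:
        if not self.abundances.index.equals(self.mz.index) or not self.abundances.index.equals(
            self.rt.index
        ):
            raise MalformedTableError("mz/rt index does not match the abundance matrix")
        if (self.abundances.to_numpy() < 0).any():
            raise MalformedTableError("negative peak areas")
        pairs = pd.MultiIndex.from_arrays([self.mz, self.rt])
        if pairs.duplicated().any():
            raise MalformedTableError("duplicate (m/z, retention time) feature rows")

    @property
    def feature_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def samples(self) -> pd.Index:
        return self.abundances.columns

    @property
    def n_features(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.abundances.copy(), self.mz.copy(), self.rt.copy())

    def select_features(self, ids) -> "FeatureTable":
        """Restrict to the given feature IDs (order preserved)."""
        return FeatureTable(self.abundances.loc[ids], self.mz.loc[ids], self.rt.loc[ids])

    def select_samples(self, samples) -> "FeatureTable":
        """Restrict to the given sample columns (order preserved)."""
        return FeatureTable(self.abundances[list(samples)], self.mz, self.rt)


@dataclass
class IncidenceMatrix:
    """Binary presence of items (features or scaffolds) per isolate.

    ``presence`` holds 0/1 values with items on rows and isolates on
    columns. ``groups`` optionally labels each isolate with a clade or
    chemical-cluster assignment.

    The incidence-frequency summaries used by richness estimation follow
    the standard incidence-based notation: ``T`` is the number of
    sampling units (isolates), ``T_i`` the number of isolates containing
    item i, ``Q1``/``Q2`` the number of items found in exactly one/two
    isolates, and ``S_obs`` the number of items observed at least once.
    """

    presence: pd.DataFrame
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        values = self.presence.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise MalformedTableError("incidence matrix entries must be 0/1")
        self.presence = self.presence.astype(np.int8)
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = self.presence.columns.difference(self.groups.index)
            if len(missing):
                raise MalformedTableError(
                    f"isolates without a group label: {sorted(missing)[:5]}"
                )
            self.groups = self.groups.loc[self.presence.columns]

    # -- incidence-frequency summaries -------------------------------------
    @property
    def T(self) -> int:
        """Number of sampling units (isolates)."""
        return self.presence.shape[1]

    @property
    def incidence_freq(self) -> pd.Series:
        """Per-item incidence frequency T_i (count of isolates with the item)."""
        return self.presence.sum(axis=1)

    @property
    def Q1(self) -> int:
        """Number of items present in exactly one isolate ("uniques")."""
        return int((self.incidence_freq == 1).sum())

    @property
    def Q2(self) -> int:
        """Number of items present in exactly two isolates ("duplicates")."""
        return int((self.incidence_freq == 2).sum())

    @property
    def S_obs(self) -> int:
        """Number of items observed in at least one isolate."""
        return int((self.incidence_freq >= 1).sum())

    @property
    def isolates(self) -> pd.Index:
        return self.presence.columns

    @property
    def items(self) -> pd.Index:
        return self.presence.index

    # -- subsetting ---------------------------------------------------------
    def subset_isolates(self, isolates, drop_absent: bool = True) -> "IncidenceMatrix":
        """Restrict to a subset of isolates.

        Items no longer present anywhere are dropped unless
        ``drop_absent`` is False, so the result satisfies the no-all-zero
        invariant expected by the accumulation machinery.
        """
        sub = self.presence[list(isolates)]
        if drop_absent:
            sub = sub.loc[sub.sum(axis=1) > 0]
        groups = self.groups.loc[list(isolates)] if self.groups is not None else None
        return IncidenceMatrix(sub, groups)

    def for_group(self, group) -> "IncidenceMatrix":
        """Restrict to the isolates carrying the given group label."""
        if self.groups is None:
            raise MalformedTableError("incidence matrix has no group labels")
        keep = self.groups.index[self.groups == group]
        return self.subset_isolates(keep)

    def group_presence(self) -> pd.DataFrame:
        """Item x group presence: an item is present in a group iff it is
        present in at least one of the group's isolates."""
        if self.groups is None:
            raise MalformedTableError("incidence matrix has no group labels")
        return self.presence.T.groupby(self.groups).max().T
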