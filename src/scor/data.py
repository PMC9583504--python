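"""Containers and IO for ordered multi-group biomarker data.

The central object is :class:`OrderedBiomarkerData`: ``M`` ordered outcome
categories, each holding an ``n_j x d`` matrix of continuous marker values.
Category order is an explicit input throughout the package — the convention
is that a *higher* combination score should correspond to a *higher*
outcome category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["OrderedBiomarkerData", "read_table"]


@dataclass(frozen=True)
class OrderedBiomarkerData:
    """M ordered groups of d-dimensional continuous observations.

    Parameters
    ----------
    groups
        Sequence of ``M >= 2`` float arrays, group ``j`` of shape
        ``(n_j, d)``; all groups share the same ``d`` and all values must
        be finite.
    category_labels
        The ``M`` ordinal levels in increasing order. Defaults to
        ``0..M-1``.
    """

    groups: tuple[np.ndarray, ...]
    category_labels: tuple = field(default=None)

    def __post_init__(self):
        groups = tuple(np.ascontiguousarray(g, dtype=float) for g in self.groups)
        if len(groups) < 2:
            raise ValueError("need at least two ordered outcome categories")
        groups = tuple(g[:, None] if g.ndim == 1 else g for g in groups)
        d = groups[0].shape[1]
        for g in groups:
            if g.ndim != 2 or g.shape[1] != d:
                raise ValueError("all groups must share the same marker dimension d")
            if g.shape[0] < 1:
                raise ValueError("every category must contain at least one observation")
            if not np.all(np.isfinite(g)):
                raise ValueError("marker values must be finite")
        object.__setattr__(self, "groups", groups)
        labels = self.category_labels
        if labels is None:
            labels = tuple(range(len(groups)))
        labels = tuple(labels)
        if len(labels) != len(groups):
            raise ValueError("one category label per group is required")
        object.__setattr__(self, "category_labels", labels)

    @property
    def n_categories(self) -> int:
        return len(self.groups)

    @property
    def n_markers(self) -> int:
        return self.groups[0].shape[1]

    @property
    def group_sizes(self) -> tuple[int, ...]:
        return tuple(g.shape[0] for g in self.groups)

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes)

    def to_frame(self, label_col: str = "outcome") -> pd.DataFrame:
        """Long-format frame: one row per subject, marker columns + label."""
        frames = []
        for lab, g in zip(self.category_labels, self.groups):
            df = pd.DataFrame(g, columns=[f"marker_{k + 1}" for k in range(self.n_markers)])
            df[label_col] = lab
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def map_markers(self, func) -> "OrderedBiomarkerData":
        """Apply a per-subject transform of the marker matrix (e.g. min-max reduction)."""
        return OrderedBiomarkerData(
            tuple(np.asarray(func(g), dtype=float) for g in self.groups),
            self.category_labels,
        )


def read_table(
    path,
    label_col: str,
    marker_cols: Sequence[str] | None = None,
    category_order: Sequence | None = None,
    sep: str | None = None,
) -> OrderedBiomarkerData:
    """Read a long-format CSV/TSV into :class:`OrderedBiomarkerData`.

    One row per subject: numeric marker columns plus one ordinal label
    column. Labels are mapped to ordered categories by their sorted unique
    values unless ``category_order`` gives the order explicitly.
    ``sep=None`` sniffs comma vs tab from the file extension.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found")
    if marker_cols is None:
        marker_cols = [c for c in df.columns if c != label_col]
    levels = list(category_order) if category_order is not None else sorted(df[label_col].unique())
    observed = set(df[label_col])
    missing = observed - set(levels)
    if missing:
        raise ValueError(f"labels {sorted(missing)} not covered by the category order")
    groups = []
    kept_levels = []
    for lev in levels:
        block = df.loc[df[label_col] == lev, marker_cols].to_numpy(dtype=float)
        if block.shape[0] == 0:
            continue
        groups.append(block)
        kept_levels.append(lev)
    return OrderedBiomarkerData(tuple(groups), tuple(kept_levels))
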