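"""From field tensors to the feature matrix PLS consumes.

Stages, in order: stack training rows with any test/prediction rows (a shared
grid and field list is required); optionally drop low-range columns (range
across molecules below a threshold; off by default); scale each field BLOCK to
zero mean and unit variance (one mean and one pooled population variance per
field over all of its kept columns and all scaling rows) so that no field
dominates by sheer magnitude while intra-field spatial contrast is preserved;
finally mean-center each column on the TRAINING rows and center the training
activities by their mean.  The per-column standard deviation of the scaled
data is recorded for contour weighting.

Scaling/filter statistics are computed over the combined rows whenever test or
prediction rows are supplied, and over the training rows alone otherwise;
column centering and activity centering always use training rows only, so no
activity information leaks from held-out molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import FieldTensor

__all__ = [
    "ColumnMeta",
    "FeatureMatrix",
    "combine_sets",
    "column_filter",
    "scale_fields",
    "assemble",
    "build_feature_matrix",
]


@dataclass
class ColumnMeta:
    """Bookkeeping for one (field, grid point) column.

    scale_mean / scale_std are the mean and population standard deviation of
    the column AFTER block scaling (over the scaling rows); scale_std is the
    weight used in field contributions and contour maps.
    """

    field_name: str
    grid_index: int
    kept: bool
    scale_mean: float = 0.0
    scale_std: float = 0.0


@dataclass
class StackedFields:
    """Field tensors of all molecule sets stacked row-wise, train first."""

    matrix: np.ndarray            # (n_molecules, n_fields * n_points), x-fastest
    field_names: tuple[str, ...]
    n_points: int
    roles: list[str]              # per-row role: train | test | predict
    row_names: list[str]
    grid: object

    @property
    def n_train(self) -> int:
        return sum(r == "train" for r in self.roles)


@dataclass
class FeatureMatrix:
    """Standardized, mean-centered molecules x kept-columns matrix."""

    X: np.ndarray                     # (n_rows, n_kept), train rows first
    y: np.ndarray                     # centered training activities
    y_mean: float
    columns: list[ColumnMeta]         # one entry per original column, kept flag set
    row_names: list[str]
    roles: list[str]
    activities: list[float | None]    # raw activities for all rows (None when absent)
    block_stats: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    grid: object = None

    @property
    def kept_columns(self) -> list[ColumnMeta]:
        return [c for c in self.columns if c.kept]

    def rows(self, role: str) -> np.ndarray:
        mask = np.array([r == role for r in self.roles])
        return self.X[mask]

    def raw_activities(self, role: str) -> np.ndarray:
        vals = [a for a, r in zip(self.activities, self.roles) if r == role]
        if any(v is None for v in vals):
            raise ValueError(f"missing activity in a {role} row")
        return np.array(vals, dtype=float)

    @property
    def X_train(self) -> np.ndarray:
        return self.rows("train")


def combine_sets(train: FieldTensor, *others: FieldTensor) -> StackedFields:
    """Stack training and test/prediction tensors row-wise, train first.

    All tensors must share the grid and the enabled-field list so that the
    scaling and filtering statistics computed later apply to every row.
    """
    for other in others:
        if other.grid != train.grid:
            raise ValueError("grid mismatch between molecule sets")
        if other.field_names != train.field_names:
            raise ValueError("enabled-field mismatch between molecule sets")
    tensors = (train,) + others
    flat = [t.values.reshape(t.values.shape[0], -1) for t in tensors]
    roles: list[str] = []
    names: list[str] = []
    for idx, t in enumerate(tensors):
        role = "train" if idx == 0 else getattr(t, "role", "test")
        roles += [role] * t.values.shape[0]
        names += t.molecule_names
    return StackedFields(
        matrix=np.vstack(flat),
        field_names=train.field_names,
        n_points=train.grid.n_points,
        roles=roles,
        row_names=names,
        grid=train.grid,
    )


def column_filter(stacked: StackedFields, threshold: float | None) -> np.ndarray:
    """Boolean keep-mask per column: kept iff max-min across molecules >= threshold.

    ``threshold`` None (the default pipeline setting) keeps every column.
    """
    n_cols = stacked.matrix.shape[1]
    if threshold is None:
        return np.ones(n_cols, dtype=bool)
    if threshold < 0:
        raise ValueError("filter threshold must be >= 0")
    rng = stacked.matrix.max(axis=0) - stacked.matrix.min(axis=0)
    return rng >= threshold


def scale_fields(
    stacked: StackedFields,
    kept: np.ndarray | None = None,
    per_column: bool = False,
) -> tuple[np.ndarray, list[ColumnMeta], dict[str, tuple[float, float]]]:
    """Standardize the stacked matrix and record per-column statistics.

    Default block mode: one mean and one population variance per field,
    pooled over that field's kept columns and all rows; every value of the
    block is transformed with the same statistics.  ``per_column`` switches to
    ordinary per-column standardization for comparison runs.

    Returns (scaled kept-column matrix, ColumnMeta for every original column,
    per-field (mean, std) block statistics).
    """
    n_rows, n_cols = stacked.matrix.shape
    if n_rows < 2:
        raise ValueError("scaling needs at least 2 molecules")
    if kept is None:
        kept = np.ones(n_cols, dtype=bool)
    n_pts = stacked.n_points
    col_field = np.repeat(np.arange(len(stacked.field_names)), n_pts)

    scaled_cols: list[np.ndarray] = []
    columns: list[ColumnMeta] = []
    block_stats: dict[str, tuple[float, float]] = {}
    for fi, fname in enumerate(stacked.field_names):
        in_field = col_field == fi
        keep_f = kept & in_field
        block = stacked.matrix[:, keep_f]
        if block.size:
            if per_column:
                mean = block.mean(axis=0)
                std = block.std(axis=0)
                if np.any(std == 0):
                    raise ValueError(
                        f"zero-variance column in field {fname!r} under per-column scaling"
                    )
            else:
                mean = block.mean()
                std = block.std()
                if std == 0:
                    raise ValueError(f"zero-variance field block {fname!r}")
            scaled = (block - mean) / std
            block_stats[fname] = (
                float(np.mean(mean)), float(np.mean(std)),
            )
            scaled_cols.append(scaled)
        else:
            block_stats[fname] = (0.0, 0.0)
            scaled = np.empty((n_rows, 0))
        col_std = scaled.std(axis=0)
        col_mean = scaled.mean(axis=0)
        kept_iter = iter(range(scaled.shape[1]))
        for local_idx, col in enumerate(np.flatnonzero(in_field)):
            grid_index = col - fi * n_pts
            if kept[col]:
                j = next(kept_iter)
                columns.append(
                    ColumnMeta(fname, grid_index, True, float(col_mean[j]), float(col_std[j]))
                )
            else:
                columns.append(ColumnMeta(fname, grid_index, False))
    return np.hstack(scaled_cols) if scaled_cols else np.empty((n_rows, 0)), columns, block_stats


def assemble(
    scaled: np.ndarray,
    columns: list[ColumnMeta],
    stacked: StackedFields,
    block_stats: dict[str, tuple[float, float]] | None = None,
    activities: list[float | None] | None = None,
) -> FeatureMatrix:
    """Mean-center columns on training rows and center training activities."""
    if activities is None:
        raise ValueError("training activities are required to assemble")
    roles = stacked.roles
    train_mask = np.array([r == "train" for r in roles])
    if not train_mask.any():
        raise ValueError("no training rows")
    y_train = [a for a, m in zip(activities, train_mask) if m]
    if any(a is None for a in y_train):
        missing = [n for n, a, m in zip(stacked.row_names, activities, train_mask)
                   if m and a is None]
        raise ValueError(f"missing activity for training molecules: {missing}")
    y_train = np.array(y_train, dtype=float)
    col_means = scaled[train_mask].mean(axis=0) if scaled.size else np.zeros(scaled.shape[1])
    X = scaled - col_means
    y_mean = float(y_train.mean())
    return FeatureMatrix(
        X=X,
        y=y_train - y_mean,
        y_mean=y_mean,
        columns=columns,
        row_names=list(stacked.row_names),
        roles=list(roles),
        activities=list(activities),
        block_stats=block_stats or {},
        grid=stacked.grid,
    )


def build_feature_matrix(
    train: FieldTensor,
    *others: FieldTensor,
    activities: list[float | None],
    filter_threshold: float | None = None,
    per_column_scaling: bool = False,
) -> FeatureMatrix:
    """Full preprocessing pipeline: stack, filter, scale, center.

    ``activities`` is per stacked row (train rows first); held-out rows may
    carry None.
    """
    stacked = combine_sets(train, *others)
    if len(activities) != stacked.matrix.shape[0]:
        raise ValueError("activities length does not match stacked row count")
    kept = column_filter(stacked, filter_threshold)
    scaled, columns, block_stats = scale_fields(stacked, kept, per_column=per_column_scaling)
    return assemble(scaled, columns, stacked, block_stats, activities)
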