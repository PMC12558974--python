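"""Cleaning, encoding, scaling and SMOTE class balancing.

Missing survey answers are imputed with central-tendency measures (mean for
continuous fields, median for ordinals, mode for categoricals by default).
Categorical answers are encoded numerically: booleans to {0, 1}, ordered
categories to their 0-based rank, range labels (water intake) to the
midpoint of their bounds. Features can then be z-scored or min-max scaled,
and minority/majority imbalance is corrected with SMOTE — synthetic
minority rows interpolated uniformly along the segment between a minority
point and one of its k nearest minority neighbours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cohort import BOOLEAN_FIELDS, CATEGORY_LEVELS, CohortTable, ORDINAL_BOUNDS
from .errors import BalancingError, ContractError, EncodingError, ImputationError, ScalingError

__all__ = [
    "EncodingSpec",
    "EncodedMatrix",
    "default_encoding_spec",
    "impute_missing",
    "default_impute_strategy",
    "encode_record",
    "encode_table",
    "decode_value",
    "FeatureScaler",
    "scale_features",
    "SmoteBalancer",
    "smote_balance",
]


@dataclass
class EncodingSpec:
    """How each survey field maps to a number.

    ``ordinal_maps`` lists categories in increasing order (rank = index);
    ``midpoint_fields`` maps a range label to its (lo, hi) bounds, encoded
    as the midpoint.
    """

    binary_fields: list = field(default_factory=list)
    ordinal_maps: dict = field(default_factory=dict)      # field -> [cat0, cat1, ...]
    midpoint_fields: dict = field(default_factory=dict)   # field -> {label: (lo, hi)}

    def __post_init__(self) -> None:
        for name, cats in self.ordinal_maps.items():
            if not cats or len(set(cats)) != len(cats):
                raise ContractError(f"ordinal map for {name!r} must be non-empty and duplicate-free")
        for name, ranges in self.midpoint_fields.items():
            for label, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ContractError(f"midpoint range {label!r} of {name!r} has lo > hi")

    def to_json(self) -> str:
        return json.dumps({
            "binary_fields": self.binary_fields,
            "ordinal_maps": self.ordinal_maps,
            "midpoint_fields": {f: {k: list(v) for k, v in r.items()}
                                for f, r in self.midpoint_fields.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EncodingSpec":
        raw = json.loads(text)
        return cls(
            binary_fields=raw.get("binary_fields", []),
            ordinal_maps=raw.get("ordinal_maps", {}),
            midpoint_fields={f: {k: tuple(v) for k, v in r.items()}
                             for f, r in raw.get("midpoint_fields", {}).items()},
        )


def default_encoding_spec() -> EncodingSpec:
    """Encoding spec matching the synthetic cohort schema.

    Ordered-category defaults (documented, overridable): shampoo_type
    organic < mild < chemical (increasing chemical load); scalp_condition
    dry < normal < oily < dandruff; hair_type by curl degree; stressor_type
    in a fixed nominal order.
    """
    return EncodingSpec(
        binary_fields=list(BOOLEAN_FIELDS),
        ordinal_maps={
            "gender": list(CATEGORY_LEVELS["gender"]),
            "hair_type": list(CATEGORY_LEVELS["hair_type"]),
            "scalp_condition": list(CATEGORY_LEVELS["scalp_condition"]),
            "shampoo_type": list(CATEGORY_LEVELS["shampoo_type"]),
            "stressor_type": list(CATEGORY_LEVELS["stressor_type"]),
        },
        midpoint_fields={
            "water_intake_range": {
                "<1 L": (0.0, 1.0), "1-2 L": (1.0, 2.0),
                "2-3 L": (2.0, 3.0), ">3 L": (3.0, 4.0),
            },
        },
    )


def default_impute_strategy(df: pd.DataFrame) -> dict:
    """Mean for continuous, median for ordinal, mode for everything else."""
    strategy = {}
    for col in df.columns:
        if col in ORDINAL_BOUNDS or col in ("protein_freq", "iron_freq", "omega_freq"):
            strategy[col] = "median"
        elif pd.api.types.is_float_dtype(df[col]):
            strategy[col] = "mean"
        elif pd.api.types.is_numeric_dtype(df[col]) and col != "age":
            strategy[col] = "median"
        else:
            strategy[col] = "mode"
    return strategy


def impute_missing(table: CohortTable | pd.DataFrame,
                   strategy: Mapping[str, str] | None = None) -> CohortTable:
    """Replace missing values with the per-field central tendency.

    Observed cells are never altered. A fully missing field raises
    :class:`ImputationError` naming the field.
    """
    df = table.records if isinstance(table, CohortTable) else table
    df = df.copy()
    strategy = dict(strategy) if strategy is not None else default_impute_strategy(df)
    for col in df.columns:
        if not df[col].isna().any():
            continue
        how = strategy.get(col, "mode")
        observed = df[col].dropna()
        if observed.empty:
            raise ImputationError(f"field {col!r} has no observed values to impute from")
        if how == "mean":
            fill = observed.astype(float).mean()
        elif how == "median":
            fill = observed.astype(float).median()
        elif how == "mode":
            fill = observed.mode(dropna=True).iloc[0]
        else:
            raise ContractError(f"unknown imputation strategy {how!r} for {col!r}")
        df[col] = df[col].fillna(fill)
    if isinstance(table, CohortTable):
        return CohortTable(records=df, anomaly_labels=table.anomaly_labels, seed=table.seed)
    return CohortTable(records=df)


def _encode_value(field_name: str, value, spec: EncodingSpec) -> float:
    if field_name in spec.binary_fields:
        if isinstance(value, (bool, np.bool_)):
            return 1.0 if value else 0.0
        if value in (0, 1, 0.0, 1.0):
            return float(value)
        if isinstance(value, str) and value.lower() in ("true", "false"):
            return 1.0 if value.lower() == "true" else 0.0
        raise EncodingError(f"field {field_name!r}: {value!r} is not boolean")
    if field_name in spec.ordinal_maps:
        cats = spec.ordinal_maps[field_name]
        try:
            return float(cats.index(value))
        except ValueError:
            raise EncodingError(f"field {field_name!r}: unseen category {value!r}") from None
    if field_name in spec.midpoint_fields:
        ranges = spec.midpoint_fields[field_name]
        if value not in ranges:
            raise EncodingError(f"field {field_name!r}: unseen range label {value!r}")
        lo, hi = ranges[value]
        return (lo + hi) / 2.0
    try:
        return float(value)
    except (TypeError, ValueError):
        raise EncodingError(f"field {field_name!r}: cannot encode {value!r}") from None


def decode_value(field_name: str, encoded: float, spec: EncodingSpec):
    """Inverse encoding for binary and ordinal fields (exact round-trip)."""
    if field_name in spec.binary_fields:
        return bool(round(encoded))
    if field_name in spec.ordinal_maps:
        return spec.ordinal_maps[field_name][int(round(encoded))]
    raise ContractError(f"field {field_name!r} is not binary or ordinal; decoding undefined")


def encode_record(record: Mapping, spec: EncodingSpec,
                  fields: Sequence[str] | None = None) -> np.ndarray:
    """Encode one record to a numeric vector (field order = ``fields``)."""
    if fields is None:
        fields = [k for k in record.keys() if k != "user_id"]
    return np.array([_encode_value(f, record[f], spec) for f in fields], dtype=float)


@dataclass
class EncodedMatrix:
    """Numeric feature matrix with column names and scaling provenance."""

    values: np.ndarray
    column_names: list
    scaling_state: dict = field(default_factory=dict)  # column -> ("zscore", mean, sd) | ("minmax", lo, hi)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ContractError("values shape must match column_names")
        if np.isnan(self.values).any():
            raise ContractError("encoded matrix must not contain missing values")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def encode_table(table: CohortTable | pd.DataFrame, spec: EncodingSpec,
                 fields: Sequence[str] | None = None) -> EncodedMatrix:
    df = table.records if isinstance(table, CohortTable) else table
    if fields is None:
        fields = [c for c in df.columns if c != "user_id"]
    rows = [encode_record(row, spec, fields) for _, row in df.iterrows()]
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(fields)))
    return EncodedMatrix(values=values, column_names=list(fields))


class FeatureScaler:
    """Column-wise z-score or min-max scaling with an inverse transform.

    Parameters
    ----------
    method : {"zscore", "minmax"}
    columns : optional list of column names; all columns when None.
    """

    def __init__(self, method: str = "zscore", columns: Sequence[str] | None = None):
        self.method = method
        self.columns = columns

    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method, "columns": self.columns}

    def set_params(self, **params) -> "FeatureScaler":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ContractError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, matrix: EncodedMatrix) -> "FeatureScaler":
        if self.method not in ("zscore", "minmax"):
            raise ContractError(f"unknown scaling method {self.method!r}")
        cols = list(self.columns) if self.columns is not None else list(matrix.column_names)
        unknown = set(cols) - set(matrix.column_names)
        if unknown:
            raise ContractError(f"unknown columns {sorted(unknown)}")
        state = {}
        for name in cols:
            x = matrix.column(name)
            if self.method == "zscore":
                mean, sd = float(x.mean()), float(x.std(ddof=0))
                if sd == 0.0:
                    raise ScalingError(f"column {name!r} has zero variance under z-score")
                state[name] = ("zscore", mean, sd)
            else:
                lo, hi = float(x.min()), float(x.max())
                if lo == hi:
                    raise ScalingError(f"column {name!r} is constant under min-max")
                state[name] = ("minmax", lo, hi)
        self.state_ = state
        return self

    def transform(self, matrix: EncodedMatrix) -> EncodedMatrix:
        values = matrix.values.copy()
        for name, (kind, a, b) in self.state_.items():
            j = matrix.column_names.index(name)
            if kind == "zscore":
                values[:, j] = (values[:, j] - a) / b
            else:
                values[:, j] = (values[:, j] - a) / (b - a)
        scaling_state = dict(matrix.scaling_state)
        scaling_state.update(self.state_)
        return EncodedMatrix(values=values, column_names=list(matrix.column_names),
                             scaling_state=scaling_state)

    def fit_transform(self, matrix: EncodedMatrix) -> EncodedMatrix:
        return self.fit(matrix).transform(matrix)

    def inverse_transform(self, matrix: EncodedMatrix) -> EncodedMatrix:
        values = matrix.values.copy()
        for name, (kind, a, b) in self.state_.items():
            j = matrix.column_names.index(name)
            if kind == "zscore":
                values[:, j] = values[:, j] * b + a
            else:
                values[:, j] = values[:, j] * (b - a) + a
        return EncodedMatrix(values=values, column_names=list(matrix.column_names))


def scale_features(matrix: EncodedMatrix, method: str = "zscore",
                   columns: Sequence[str] | None = None) -> EncodedMatrix:
    """Functional wrapper over :class:`FeatureScaler` (fit on the same matrix)."""
    return FeatureScaler(method=method, columns=columns).fit_transform(matrix)


class SmoteBalancer:
    """SMOTE oversampling of the minority class to exact 1:1 balance.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of ``x_i``
    (Euclidean). Parent bookkeeping (``parents_``: rows of
    ``(i, nn, u)``) is kept so each synthetic point can be verified to lie
    on its generating segment.
    """

    def __init__(self, k: int = 5, seed: int = 0):
        self.k = k
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "seed": self.seed}

    def set_params(self, **params) -> "SmoteBalancer":
        for key, v in params.items():
            if not hasattr(self, key):
                raise ContractError(f"unknown parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1:
            raise BalancingError("k must be >= 1")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise BalancingError(f"need exactly 2 classes, got {len(classes)}")
        self.parents_ = np.empty((0, 3))
        if counts[0] == counts[1]:
            self.synthetic_ = np.empty((0, X.shape[1]))
            return X.copy(), y.copy()
        minority = classes[np.argmin(counts)]
        idx_min = np.flatnonzero(y == minority)
        n_needed = int(abs(counts[0] - counts[1]))
        if len(idx_min) < 2:
            raise BalancingError("minority class must have at least 2 samples")

        Xmin = X[idx_min]
        k_eff = min(self.k, len(idx_min) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
        _, neigh = nn.kneighbors(Xmin)  # column 0 is the point itself

        rng = np.random.default_rng(self.seed)
        base = rng.integers(0, len(idx_min), size=n_needed)
        pick = rng.integers(1, k_eff + 1, size=n_needed)
        u = rng.random(n_needed)
        partner = neigh[base, pick]
        synthetic = Xmin[base] + u[:, None] * (Xmin[partner] - Xmin[base])

        self.parents_ = np.column_stack([idx_min[base], idx_min[partner], u])
        self.synthetic_ = synthetic
        X_out = np.vstack([X, synthetic])
        y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
        return X_out, y_out


def smote_balance(matrix: EncodedMatrix, labels, k: int = 5,
                  seed: int = 0) -> tuple[EncodedMatrix, np.ndarray]:
    """Balance an encoded matrix; returns the augmented matrix and labels."""
    balancer = SmoteBalancer(k=k, seed=seed)
    X_out, y_out = balancer.fit_resample(matrix.values, np.asarray(labels))
    out = EncodedMatrix(values=X_out, column_names=list(matrix.column_names),
                        scaling_state=dict(matrix.scaling_state))
    return out, y_out
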