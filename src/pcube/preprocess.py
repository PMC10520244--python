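"""Mixed-type encoding shared by clustering, MTLR and the router.

Continuous covariates are z-scored with statistics stored at fit time
(sample SD, ddof=1); categorical covariates are one-hot encoded with the
first level dropped.  Both choices put every encoded column on a common
scale, which is what makes a single absolute weight threshold meaningful
across features during risk-factor selection.

Missing policy: continuous missing values are imputed with the training
mean (i.e. encode to 0 after z-scoring); categorical missingness becomes an
explicit ``__missing__`` level when it occurs in the training data,
otherwise an all-zero row for that feature (with a warning).  Encodings are
always fit on the derivation cohort only and applied unchanged to
validation or new patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, FeatureSchema

MISSING_LEVEL = "__missing__"


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class EncodingSpec:
    """Frozen per-feature encoding rules fitted on a training cohort."""

    schema: FeatureSchema
    continuous_stats: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    categorical_levels: dict[str, tuple[str, ...]]  # feature -> ordered levels (first dropped)

    @property
    def feature_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for f in self.schema.continuous:
            names.append(f)
        for f in self.schema.categorical:
            for level in self.categorical_levels[f][1:]:
                names.append(f"{f}={level}")
        return tuple(names)

    @property
    def n_columns(self) -> int:
        return len(self.feature_names)

    def raw_feature_of(self, column: str) -> str:
        """Raw covariate name behind an encoded column ('sex=M' -> 'sex')."""
        return column.split("=", 1)[0]

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema": self.schema.to_dict(),
            "continuous_stats": {k: list(v) for k, v in self.continuous_stats.items()},
            "categorical_levels": {k: list(v) for k, v in self.categorical_levels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EncodingSpec":
        return cls(
            schema=FeatureSchema.from_dict(d["schema"]),
            continuous_stats={k: (float(v[0]), float(v[1])) for k, v in d["continuous_stats"].items()},
            categorical_levels={k: tuple(v) for k, v in d["categorical_levels"].items()},
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Numeric n x p design matrix aligned to a cohort's rows."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    ids: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise EncodingError("feature matrix shape inconsistent with feature names")
        if not np.isfinite(self.values).all():
            raise EncodingError("feature matrix contains non-finite entries after encoding")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def fit_encoding(cohort: CohortTable, schema: FeatureSchema | None = None) -> EncodingSpec:
    """Learn z-score statistics and categorical level orders from a cohort.

    Raises :class:`EncodingError` for zero-variance continuous features
    (a constant column cannot be standardized).
    """
    schema = schema or cohort.schema
    df = cohort.data
    cont_stats: dict[str, tuple[float, float]] = {}
    for f in schema.continuous:
        x = pd.to_numeric(df[f], errors="coerce").to_numpy(dtype=float)
        obs = x[np.isfinite(x)]
        if obs.size < 2 or np.unique(obs).size < 2:
            raise EncodingError(f"continuous feature {f!r} has fewer than 2 distinct observed values")
        mean = float(np.mean(obs))
        sd = float(np.std(obs, ddof=1))
        if sd <= 0:
            raise EncodingError(f"continuous feature {f!r} has zero variance")
        cont_stats[f] = (mean, sd)
    cat_levels: dict[str, tuple[str, ...]] = {}
    for f in schema.categorical:
        col = df[f]
        observed = sorted({str(v) for v in col[col.notna()]})
        if not observed:
            raise EncodingError(f"categorical feature {f!r} is entirely missing")
        if col.isna().any():
            observed.append(MISSING_LEVEL)
        cat_levels[f] = tuple(observed)
    return EncodingSpec(schema=schema, continuous_stats=cont_stats, categorical_levels=cat_levels)


def transform(cohort: CohortTable, spec: EncodingSpec) -> FeatureMatrix:
    """Apply a fitted encoding: deterministic, row-wise independent."""
    df = cohort.data
    for f in spec.schema.features:
        if f not in df.columns:
            raise EncodingError(f"feature {f!r} missing from cohort table")
    n = len(df)
    cols: list[np.ndarray] = []
    for f in spec.schema.continuous:
        mean, sd = spec.continuous_stats[f]
        x = pd.to_numeric(df[f], errors="coerce").to_numpy(dtype=float)
        x = np.where(np.isfinite(x), x, mean)  # mean imputation == 0 after scaling
        cols.append((x - mean) / sd)
    for f in spec.schema.categorical:
        levels = spec.categorical_levels[f]
        raw = df[f]
        vals = np.array(
            [MISSING_LEVEL if pd.isna(v) else str(v) for v in raw], dtype=object
        )
        known = set(levels)
        unseen = sorted(set(vals) - known)
        if unseen:
            warnings.warn(
                f"feature {f!r}: unseen level(s) {unseen} encode as all-zeros",
                stacklevel=2,
            )
        for level in levels[1:]:
            cols.append((vals == level).astype(float))
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return FeatureMatrix(values=values, feature_names=spec.feature_names, ids=cohort.ids)


def inverse_continuous(spec: EncodingSpec, feature: str, z: np.ndarray) -> np.ndarray:
    """De-standardize a continuous column (exact algebraic inverse)."""
    mean, sd = spec.continuous_stats[feature]
    return np.asarray(z, dtype=float) * sd + mean


def encode_records(records: pd.DataFrame, spec: EncodingSpec) -> np.ndarray:
    """Encode bare covariate records (no time/event) with a fitted spec."""
    df = records.copy()
    from .cohort import ID_COL, TIME_COL, EVENT_COL

    if ID_COL not in df.columns:
        df[ID_COL] = [f"_r{i}" for i in range(len(df))]
    if TIME_COL not in df.columns:
        df[TIME_COL] = 1.0
    if EVENT_COL not in df.columns:
        df[EVENT_COL] = 0
    for f in spec.schema.features:
        if f not in df.columns:
            df[f] = np.nan
    cohort = CohortTable(df, spec.schema)
    return transform(cohort, spec).values
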