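"""Cohort tables and model-bundle serialization.

A cohort is a rectangular table of donor/recipient covariates together with
right-censored follow-up: for each patient we observe ``time`` (years,
strictly positive) and ``event`` (1 = graft loss / death observed,
0 = censored).  Covariates are mixed-type: continuous (donor age, PRA, ...)
or categorical (sex, DCD status, ...).  Missing values are carried as an
explicit marker (NaN internally, empty string on disk).

Fitted pipelines are serialized as JSON "model bundles" with an explicit
schema version; loading a bundle restores an object whose predictions are
bit-identical to the original (floats survive the JSON round trip via
shortest-repr encoding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

ID_COL = "patient_id"
TIME_COL = "time"
EVENT_COL = "event"
SUBGROUP_COL = "true_subgroup"
_RESERVED = {ID_COL, TIME_COL, EVENT_COL, SUBGROUP_COL}


class CohortValidationError(ValueError):
    """Raised when a cohort table violates its invariants."""


@dataclass(frozen=True)
class FeatureSchema:
    """Declares which covariate columns are continuous and which categorical."""

    continuous: tuple[str, ...]
    categorical: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.continuous) & set(self.categorical)
        if overlap:
            raise CohortValidationError(
                f"features declared both continuous and categorical: {sorted(overlap)}"
            )

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.continuous) + tuple(self.categorical)

    def to_dict(self) -> dict[str, Any]:
        return {
            "continuous": list(self.continuous),
            "categorical": list(self.categorical),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FeatureSchema":
        return cls(tuple(d["continuous"]), tuple(d["categorical"]))


@dataclass
class CohortTable:
    """Validated patient table: covariates + (time, event) per patient.

    ``data`` holds one row per patient with columns ``patient_id``, ``time``,
    ``event``, optionally ``true_subgroup`` (simulator output only), and one
    column per declared covariate.
    """

    data: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self) -> None:
        df = self.data
        for col in (ID_COL, TIME_COL, EVENT_COL):
            if col not in df.columns:
                raise CohortValidationError(f"missing required column {col!r}")
        if df[ID_COL].duplicated().any():
            dupes = df.loc[df[ID_COL].duplicated(), ID_COL].head(3).tolist()
            raise CohortValidationError(f"duplicate patient_id values, e.g. {dupes}")
        times = pd.to_numeric(df[TIME_COL], errors="coerce")
        bad = ~(np.isfinite(times) & (times > 0))
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"non-positive or non-finite follow-up time at row {idx} "
                f"(patient_id={df[ID_COL].iloc[idx]!r}, time={df[TIME_COL].iloc[idx]!r})"
            )
        events = df[EVENT_COL]
        if not events.isin([0, 1]).all():
            raise CohortValidationError("event indicator must be 0 or 1 for every row")
        for f in self.schema.features:
            if f not in df.columns:
                raise CohortValidationError(f"declared covariate {f!r} absent from table")
        extra = [c for c in df.columns if c not in _RESERVED and c not in self.schema.features]
        if extra:
            raise CohortValidationError(f"undeclared covariate columns: {extra}")
        # normalize dtypes once so downstream code can rely on them
        self.data = df.copy()
        self.data[TIME_COL] = times.astype(float)
        self.data[EVENT_COL] = events.astype(int)
        for f in self.schema.continuous:
            self.data[f] = pd.to_numeric(self.data[f], errors="raise").astype(float)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> np.ndarray:
        return self.data[ID_COL].to_numpy()

    @property
    def time(self) -> np.ndarray:
        return self.data[TIME_COL].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data[EVENT_COL].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def true_subgroup(self) -> np.ndarray | None:
        if SUBGROUP_COL in self.data.columns:
            return self.data[SUBGROUP_COL].to_numpy(dtype=int)
        return None

    def covariates(self) -> pd.DataFrame:
        return self.data[list(self.schema.features)]

    def subset(self, mask_or_index) -> "CohortTable":
        """Row subset (boolean mask or positional indices), keeping the schema."""
        sel = np.asarray(mask_or_index)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        sub = self.data.iloc[sel]
        return CohortTable(sub.reset_index(drop=True), self.schema)


def read_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read a cohort CSV (comma-separated, UTF-8, empty string = missing)."""
    df = pd.read_csv(
        path,
        dtype={ID_COL: str},
        keep_default_na=False,
        na_values=[""],
    )
    for col in (ID_COL, TIME_COL, EVENT_COL):
        if col not in df.columns:
            raise CohortValidationError(f"{path}: missing required column {col!r}")
    try:
        df[TIME_COL] = pd.to_numeric(df[TIME_COL])
    except (ValueError, TypeError) as exc:
        bad = pd.to_numeric(df[TIME_COL], errors="coerce").isna() & df[TIME_COL].notna()
        rows = np.flatnonzero(bad.to_numpy())[:3].tolist()
        raise CohortValidationError(f"{path}: non-numeric time at rows {rows}") from exc
    try:
        df[EVENT_COL] = pd.to_numeric(df[EVENT_COL])
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(f"{path}: non-numeric event column") from exc
    # categorical columns stay as strings; missing stays NaN
    for f in schema.categorical:
        if f in df.columns:
            df[f] = df[f].astype(object).where(df[f].notna(), np.nan)
            df[f] = df[f].map(lambda v: v if (isinstance(v, float) and np.isnan(v)) else str(v))
    return CohortTable(df, schema)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; missing values become empty strings."""
    cohort.data.to_csv(path, index=False, na_rep="")


class BundleError(ValueError):
    """Raised on unreadable or incompatible model bundles."""


@dataclass
class ModelBundle:
    """Serializable container for a fitted pipeline.

    ``payload`` is the nested-dict form of the fitted model (produced by the
    model's own ``to_dict``); ``fit_config`` records every hyperparameter of
    the run; ``rng_seed`` is the master seed.
    """

    kind: str  # "pcube" or "baseline"
    payload: dict[str, Any]
    fit_config: dict[str, Any]
    rng_seed: int
    schema_version: str = SCHEMA_VERSION
    meta: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "kind": self.kind,
            "payload": self.payload,
            "fit_config": self.fit_config,
            "rng_seed": self.rng_seed,
            "meta": self.meta,
        }


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    """Write a bundle as JSON (sorted keys, so identical bundles are byte-identical)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle.to_dict(), fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> ModelBundle:
    """Load a bundle; truncated or corrupt files raise, never a partial model."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise BundleError(f"{path}: corrupt or truncated model bundle ({exc})") from exc
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise BundleError(
            f"{path}: bundle schema_version {version!r} is incompatible with "
            f"this build ({SCHEMA_VERSION!r})"
        )
    return ModelBundle(
        kind=d["kind"],
        payload=d["payload"],
        fit_config=d["fit_config"],
        rng_seed=d["rng_seed"],
        schema_version=version,
        meta=d.get("meta", {}),
    )
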