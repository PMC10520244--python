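"""Elbow-rule selection of subgroup-specific risk factors.

Per-feature importance is the *net weight* across the m time points,
w_f = |sum_j theta_{j,f}|: the coefficient of feature f in the
log-probability contrast f_1(x) - f_{m+1}(x) between failing in the first
interval and surviving the whole grid.  The MTLR likelihood spreads a
covariate's effect over the m time-specific rows, so the signed sum
recovers the total effect while row-wise oscillation (noise) cancels;
one-hot columns belonging to the same raw categorical covariate are
combined by their maximum and reported under the raw name.  Because every
encoded column is on a common scale (z-scores / 0-1 indicators), a single
absolute threshold on consecutive differences of the ranked importances is
meaningful across features.

The stop rule: rank importances in descending order, compute consecutive
differences d_f = w_f - w_{f+1}, and place the stop line at the first
position where d_f falls below the threshold (default 0.007).  Features
strictly above the stop line are selected; if no difference is below the
threshold every feature is selected, and if the very first difference is
below it the single top feature is still selected (selection is never
empty).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .mtlr import MTLRModel
from .preprocess import EncodingSpec

DEFAULT_THRESHOLD = 0.007


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureRanking:
    """Features ranked by importance with the elbow stop line applied."""

    feature_names: tuple[str, ...]  # descending importance
    importance: tuple[float, ...]
    diffs: tuple[float, ...]  # length len(features) - 1
    selected: tuple[bool, ...]
    threshold: float

    @property
    def selected_features(self) -> tuple[str, ...]:
        return tuple(f for f, s in zip(self.feature_names, self.selected) if s)

    def to_dict(self) -> dict[str, Any]:
        return {
            "feature_names": list(self.feature_names),
            "importance": list(self.importance),
            "diffs": list(self.diffs),
            "selected": list(self.selected),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FeatureRanking":
        return cls(
            feature_names=tuple(d["feature_names"]),
            importance=tuple(float(v) for v in d["importance"]),
            diffs=tuple(float(v) for v in d["diffs"]),
            selected=tuple(bool(v) for v in d["selected"]),
            threshold=float(d["threshold"]),
        )


def aggregate_importance(model: MTLRModel, encoding: EncodingSpec | None = None) -> dict[str, float]:
    """Net weight |sum_j theta_{j,f}| per column, folded to raw features (max rule)."""
    w_col = np.abs(np.sum(model.theta, axis=0))
    names = model.feature_names or tuple(f"x{j}" for j in range(model.p))
    out: dict[str, float] = {}
    for name, w in zip(names, w_col):
        raw = encoding.raw_feature_of(name) if encoding is not None else name.split("=", 1)[0]
        out[raw] = max(out[raw], float(w)) if raw in out else float(w)
    return out


def elbow_select(importance: Mapping[str, float], threshold: float = DEFAULT_THRESHOLD) -> FeatureRanking:
    """Apply the ranked-difference stop rule to an importance map."""
    if not importance:
        raise SelectionError("empty importance map")
    if threshold <= 0:
        raise SelectionError("threshold must be strictly positive")
    items = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    names = tuple(k for k, _ in items)
    w = np.array([v for _, v in items], dtype=float)
    diffs = -np.diff(w)
    below = np.flatnonzero(diffs < threshold)
    if below.size == 0:
        n_sel = len(names)
    else:
        n_sel = max(1, int(below[0]) + 1)  # stop line at first sub-threshold gap
    selected = tuple(i < n_sel for i in range(len(names)))
    return FeatureRanking(
        feature_names=names,
        importance=tuple(float(v) for v in w),
        diffs=tuple(float(v) for v in diffs),
        selected=selected,
        threshold=float(threshold),
    )


def rank_report(rankings: Mapping[int, FeatureRanking]) -> pd.DataFrame:
    """Long-format cross-subgroup table with common/unique annotations.

    A feature is "common" when selected in every subgroup and "unique" when
    selected in exactly one.
    """
    if not rankings:
        raise SelectionError("no subgroup rankings supplied")
    rows = []
    sel_count: dict[str, int] = {}
    for sg, rk in rankings.items():
        for f in rk.selected_features:
            sel_count[f] = sel_count.get(f, 0) + 1
    n_sub = len(rankings)
    for sg in sorted(rankings):
        rk = rankings[sg]
        for f, w, s in zip(rk.feature_names, rk.importance, rk.selected):
            rows.append(
                {
                    "subgroup": sg,
                    "feature": f,
                    "importance": w,
                    "selected": bool(s),
                    "common": sel_count.get(f, 0) == n_sub and bool(s),
                    "unique": sel_count.get(f, 0) == 1 and bool(s),
                }
            )
    return pd.DataFrame(rows)
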