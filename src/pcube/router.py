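"""Model decision tree: route a donor-recipient pair to its subgroup pathway.

After consensus clustering, a shallow CART classifier is trained to
reproduce the subgroup labels from the encoded covariates.  The tree is
immediately exported to explicit split-rule arrays and all routing runs off
the stored arrays, so a serialized model routes bit-identically after a
JSON round trip.  A nearest-centroid fallback router is kept for audit.

Routing a patient yields the subgroup label plus a human-readable pathway
trace ("recipient_age <= 17.6 -> subgroup 1"), with thresholds reported in
raw units for continuous covariates (de-standardized via the encoding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .consensus import assign_to_centroids
from .features import FeatureRanking
from .mtlr import MTLRModel, predict_curve, survival_at
from .preprocess import EncodingSpec, encode_records


class RouterError(ValueError):
    pass


@dataclass(frozen=True)
class TreeRules:
    """Explicit CART split arrays; prediction uses only these arrays."""

    children_left: tuple[int, ...]
    children_right: tuple[int, ...]
    feature: tuple[int, ...]  # -1 at leaves
    threshold: tuple[float, ...]
    leaf_label: tuple[int, ...]  # -1 at internal nodes
    feature_names: tuple[str, ...]
    training_accuracy: float

    def predict_one(self, x: np.ndarray, trace: list[str] | None = None) -> int:
        node = 0
        while self.feature[node] >= 0:
            f = self.feature[node]
            thr = self.threshold[node]
            go_left = x[f] <= thr
            if trace is not None:
                op = "<=" if go_left else ">"
                trace.append(f"{self.feature_names[f]} {op} {thr:.6g}")
            node = self.children_left[node] if go_left else self.children_right[node]
        label = self.leaf_label[node]
        if trace is not None:
            trace.append(f"-> subgroup {label}")
        return int(label)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.predict_one(row) for row in X], dtype=int)

    def split_features(self) -> tuple[str, ...]:
        used = sorted({self.feature_names[f] for f in self.feature if f >= 0})
        return tuple(used)

    def rules_text(self) -> str:
        lines: list[str] = []

        def walk(node: int, depth: int) -> None:
            pad = "  " * depth
            if self.feature[node] < 0:
                lines.append(f"{pad}-> subgroup {self.leaf_label[node]}")
                return
            name = self.feature_names[self.feature[node]]
            thr = self.threshold[node]
            lines.append(f"{pad}{name} <= {thr:.6g}:")
            walk(self.children_left[node], depth + 1)
            lines.append(f"{pad}{name} > {thr:.6g}:")
            walk(self.children_right[node], depth + 1)

        walk(0, 0)
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "children_left": list(self.children_left),
            "children_right": list(self.children_right),
            "feature": list(self.feature),
            "threshold": list(self.threshold),
            "leaf_label": list(self.leaf_label),
            "feature_names": list(self.feature_names),
            "training_accuracy": self.training_accuracy,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TreeRules":
        return cls(
            children_left=tuple(int(v) for v in d["children_left"]),
            children_right=tuple(int(v) for v in d["children_right"]),
            feature=tuple(int(v) for v in d["feature"]),
            threshold=tuple(float(v) for v in d["threshold"]),
            leaf_label=tuple(int(v) for v in d["leaf_label"]),
            feature_names=tuple(d["feature_names"]),
            training_accuracy=float(d["training_accuracy"]),
        )


def fit_router(
    X: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str],
    max_depth: int = 4,
    min_samples_leaf: int = 20,
    encoding: EncodingSpec | None = None,
) -> TreeRules:
    """Fit a CART router on consensus labels and export its split rules.

    Thresholds on z-scored continuous columns are de-standardized so the
    stored rules read in raw units; the encoded design matrix passed at
    prediction time is de-standardized consistently (see ``_to_rule_space``).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if uniq.size < 2:
        warnings.warn("single consensus label: router is constant")
        return TreeRules(
            children_left=(-1,),
            children_right=(-1,),
            feature=(-1,),
            threshold=(0.0,),
            leaf_label=(int(uniq[0]),),
            feature_names=tuple(feature_names),
            training_accuracy=1.0,
        )
    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min(min_samples_leaf, max(1, len(labels) // (2 * uniq.size))),
        random_state=0,
    )
    Xr = _to_rule_space(X, tuple(feature_names), encoding)
    clf.fit(Xr, labels)
    acc = float(clf.score(Xr, labels))
    t = clf.tree_
    leaf_label = []
    for node in range(t.node_count):
        if t.children_left[node] == -1:
            leaf_label.append(int(clf.classes_[int(np.argmax(t.value[node][0]))]))
        else:
            leaf_label.append(-1)
    return TreeRules(
        children_left=tuple(int(v) for v in t.children_left),
        children_right=tuple(int(v) for v in t.children_right),
        feature=tuple(int(v) if l != -1 else -1 for v, l in zip(t.feature, t.children_left)),
        threshold=tuple(float(v) for v in t.threshold),
        leaf_label=tuple(leaf_label),
        feature_names=tuple(feature_names),
        training_accuracy=acc,
    )


def _to_rule_space(X: np.ndarray, feature_names: tuple[str, ...], encoding: EncodingSpec | None) -> np.ndarray:
    """De-standardize continuous columns so tree thresholds read in raw units."""
    if encoding is None:
        return X
    X = np.array(X, dtype=float, copy=True)
    for j, name in enumerate(feature_names):
        if name in encoding.continuous_stats:
            mean, sd = encoding.continuous_stats[name]
            X[:, j] = X[:, j] * sd + mean
    return X


@dataclass
class PCubeModel:
    """The full precision-pathway model.

    Holds the shared encoding, the consensus partition of the derivation
    cohort (labels + centroids), the decision-tree router, and one fitted
    MTLR model plus selected-feature ranking per subgroup.
    """

    encoding: EncodingSpec
    training_labels: np.ndarray
    centroid_labels: np.ndarray
    centroids: np.ndarray
    tree: TreeRules
    subgroup_models: dict[int, MTLRModel]
    subgroup_rankings: dict[int, FeatureRanking]
    router_mode: str = "tree"  # "tree" or "centroid"

    def __post_init__(self) -> None:
        tree_labels = {lab for lab in self.tree.leaf_label if lab >= 0}
        missing = tree_labels - set(self.subgroup_models)
        if missing:
            raise RouterError(f"router can emit labels without fitted models: {sorted(missing)}")
        if self.router_mode not in ("tree", "centroid"):
            raise RouterError(f"unknown router_mode {self.router_mode!r}")

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(sorted(self.subgroup_models))

    # -- routing ---------------------------------------------------------
    def _encode(self, patient: Mapping[str, Any] | pd.DataFrame) -> np.ndarray:
        if isinstance(patient, pd.DataFrame):
            df = patient
        else:
            df = pd.DataFrame([dict(patient)])
        if not isinstance(patient, pd.DataFrame):
            provided = set(patient.keys())
            split_feats = {
                self.encoding.raw_feature_of(f) for f in self.tree.split_features()
            }
            if self.router_mode == "tree" and split_feats and not (provided & split_feats):
                raise RouterError(
                    f"patient record provides none of the routing features {sorted(split_feats)}"
                )
        return encode_records(df, self.encoding)

    def route(self, patient: Mapping[str, Any] | pd.DataFrame, trace: list[str] | None = None) -> int:
        """Subgroup label for one patient (record mapping or 1-row frame)."""
        Xe = self._encode(patient)
        if self.router_mode == "tree":
            Xr = _to_rule_space(Xe, self.tree.feature_names, self.encoding)
            return self.tree.predict_one(Xr[0], trace=trace)
        label = int(assign_to_centroids(Xe, self.centroid_labels, self.centroids)[0])
        if trace is not None:
            trace.append(f"nearest centroid -> subgroup {label}")
        return label

    def route_matrix(self, X_encoded: np.ndarray) -> np.ndarray:
        """Vectorized routing of already-encoded rows."""
        X_encoded = np.atleast_2d(X_encoded)
        if self.router_mode == "tree":
            Xr = _to_rule_space(X_encoded, self.tree.feature_names, self.encoding)
            return self.tree.predict(Xr)
        return np.asarray(
            assign_to_centroids(X_encoded, self.centroid_labels, self.centroids), dtype=int
        )

    # -- prediction ------------------------------------------------------
    def predict_survival(
        self, patient: Mapping[str, Any] | pd.DataFrame, times: Sequence[float]
    ) -> tuple[int, list[str], np.ndarray]:
        """(subgroup, pathway trace, survival probabilities at ``times``)."""
        trace: list[str] = []
        label = self.route(patient, trace=trace)
        model = self.subgroup_models[label]
        Xe = self._encode(patient)
        curve = predict_curve(model, Xe[0])
        probs = np.asarray([survival_at(curve, float(t)) for t in times])
        return label, trace, probs

    def risk_scores(self, X_encoded: np.ndarray) -> np.ndarray:
        from .mtlr import risk_score

        X_encoded = np.atleast_2d(X_encoded)
        labels = self.route_matrix(X_encoded)
        # common integration horizon so scores are comparable across subgroups
        horizon = max(m.grid.points[-1] for m in self.subgroup_models.values())
        out = np.empty(X_encoded.shape[0])
        for lab in np.unique(labels):
            idx = labels == lab
            out[idx] = risk_score(self.subgroup_models[int(lab)], X_encoded[idx], horizon=horizon)
        return out

    def survival_probabilities(self, X_encoded: np.ndarray, times: Sequence[float]) -> np.ndarray:
        """(n, len(times)) matrix of routed survival probabilities."""
        X_encoded = np.atleast_2d(X_encoded)
        labels = self.route_matrix(X_encoded)
        out = np.empty((X_encoded.shape[0], len(times)))
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            model = self.subgroup_models[int(lab)]
            for i in idx:
                curve = predict_curve(model, X_encoded[i])
                out[i] = [survival_at(curve, float(t)) for t in times]
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "encoding": self.encoding.to_dict(),
            "training_labels": self.training_labels.tolist(),
            "centroid_labels": self.centroid_labels.tolist(),
            "centroids": self.centroids.tolist(),
            "tree": self.tree.to_dict(),
            "subgroup_models": {str(k): v.to_dict() for k, v in self.subgroup_models.items()},
            "subgroup_rankings": {str(k): v.to_dict() for k, v in self.subgroup_rankings.items()},
            "router_mode": self.router_mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PCubeModel":
        return cls(
            encoding=EncodingSpec.from_dict(d["encoding"]),
            training_labels=np.asarray(d["training_labels"], dtype=int),
            centroid_labels=np.asarray(d["centroid_labels"], dtype=int),
            centroids=np.asarray(d["centroids"], dtype=float),
            tree=TreeRules.from_dict(d["tree"]),
            subgroup_models={int(k): MTLRModel.from_dict(v) for k, v in d["subgroup_models"].items()},
            subgroup_rankings={
                int(k): FeatureRanking.from_dict(v) for k, v in d["subgroup_rankings"].items()
            },
            router_mode=d.get("router_mode", "tree"),
        )
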