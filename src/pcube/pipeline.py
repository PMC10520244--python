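"""End-to-end orchestration: simulate -> encode -> cluster -> fit per-subgroup
MTLR -> select risk factors -> fit router -> evaluate against the pooled
baseline.  Every stage draws its randomness from one master seed, and a run
is fully reproducible from the echoed configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import consensus as cc
from . import features as fs
from . import mtlr
from .cohort import CohortTable, ModelBundle, save_model
from .evaluate import (
    BaselineCoxModel,
    EvalReport,
    StabilityResult,
    compare_models,
    fit_baseline,
    perturbation_stability,
)
from .preprocess import fit_encoding, transform
from .router import PCubeModel, fit_router
from .simulate import default_preset, simulate_cohort

log = logging.getLogger("pcube")


@dataclass
class RunConfig:
    """All pipeline hyperparameters with their defaults."""

    seed: int = 0
    # clustering
    k_min: int = 2
    k_max: int = 8
    kmeans_restarts: int = 10
    linkages: tuple[str, ...] = ("ward", "average", "complete")
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    min_cluster_size: int | None = None  # None -> max(30, 2% of n)
    # mtlr
    mtlr_m: int | str = "auto"
    mtlr_c1: float = 5.0
    mtlr_c2: float = 20.0
    mtlr_tol: float = 1e-5
    mtlr_max_iter: int = 500
    # selection
    selection_threshold: float = fs.DEFAULT_THRESHOLD
    # router
    router_mode: str = "tree"
    router_max_depth: int = 4
    router_min_leaf: int = 20
    # evaluation
    split_fraction: float = 0.8
    horizons: tuple[float, ...] = (5.0, 10.0)
    bootstrap_B: int = 200
    baseline_penalizer: float = 0.1

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["linkages"] = list(self.linkages)
        d["pac_bounds"] = list(self.pac_bounds)
        d["horizons"] = list(self.horizons)
        return d


def split_cohort(cohort: CohortTable, fraction: float, seed: int) -> tuple[CohortTable, CohortTable]:
    """Derivation/validation split, stratified on the event indicator."""
    idx = np.arange(len(cohort))
    der, val = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=cohort.event
    )
    return cohort.subset(np.sort(der)), cohort.subset(np.sort(val))


def fit_pcube(
    cohort: CohortTable,
    config: RunConfig,
    K_override: int | None = None,
) -> PCubeModel:
    """Fit the full precision-pathway model on a derivation cohort.

    ``K_override`` pins the number of subgroups (used by the perturbation
    stability analysis, where K stays fixed to the original model's).
    """
    spec = fit_encoding(cohort)
    fm = transform(cohort, spec)
    k_range = list(range(config.k_min, config.k_max + 1))
    k_range = [k for k in k_range if k <= max(2, len(cohort) // 10)] or [2]
    parts = cc.run_base_clusterings(
        fm,
        k_range=k_range,
        n_kmeans_restarts=config.kmeans_restarts,
        linkages=config.linkages,
        seed=config.seed,
    )
    min_size = (
        config.min_cluster_size
        if config.min_cluster_size is not None
        else cc.default_min_cluster_size(len(cohort))
    )
    result = cc.consensus_partition(
        parts,
        k_range=k_range,
        pac_bounds=config.pac_bounds,
        min_cluster_size=min_size,
        force_K=K_override,
    )
    log.info("consensus: chose K=%d, sizes=%s", result.chosen_K, result.cluster_sizes())

    labels = result.labels
    uniq, cents = cc.cluster_centroids(fm.values, labels)
    tree = fit_router(
        fm.values,
        labels,
        feature_names=fm.feature_names,
        max_depth=config.router_max_depth,
        min_samples_leaf=config.router_min_leaf,
        encoding=spec,
    )

    subgroup_models: dict[int, mtlr.MTLRModel] = {}
    subgroup_rankings: dict[int, fs.FeatureRanking] = {}
    for lab in uniq:
        sub = cohort.subset(labels == lab)
        Xsub = fm.values[labels == lab]
        model = mtlr.fit(
            Xsub,
            sub,
            m=config.mtlr_m,
            c1=config.mtlr_c1,
            c2=config.mtlr_c2,
            tol=config.mtlr_tol,
            max_iter=config.mtlr_max_iter,
            feature_names=fm.feature_names,
        )
        imp = fs.aggregate_importance(model, spec)
        subgroup_models[int(lab)] = model
        subgroup_rankings[int(lab)] = fs.elbow_select(imp, config.selection_threshold)

    return PCubeModel(
        encoding=spec,
        training_labels=labels,
        centroid_labels=uniq,
        centroids=cents,
        tree=tree,
        subgroup_models=subgroup_models,
        subgroup_rankings=subgroup_rankings,
        router_mode=config.router_mode,
    )


@dataclass
class PipelineResult:
    model: PCubeModel
    baseline: BaselineCoxModel
    report: EvalReport
    derivation: CohortTable
    validation: CohortTable
    config: RunConfig


def run_pipeline(cohort: CohortTable, config: RunConfig) -> PipelineResult:
    """Split, fit both models on the derivation half, evaluate on validation."""
    derivation, validation = split_cohort(cohort, config.split_fraction, config.seed)
    model = fit_pcube(derivation, config)
    baseline = fit_baseline(derivation, model.encoding, penalizer=config.baseline_penalizer)
    report = compare_models(
        model,
        baseline,
        validation,
        horizons=config.horizons,
        derivation_ids=derivation.ids,
        B=config.bootstrap_B,
        seed=config.seed,
    )
    return PipelineResult(
        model=model,
        baseline=baseline,
        report=report,
        derivation=derivation,
        validation=validation,
        config=config,
    )


def bundle_pcube(model: PCubeModel, config: RunConfig) -> ModelBundle:
    return ModelBundle(
        kind="pcube",
        payload=model.to_dict(),
        fit_config=config.to_dict(),
        rng_seed=config.seed,
    )


def run_stability(
    cohort: CohortTable,
    config: RunConfig,
    original_model: PCubeModel | None = None,
    fraction: float = 0.8,
    seed: int = 0,
) -> StabilityResult:
    """Perturbation analysis: refit on a random subsample (K fixed) and
    correlate survival predictions with the original model's."""

    def fit_fn(sub: CohortTable, K_override: int | None) -> PCubeModel:
        return fit_pcube(sub, config, K_override=K_override)

    return perturbation_stability(
        cohort, fit_fn, original_model=original_model, fraction=fraction, seed=seed
    )


DEMO_PATIENTS = (
    {
        "label": "paediatric recipient, 16 y, sensitized",
        "record": {
            "donor_age": 35.0, "recipient_age": 16.0, "pra": 60.0,
            "hla_a_mm": 1, "hla_b_mm": 1, "hla_dr_mm": 1,
            "sex": "F", "diabetes": "0", "cvd": "0", "abo_compatible": "1",
            "dcd": "0", "age_difference": 19.0,
        },
    },
    {
        "label": "middle-aged recipient, 45 y, no comorbidity",
        "record": {
            "donor_age": 45.0, "recipient_age": 45.0, "pra": 5.0,
            "hla_a_mm": 1, "hla_b_mm": 1, "hla_dr_mm": 1,
            "sex": "M", "diabetes": "0", "cvd": "0", "abo_compatible": "1",
            "dcd": "0", "age_difference": 0.0,
        },
    },
    {
        "label": "elderly recipient, 62 y, diabetes + cardiovascular disease",
        "record": {
            "donor_age": 55.0, "recipient_age": 62.0, "pra": 10.0,
            "hla_a_mm": 1, "hla_b_mm": 1, "hla_dr_mm": 2,
            "sex": "F", "diabetes": "1", "cvd": "1", "abo_compatible": "1",
            "dcd": "0", "age_difference": -7.0,
        },
    },
)


def run_demo(
    out_dir: str | Path,
    n: int = 1500,
    seed: int = 7,
    config: RunConfig | None = None,
) -> dict[str, Any]:
    """One-command synthetic end-to-end run; writes all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig(seed=seed)
    cohort = simulate_cohort(default_preset(n=n, seed=seed))

    from .cohort import write_cohort

    write_cohort(cohort, out / "cohort.csv")
    result = run_pipeline(cohort, config)
    save_model(bundle_pcube(result.model, config), out / "model.json")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.report.to_dict(), fh, sort_keys=True, indent=1)
    fs.rank_report(result.model.subgroup_rankings).to_csv(out / "feature_ranking.csv", index=False)
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, sort_keys=True, indent=1)

    pathways = []
    times = [1.0, 3.0, 5.0, 10.0]
    for pat in DEMO_PATIENTS:
        label, trace, probs = result.model.predict_survival(pat["record"], times)
        pathways.append(
            {
                "patient": pat["label"],
                "subgroup": label,
                "pathway": trace,
                "times": times,
                "survival": [float(p) for p in probs],
            }
        )
    with open(out / "pathways.json", "w", encoding="utf-8") as fh:
        json.dump(pathways, fh, sort_keys=True, indent=1)
    return {
        "chosen_K": len(result.model.labels),
        "report": result.report.to_dict(),
        "pathways": pathways,
    }
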