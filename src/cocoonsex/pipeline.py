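"""End-to-end orchestration: synth -> extract -> compress/fuse -> evaluate.

The pipeline mirrors how the method is meant to be used on real rearing
batches: HOG descriptors are extracted once per specimen; everything that is
fitted (block-LDA projections, weight standardization, the classifier) is
fitted on the training folds only, so the reported cross-validated metrics
are leakage-free.  ``run_pipeline`` drives the stages from a single JSON
config and writes a self-describing run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .blockfeatures import WeightStats, fit_block_lda, fuse_weight, transform_block_lda
from .classify import (
    ClassifierSpec,
    ConfusionMatrix,
    MetricsReport,
    make_classifier,
    metrics_from_confusion,
    rank_auc,
)
from .fasthog import HOGParams, fast_hog
from .preprocess import load_gray_image, load_manifest, resize_canonical
from .synthgen import SyntheticDataset, generate_dataset, preset, write_dataset


def extract_descriptors(
    images: np.ndarray, params: HOGParams | None = None
) -> np.ndarray:
    """FFT-HOG descriptors for a stack of raw (pre-resize) grayscale images."""
    params = params or HOGParams()
    out = np.empty((len(images), params.descriptor_length))
    for i, img in enumerate(images):
        out[i] = fast_hog(resize_canonical(np.asarray(img, dtype=float)), params)
    return out


def extract_from_manifest(
    manifest_path: str, params: HOGParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a manifest and return (descriptors, weights, labels)."""
    params = params or HOGParams()
    specimens = load_manifest(manifest_path)
    D = np.empty((len(specimens), params.descriptor_length))
    for i, s in enumerate(specimens):
        D[i] = fast_hog(load_gray_image(s.image_path), params)
    weights = np.array([s.weight for s in specimens])
    labels = np.array([s.label for s in specimens])
    return D, weights, labels


def crossval_pipeline(
    descriptors: np.ndarray,
    weights: np.ndarray,
    labels: np.ndarray,
    hog_params: HOGParams | None = None,
    classifier: ClassifierSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[MetricsReport, pd.DataFrame, ConfusionMatrix]:
    """Stratified k-fold evaluation of the full compress-fuse-classify stack.

    Per fold: block-LDA and weight statistics are fitted on the training
    split, both splits are compressed to 105 + 1 features, and the
    classifier is trained and scored.  Returns fold-mean metrics (AUC from
    pooled out-of-fold scores), the per-fold table and the pooled confusion
    matrix.
    """
    hog_params = hog_params or HOGParams()
    classifier = classifier or ClassifierSpec("xgboost")
    D = np.asarray(descriptors, dtype=float)
    w = np.asarray(weights, dtype=float)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    oof = np.empty(len(y))
    rows = []
    for fold, (tr, te) in enumerate(skf.split(D, y)):
        lda = fit_block_lda(D[tr], y[tr], params=hog_params)
        wstats = WeightStats.fit(w[tr])
        Xtr = fuse_weight(transform_block_lda(lda, D[tr]), w[tr], wstats)
        Xte = fuse_weight(transform_block_lda(lda, D[te]), w[te], wstats)
        model = make_classifier(classifier, seed=seed).fit(Xtr, y[tr])
        pred = model.predict(Xte)
        oof[te] = model.predict_score(Xte)
        cm = ConfusionMatrix.from_predictions(y[te], pred)
        pooled = pooled + cm
        rep = metrics_from_confusion(cm)
        rows.append(
            {
                "fold": fold,
                "n_test": len(te),
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
            }
        )
    folds = pd.DataFrame(rows)
    report = MetricsReport(
        accuracy=float(folds["accuracy"].mean()),
        precision=float(folds["precision"].mean()),
        recall=float(folds["recall"].mean()),
        f1=float(folds["f1"].mean()),
        auc=rank_auc(y, oof),
    )
    return report, folds, pooled


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int
    preset: str = "fc1"  # synthetic preset; ignored when manifest given
    manifest: str | None = None
    hog: dict = field(default_factory=dict)
    folds: int = 10
    mi_bins: int = 10
    classifiers: tuple[str, ...] = ("xgboost",)
    run_rfe: bool = False
    rfe_model: str = "xgboost"
    optimize_method: str | None = None  # None | grid | ga | tlbpsga
    ga: dict = field(default_factory=dict)
    grid_sizes: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2)

    @classmethod
    def from_json(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        if "classifiers" in raw:
            raw["classifiers"] = tuple(raw["classifiers"])
        if "grid_sizes" in raw:
            raw["grid_sizes"] = tuple(raw["grid_sizes"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike) -> dict:
    """Execute the configured stages and write a self-describing run directory.

    Artifacts: ``config.json`` (with its hash and library versions),
    ``features.csv`` (fused 106-feature table), ``metrics.json`` per
    classifier, optionally ``rfe_path.csv`` and ``optimization.json``.
    Deterministic stages are bit-identical under rerun with the same config.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    marker = os.path.join(out_dir, "FAILED")
    try:
        result = _run_stages(config, out_dir)
    except Exception:
        with open(marker, "w") as fh:
            fh.write("pipeline stage failed; partial artifacts retained\n")
        raise
    if os.path.exists(marker):
        os.remove(marker)
    return result


def _run_stages(config: RunConfig, out_dir: str) -> dict:
    hog_params = HOGParams(**config.hog)
    provenance = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "python": platform.python_version(),
        "cocoonsex": __version__,
        "numpy": np.__version__,
    }
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    if config.manifest:
        D, weights, labels = extract_from_manifest(config.manifest, hog_params)
    else:
        dataset = generate_dataset(preset(config.preset, seed=config.seed))
        D = extract_descriptors(dataset.images, hog_params)
        weights, labels = dataset.weights, dataset.labels

    counts = np.bincount(labels, minlength=2)
    if counts.min() < config.folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < folds={config.folds}"
        )

    # full-data fused feature table exported for inspection; CV below refits
    # the compression per training fold and never reads this file
    lda_full = fit_block_lda(D, labels, params=hog_params)
    wstats_full = WeightStats.fit(weights)
    fused = fuse_weight(transform_block_lda(lda_full, D), weights, wstats_full)
    table = pd.DataFrame(
        fused, columns=[f"f{i + 1:03d}" for i in range(fused.shape[1] - 1)] + ["weight_z"]
    )
    table["label"] = labels
    table.to_csv(os.path.join(out_dir, "features.csv"), index=False)

    metrics = {}
    for name in config.classifiers:
        report, folds, pooled = crossval_pipeline(
            D, weights, labels, hog_params,
            ClassifierSpec(name), k=config.folds, seed=config.seed,
        )
        metrics[name] = {
            **report.as_dict(),
            "confusion": {"tp": pooled.tp, "fp": pooled.fp,
                          "fn": pooled.fn, "tn": pooled.tn},
        }
        folds.to_csv(os.path.join(out_dir, f"folds_{name}.csv"), index=False)
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2)

    result = {"metrics": metrics, "out_dir": out_dir}

    if config.run_rfe:
        from .featselect import rfe

        X = fused
        path = rfe(
            X, labels, model_name=config.rfe_model,
            k=config.folds, seed=config.seed, bins=config.mi_bins,
        )
        path.to_frame().to_csv(os.path.join(out_dir, "rfe_path.csv"), index=False)
        with open(os.path.join(out_dir, "rfe_best.json"), "w") as fh:
            json.dump({"features": list(path.best_features),
                       "metrics": path.best_metrics}, fh, indent=2)
        result["rfe_best"] = path.best_features

    if config.optimize_method:
        from .optimize import (
            GAConfig, classical_ga, default_space, grid_search,
            make_cv_fitness, tlbpsga,
        )

        space = default_space()
        fitness = make_cv_fitness(
            fused, labels, space, k=config.folds, seed=config.seed
        )
        ga_cfg = GAConfig(**{"seed": config.seed, **config.ga})
        if config.optimize_method == "grid":
            opt = grid_search(space, config.grid_sizes, fitness)
        elif config.optimize_method == "ga":
            opt = classical_ga(space, fitness, ga_cfg)
        elif config.optimize_method == "tlbpsga":
            opt = tlbpsga(space, fitness, ga_cfg)
        else:
            raise ValueError(f"unknown optimize_method {config.optimize_method!r}")
        with open(os.path.join(out_dir, "optimization.json"), "w") as fh:
            json.dump(
                {
                    "method": config.optimize_method,
                    "best_params": opt.best_params,
                    "best_fitness": opt.best_fitness,
                    "first_attained": opt.first_attained,
                    "n_evaluations": opt.n_evaluations,
                    "trajectory": opt.trajectory.tolist(),
                },
                fh, indent=2,
            )
        result["optimization"] = opt
    return result
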