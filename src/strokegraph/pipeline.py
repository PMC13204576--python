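"""End-to-end orchestration: preprocess -> graph -> CV train/eval -> artifacts.

The pixel-level evaluation path is: predict node labels on the slice's
region graph, paint them back onto the pixel grid, and pool confusion
counts over all test slices of a fold ("global-pooled" aggregation, under
which the Dice/Jaccard identity J = D/(2-D) is exact).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import PipelineConfig, GraphConfig
from .errors import StrokeGraphError
from .evaluate import (MetricsReport, confusion_counts, metrics_from_counts,
                       patient_kfold, robustness_sweep)
from .graphs import build_region_graph, nodes_to_mask, slic_segment
from .io import load_cohort, save_cohort_png
from .model import ChebGCN, train
from .phantom import PhantomSpec, SliceSample, generate_cohort
from .preprocess import (PreprocessConfig, clip_hounsfield, normalize_intensity,
                         standardize_size)
from .spectral import scaled_laplacian

__all__ = [
    "preprocess_sample",
    "build_graph_for_slice",
    "predict_mask",
    "evaluate_samples",
    "run_cv",
    "run_pipeline",
]


def preprocess_sample(sample: SliceSample,
                      pre_cfg: PreprocessConfig | None = None):
    """HU clip -> [0,1] normalization -> size standardization."""
    pre_cfg = pre_cfg or PreprocessConfig()
    image = clip_hounsfield(sample.image, pre_cfg)
    image = normalize_intensity(image, pre_cfg)
    image, mask = standardize_size(image, sample.mask, pre_cfg)
    return image, mask


def build_graph_for_slice(sample: SliceSample,
                          pre_cfg: PreprocessConfig | None = None,
                          graph_cfg: GraphConfig | None = None):
    """Full slice -> (RegionGraph, SuperpixelMap, mask) construction."""
    graph_cfg = graph_cfg or GraphConfig()
    image, mask = preprocess_sample(sample, pre_cfg)
    spmap = slic_segment(image, n_zones=graph_cfg.n_zones,
                         compactness=graph_cfg.compactness)
    graph = build_region_graph(spmap, image, mask, sigma=graph_cfg.sigma,
                               label_threshold=graph_cfg.label_threshold,
                               feature_mode=graph_cfg.feature_mode)
    graph.provenance = (sample.patient_id, sample.slice_index)
    return graph, spmap, mask


def predict_mask(model: ChebGCN, sample: SliceSample,
                 pre_cfg: PreprocessConfig | None = None,
                 graph_cfg: GraphConfig | None = None):
    """Predicted pixel mask + standardized truth mask for one slice."""
    graph, spmap, mask = build_graph_for_slice(sample, pre_cfg, graph_cfg)
    _, preds = model.predict_graph(graph)
    return nodes_to_mask(spmap, preds), mask


def evaluate_samples(model: ChebGCN, samples: list[SliceSample],
                     pre_cfg: PreprocessConfig | None = None,
                     graph_cfg: GraphConfig | None = None,
                     fold_id: int = -1) -> MetricsReport:
    """Globally pooled pixel metrics of a model over a set of slices."""
    totals = np.zeros(4, dtype=np.float64)
    for s in samples:
        pred, truth = predict_mask(model, s, pre_cfg, graph_cfg)
        totals += confusion_counts(pred, truth)
    tp, fp, fn, tn = totals
    return metrics_from_counts(tp, fp, fn, tn, n_slices=len(samples),
                               fold_id=fold_id)


def run_cv(samples: list[SliceSample], cfg: PipelineConfig | None = None,
           return_models: bool = False):
    """Patient-level k-fold cross-validation of the full pipeline.

    Graphs are built once per slice; each fold trains a fresh model on the
    training patients' graphs and is scored on the held-out patients'
    slices.  Returns a dict with per-fold reports, the fold assignment and
    (optionally) the trained models.
    """
    cfg = cfg or PipelineConfig()
    built = [build_graph_for_slice(s, cfg.preprocess, cfg.graph)
             for s in samples]
    laplacians = [scaled_laplacian(g.adjacency) for g, _, _ in built]
    folds = patient_kfold([s.patient_id for s in samples], k=cfg.eval.k,
                          seed=cfg.seed)
    reports: list[MetricsReport] = []
    models: list[ChebGCN] = []
    for fold in range(folds.k):
        train_idx = [i for i, s in enumerate(samples)
                     if folds.mapping[s.patient_id] != fold]
        test_idx = [i for i, s in enumerate(samples)
                    if folds.mapping[s.patient_id] == fold]
        tcfg = cfg.train
        model, _ = train([built[i][0] for i in train_idx], cfg.model, tcfg,
                         scaled_laplacians=[laplacians[i] for i in train_idx])
        totals = np.zeros(4, dtype=np.float64)
        for i in test_idx:
            graph, spmap, mask = built[i]
            _, preds = model.predict_graph(graph, Lt=laplacians[i])
            totals += confusion_counts(nodes_to_mask(spmap, preds), mask)
        reports.append(metrics_from_counts(*totals, n_slices=len(test_idx),
                                           fold_id=fold))
        if return_models:
            models.append(model)
    out = {"reports": reports, "folds": folds}
    if return_models:
        out["models"] = models
    return out


def run_pipeline(cfg: PipelineConfig | None = None) -> str:
    """Execute the whole pipeline and write a self-describing artifact directory.

    Stages: data loading (or phantom generation), cross-validated training
    and evaluation, optional SNR robustness sweep.  The directory contains
    the config, seed and package version, per-fold checkpoints and metrics,
    predicted masks for the last fold, and a JSON summary.
    """
    cfg = cfg or PipelineConfig()
    out_dir = cfg.paths.out_dir
    os.makedirs(out_dir, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StrokeGraphError(f"pipeline stage {name!r} failed: {exc}") from exc

    if cfg.paths.data_manifest:
        samples = stage("load", lambda: load_cohort(cfg.paths.data_manifest))
    else:
        spec = PhantomSpec(seed=cfg.seed, n_patients=cfg.phantom_patients)
        samples = stage("phantom", lambda: generate_cohort(spec))

    cv = stage("cross-validation", lambda: run_cv(samples, cfg, return_models=True))

    rows = [r.as_dict() for r in cv["reports"]]
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    for fold, model in enumerate(cv["models"]):
        model.save(os.path.join(out_dir, f"model_fold{fold}.json"))

    # Predicted masks for the last fold's test patients, as PNG pairs.
    last = cv["folds"].k - 1
    test_samples = [s for s in samples if cv["folds"].mapping[s.patient_id] == last]
    preds = []
    for s in test_samples:
        pm, _ = predict_mask(cv["models"][last], s, cfg.preprocess, cfg.graph)
        windowed = clip_hounsfield(s.image, cfg.preprocess)
        windowed, _ = standardize_size(windowed, s.mask, cfg.preprocess)
        preds.append(SliceSample(image=windowed, mask=pm,
                                 patient_id=s.patient_id,
                                 slice_index=s.slice_index))
    stage("write-predictions",
          lambda: save_cohort_png(preds, os.path.join(out_dir, "predictions")))

    summary = {
        "seed": cfg.seed,
        "version": _pkg_version,
        "n_slices": len(samples),
        "n_patients": len({s.patient_id for s in samples}),
        "mean_dsc": float(np.mean([r.dsc for r in cv["reports"]])),
        "mean_jaccard": float(np.mean([r.jaccard for r in cv["reports"]])),
        "mean_accuracy": float(np.mean([r.accuracy for r in cv["reports"]])),
        "per_fold": rows,
    }

    if cfg.eval.run_sweep:
        sweep = stage("snr-sweep", lambda: robustness_sweep(
            cv["models"][last], test_samples, cfg.eval.snr_grid,
            pre_cfg=cfg.preprocess, graph_cfg=cfg.graph, seed=cfg.seed))
        sweep_rows = [{"snr_db": "clean" if k is None else k, **v.as_dict()}
                      for k, v in sweep.items()]
        pd.DataFrame(sweep_rows).to_csv(os.path.join(out_dir, "snr_sweep.csv"),
                                        index=False)
        summary["snr_sweep"] = {str(k): v.dsc for k, v in sweep.items()}

    cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(os.path.join(out_dir, "log.txt"), "w") as fh:
        fh.write(f"strokegraph {_pkg_version}\nseed {cfg.seed}\n"
                 f"slices {len(samples)}\nfolds {cfg.eval.k}\n")
    return out_dir
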