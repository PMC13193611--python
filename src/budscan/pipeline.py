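"""End-to-end orchestration: simulate -> preprocess -> pretrain -> train ->
predict -> evaluate.

:func:`end_to_end_experiment` is the in-memory experiment used for validation
on synthetic movies: it generates cells with known division schedules, holds
out a cell-exclusive evaluation set, pretrains the masked auto-encoder on
unlabeled training-cell crops, trains the temporal detector on the training
cells, and scores held-out event detection and lifespan recovery, together
with the untrained-baseline and event-free negative controls.

:func:`run_pipeline` is the on-disk variant behind the command-line
interface; every artifact it writes carries the run configuration hash and
seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DivisionTimeline
from .detector import DetectorConfig, Detector, predict_timeline, train_detector
from .evaluate import (DetectionScores, LifespanAgreement, detection_scores,
                       lifespan_agreement, match_events, pool_reports,
                       untrained_baseline)
from .io import RunConfig, config_hash, read_annotations, read_movie, save_checkpoint
from .mae import MAEConfig, masked_mse, mean_baseline_mse, pretrain, _fixed_plans
from .postprocess import binarize, collapse_runs
from .preprocess import build_stacks, compute_norm_stats, label_stacks, split_by_cell
from .synthetic import ScheduleParams, SyntheticCellSpec, simulate_cells

__all__ = ["ExperimentResult", "end_to_end_experiment", "run_pipeline"]


@dataclass
class ExperimentResult:
    scores: DetectionScores            # pooled held-out detection scores (+/- tolerance)
    agreement: LifespanAgreement       # held-out per-cell RLS agreement
    baseline_scores: DetectionScores   # untrained-detector diagnostic control
    negative_control_zero: int         # event-free movies predicted with 0 events
    negative_control_total: int
    mae_val_mse: float                 # held-out masked-patch reconstruction MSE
    mae_baseline_mse: float            # per-image-mean reference MSE
    per_cell: pd.DataFrame             # cell_id, gt_rls, pred_rls
    detector: Detector
    norm_stats: object
    mae_log: object
    detector_log: object


def _labels_for(timeline: DivisionTimeline, n_frames: int, positive_span: int) -> np.ndarray:
    stacks = label_stacks(build_stacks(timeline.cell_id, n_frames), timeline,
                          positive_span=positive_span)
    return np.asarray([s.label for s in stacks], dtype=int)


def _pooled_scores(detector: Detector, movies: dict[str, np.ndarray],
                   truths: dict[str, DivisionTimeline], threshold: float,
                   max_gap: int, tolerance: int):
    reports, rls_records = [], []
    for c in sorted(movies):
        probs = predict_timeline(detector, movies[c], cell_id=c)
        pred = collapse_runs(binarize(probs, threshold))
        reports.append(match_events(truths[c], pred, max_gap=max_gap))
        rls_records.append((c, truths[c].rls, pred.rls))
    return pool_reports(reports), rls_records


def end_to_end_experiment(seed: int = 0, n_cells: int = 60, train_frac: float = 2 / 3,
                          schedule: ScheduleParams | None = None,
                          cell_spec: SyntheticCellSpec | None = None,
                          mae_cfg: MAEConfig | None = None,
                          det_cfg: DetectorConfig | None = None,
                          n_pretrain_crops: int = 2000,
                          n_negative_controls: int = 10,
                          positive_span: int = 1,
                          max_gap: int = 5, tolerance: int = 1,
                          verbose: bool = False) -> ExperimentResult:
    """Run the whole two-stage pipeline on synthetic cells and score it.

    Cells are split cell-exclusively into training and held-out evaluation
    sets (``train_frac``, default 40/20 of 60). Within the training set a
    further 80/20 cell split provides validation for both training stages;
    held-out cells are never touched before final scoring.
    """
    schedule = schedule or ScheduleParams()
    cell_spec = cell_spec or SyntheticCellSpec()
    ss = np.random.SeedSequence(seed)
    (sim_seed, split_seed, inner_seed, crop_seed, mae_seed, det_seed,
     base_seed, neg_seed, plan_seed) = (int(s) % (2 ** 31) for s in ss.generate_state(9))

    cells = simulate_cells(n_cells, schedule, cell_spec, seed=sim_seed)
    split = split_by_cell(cells, train_frac=train_frac, seed=split_seed)
    movies = {c: m for c, (m, _) in cells.items()}
    truths = {c: t for c, (_, t) in cells.items()}

    stats = compute_norm_stats(movies, split.train_cells)
    norm = {c: stats.apply(m) for c, m in movies.items()}

    # --- stage 1: masked auto-encoder on unlabeled training-cell crops ----
    inner = split_by_cell(split.train_cells, train_frac=0.8, seed=inner_seed)
    crop_rng = np.random.default_rng(crop_seed)
    mae_train = np.concatenate([norm[c] for c in sorted(inner.train_cells)])
    mae_val = np.concatenate([norm[c] for c in sorted(inner.val_cells)])
    if len(mae_train) > n_pretrain_crops:
        mae_train = mae_train[crop_rng.choice(len(mae_train), n_pretrain_crops, replace=False)]
    if len(mae_val) > n_pretrain_crops // 4:
        mae_val = mae_val[crop_rng.choice(len(mae_val), n_pretrain_crops // 4, replace=False)]
    mae_cfg = mae_cfg or MAEConfig(epochs=12, seed=mae_seed)
    model, ema_state, mae_log = pretrain(mae_train, mae_val, mae_cfg, verbose=verbose)

    # held-out reconstruction quality vs the per-image-mean reference
    ho_crops = np.concatenate([norm[c] for c in sorted(split.val_cells)])
    if len(ho_crops) > 500:
        ho_crops = ho_crops[crop_rng.choice(len(ho_crops), 500, replace=False)]
    plans = _fixed_plans(len(ho_crops), mae_cfg, plan_seed)
    mae_val_mse = masked_mse(model, ho_crops, plans)
    mae_base_mse = mean_baseline_mse(ho_crops, mae_cfg, plans)

    # --- stage 2: temporal detector on annotated training cells -----------
    det_cfg = det_cfg or DetectorConfig(encoder_mode="frozen",
                                        frame_embedding="meanpool", seed=det_seed)
    train_data = {c: (norm[c], _labels_for(truths[c], len(norm[c]), positive_span))
                  for c in sorted(inner.train_cells)}
    val_data = {c: (norm[c], truths[c]) for c in sorted(inner.val_cells)}
    detector, det_log = train_detector(train_data, val_data, model.encoder.state_dict(),
                                       mae_cfg, det_cfg, verbose=verbose)

    # --- held-out evaluation ----------------------------------------------
    ho_movies = {c: norm[c] for c in sorted(split.val_cells)}
    report, rls_records = _pooled_scores(detector, ho_movies, truths,
                                         det_cfg.threshold, max_gap, tolerance)
    scores = detection_scores(report, tolerance=tolerance)
    agreement = lifespan_agreement([(g, p) for _, g, p in rls_records])

    # untrained-detector control on the same held-out cells
    base_probs = untrained_baseline(mae_cfg, det_cfg, ho_movies, seed=base_seed)
    base_reports = []
    for c, probs in base_probs.items():
        pred = collapse_runs(binarize(probs, det_cfg.threshold))
        base_reports.append(match_events(truths[c], pred, max_gap=max_gap))
    baseline_scores = detection_scores(pool_reports(base_reports), tolerance=tolerance)

    # event-free negative controls
    neg = simulate_cells(n_negative_controls, schedule, cell_spec, seed=neg_seed,
                         event_free=True)
    n_zero = 0
    for c, (movie, _) in neg.items():
        probs = predict_timeline(detector, stats.apply(movie), cell_id=c)
        pred = collapse_runs(binarize(probs, det_cfg.threshold))
        n_zero += int(pred.rls == 0)

    per_cell = pd.DataFrame(rls_records, columns=["cell_id", "gt_rls", "pred_rls"])
    return ExperimentResult(
        scores=scores, agreement=agreement, baseline_scores=baseline_scores,
        negative_control_zero=n_zero, negative_control_total=n_negative_controls,
        mae_val_mse=mae_val_mse, mae_baseline_mse=mae_base_mse,
        per_cell=per_cell, detector=detector, norm_stats=stats,
        mae_log=mae_log, detector_log=det_log,
    )


def run_pipeline(config: RunConfig, out_dir, verbose: bool = False) -> dict:
    """Disk-backed pipeline run; returns the evaluation summary dict.

    Writes ``fixtures/`` (synthetic dataset), ``encoder.npz`` and
    ``detector.npz`` checkpoints, ``predictions.csv``
    (``cell_id,frame,prob_budding``), ``events.csv``
    (``cell_id,source,frame``) and ``report.json``; every artifact directory
    carries ``config.yaml`` and its hash. Fails loudly with the stage name.
    """
    os.makedirs(out_dir, exist_ok=True)
    chash = config_hash(config)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        fh.write(f"# config_hash: {chash}\n" + config.to_yaml())
    log_path = os.path.join(out_dir, "run_log.jsonl")

    def _log(stage, **kw):
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, "time": time.time(),
                                 "seed": config.seed, "config_hash": chash, **kw}) + "\n")

    stage = "simulate"
    try:
        result = end_to_end_experiment(
            seed=config.seed, n_cells=config.n_cells, train_frac=config.train_frac,
            mae_cfg=config.mae, det_cfg=config.detector,
            positive_span=config.positive_span, max_gap=config.max_gap,
            tolerance=config.tolerance, verbose=verbose)
        stage = "write_artifacts"
        save_checkpoint(os.path.join(out_dir, "detector.npz"),
                        result.detector.state_dict(), mae_config=config.mae,
                        detector_config=config.detector, norm_stats=result.norm_stats,
                        extra={"config_hash": chash, "seed": config.seed})
        result.per_cell.to_csv(os.path.join(out_dir, "per_cell_rls.csv"), index=False)
        summary = {
            "config_hash": chash,
            "seed": config.seed,
            "f1": result.scores.f1,
            "precision": result.scores.precision,
            "recall": result.scores.recall,
            "rls_r_squared": result.agreement.r_squared,
            "rls_error_sd": result.agreement.error_sd,
            "baseline_f1": result.baseline_scores.f1_or_zero(),
            "negative_control_zero": result.negative_control_zero,
            "negative_control_total": result.negative_control_total,
            "mae_val_mse": result.mae_val_mse,
            "mae_baseline_mse": result.mae_baseline_mse,
        }
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        _log("done", **{k: v for k, v in summary.items() if k != "config_hash"})
        return summary
    except Exception as exc:
        _log("failed", failed_stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
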