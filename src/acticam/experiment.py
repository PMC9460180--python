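"""End-to-end orchestration: simulate -> prepare -> train -> CAM.

``run_experiment`` executes all four phases for every configured
(task, architecture) pair, writing metrics, confusion matrices, epoch logs,
checkpoints, learning-curve plots, CAM exemplars and a manifest that records
the config hash and all derived seeds.  Rerunning with an identical config
reproduces every metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cam import select_exemplars, render_cam_plot
from .cohort import generate_cohort, verify_ground_truth, write_drive_manifest
from .config import ExperimentConfig, derive_seed
from .prep import build_drive_records
from .training import CVSummary, TaskDataset, cross_validate, plot_learning_curves, predict_logits

logger = logging.getLogger(__name__)


def _summary_row(summary: CVSummary) -> dict:
    return {
        "task": summary.task,
        "architecture": summary.architecture,
        "mean_accuracy": summary.mean_accuracy,
        "sd_accuracy": summary.sd_accuracy,
        "mean_f_score": summary.mean_f_score,
        "sd_f_score": summary.sd_f_score,
    }


def run_experiment(config: ExperimentConfig, write_signal_csvs: bool = False) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- phase 1: simulate the cohort -------------------------------------
    cohort_cfg = config.cohort.to_cohort_config(seed=config.stage_seed("cohort"))
    base_params = config.movement.to_params()
    profiles, metadata = generate_cohort(cohort_cfg)
    metadata.to_csv(out / "metadata.csv", index=False)
    write_drive_manifest(profiles, cohort_cfg, out / "manifest.csv")
    ground_truth = {k: asdict(v) for k, v in verify_ground_truth(metadata).items()}
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))
    logger.info("simulated %d participants", len(profiles))

    drives = build_drive_records(cohort_cfg, profiles, base_params)
    if write_signal_csvs:
        from .signals import write_activpal_csv

        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for d in drives:
            write_activpal_csv(d.signal, sig_dir / f"{d.drive_id}.csv")

    # -- phases 2-4 per (task, architecture) ------------------------------
    summary_rows = []
    artifacts: dict[str, str] = {"metadata": "metadata.csv", "manifest": "manifest.csv"}
    for task in config.tasks:
        spec = config.dataset.to_spec(task, seed=derive_seed(config.seed, f"dataset:{task}"))
        dataset = TaskDataset(drives, spec)
        logger.info("task %s: %d drives, %d windows, %d folds", task, len(dataset.drives), len(dataset.windows), spec.k)
        for arch in config.architectures:
            tag = f"{task}__{arch}"
            run_dir = out / tag
            run_dir.mkdir(exist_ok=True)
            train_cfg = config.training.to_config(seed=derive_seed(config.seed, f"train:{tag}"))
            model_cfg = config.model_config_for(arch, seed=derive_seed(config.seed, f"model:{tag}"))
            summary, models = cross_validate(model_cfg, dataset, train_cfg, return_models=True)
            summary_rows.append(_summary_row(summary))

            metrics = _summary_row(summary)
            metrics["folds"] = [
                {
                    "fold": r.fold,
                    "accuracy": r.accuracy,
                    "f_score": r.f_score,
                    "confusion": asdict(r.confusion),
                }
                for r in summary.folds
            ]
            (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
            pd.DataFrame(
                [{"fold": r.fold, **asdict(r.confusion)} for r in summary.folds]
            ).to_csv(run_dir / "confusion.csv", index=False)
            pd.DataFrame(
                [{"fold": r.fold, **asdict(log)} for r in summary.folds for log in r.epoch_logs]
            ).to_csv(run_dir / "epochs.csv", index=False)
            plot_learning_curves(summary.folds, run_dir / "learning_curves.png")
            for r, model in zip(summary.folds, models):
                model.save(run_dir / f"fold{r.fold}_checkpoint.npz")

            # CAM on the first fold's validation windows
            fold0 = dataset.fold_data(0)
            model0 = models[0]
            x_val, _, _ = fold0.val_arrays()
            logits = predict_logits(model0, x_val)
            exemplars = select_exemplars(model0, fold0.val_windows, logits, n=config.cam.n_exemplars)
            cam_rows = []
            for role, per_class in (("highest", exemplars.highest), ("lowest", exemplars.lowest)):
                for cls, cams in per_class.items():
                    for rank, cam in enumerate(cams):
                        name = f"cam_{role}_class{cls}_{rank}.png"
                        render_cam_plot(cam.window, cam, run_dir / name, sample_rate=cohort_cfg.sample_rate)
                        cam_rows.append(
                            {
                                "role": role,
                                "class": cls,
                                "rank": rank,
                                "drive_id": cam.window.drive_id,
                                "start_index": cam.window.start_index,
                                "logit": cam.logit,
                                "plot": name,
                                "cam_values": ";".join(f"{v:.5g}" for v in cam.M),
                            }
                        )
            pd.DataFrame(cam_rows).to_csv(run_dir / "cam_exemplars.csv", index=False)
            artifacts[tag] = str(run_dir.relative_to(out))

    summary_frame = pd.DataFrame(summary_rows)
    summary_frame.to_csv(out / "summary.csv", index=False)

    report = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_seeds": {
            "cohort": config.stage_seed("cohort"),
            **{f"dataset:{t}": derive_seed(config.seed, f"dataset:{t}") for t in config.tasks},
        },
        "n_participants": len(profiles),
        "ground_truth": ground_truth,
        "summary": summary_rows,
        "artifacts": artifacts,
    }
    (out / "experiment.json").write_text(json.dumps(report, indent=2))
    return report
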