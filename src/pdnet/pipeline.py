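"""End-to-end orchestration: cohort -> features -> images -> classifier.

One call wires every stage together with a single config and seed and
writes a JSON summary carrying the config hash, per-stage counts, and
(if training is enabled) the validation metrics per combined task — so a
run is fully reproducible from the summary alone.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from .config import RunConfig
from .net import (
    DatasetManifest,
    build_parkinsonnet,
    classify,
    evaluate_f1,
    split_by_subject,
    train,
)
from .synth import generate_cohort_images

__all__ = ["run_end_to_end", "train_task"]


def _stack_images(images: dict, paths) -> np.ndarray:
    return np.stack(
        [images[p].astype(np.float32).transpose(2, 0, 1) / 255.0 for p in paths]
    )


def train_task(
    result: dict,
    manifestation: str,
    cfg: RunConfig,
    seed: int = 0,
):
    """Split, train and evaluate one classification task on an in-memory cohort.

    Returns ``(report, manifest)`` with the validation precision/recall/F1
    filled in; splits are subject-level with an automatic per-class holdout.
    """
    df = result["manifest"]
    task = DatasetManifest(df[df["manifestation"] == manifestation].copy())
    task = split_by_subject(task, seed=seed)
    task.check_subject_disjoint()
    arrays = {}
    for split in ("train", "test", "validation"):
        sub = task.subset(split)
        arrays[split] = (
            _stack_images(result["images"], sub["path"]),
            sub["label"].to_numpy(),
        )
    task_hw = result["images"][task.frame["path"].iloc[0]].shape[0]
    model_cfg = dataclasses.replace(cfg.model, seed=seed, input_hw=task_hw)
    hyper = dataclasses.replace(cfg.training, seed=seed)
    model = build_parkinsonnet(model_cfg)
    report = train(model, *arrays["train"], *arrays["test"], hyper, model_cfg)
    prob = classify(model, arrays["validation"][0])
    p, r, f1, flags = evaluate_f1(prob, arrays["validation"][1])
    report.precision, report.recall, report.f1, report.flags = p, r, f1, flags
    return report, task


def run_end_to_end(
    out_dir,
    cfg: RunConfig | None = None,
    seed: int = 0,
    train_net: bool = True,
) -> dict:
    """Synthesize a cohort, run both pipelines, optionally train the CNN.

    Writes the manifest and a ``summary.json`` under ``out_dir`` and
    returns the summary dict.
    """
    cfg = cfg or RunConfig()
    spec = dataclasses.replace(cfg.cohort, seed=seed)
    result = generate_cohort_images(spec)
    os.makedirs(out_dir, exist_ok=True)
    summary = {
        "config_hash": cfg.hash,
        "seed": seed,
        "n_subjects": len(result["subjects"]),
        "n_images": len(result["images"]),
        "tasks": {},
    }
    if train_net:
        for task_name in ("speech_combined", "writing_combined"):
            report, manifest = train_task(result, task_name, cfg, seed=seed)
            manifest.to_csv(os.path.join(out_dir, f"manifest_{task_name}.csv"))
            summary["tasks"][task_name] = {
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
                "epochs_run": len(report.epochs),
            }
    result["manifest"].to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
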