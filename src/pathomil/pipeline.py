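"""End-to-end pipeline driver: simulate/load → train → evaluate → report.

A YAML config describes the cohort source (a ``simulate`` block or a
``manifest`` path), per-task training overrides and evaluation options. Every
artifact is stamped with the config hash and seed; a plain-text log records
per-stage timings and counts.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .cohort import Cohort
from .metrics import (
    assign_risk_groups,
    harrell_c,
    km_estimate,
    roc_auc,
    tertile_stratify,
    threshold_metrics,
)
from .simulate import SimConfig, simulate_cohort
from .training import TrainConfig, evaluate_patients, train_model

__all__ = ["run_pipeline"]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _load_cohort(config: dict, seed: int) -> Cohort:
    if "simulate" in config:
        sim = SimConfig(seed=seed, **config["simulate"])
        cohort, _ = simulate_cohort(sim)
        return cohort
    if "manifest" in config:
        from .manifest import manifest_to_cohort, read_manifest

        return manifest_to_cohort(read_manifest(config["manifest"]))
    raise ValueError("config must provide a 'simulate' block or a 'manifest' path")


def _survival_arrays(preds):
    scores = np.array([p.aggregate for p, _ in preds])
    times = np.array([r.survival.time for _, r in preds])
    events = np.array([r.survival.event for _, r in preds])
    return scores, times, events


def run_pipeline(config_path) -> dict:
    with open(config_path) as f:
        config = yaml.safe_load(f)
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "pathomil_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    log_lines: list[str] = [f"config_hash={chash} seed={seed}"]

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            dt = time.perf_counter() - t0
            kv = " ".join(f"{k}={v}" for k, v in counts.items())
            log_lines.append(f"stage={name} seconds={dt:.2f} {kv}")

        return done

    done = stage("cohort")
    try:
        cohort = _load_cohort(config, seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc
    done(slides=len(cohort), patients=len(cohort.patient_ids))

    agg = config.get("evaluate", {}).get("aggregation", "mean")
    threshold = config.get("evaluate", {}).get("threshold", 0.5)
    n_boot = config.get("evaluate", {}).get("n_boot", 200)
    metrics: dict = {"config_hash": chash, "seed": seed}

    for task in ("classification", "survival"):
        block = config.get(task, {})
        if block.get("skip"):
            continue
        done = stage(f"train-{task}")
        base = (TrainConfig.classification() if task == "classification"
                else TrainConfig.survival())
        for k, v in block.items():
            if k != "skip":
                setattr(base, k, v)
        base.aggregation = agg
        try:
            result = train_model(cohort, base, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'train-{task}' failed: {exc}") from exc
        done(epochs=len(result.history), best_epoch=result.best_epoch)
        result.model.save(out_dir / f"model_{task}.npz", schema=cohort.schema)
        import csv as _csv

        with open(out_dir / f"history_{task}.csv", "w", newline="") as fh:
            writer = _csv.DictWriter(
                fh, fieldnames=["epoch", "train_loss", "val_metric"]
            )
            writer.writeheader()
            writer.writerows(result.history)

        done = stage(f"evaluate-{task}")
        task_metrics: dict = {}
        train_preds = evaluate_patients(result.model, cohort.split("train"), agg)
        for split in ("train", "val", "test"):
            preds = evaluate_patients(result.model, cohort.split(split), agg)
            scores = np.array([p.aggregate for p, _ in preds])
            if task == "classification":
                labels = np.array([r.label for _, r in preds])
                try:
                    summary = roc_auc(scores, labels, n_boot=n_boot, seed=seed)
                    auc, ci = summary.point, [summary.ci_low, summary.ci_high]
                except ValueError:  # degenerate split (single class)
                    auc, ci = None, [None, None]
                task_metrics[split] = {
                    "auc": auc,
                    "auc_ci": ci,
                    **threshold_metrics(scores, labels, threshold),
                    "n_patients": len(preds),
                }
            else:
                from .losses import SurvivalLabel

                scores, times, events = _survival_arrays(preds)
                labels = [SurvivalLabel(t, int(e)) for t, e in zip(times, events)]
                try:
                    summary = harrell_c(scores, labels, n_boot=n_boot, seed=seed)
                    cidx, ci = summary.point, [summary.ci_low, summary.ci_high]
                except (ValueError, ZeroDivisionError):
                    cidx, ci = None, [None, None]
                task_metrics[split] = {
                    "c_index": cidx,
                    "c_index_ci": ci,
                    "n_patients": len(preds),
                }
        if task == "survival":
            tr_scores, _, _ = _survival_arrays(train_preds)
            thresholds = tertile_stratify(tr_scores)
            task_metrics["risk_thresholds"] = [thresholds.q1, thresholds.q2]
            from .losses import SurvivalLabel

            groups_block = {}
            for split in ("train", "val", "test"):
                preds = evaluate_patients(result.model, cohort.split(split), agg)
                scores, times, events = _survival_arrays(preds)
                groups = assign_risk_groups(scores, thresholds)
                by_group = {}
                for g in ("low", "intermediate", "high"):
                    sel = [i for i, gg in enumerate(groups) if gg == g]
                    if not sel:
                        by_group[g] = None
                        continue
                    labs = [SurvivalLabel(times[i], int(events[i])) for i in sel]
                    curve, _ = km_estimate(labs)
                    by_group[g] = {
                        "n": len(sel),
                        "median_pfs": curve.median if curve.median_reached else "NR",
                    }
                groups_block[split] = by_group
            task_metrics["risk_groups"] = groups_block
        metrics[task] = task_metrics
        done()

    with open(out_dir / "metrics.json", "w") as f:
        json.dump(metrics, f, indent=2, default=float)
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return metrics
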