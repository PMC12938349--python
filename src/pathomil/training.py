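"""Training procedures for the classification and survival tasks.

Both tasks train at slide level (each slide is one optimization example,
inheriting its patient's label) and evaluate at patient level by aggregating
slide scores with the mean or median. Classification optimizes
L_bag + λ·L_inst per slide with Adam (lr 5e-5, weight decay 1e-4, dropout
0.5); survival optimizes the within-batch Cox partial-likelihood loss with
Adam (lr 2e-4, weight decay 1e-5, dropout 0.25) and a step learning-rate
scheduler. Training runs at most 50 epochs with early stopping (patience 5)
on the validation metric: patient-level AUC for classification, patient-level
Harrell C-index for survival.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor, stack
from .cohort import Cohort, SlideRecord
from .losses import (
    cox_loss_tensor,
    cross_entropy_logits,
    instance_pseudo_labels,
)
from .model import GatedAttentionMIL, ModelConfig

__all__ = [
    "TrainConfig",
    "EarlyStopState",
    "PatientPrediction",
    "Adam",
    "aggregate_patient",
    "train_model",
    "TrainResult",
    "evaluate_patients",
    "run_trials",
]


@dataclass
class TrainConfig:
    task: str = "classification"
    learning_rate: float = 5e-5
    weight_decay: float = 1e-4
    max_epochs: int = 50
    patience: int = 5
    min_epochs: int = 10  # early-stop monitoring starts here
    lambda_inst: float = 0.9
    k_instances: int = 8
    dropout: float = 0.5
    scheduler_step: int | None = None  # survival: step LR scheduler
    scheduler_gamma: float = 0.5
    batch_scheme: str = "per_slide"  # or "full_cohort_risk_set" / "minibatch"
    batch_size: int = 32
    aggregation: str = "mean"
    split_fractions: tuple[float, float, float] = (0.65, 0.20, 0.15)
    seeds: tuple[int, ...] = tuple(range(10))

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    @classmethod
    def classification(cls, **kw) -> "TrainConfig":
        defaults = dict(learning_rate=5e-5, weight_decay=1e-4, dropout=0.5,
                        batch_scheme="per_slide")
        return cls(task="classification", **{**defaults, **kw})

    @classmethod
    def survival(cls, **kw) -> "TrainConfig":
        defaults = dict(learning_rate=2e-4, weight_decay=1e-5, dropout=0.25,
                        scheduler_step=10, scheduler_gamma=0.5,
                        batch_scheme="minibatch")
        return cls(task="survival", **{**defaults, **kw})


@dataclass
class EarlyStopState:
    best_metric: float = -np.inf
    best_epoch: int = 0
    epochs_since_improvement: int = 0

    def update(self, metric: float, epoch: int, min_epochs: int) -> None:
        if metric > self.best_metric:
            self.best_metric = metric
            self.best_epoch = epoch
            self.epochs_since_improvement = 0
        elif epoch > min_epochs:
            self.epochs_since_improvement += 1

    def should_stop(self, patience: int) -> bool:
        return self.epochs_since_improvement >= patience


@dataclass
class PatientPrediction:
    patient_id: str
    slide_scores: list[float]
    aggregate: float
    method: str


def aggregate_patient(
    slide_scores, method: str = "mean", patient_id: str = ""
) -> PatientPrediction:
    """Aggregate per-slide scores to one patient-level score (mean or median)."""
    scores = [float(s) for s in slide_scores]
    if not scores:
        raise ValueError("cannot aggregate an empty score list")
    if method == "mean":
        agg = float(np.mean(scores))
    elif method == "median":
        agg = float(np.median(scores))
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return PatientPrediction(
        patient_id=patient_id, slide_scores=scores, aggregate=agg, method=method
    )


class Adam:
    """Adam with L2 weight decay added to the gradient (torch-style).

    Parameters that received no gradient in a step (e.g. the inactive surgery
    route's attention network) are left untouched, including weight decay, so
    updates are confined to the parameters that participated in the forward
    pass.
    """

    def __init__(self, params: dict[str, Tensor], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = {k: 0 for k in params}

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.t[k] += 1
            t = self.t[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**t)
            v_hat = self.v[k] / (1 - self.b2**t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _slide_score(model: GatedAttentionMIL, record: SlideRecord) -> float:
    return model.predict(record.bag, record.clinical).score


def evaluate_patients(
    model: GatedAttentionMIL,
    slides: list[SlideRecord],
    aggregation: str = "mean",
) -> list[tuple[PatientPrediction, SlideRecord]]:
    """Patient-level predictions: (aggregate score, a representative record)."""
    groups: dict[str, list[SlideRecord]] = {}
    for s in slides:
        groups.setdefault(s.patient_id, []).append(s)
    out = []
    for pid, group in groups.items():
        pred = aggregate_patient(
            [_slide_score(model, s) for s in group], aggregation, patient_id=pid
        )
        out.append((pred, group[0]))
    return out


def _validation_metric(
    model: GatedAttentionMIL, slides: list[SlideRecord], config: TrainConfig
) -> float:
    preds = evaluate_patients(model, slides, config.aggregation)
    scores = np.array([p.aggregate for p, _ in preds])
    if config.task == "classification":
        labels = np.array([r.label for _, r in preds])
        if len(set(labels.tolist())) < 2:
            return 0.5
        return float(roc_auc_score(labels, scores))
    times = np.array([r.survival.time for _, r in preds])
    events = np.array([r.survival.event for _, r in preds])
    if events.sum() == 0:
        return 0.5
    return float(concordance_index(times, -scores, events))


@dataclass
class TrainResult:
    model: GatedAttentionMIL
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_metric: float = np.nan
    config: TrainConfig | None = None


def _instance_loss_tensor(out: dict, label: int, k: int) -> Tensor:
    idx, plabels = instance_pseudo_labels(out["alpha"].data, label, k)
    sel = out["inst_logits"][idx]  # (2k, 2)
    lse = sel.logsumexp(axis=1)
    z_true = sel[(np.arange(len(idx)), plabels)]
    return (lse - z_true).mean()


def train_model(
    cohort: Cohort,
    config: TrainConfig,
    seed: int = 0,
    model_config: ModelConfig | None = None,
) -> TrainResult:
    """Fit the MIL network on the cohort's train split; early-stop on val."""
    train_slides = cohort.split("train")
    val_slides = cohort.split("val")
    if not train_slides or not val_slides:
        raise ValueError("cohort must carry non-empty train and val splits")
    if model_config is None:
        d = train_slides[0].bag.dim
        c = len(train_slides[0].clinical.values)
        model_config = ModelConfig(
            input_dim=d, clinical_dim=c, dropout=config.dropout,
            lambda_inst=config.lambda_inst, k_instances=config.k_instances,
            task=config.task,
        )
    model = GatedAttentionMIL(model_config, seed=seed)
    opt = Adam(model.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng((seed, 1))
    dropout_rng = np.random.default_rng((seed, 2))
    stopper = EarlyStopState()
    best_state = model.state_dict()
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_slides))
        epoch_losses: list[float] = []
        if config.task == "classification":
            for i in order:
                rec = train_slides[i]
                out = model.forward(rec.bag, rec.clinical, rng=dropout_rng)
                loss = cross_entropy_logits(out["logits"], rec.label)
                if config.lambda_inst > 0:
                    loss = loss + Tensor(config.lambda_inst) * \
                        _instance_loss_tensor(out, rec.label, config.k_instances)
                model.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
        else:
            if config.scheduler_step:
                opt.lr = config.learning_rate * config.scheduler_gamma ** (
                    (epoch - 1) // config.scheduler_step
                )
            batches = _survival_batches(order, config)
            for batch_idx in batches:
                records = [train_slides[i] for i in batch_idx]
                risks = stack([
                    model.forward(r.bag, r.clinical, rng=dropout_rng)["logits"][0]
                    for r in records
                ])
                times = np.array([r.survival.time for r in records])
                events = np.array([r.survival.event for r in records])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    loss = cox_loss_tensor(risks, times, events)
                model.zero_grad()
                if loss.requires_grad:
                    loss.backward()
                    opt.step()
                epoch_losses.append(float(loss.data))
        mean_loss = float(np.mean(epoch_losses))
        if not np.isfinite(mean_loss):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        val_metric = _validation_metric(model, val_slides, config)
        history.append(
            {"epoch": epoch, "train_loss": mean_loss, "val_metric": val_metric}
        )
        stopper.update(val_metric, epoch, config.min_epochs)
        if stopper.epochs_since_improvement == 0:
            best_state = model.state_dict()
        if epoch >= config.min_epochs and stopper.should_stop(config.patience):
            break
    model.load_state_dict(best_state)
    return TrainResult(
        model=model, history=history, best_epoch=stopper.best_epoch,
        best_metric=stopper.best_metric, config=copy.deepcopy(config),
    )


def _survival_batches(order: np.ndarray, config: TrainConfig) -> list[np.ndarray]:
    if config.batch_scheme == "full_cohort_risk_set":
        return [order]
    if config.batch_scheme == "minibatch":
        bs = config.batch_size
        return [order[i : i + bs] for i in range(0, len(order), bs)]
    raise ValueError(f"unknown batch_scheme {config.batch_scheme!r} for survival")


def run_trials(
    cohort_factory,
    config: TrainConfig,
    seeds: tuple[int, ...] | None = None,
    eval_split: str = "test",
) -> dict:
    """The multi-seed protocol: independent trials with different random seeds.

    ``cohort_factory(seed)`` must return a split cohort; each trial trains a
    fresh model and records the patient-level metric on ``eval_split``.
    Returns per-seed values and their mean with normal-approximation 95% CI.
    """
    from .metrics import trials_summary

    seeds = tuple(config.seeds if seeds is None else seeds)
    values = []
    for s in seeds:
        cohort = cohort_factory(s)
        result = train_model(cohort, config, seed=s)
        values.append(
            _validation_metric(result.model, cohort.split(eval_split), config)
        )
    summary = trials_summary(values)
    return {"seeds": list(seeds), "values": values, "summary": summary}
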