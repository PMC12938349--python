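"""Training losses: bag cross-entropy, instance clustering, combined, Cox.

The classification objective is L_total = L_bag + λ·L_inst with λ = 0.9 by
default. L_bag is the bag-level cross-entropy of the slide prediction against
the slide's (inherited patient) label. L_inst is the clustering loss of the
attention-MIL lineage: the k most-attended instances receive the bag label as
a pseudo-label, the k least-attended receive the complementary label, and the
loss is the mean cross-entropy of the shared instance classifier over those
2k instances.

The survival objective is the negative mean Cox partial log-likelihood over a
batch B,

    L = −(1/B) Σᵢ δᵢ [ r̂ᵢ − log Σ_{j : tⱼ ≥ tᵢ} exp(r̂ⱼ) ],

with risk sets formed within the batch and ties in time handled by the
inclusive comparison tⱼ ≥ tᵢ (Breslow-style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "SurvivalLabel",
    "bag_loss",
    "instance_pseudo_labels",
    "instance_loss",
    "total_classification_loss",
    "cox_loss",
    "cross_entropy_logits",
    "cox_loss_tensor",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class SurvivalLabel:
    """(time, event) pair: time in months > 0, event 1 = progression/death."""

    time: float
    event: int

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError("survival time must be finite and positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


def bag_loss(class_probs, label: int) -> float:
    """Negative log probability of the true class."""
    probs = np.asarray(class_probs, dtype=np.float64)
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    p = probs[label]
    if p < PROB_FLOOR:
        warnings.warn("true-class probability clamped at 1e-12", RuntimeWarning)
        p = PROB_FLOOR
    return float(-np.log(p))


def instance_pseudo_labels(
    alpha: np.ndarray, bag_label: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Select top/bottom-k instances by attention and assign pseudo-labels.

    Returns (selected indices, pseudo-labels). With N < 2k, k is reduced to
    max(floor(N/2), 1); a single-instance bag contributes only that instance
    with the bag label.
    """
    alpha = np.asarray(alpha, dtype=np.float64).ravel()
    n = alpha.shape[0]
    if n == 1:
        return np.array([0]), np.array([bag_label])
    k_eff = min(k, n // 2)
    k_eff = max(k_eff, 1)
    order = np.argsort(alpha, kind="stable")
    bottom = order[:k_eff]
    top = order[::-1][:k_eff]
    idx = np.concatenate([top, bottom])
    labels = np.concatenate(
        [np.full(k_eff, bag_label), np.full(k_eff, 1 - bag_label)]
    )
    return idx, labels


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def instance_loss(alpha, inst_scores, bag_label: int, k: int = 8) -> float:
    """Mean cross-entropy of instance scores against attention pseudo-labels."""
    inst_scores = np.asarray(inst_scores, dtype=np.float64)
    idx, labels = instance_pseudo_labels(alpha, bag_label, k)
    probs = _softmax_rows(inst_scores[idx])
    p_true = np.clip(probs[np.arange(len(idx)), labels], PROB_FLOOR, None)
    return float(-np.log(p_true).mean())


def total_classification_loss(
    bag_loss_value: float, instance_loss_value: float, lambda_inst: float = 0.9
) -> float:
    if lambda_inst < 0:
        raise ValueError("lambda must be >= 0")
    return float(bag_loss_value + lambda_inst * instance_loss_value)


def cox_loss(risks, labels: list[SurvivalLabel] | None = None, *, times=None,
             events=None) -> float:
    """Negative mean Cox partial log-likelihood over the batch.

    Accepts either a list of :class:`SurvivalLabel` or explicit
    ``times``/``events`` arrays. Returns 0 (with a warning) when the batch
    contains no events.
    """
    risks = np.asarray(risks, dtype=np.float64).ravel()
    if labels is not None:
        times = np.array([lab.time for lab in labels], dtype=np.float64)
        events = np.array([lab.event for lab in labels], dtype=np.int64)
    else:
        times = np.asarray(times, dtype=np.float64)
        events = np.asarray(events, dtype=np.int64)
    if risks.shape[0] != times.shape[0] or risks.shape[0] < 1:
        raise ValueError("risks and labels must be non-empty and aligned")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if events.sum() == 0:
        warnings.warn("no events in batch; Cox loss is 0", RuntimeWarning)
        return 0.0
    b = risks.shape[0]
    shift = risks.max()
    exp_r = np.exp(risks - shift)
    total = 0.0
    for i in np.flatnonzero(events == 1):
        risk_set = times >= times[i]
        total += (risks[i] - shift) - np.log(exp_r[risk_set].sum())
    return float(-total / b)


# -- graph (autodiff) versions used by the training loop -------------------------


def cross_entropy_logits(logits: Tensor, label: int) -> Tensor:
    """CE from raw logits: logsumexp(z) − z[label]."""
    return logits.logsumexp() - logits[label]


def cox_loss_tensor(risks: Tensor, times: np.ndarray, events: np.ndarray) -> Tensor:
    """Differentiable Cox loss; risk-set membership enters as a constant mask."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.float64)
    b = times.shape[0]
    if events.sum() == 0:
        return Tensor(0.0)
    shift = float(risks.data.max())
    shifted = risks - Tensor(shift)
    mask = (times[None, :] >= times[:, None]).astype(np.float64)  # (i, j)
    log_den = (Tensor(mask) * shifted.exp().reshape(1, -1) + Tensor(1e-300)) \
        .sum(axis=1).log()
    terms = (shifted - log_den) * Tensor(events)
    return -(terms.sum() / float(b))
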