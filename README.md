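# pathomil

Multimodal gated-attention multiple-instance learning (MIL) for predicting
platinum-chemotherapy response and recurrence risk in advanced ovarian
cancer from whole-slide images (WSIs) fused with clinical covariates.

## Who this is for

Computational-pathology researchers who want a desk-scale, fully
reproducible implementation of the weakly supervised WSI outcome-prediction
recipe: automated tissue segmentation and tiling, pluggable tile encoders
producing per-slide feature bags, an attention-MIL network with surgery-route
(PDS/IDS) specific attention and gated clinical fusion, slide-level training
with patient-level aggregation, tertile risk stratification, and the full
evaluation toolkit (AUC, Harrell C, time-dependent AUC, Kaplan–Meier,
baseline tests, bootstrap model comparison). Everything runs on synthetic
cohorts with known ground truth; real cohorts plug in through the same
manifest + HDF5-bag interface.

## The model

A slide is a bag of tile features h₁…h_N. Instances are projected,
hᵢ′ = ReLU(W hᵢ + b), and scored by gated attention

    aᵢ = wᵀ(tanh(V hᵢ′) ⊙ σ(U hᵢ′)),   αᵢ = softmaxᵢ(aᵢ),
    M_WSI = Σᵢ αᵢ hᵢ′,

with separate attention networks per surgery route. Clinical covariates C
enter through a learned gate,

    g = σ(f_gate([M_WSI ; C])),
    M_fused = g ⊙ (W_w M_WSI) + (1 − g) ⊙ (W_c C),

and M_fused feeds a dual-output softmax head (platinum-sensitive vs
-resistant) or a single-output risk head r̂.

Classification trains per slide with L_total = L_bag + 0.9·L_inst (bag
cross-entropy plus the instance clustering loss on the top/bottom-k
attended tiles; Adam, lr 5·10⁻⁵, weight decay 10⁻⁴, dropout 0.5).
Survival trains with the within-batch Cox partial-likelihood loss

    L = −(1/B) Σᵢ δᵢ [ r̂ᵢ − log Σ_{tⱼ ≥ tᵢ} exp(r̂ⱼ) ]

(Adam, lr 2·10⁻⁴, weight decay 10⁻⁵, dropout 0.25, step LR scheduler).
Both run ≤ 50 epochs with early stopping (patience 5) on the validation
patient-level AUC / C-index; patients are split 0.65/0.20/0.15. Risk groups
are tertiles of the training risk scores, frozen and applied to held-out
patients. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from pathomil import (SimConfig, simulate_cohort, TrainConfig, train_model,
                      evaluate_patients, roc_auc)
from pathomil.experiments import desk_model_config

cohort, truth = simulate_cohort(SimConfig(n_patients=300, dim=64, seed=0))
result = train_model(
    cohort, TrainConfig.classification(), seed=0,
    model_config=desk_model_config(64, len(cohort.schema),
                                   "classification", 0.5),
)
preds = evaluate_patients(result.model, cohort.split("test"), "mean")
scores = np.array([p.aggregate for p, _ in preds])
labels = np.array([r.label for _, r in preds])
print(f"best epoch {result.best_epoch}, "
      f"val AUC {result.best_metric:.3f}, "
      f"test AUC {roc_auc(scores, labels, ci=False).point:.3f}")
```

Output:

```
best epoch 12, val AUC 1.000, test AUC 1.000
```

The cohort plants a mean shift of μ = 2.0 along a hidden direction in 20%
of the tiles of signal-carrying patients; the numbers show the trained
attention-MIL model recovering that signal on held-out patients (45 test
patients here). On a matched null cohort (no planted signal) the same
pipeline stays at chance (AUC ≈ 0.5).

The same cohort drives the survival task (`TrainConfig.survival()`), and
the command-line interface exposes each stage —
`pathomil simulate | segment | tile | encode | train-cls | train-surv |
evaluate | stratify | baseline-table | heatmap | run`.

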