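"""Dual-route gated-attention MIL with gated clinical fusion.

The network follows the clustering-constrained attention MIL lineage. Each
instance feature hᵢ is projected to an embedding hᵢ′ = ReLU(W·hᵢ + b); a
surgery-route-specific gated attention network scores instances,

    aᵢ = wᵀ( tanh(V·hᵢ′) ⊙ sigmoid(U·hᵢ′) ),    αᵢ = softmaxᵢ(aᵢ),

and the slide embedding is the attention-weighted sum M_WSI = Σᵢ αᵢ hᵢ′
(computed in the projected space). Two attention networks exist, one per
pre-treatment protocol (PDS / IDS); the projection, instance classifier,
fusion and output heads are shared between routes.

Clinical covariates C are fused through a learned sigmoid gate

    g = σ(f_gate([M_WSI ; C])),    M_fused = g ⊙ (W_w·M_WSI) + (1−g) ⊙ (W_c·C),

a convex element-wise combination that dynamically balances the imaging and
clinical contributions. The classification head is dual-output (softmax over
two classes); the survival head is a single linear output producing the
continuous risk score r̂.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, parameter
from .encoding import FeatureBag

__all__ = [
    "ClinicalVector",
    "ModelConfig",
    "AttentionWeights",
    "SlideEmbedding",
    "FusedEmbedding",
    "SlidePrediction",
    "GatedAttentionMIL",
]

ROUTES = ("PDS", "IDS")


@dataclass
class ClinicalVector:
    """Fixed-order encoded covariates plus the surgery-type routing flag.

    ``values`` holds z-scored continuous covariates and one-hot categorical
    blocks in the order given by ``schema`` (a list of column names). The
    surgery type is kept outside the vector; it selects the attention route.
    """

    values: np.ndarray
    surgery_type: str
    schema: tuple[str, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.surgery_type not in ROUTES:
            raise ValueError(f"surgery_type must be one of {ROUTES}")
        if self.schema and len(self.schema) != len(self.values):
            raise ValueError("schema length does not match value vector")
        if not np.isfinite(self.values).all():
            raise ValueError("clinical vector contains missing/non-finite values")


@dataclass
class ModelConfig:
    input_dim: int = 64
    clinical_dim: int = 6
    attention_hidden: int = 256
    fusion_dim: int = 256
    n_classes: int = 2
    dropout: float = 0.5  # classification default; survival uses 0.25
    lambda_inst: float = 0.9
    k_instances: int = 8
    task: str = "classification"  # or "survival"

    def __post_init__(self):
        if min(self.input_dim, self.clinical_dim, self.attention_hidden,
               self.fusion_dim) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.lambda_inst < 0:
            raise ValueError("lambda_inst must be >= 0")
        if self.task not in ("classification", "survival"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_outputs(self) -> int:
        return self.n_classes if self.task == "classification" else 1


@dataclass
class AttentionWeights:
    alpha: np.ndarray
    path_used: str

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64).ravel()
        if (self.alpha < 0).any() or abs(self.alpha.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must be a probability vector")


@dataclass
class SlideEmbedding:
    m_wsi: np.ndarray


@dataclass
class FusedEmbedding:
    m_fused: np.ndarray
    gate: np.ndarray


@dataclass
class SlidePrediction:
    task: str
    attention: AttentionWeights
    class_probs: np.ndarray | None = None
    risk: float | None = None

    @property
    def score(self) -> float:
        """Scalar slide score: P(class 1) for classification, r̂ for survival."""
        if self.task == "classification":
            return float(self.class_probs[1])
        return float(self.risk)


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Seeded uniform fan-in initialization, U(−1/√fan_in, 1/√fan_in)."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class GatedAttentionMIL:
    """The full multimodal MIL network; parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D, L, F, c = (
            config.input_dim,
            config.attention_hidden,
            config.fusion_dim,
            config.clinical_dim,
        )
        p: dict[str, Tensor] = {}
        p["W_proj"] = parameter(_uniform_init(rng, (D, L)))
        p["b_proj"] = parameter(np.zeros(L))
        for r in ROUTES:
            p[f"V_{r}"] = parameter(_uniform_init(rng, (L, L)))
            p[f"bV_{r}"] = parameter(np.zeros(L))
            p[f"U_{r}"] = parameter(_uniform_init(rng, (L, L)))
            p[f"bU_{r}"] = parameter(np.zeros(L))
            p[f"w_{r}"] = parameter(_uniform_init(rng, (L,)))
        p["W_wsi"] = parameter(_uniform_init(rng, (L, F)))
        p["W_clin"] = parameter(_uniform_init(rng, (c, F)))
        p["W_gate"] = parameter(_uniform_init(rng, (L + c, F)))
        p["b_gate"] = parameter(np.zeros(F))
        p["W_head"] = parameter(_uniform_init(rng, (F, config.n_outputs)))
        p["b_head"] = parameter(np.zeros(config.n_outputs))
        p["W_inst"] = parameter(_uniform_init(rng, (L, 2)))
        p["b_inst"] = parameter(np.zeros(2))
        self.params = p

    # -- parameter bookkeeping -------------------------------------------------
    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)

    # -- dropout ---------------------------------------------------------------
    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        rate = self.config.dropout
        if rng is None or rate <= 0.0:
            return x
        mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(mask)

    # -- forward pieces ----------------------------------------------------------
    def _project(self, bag: FeatureBag) -> Tensor:
        if bag.n_instances == 0:
            raise ValueError("empty bag")
        if bag.dim != self.config.input_dim:
            raise ValueError(
                f"bag dim {bag.dim} does not match model input_dim "
                f"{self.config.input_dim}"
            )
        h = Tensor(bag.features.astype(np.float64))
        return (h @ self.params["W_proj"] + self.params["b_proj"]).relu()

    def _attention(
        self, h_proj: Tensor, route: str, rng: np.random.Generator | None
    ) -> tuple[Tensor, Tensor]:
        if route not in ROUTES:
            raise ValueError(f"surgery route must be one of {ROUTES}")
        p = self.params
        hd = self._dropout(h_proj, rng)
        gate_tanh = (hd @ p[f"V_{route}"] + p[f"bV_{route}"]).tanh()
        gate_sig = (hd @ p[f"U_{route}"] + p[f"bU_{route}"]).sigmoid()
        scores = (gate_tanh * gate_sig) @ p[f"w_{route}"]  # (N,)
        alpha = scores.softmax(axis=0)
        m_wsi = alpha @ h_proj  # weighted sum in projected space
        return alpha, m_wsi

    def attention_pool(
        self,
        bag: FeatureBag,
        surgery_type: str,
        rng: np.random.Generator | None = None,
    ) -> tuple[AttentionWeights, SlideEmbedding]:
        alpha, m_wsi = self._attention(self._project(bag), surgery_type, rng)
        return (
            AttentionWeights(alpha=alpha.data, path_used=surgery_type),
            SlideEmbedding(m_wsi=m_wsi.data),
        )

    def _fuse(
        self,
        m_wsi: Tensor,
        clinical: np.ndarray,
        rng: np.random.Generator | None,
        force_gate: float | None = None,
    ) -> tuple[Tensor, Tensor]:
        p = self.params
        c = np.asarray(clinical, dtype=np.float64).ravel()
        if c.shape[0] != self.config.clinical_dim:
            raise ValueError(
                f"clinical vector length {c.shape[0]} does not match "
                f"clinical_dim {self.config.clinical_dim}"
            )
        ct = Tensor(c)
        joint = concat([m_wsi, ct])
        gate = (joint @ p["W_gate"] + p["b_gate"]).sigmoid()
        if force_gate is not None:  # diagnostic endpoints g ≡ 0 or 1
            gate = Tensor(np.full(gate.shape, float(force_gate)))
        fused = gate * (m_wsi @ p["W_wsi"]) + (1.0 - gate) * (ct @ p["W_clin"])
        return self._dropout(fused, rng), gate

    def gate_fuse(
        self,
        m_wsi: SlideEmbedding | np.ndarray,
        clinical: ClinicalVector | np.ndarray,
        force_gate: float | None = None,
    ) -> FusedEmbedding:
        m = m_wsi.m_wsi if isinstance(m_wsi, SlideEmbedding) else np.asarray(m_wsi)
        cv = clinical.values if isinstance(clinical, ClinicalVector) else clinical
        fused, gate = self._fuse(Tensor(m), cv, rng=None, force_gate=force_gate)
        return FusedEmbedding(m_fused=fused.data, gate=gate.data)

    def _head(self, fused: Tensor) -> Tensor:
        return fused @ self.params["W_head"] + self.params["b_head"]

    def predict_slide(
        self, fused: FusedEmbedding | np.ndarray, attention: AttentionWeights | None = None
    ) -> SlidePrediction:
        f = fused.m_fused if isinstance(fused, FusedEmbedding) else np.asarray(fused)
        logits = self._head(Tensor(f)).data
        if attention is None:
            attention = AttentionWeights(alpha=np.ones(1), path_used="PDS")
        if self.config.task == "classification":
            probs = Tensor(logits).softmax().data
            return SlidePrediction(
                task="classification", class_probs=probs, attention=attention
            )
        return SlidePrediction(
            task="survival", risk=float(logits[0]), attention=attention
        )

    def instance_logits(self, bag: FeatureBag) -> np.ndarray:
        h_proj = self._project(bag)
        return (h_proj @ self.params["W_inst"] + self.params["b_inst"]).data

    # -- full forward (used by training; returns graph tensors) -----------------
    def forward(
        self,
        bag: FeatureBag,
        clinical: ClinicalVector,
        rng: np.random.Generator | None = None,
        force_gate: float | None = None,
    ) -> dict:
        """Run the complete slide forward pass.

        Returns a dict of graph :class:`Tensor` objects (``alpha``, ``m_wsi``,
        ``gate``, ``m_fused``, ``logits``, ``inst_logits``) so the training
        loop can build losses; use :meth:`predict` for a plain prediction.
        """
        h_proj = self._project(bag)
        alpha, m_wsi = self._attention(h_proj, clinical.surgery_type, rng)
        fused, gate = self._fuse(m_wsi, clinical.values, rng, force_gate)
        logits = self._head(fused)
        inst_logits = h_proj @ self.params["W_inst"] + self.params["b_inst"]
        return {
            "alpha": alpha,
            "m_wsi": m_wsi,
            "gate": gate,
            "m_fused": fused,
            "logits": logits,
            "inst_logits": inst_logits,
        }

    def predict(
        self, bag: FeatureBag, clinical: ClinicalVector,
        force_gate: float | None = None,
    ) -> SlidePrediction:
        out = self.forward(bag, clinical, rng=None, force_gate=force_gate)
        attention = AttentionWeights(
            alpha=out["alpha"].data, path_used=clinical.surgery_type
        )
        logits = out["logits"].data
        if self.config.task == "classification":
            return SlidePrediction(
                task="classification",
                class_probs=Tensor(logits).softmax().data,
                attention=attention,
            )
        return SlidePrediction(task="survival", risk=float(logits[0]), attention=attention)

    # -- persistence --------------------------------------------------------------
    def schema_hash(self, schema: tuple[str, ...]) -> str:
        return hashlib.sha256(json.dumps(list(schema)).encode()).hexdigest()[:16]

    def save(self, path, schema: tuple[str, ...] = ()) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        cfg = json.dumps(self.config.__dict__)
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **arrays)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as f:
            json.dump(
                {"config": self.config.__dict__,
                 "schema": list(schema),
                 "schema_hash": self.schema_hash(tuple(schema))},
                f, indent=2,
            )

    @classmethod
    def load(cls, path, expected_schema: tuple[str, ...] | None = None):
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            model = cls(ModelConfig(**cfg), seed=0)
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"}
            )
        sidecar = str(path) + ".json"
        if expected_schema is not None:
            with open(sidecar) as f:
                meta = json.load(f)
            got = model.schema_hash(tuple(expected_schema))
            if meta["schema_hash"] != got:
                raise ValueError(
                    "clinical schema mismatch: checkpoint was trained with "
                    f"{meta['schema']}, got {list(expected_schema)}"
                )
        return model
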