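"""Seeded synthetic-data generators with known ground truth.

Two generators:

* :func:`simulate_cohort` emulates the multimodal cohort the pipeline
  consumes: per-patient feature bags (2 primary + 1 metastatic slide by
  default) with a planted fraction of signal instances shifted by μ along a
  fixed unit direction, clinical covariates with configurable effects, a
  Bernoulli response label driven by a logistic model on the latent score,
  and exponential survival times with independent exponential censoring
  calibrated to a target censoring fraction.

* :func:`simulate_tissue_image` paints saturated elliptical "tissue" blobs
  (plus optional black artifact patches) on a white canvas, returning the
  image together with its exact ground-truth mask, to exercise segmentation
  and tiling.

All randomness flows from a single seed through per-patient child generators
(``default_rng([seed, patient_index])``), so enlarging the cohort never
perturbs earlier patients' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, SlideRecord
from .encoding import FeatureBag
from .losses import SurvivalLabel
from .model import ClinicalVector
from .wsi_tiling import SlideImage, TileCoordinates

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "simulate_tissue_image"]

#: fixed clinical schema: binary stage-like, binary cytoreduction-like,
#: z-scored log marker, 3-level categorical (one-hot block sums to 1)
CLINICAL_SCHEMA = (
    "stage_iv",
    "suboptimal_cytoreduction",
    "log_ca125_z",
    "crs_1",
    "crs_2",
    "crs_3",
)

_P_STAGE_IV = 0.17
_P_SUBOPT = 0.70
_LOG_CA125_MU = 7.0
_LOG_CA125_SD = 1.0


@dataclass
class SimConfig:
    n_patients: int = 300
    slides_primary: int = 2
    slides_metastatic: int = 1
    bag_size_range: tuple[int, int] = (50, 200)
    dim: int = 64
    signal_fraction: float = 0.2  # π, planted fraction on signal slides
    effect_size: float = 2.0  # μ, mean shift along the unit direction
    metastatic_boost: float = 1.25  # planted-fraction multiplier on metastases
    clinical_effect: tuple[float, ...] = (0.4, 0.3, 0.3, 0.2, 0.0, -0.2)
    signal_coefficient: float = 20.0  # latent-score weight on realized fraction
    latent_noise: float = 0.25
    label_slope: float = 6.0  # logistic slope on the centered latent score
    baseline_hazard: float = 0.05  # per month
    survival_effect: float = 1.0  # β_s
    censoring_rate: float = 0.3
    surgery_mix: float = 0.35  # P(PDS)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.bag_size_range[0] < 1 or self.bag_size_range[0] > self.bag_size_range[1]:
            raise ValueError("invalid bag_size_range")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if len(self.clinical_effect) != len(CLINICAL_SCHEMA):
            raise ValueError(
                f"clinical_effect must have {len(CLINICAL_SCHEMA)} entries"
            )

    @classmethod
    def null(cls, **kw) -> "SimConfig":
        """Matched null: no image effect, no clinical effect."""
        kw.setdefault("effect_size", 0.0)
        kw.setdefault("clinical_effect", (0.0,) * len(CLINICAL_SCHEMA))
        return cls(**kw)


@dataclass
class GroundTruth:
    signal_direction: np.ndarray
    latent_scores: dict[str, float]
    label_probs: dict[str, float]
    hazards: dict[str, float]
    oracle_scores: dict[str, float]  # projection of mean bag feature onto u
    planted_flags: dict[str, np.ndarray] = field(default_factory=dict)
    signal_carrier: dict[str, bool] = field(default_factory=dict)


def _expected_latent_mean(config: SimConfig) -> float:
    pi_eff = (
        config.slides_primary * config.signal_fraction
        + config.slides_metastatic
        * min(config.metastatic_boost * config.signal_fraction, 1.0)
    ) / (config.slides_primary + config.slides_metastatic)
    mean_frac = 0.5 * pi_eff  # half the patients carry signal
    ce = np.asarray(config.clinical_effect)
    mean_clinical = float(
        ce[0] * _P_STAGE_IV + ce[1] * _P_SUBOPT + ce[2] * 0.0 + ce[3:].mean()
    )
    return config.signal_coefficient * mean_frac + mean_clinical


def _grid_coords(n: int, tile_size: int = 256, slide_id: str = "s") -> TileCoordinates:
    cols = int(np.ceil(np.sqrt(n)))
    k = np.arange(n)
    coords = np.stack([(k % cols) * tile_size, (k // cols) * tile_size], axis=1)
    return TileCoordinates(coords, tile_size=tile_size, slide_id=slide_id)


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def simulate_cohort(config: SimConfig | None = None) -> tuple[Cohort, GroundTruth]:
    """Generate a full multimodal cohort with ground truth.

    Background instances are standard normal in D dimensions; on the slides
    of signal-carrier patients, ``round(π·N)`` instances are shifted by μ·u
    (metastatic slides use 1.25·π, capped at 1, so that aggregation over the
    third slide is informative). The patient latent score combines the
    realized planted fraction, the clinical effect and Gaussian noise; the
    response label is Bernoulli in a logistic model on the centered score and
    the survival time is exponential with hazard λ0·exp(β_s·score).
    """
    config = config or SimConfig()
    seed = config.seed
    u_rng = np.random.default_rng([seed, 1 << 20])
    u = u_rng.standard_normal(config.dim)
    u /= np.linalg.norm(u)
    mean_s = _expected_latent_mean(config)
    ce = np.asarray(config.clinical_effect)

    slides: list[SlideRecord] = []
    gt = GroundTruth(
        signal_direction=u, latent_scores={}, label_probs={}, hazards={},
        oracle_scores={},
    )
    hazards = np.empty(config.n_patients)
    censor_quantiles = np.empty(config.n_patients)
    raw_event_times = np.empty(config.n_patients)
    patient_slides: list[list[SlideRecord]] = []

    for i in range(config.n_patients):
        rng = np.random.default_rng([seed, i])
        pid = f"P{i:04d}"
        surgery = "PDS" if rng.random() < config.surgery_mix else "IDS"
        carrier = bool(rng.random() < 0.5)
        stage = float(rng.random() < _P_STAGE_IV)
        subopt = float(rng.random() < _P_SUBOPT)
        log_ca125 = rng.normal(_LOG_CA125_MU, _LOG_CA125_SD)
        ca_z = (log_ca125 - _LOG_CA125_MU) / _LOG_CA125_SD
        crs = rng.integers(0, 3)
        onehot = np.zeros(3)
        onehot[crs] = 1.0
        cvec = np.concatenate([[stage, subopt, ca_z], onehot])
        clinical = ClinicalVector(cvec, surgery, schema=CLINICAL_SCHEMA)

        sites = ["primary"] * config.slides_primary + \
                ["metastatic"] * config.slides_metastatic
        total_planted = 0
        total_instances = 0
        oracle_slide_scores = []
        recs: list[SlideRecord] = []
        for j, site in enumerate(sites):
            n = int(rng.integers(config.bag_size_range[0],
                                 config.bag_size_range[1] + 1))
            feats = rng.standard_normal((n, config.dim))
            frac = 0.0
            if carrier:
                frac = config.signal_fraction
                if site == "metastatic":
                    frac = min(config.metastatic_boost * frac, 1.0)
            n_plant = int(round(frac * n))
            flags = np.zeros(n, dtype=bool)
            if n_plant > 0:
                idx = rng.choice(n, size=n_plant, replace=False)
                feats[idx] += config.effect_size * u
                flags[idx] = True
            sid = f"{pid}-S{j}"
            bag = FeatureBag(
                slide_id=sid, patient_id=pid, site=site,
                features=feats, coords=_grid_coords(n, slide_id=sid),
                encoder_name="synthetic-cohort",
            )
            gt.planted_flags[sid] = flags
            total_planted += n_plant
            total_instances += n
            oracle_slide_scores.append(float(feats.mean(axis=0) @ u))
            recs.append(SlideRecord(bag=bag, clinical=clinical))

        realized_frac = total_planted / total_instances
        s = (
            config.signal_coefficient * realized_frac
            + float(ce @ cvec)
            + config.latent_noise * rng.normal()
            - mean_s
        )
        prob = _sigmoid(config.label_slope * s)
        label = int(rng.random() < prob)
        hazard = config.baseline_hazard * np.exp(config.survival_effect * s)
        raw_event_times[i] = rng.exponential(1.0 / hazard)
        censor_quantiles[i] = rng.random()
        hazards[i] = hazard
        gt.latent_scores[pid] = s
        gt.label_probs[pid] = prob
        gt.hazards[pid] = hazard
        gt.oracle_scores[pid] = float(np.mean(oracle_slide_scores))
        gt.signal_carrier[pid] = carrier
        for rec in recs:
            rec.label = label
        patient_slides.append(recs)

    censor_times = _calibrated_censoring(
        hazards, censor_quantiles, config.censoring_rate
    )
    for i, recs in enumerate(patient_slides):
        t_event = raw_event_times[i]
        t_cens = censor_times[i]
        observed = float(max(min(t_event, t_cens), 1e-6))
        event = int(t_event <= t_cens)
        for rec in recs:
            rec.survival = SurvivalLabel(observed, event)
        slides.extend(recs)

    cohort = Cohort(slides=slides, schema=CLINICAL_SCHEMA)
    cohort.assign_splits(seed=(seed, 3))
    return cohort, gt


def _calibrated_censoring(
    hazards: np.ndarray, quantiles: np.ndarray, target: float
) -> np.ndarray:
    """Censoring times from an independent exponential whose rate solves
    mean_i λc/(λc + hᵢ) = target (bisection on the realized hazards)."""
    if target <= 0.0:
        return np.full(len(hazards), np.inf)

    def frac(lam: float) -> float:
        return float(np.mean(lam / (lam + hazards)))

    lo, hi = 1e-9, 1e6
    if frac(hi) < target:
        raise ValueError("infeasible censoring target")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    lam_c = np.sqrt(lo * hi)
    return -np.log(np.clip(1.0 - quantiles, 1e-12, None)) / lam_c


def simulate_tissue_image(
    width: int = 1024,
    height: int = 1024,
    n_blobs: int = 3,
    seed: int = 0,
    n_black_patches: int = 0,
) -> tuple[SlideImage, np.ndarray]:
    """White canvas with saturated elliptical tissue blobs; returns the exact
    ground-truth tissue mask alongside the image."""
    from matplotlib.colors import hsv_to_rgb
    from skimage.draw import ellipse

    if min(width, height) < 256:
        raise ValueError("canvas must be at least 256×256")
    rng = np.random.default_rng(seed)
    img = np.full((height, width, 3), 255, dtype=np.uint8)
    mask = np.zeros((height, width), dtype=np.uint8)
    max_r = min(width, height) // 4
    for _ in range(n_blobs):
        ry = int(rng.integers(40, max_r + 1))
        rx = int(rng.integers(40, max_r + 1))
        cy = int(rng.integers(ry, height - ry))
        cx = int(rng.integers(rx, width - rx))
        hue = float(rng.random())
        rgb = (hsv_to_rgb([hue, 0.8, 0.9]) * 255).astype(np.uint8)
        rr, cc = ellipse(cy, cx, ry, rx, shape=mask.shape)
        img[rr, cc] = rgb
        mask[rr, cc] = 1
    for _ in range(n_black_patches):
        size = int(rng.integers(32, 97))
        y0 = int(rng.integers(0, height - size))
        x0 = int(rng.integers(0, width - size))
        img[y0 : y0 + size, x0 : x0 + size] = 0
        mask[y0 : y0 + size, x0 : x0 + size] = 0
    slide = SlideImage(img, slide_id=f"synthetic-{seed}")
    return slide, mask
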