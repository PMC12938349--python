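"""Cohort manifest I/O (CSV) and conversion to/from in-memory cohorts.

The manifest has one row per slide: patient_id, slide_id, bag_path, site
(primary/metastatic), surgery_type (PDS/IDS), the clinical covariate columns,
label (0 = resistant-like, 1 = sensitive-like; class 1 is the favorable
response), time (months), event (0/1) and split (train/val/test). Splits,
labels, survival and clinical values are patient-level attributes and must
agree across a patient's slides; validation enforces this at load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SPLITS, Cohort
from .encoding import load_bag, save_bag

__all__ = ["read_manifest", "write_manifest", "cohort_to_manifest", "manifest_to_cohort"]

REQUIRED_COLUMNS = (
    "patient_id",
    "slide_id",
    "bag_path",
    "site",
    "surgery_type",
    "label",
    "time",
    "event",
    "split",
)
SITES = ("primary", "metastatic")
SURGERY = ("PDS", "IDS")


def validate_manifest(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    bad_site = set(df["site"]) - set(SITES)
    if bad_site:
        raise ValueError(f"unknown site value(s): {sorted(bad_site)}")
    bad_surg = set(df["surgery_type"]) - set(SURGERY)
    if bad_surg:
        raise ValueError(f"unknown surgery_type value(s): {sorted(bad_surg)}")
    bad_split = set(df["split"]) - set(SPLITS)
    if bad_split:
        raise ValueError(f"unknown split value(s): {sorted(bad_split)}")
    clinical_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    for pid, group in df.groupby("patient_id"):
        if group["split"].nunique() > 1:
            raise ValueError(
                f"patient {pid} straddles splits {sorted(group['split'].unique())}"
            )
        for col in ("label", "time", "event", "surgery_type", *clinical_cols):
            if group[col].nunique() > 1:
                raise ValueError(f"patient {pid} has inconsistent {col!r} values")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_manifest(df)
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    validate_manifest(df)
    df.to_csv(path, index=False)


def cohort_to_manifest(cohort: Cohort, bag_dir) -> pd.DataFrame:
    """Persist bags to HDF5 files and build the matching manifest table."""
    bag_dir = Path(bag_dir)
    bag_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.slides:
        bag_path = bag_dir / f"{rec.slide_id}.h5"
        save_bag(rec.bag, bag_path)
        row = {
            "patient_id": rec.patient_id,
            "slide_id": rec.slide_id,
            "bag_path": str(bag_path),
            "site": rec.bag.site,
            "surgery_type": rec.clinical.surgery_type,
            "label": rec.label,
            "time": rec.survival.time if rec.survival else np.nan,
            "event": rec.survival.event if rec.survival else 0,
            "split": rec.split,
        }
        for name, value in zip(cohort.schema, rec.clinical.values):
            row[name] = value
        rows.append(row)
    return pd.DataFrame(rows)


def manifest_to_cohort(df: pd.DataFrame) -> Cohort:
    """Load bags referenced by a manifest into an in-memory cohort."""
    from .losses import SurvivalLabel
    from .model import ClinicalVector
    from .cohort import SlideRecord

    validate_manifest(df)
    clinical_cols = tuple(c for c in df.columns if c not in REQUIRED_COLUMNS)
    slides = []
    for _, row in df.iterrows():
        bag = load_bag(row["bag_path"])
        clinical = ClinicalVector(
            np.array([row[c] for c in clinical_cols], dtype=np.float64),
            row["surgery_type"],
            schema=clinical_cols,
        )
        survival = None
        if np.isfinite(row["time"]):
            survival = SurvivalLabel(float(row["time"]), int(row["event"]))
        slides.append(
            SlideRecord(
                bag=bag,
                clinical=clinical,
                label=int(row["label"]) if not pd.isna(row["label"]) else None,
                survival=survival,
                split=row["split"],
            )
        )
    cohort = Cohort(slides=slides, schema=clinical_cols)
    cohort.validate()
    return cohort
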