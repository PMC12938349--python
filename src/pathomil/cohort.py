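"""In-memory cohort container: slides with bags, clinical vectors and labels.

A cohort is a flat list of slide records; every slide carries its patient's
label, survival outcome and clinical covariates (slide-level training uses
the inherited labels; patient-level aggregation happens only at evaluation).
Splits are assigned at the patient level so no patient straddles splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import FeatureBag
from .losses import SurvivalLabel
from .model import ClinicalVector

__all__ = ["SlideRecord", "Cohort", "split_patients"]

SPLITS = ("train", "val", "test")


@dataclass
class SlideRecord:
    bag: FeatureBag
    clinical: ClinicalVector
    label: int | None = None
    survival: SurvivalLabel | None = None
    split: str = ""

    @property
    def patient_id(self) -> str:
        return self.bag.patient_id

    @property
    def slide_id(self) -> str:
        return self.bag.slide_id


@dataclass
class Cohort:
    slides: list[SlideRecord]
    schema: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.slides)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.slides:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def split(self, name: str) -> list[SlideRecord]:
        return [s for s in self.slides if s.split == name]

    def by_patient(self, slides=None) -> dict[str, list[SlideRecord]]:
        groups: dict[str, list[SlideRecord]] = {}
        for s in self.slides if slides is None else slides:
            groups.setdefault(s.patient_id, []).append(s)
        return groups

    def validate(self) -> None:
        for pid, group in self.by_patient().items():
            splits = {s.split for s in group}
            if len(splits) > 1:
                raise ValueError(f"patient {pid} straddles splits {sorted(splits)}")
            labels = {s.label for s in group}
            if len(labels) > 1:
                raise ValueError(f"patient {pid} has inconsistent labels")

    def assign_splits(
        self,
        fractions: tuple[float, float, float] = (0.65, 0.20, 0.15),
        seed: int = 0,
        stratify: bool = False,
    ) -> None:
        """Patient-level random allocation into train/val/test."""
        assignment = split_patients(
            self.patient_ids,
            fractions,
            seed,
            labels={s.patient_id: s.label for s in self.slides} if stratify else None,
        )
        for s in self.slides:
            s.split = assignment[s.patient_id]


def split_patients(
    patient_ids: list[str],
    fractions: tuple[float, float, float] = (0.65, 0.20, 0.15),
    seed: int = 0,
    labels: dict[str, int] | None = None,
) -> dict[str, str]:
    """Randomly allocate patients to splits, optionally stratified by label."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)

    def allocate(ids: list[str]) -> dict[str, str]:
        ids = list(ids)
        perm = rng.permutation(len(ids))
        n = len(ids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        out: dict[str, str] = {}
        for rank, idx in enumerate(perm):
            if rank < n_train:
                out[ids[idx]] = "train"
            elif rank < n_train + n_val:
                out[ids[idx]] = "val"
            else:
                out[ids[idx]] = "test"
        return out

    if labels is None:
        return allocate(patient_ids)
    assignment: dict[str, str] = {}
    for value in sorted({labels[p] for p in patient_ids}, key=str):
        assignment.update(allocate([p for p in patient_ids if labels[p] == value]))
    return assignment
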