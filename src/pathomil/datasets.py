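"""Bundled reference tables.

``BASELINE_CATEGORICAL`` holds the published baseline-characteristics counts
of the ovarian-carcinoma development cohort (advanced-stage high-grade serous
carcinoma; N = 376 split into training / validation / internal-test groups of
245 / 76 / 55 patients). Each entry is the r×c contingency table of a
categorical variable against the three splits, together with the p-value
printed alongside it. These counts fully determine the Pearson chi-square
statistics and serve as a fixed numerical reference for the baseline-test
implementation; the rows listed here are the ones whose printed p-values are
reproduced exactly by the chi-square test without continuity correction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BASELINE_CATEGORICAL", "BaselineRow"]


class BaselineRow:
    def __init__(self, counts, row_labels, printed_p):
        self.counts = np.asarray(counts, dtype=np.int64)
        self.row_labels = tuple(row_labels)
        self.col_labels = ("training", "validation", "internal_test")
        self.printed_p = float(printed_p)


BASELINE_CATEGORICAL: dict[str, BaselineRow] = {
    "figo_stage": BaselineRow(
        [[200, 64, 48], [45, 12, 7]], ("III", "IV"), 0.573
    ),
    "optimal_cytoreduction": BaselineRow(
        [[79, 19, 14], [166, 57, 41]], ("optimal", "suboptimal"), 0.362
    ),
    "vascular_tumor_thrombus": BaselineRow(
        [[205, 59, 42], [40, 17, 13]], ("negative", "positive"), 0.291
    ),
    "chemotherapy_response_score": BaselineRow(
        [[69, 15, 13], [92, 19, 17], [13, 4, 3], [71, 38, 22]],
        ("CRS1", "CRS2", "CRS3", "N (PDS)"),
        0.053,
    ),
    "lymph_resection": BaselineRow(
        [[111, 24, 30], [35, 13, 5], [99, 39, 20]],
        ("none", "enlarged_node", "systematic"),
        0.101,
    ),
    "hypertension": BaselineRow(
        [[192, 58, 46], [53, 18, 9]], ("no", "yes"), 0.584
    ),
    "menopause": BaselineRow(
        [[158, 47, 33], [87, 29, 22]], ("no", "yes"), 0.788
    ),
    "platinum_response": BaselineRow(
        [[93, 29, 21], [152, 47, 34]], ("resistant", "sensitive"), 0.999
    ),
}
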