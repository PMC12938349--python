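import numpy as np
import pytest

from pathomil.encoding import FeatureBag
from pathomil.model import ClinicalVector
from pathomil.wsi_tiling import TileCoordinates


def make_bag(features, slide_id="s0", patient_id="p0", site="primary"):
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    coords = TileCoordinates(
        np.stack([np.arange(n) * 256, np.zeros(n, dtype=int)], axis=1),
        slide_id=slide_id,
    )
    return FeatureBag(
        slide_id=slide_id, patient_id=patient_id, site=site,
        features=features, coords=coords, encoder_name="test",
    )


def make_clinical(values, surgery="IDS"):
    return ClinicalVector(np.asarray(values, dtype=float), surgery)


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient synthetic cohort shared by training-level tests."""
    from pathomil.simulate import SimConfig, simulate_cohort

    cohort, gt = simulate_cohort(SimConfig(n_patients=30, dim=16, seed=11))
    return cohort, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
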