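import numpy as np
import pandas as pd
import pytest

from glycobarcode import CohortSpec, generate_cohort
from glycobarcode.peaks import FeatureMatrix


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for fast pipeline tests: 30 + 30 samples, 200 features."""
    return generate_cohort(
        CohortSpec(n_eoc=30, n_non=30, n_features=200, n_blocks=4, effect_size=1.5, seed=11)
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Full-feature-count cohort at reduced sample size (60 + 60, 1712 features)."""
    return generate_cohort(CohortSpec(n_eoc=60, n_non=60, n_features=1712, seed=1))


def make_matrix(values: np.ndarray, rts=None, mzs=None, **kwargs) -> FeatureMatrix:
    """Assemble a FeatureMatrix from a plain array for unit tests."""
    n_samp, n_feat = values.shape
    rts = np.linspace(1.0, 10.0, n_feat) if rts is None else np.asarray(rts)
    mzs = np.linspace(900.0, 1900.0, n_feat) if mzs is None else np.asarray(mzs)
    fids = [f"F{r:.2f}_{m:.4f}" for r, m in zip(rts, mzs)]
    sample_ids = kwargs.pop("sample_ids", [f"S{i}" for i in range(n_samp)])
    meta = pd.DataFrame(
        {"rt": rts, "mz": mzs, "snr": kwargs.pop("snr", np.nan)}, index=fids
    )
    return FeatureMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=fids),
        feature_meta=meta,
        **kwargs,
    )
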