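import numpy as np
import pandas as pd
import pytest

from sorshoney import preprocess, synthetic
from sorshoney.spectra_io import SpectraSet


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down Year-2-style design: 5 honey types, 2 replicates."""
    return synthetic.year2_design(n_types=5, seed=7, replicates=2)


@pytest.fixture(scope="session")
def small_set(small_design):
    return synthetic.generate_study(small_design)


@pytest.fixture(scope="session")
def small_pre(small_set):
    """Preprocessed, replicate-averaged small study (one row per sample)."""
    return preprocess.preprocess_pipeline(small_set)


@pytest.fixture(scope="session")
def year2_pre():
    """Full default Year-2 design (14 types, rice + beet), preprocessed."""
    sset = synthetic.generate_study(synthetic.year2_design(seed=0))
    return preprocess.preprocess_pipeline(sset)


def make_set(axis, intensities, sample_ids=None, **meta_overrides):
    """Assemble a minimal valid SpectraSet around an intensity matrix."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "measurement_id": [f"m{i}" for i in range(n)],
            "sample_id": ids,
            "honey_type": meta_overrides.get("honey_type", ["H1"] * n),
            "role": meta_overrides.get("role", ["honey"] * n),
            "adulterant": meta_overrides.get("adulterant", ["none"] * n),
            "level_pct": meta_overrides.get("level_pct", [0.0] * n),
            "replicate": meta_overrides.get("replicate", list(range(1, n + 1))),
            "spatial_offset_mm": 4.0,
        }
    )
    return SpectraSet(np.asarray(axis, dtype=float), intensities, meta)
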