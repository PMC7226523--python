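import numpy as np
import pandas as pd
import pytest

from radsurv import (
    CohortSpec,
    DiscretizedROI,
    ExtractionConfig,
    extract_all,
    generate_cohort,
)


def roi_from_levels(levels: np.ndarray) -> DiscretizedROI:
    levels = np.asarray(levels, dtype=np.int32)
    return DiscretizedROI(
        levels=levels,
        n_levels=int(levels.max()) if levels.max() > 0 else 1,
        bin_width=1.0,
        min_intensity=0.0,
    )


def random_roi(rng: np.random.Generator, shape=(4, 4, 4), n_levels=4) -> DiscretizedROI:
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    levels[~mask] = 0
    if (levels > 0).sum() < 2:  # keep at least two voxels
        levels[0, 0, 0] = 1
        levels[0, 0, 1] = 2
    return roi_from_levels(levels)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small phantom cohort shared by pipeline-level tests."""
    spec = CohortSpec(n_patients=12, image_shape=(18, 18, 18), seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    rows = {
        p.patient_id: extract_all(
            p.volume, p.mask, ExtractionConfig(resample=False), patient_id=p.patient_id
        ).values
        for p in tiny_cohort.patients
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
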