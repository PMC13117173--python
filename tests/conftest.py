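import numpy as np
import pandas as pd
import pytest

from nucrisk.cflcm import ROIFeaturizer
from nucrisk.synth import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by unit tests (40 cases, 3 ROIs, 60 nuclei)."""
    return generate_cohort(
        CohortParams(n_cases=40, rois_per_case=3, nuclei_per_roi=60, seed=5)
    )


@pytest.fixture(scope="session")
def small_roi_features(small_cohort):
    return ROIFeaturizer().fit().transform(small_cohort.nuclei)


def make_nucleus_table(
    n: int,
    seed: int = 0,
    orientation=None,
    feature_overrides: dict | None = None,
    canvas: float = 1000.0,
) -> pd.DataFrame:
    """Minimal synthetic nucleus table with all 90 registry columns.

    Centroids on a jittered grid; every feature defaults to small positive
    noise unless overridden (scalar or array per feature name).
    """
    from nucrisk.registry import NUCLEUS_FEATURE_NAMES
    from nucrisk.synth import sample_centroids

    rng = np.random.default_rng(seed)
    xy = sample_centroids(n, int(canvas), rng)
    df = pd.DataFrame(
        {
            "case_id": "caseX",
            "roi_id": 0,
            "nucleus_id": np.arange(1, n + 1),
            "centroid_x": xy[:, 0],
            "centroid_y": xy[:, 1],
        }
    )
    for name in NUCLEUS_FEATURE_NAMES:
        df[name] = rng.uniform(0.1, 1.0, size=n)
    df["area"] = rng.uniform(200.0, 400.0, size=n)
    df["eccentricity"] = rng.uniform(0.3, 0.9, size=n)
    df["solidity"] = rng.uniform(0.95, 1.0, size=n)
    df["form_factor"] = rng.uniform(0.7, 1.0, size=n)
    df["orientation"] = (
        np.asarray(orientation, dtype=float)
        if orientation is not None
        else rng.uniform(0.0, 180.0, size=n)
    )
    for name, val in (feature_overrides or {}).items():
        df[name] = val
    return df
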