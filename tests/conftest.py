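"""Shared fixtures: schemes, small synthetic cohorts, toy feature tables."""

import numpy as np
import pandas as pd
import pytest

from gmshore.acquisition import default_scheme
from gmshore.cohort import CohortConfig, build_cohort
from gmshore.features import assemble_feature_table
from gmshore.maps import compute_index_maps


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_cohort(scheme):
    """4+4 subjects, 30 voxels per ROI: the default world at desk scale."""
    config = CohortConfig(n_per_group=4, voxels_per_roi=30, seed=7)
    return build_cohort(config, scheme), config


@pytest.fixture(scope="session")
def small_table(small_cohort, scheme):
    cohort, config = small_cohort
    maps = {
        s.subject_id: {roi: compute_index_maps(block, scheme)
                       for roi, block in s.signals.items()}
        for s in cohort
    }
    return assemble_feature_table(cohort, maps, metadata={"seed": config.seed})


class ToyTable:
    """Duck-typed feature table for selection unit tests."""

    def __init__(self, x, y, names=None):
        self.x_arr = np.asarray(x, dtype=float)
        self.y_arr = np.asarray(y)
        self.names = list(names) if names is not None else [
            f"f{i}" for i in range(self.x_arr.shape[1])
        ]
        self.data = pd.DataFrame(self.x_arr, columns=self.names)
        self.data.insert(0, "group", self.y_arr)

    @property
    def feature_names(self):
        return list(self.names)

    @property
    def x(self):
        return self.x_arr

    @property
    def y(self):
        return self.y_arr

    def __len__(self):
        return len(self.y_arr)


@pytest.fixture
def toy_table():
    """Linearly separable 12-subject, 5-feature toy problem."""
    rng = np.random.default_rng(42)
    n = 12
    y = np.array(["PPMS", "RRMS"] * (n // 2))
    x = rng.standard_normal((n, 5))
    x[:, 2] = np.where(y == "RRMS", 5.0, -5.0) + 0.1 * rng.standard_normal(n)
    return ToyTable(x, y)
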