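import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from varstrat.io import FormatLevel, FunctionalDataset
from varstrat.synthetic import PanelSpec, default_profiles, generate_panel

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_dataset(rows, level=FormatLevel.CONTROL_NORMALIZED):
    """Build a FunctionalDataset from (variant, lab, assay, replicate, value) tuples."""
    df = pd.DataFrame(rows, columns=["variant", "lab", "assay", "replicate", "value"])
    return FunctionalDataset(df, level)


@pytest.fixture(scope="session")
def default_panel():
    """Default two-laboratory panel at seed 1 with truth labels."""
    spec = PanelSpec(seed=1)
    ds, annotations, truth = generate_panel(spec)
    return spec, ds, annotations, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def blobs_3():
    """Three well-separated planted blobs with labels."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    pts, labels = [], []
    for c, center in enumerate(centers):
        pts.append(center + rng.normal(0, 0.3, size=(12, 2)))
        labels += [c] * 12
    X = np.vstack(pts)
    index = [f"v{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=index), pd.Series(labels, index=index)
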