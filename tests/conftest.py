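import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def small_labeled_data(rng):
    """60 points in 3-D with a weak signal in the first coordinate."""
    X = rng.normal(size=(60, 3))
    y = np.where(X[:, 0] + 0.5 * rng.normal(size=60) > 0, 1, -1)
    return X, y


def write_csv(path, rows):
    path.write_text("\n".join(",".join(map(str, row)) for row in rows) + "\n")


@pytest.fixture
def uci_rows():
    """Three syntactically valid 14-field UCI-dialect rows, one incomplete."""
    base = [63.0, 1, 1, 145.0, 233.0, 1, 2, 150.0, 0, 2.3, 3, 0.0, 6, 0]
    complete2 = [67.0, 1, 4, 160.0, 286.0, 0, 2, 108.0, 1, 1.5, 2, 3.0, 3, 2]
    missing = [41.0, 0, 2, 130.0, 204.0, 0, 2, 172.0, 0, 1.4, 1, "?", 3, 0]
    return [base, complete2, missing]
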