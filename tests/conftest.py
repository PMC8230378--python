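import numpy as np
import pandas as pd
import pytest

from panelstrat import calibration
from panelstrat.synthetic_cohort import cohort_to_frame, generate_cohort


def make_frame(values: dict, infected) -> pd.DataFrame:
    """Minimal cohort frame from per-marker value lists plus labels."""
    df = pd.DataFrame(values)
    df["infected"] = np.asarray(infected, dtype=bool)
    return df


def random_frame(rng: np.random.Generator, n: int, markers=("a", "b", "c"),
                 discrete: bool = False) -> pd.DataFrame:
    """Random labelled frame with a mild class shift (both classes present)."""
    labels = np.zeros(n, dtype=bool)
    labels[: max(1, n // 3)] = True
    rng.shuffle(labels)
    data = {}
    for m in markers:
        base = rng.integers(0, 6, size=n).astype(float) if discrete else rng.normal(0, 1, n)
        data[m] = base + 0.8 * labels
    return make_frame(data, labels)


@pytest.fixture(scope="session")
def discovery_frame():
    return cohort_to_frame(generate_cohort(calibration.discovery_spec(seed=42)))


@pytest.fixture(scope="session")
def validation_frame():
    return cohort_to_frame(generate_cohort(calibration.validation_spec(seed=43)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
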