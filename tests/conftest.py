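import numpy as np
import pytest

from lactodb import StudyRecord, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def two_study_records():
    """Two equal-size studies whose concatenated subject values are {1,3,5,7}.

    Study A has subjects {1, 3} (mean 2, population SD 1), study B has {5, 7}
    (mean 6, population SD 1); pooling must reproduce the population mean 4
    and SD sqrt(5) of the four raw values.
    """
    return [
        StudyRecord("A", "demo", 0.5, None, 2.0, "SD", 1.0, 2, "u"),
        StudyRecord("B", "demo", 0.5, None, 6.0, "SD", 1.0, 2, "u"),
    ]


@pytest.fixture
def grid_1201():
    return np.linspace(0.0, 12.0, 1201)
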