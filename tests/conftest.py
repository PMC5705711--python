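import numpy as np
import pytest

from occudesign import DetectionHistory, StudyGeneratorConfig, generate_study


@pytest.fixture
def tiny_history() -> DetectionHistory:
    """3 sites x 2 occasions with one missing visit."""
    return DetectionHistory(
        ["A", "B", "C"],
        np.array([[1.0, 0.0], [0.0, np.nan], [0.0, 0.0]]),
        ["occ_1", "occ_2"],
    )


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study under the default design, fixed seed."""
    return generate_study(StudyGeneratorConfig(), seed=20150201)


@pytest.fixture(scope="session")
def single_month_config() -> StudyGeneratorConfig:
    """A single 6-night monthly survey (the smallest covariate-rich design)."""
    return StudyGeneratorConfig(n_months=1, occasions_per_month=(6, 6))
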