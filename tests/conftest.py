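import numpy as np
import pytest

from margincnn import ADENOMA, CARCINOMA, NoduleCase, SyntheticConfig


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Compact phantom configuration for fast unit tests."""
    return SyntheticConfig(image_size=170, nodule_radius_range=(32.0, 45.0), rim_width=6.0)


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


def make_case(image: np.ndarray, contour, label=ADENOMA, cohort="A", case_id="t"):
    return NoduleCase(case_id, np.asarray(image, dtype=np.uint8), contour, label, cohort)


def square_contour(r0: int, c0: int, side: int) -> np.ndarray:
    """Axis-aligned square polygon vertices (row, col), corners `side` apart."""
    return np.array(
        [[r0, c0], [r0, c0 + side], [r0 + side, c0 + side], [r0 + side, c0]]
    )


class MeanThresholdStub:
    """Duck-typed stand-in for a fitted patch classifier.

    Votes carcinoma when a normalized patch's mean exceeds ``threshold``;
    the alpha shift in the test normalization moves patch means, so this
    stub produces alpha-dependent votes without any training. ``bias``
    forces a constant vote regardless of input.
    """

    classes_ = np.array([ADENOMA, CARCINOMA])

    def __init__(self, threshold: float = 0.5, bias: str | None = None):
        self.threshold = threshold
        self.bias = bias

    def predict_proba(self, X):
        X = np.asarray(X)
        means = X.reshape(len(X), -1).mean(axis=1)
        if self.bias == ADENOMA:
            p_car = np.zeros(len(X))
        elif self.bias == CARCINOMA:
            p_car = np.ones(len(X))
        else:
            p_car = (means > self.threshold).astype(float)
        return np.column_stack([1 - p_car, p_car])

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@pytest.fixture
def stub_model_factory():
    return MeanThresholdStub
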