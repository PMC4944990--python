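import numpy as np
import pytest

from dyadsync.compliance import ClassroomLayout
from dyadsync.hrv import FeatureVector, WindowSpec
from dyadsync.simulate import SyntheticConfig, generate_classroom


def make_fv(pid, values, feature="SDNN", length_s=300.0, valid=None):
    """FeatureVector on a canonical window grid, for unit tests."""
    values = np.asarray(values, dtype=float)
    spec = WindowSpec(length_s=length_s)
    starts = spec.step_s * np.arange(values.size)
    if valid is None:
        valid = ~np.isnan(values)
    return FeatureVector(pid, feature, spec, starts, values, valid)


@pytest.fixture(scope="session")
def small_classroom():
    """Deterministic 2-classes-by-2-dyads classroom, 25 minutes."""
    cfg = SyntheticConfig(
        n_dyads_per_class=[2, 2], session_length_s=1500.0, seed=11
    )
    return generate_classroom(cfg)


@pytest.fixture(scope="session")
def default_classroom():
    """One full-scale classroom at the generator's default settings."""
    return generate_classroom(SyntheticConfig(seed=202))


@pytest.fixture
def toy_layout():
    return ClassroomLayout(
        [(1, 5), (2, 6), (3, 7), (4, 8)], {1: 0, 5: 0, 2: 0, 6: 0, 3: 1, 7: 1, 4: 1, 8: 1}
    )
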