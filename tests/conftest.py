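import warnings

import numpy as np
import pytest

from hergml.synthetic import SyntheticSpec, generate_descriptor_dataset, generate_activity_table

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def planted_data():
    """Balanced 120-compound matrix with 5 informative + 25 noise descriptors."""
    spec = SyntheticSpec(
        n_compounds=120, class_ratio=(1, 1), n_informative=5, n_noise=25,
        effect_size=1.5, seed=20240901,
    )
    X, y, planted = generate_descriptor_dataset(spec)
    return X, y, planted


@pytest.fixture(scope="session")
def separable_data():
    """Linearly separable two-class data: one descriptor fully decides the class."""
    rng = np.random.default_rng(7)
    n = 60
    y = np.array(["ACT"] * 30 + ["INA"] * 30)
    sep = np.where(y == "ACT", 1.0, -1.0) * (2.0 + rng.random(n))
    noise = rng.normal(0, 1, (n, 3))
    X = np.column_stack([sep, noise])
    return X, y


@pytest.fixture(scope="session")
def activity_fixture():
    """Raw activity export at modest scale with 2% sigma-outliers."""
    spec = SyntheticSpec(n_compounds=200, fraction_outliers=0.05, seed=11)
    table, truth = generate_activity_table(spec)
    return table, truth
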