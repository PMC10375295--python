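import numpy as np
import pytest

from siliqueseg.synthetic import PlantSpec, make_plant


@pytest.fixture(scope="session")
def small_plant():
    """A 25-silique plant, well separated, moderate density."""
    spec = PlantSpec(n_siliques=25, points_per_silique=800, stem_points=6000,
                     adhesion_fraction=0.0, seed=7)
    return make_plant(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
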