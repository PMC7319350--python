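import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    from samconf.synthetic import build_template

    return build_template()


@pytest.fixture(scope="session")
def water_components():
    from samconf.synthetic import water_mixture_components

    return water_mixture_components()


@pytest.fixture(scope="session")
def component_conformers(water_components):
    """Mean-geometry conformer of each default mixture component."""
    from samconf.synthetic import set_torsions

    return {
        c.name: set_torsions(c.torsion_targets(c.chi_mean), conf_id=c.name)
        for c in water_components
    }


@pytest.fixture(scope="session")
def small_bundle():
    """A 200-conformer noise-free ground-truth bundle (grid populations)."""
    import samconf as sc

    spec = sc.SyntheticSpec.water_default(n_conformers=200, seed=11)
    return sc.generate_bundle(spec)


@pytest.fixture(scope="session")
def table1():
    from samconf import load_reference_distances

    return load_reference_distances()


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation + translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-10, 10, size=3)
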