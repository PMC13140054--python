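import numpy as np
import pandas as pd
import pytest

from stemvb.imgseg import segment_section
from stemvb.synthdata import SectionSpec, simulate_cross_section


def small_section_spec(seed: int = 7, **overrides) -> SectionSpec:
    """A quarter-scale section that keeps unit tests fast."""
    params = dict(
        image_shape=(600, 600),
        stem_center=(300.0, 300.0),
        semi_axes=(4000.0, 3500.0),
        ez_thickness=240.0,
        pz_thickness=1200.0,
        n_pz_bundles=40,
        n_iz_bundles=15,
        seed=seed,
    )
    params.update(overrides)
    return SectionSpec(**params)


@pytest.fixture(scope="session")
def small_spec():
    return small_section_spec()


@pytest.fixture(scope="session")
def small_section(small_spec):
    return simulate_cross_section(small_spec)


@pytest.fixture(scope="session")
def default_section():
    """One full-scale section (the default spec) with its truth."""
    spec = SectionSpec(seed=7)
    image, truth = simulate_cross_section(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def default_segmentation(default_section):
    _, image, _ = default_section
    return segment_section(image)


def random_bundle_table(n: int, rng: np.random.Generator,
                        extent_um: float = 8000.0) -> pd.DataFrame:
    """Random accepted-bundle table around the origin, areas in µm²."""
    return pd.DataFrame({
        "centroid_x_um": rng.uniform(-extent_um, extent_um, n),
        "centroid_y_um": rng.uniform(-extent_um, extent_um, n),
        "area_um2": rng.uniform(1e4, 3e5, n),
        "zone": rng.choice(["PZ", "IZ"], n),
        "accepted": True,
    })
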