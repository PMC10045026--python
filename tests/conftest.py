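import numpy as np
import pytest

from hemodyn import segmentation as sg
from hemodyn import synthetic as sy
from hemodyn.fluids import FluidProperties


@pytest.fixture(scope="session")
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_lumen_spec() -> sy.PhantomSpec:
    """Two disks separated by a 2+ px septum, noiseless."""
    return sy.PhantomSpec(
        image_size=(96, 96),
        n_slices=3,
        lumens=(
            sy.LumenSpec(center=(48, 32), radii=(12, 12), intensity=200.0),
            sy.LumenSpec(center=(48, 66), radii=(10, 10), intensity=180.0),
        ),
        noise_sd=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def two_lumen_phantom(two_lumen_spec) -> sy.PhantomResult:
    return sy.gen_phantom_ct(two_lumen_spec)


@pytest.fixture(scope="session")
def tight_roi() -> sg.RegionOfInterest:
    """ROI drawn tightly around both lumens of the two-lumen phantom."""
    return sg.RegionOfInterest(32, 64, 16, 80)


@pytest.fixture(scope="session")
def poiseuille_field():
    spec = sy.AnalyticFieldSpec(kind="poiseuille")
    return spec, sy.gen_analytic_field(spec)
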