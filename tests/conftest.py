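import numpy as np
import pytest

from ringsym import AnalysisConfig, RadialBand, make_multishell_fixture
from ringsym.ringforge import PhantomSpec, ShellSpec, make_phantom


@pytest.fixture(scope="session")
def sring34():
    """Noiseless single-shell 34-fold fixture (image, spec)."""
    return make_multishell_fixture("sring34")


@pytest.fixture(scope="session")
def msring_shells():
    """Noiseless three-shell fixture with orders 23 / 11 / 34 inner-to-outer."""
    return make_multishell_fixture("msring_shells")


@pytest.fixture(scope="session")
def small_ring34():
    """A compact noiseless 34-fold phantom for fast per-test pipelines."""
    spec = PhantomSpec(
        image_size_px=160,
        shells=(ShellSpec(radius_px=60.0, order_n=34, blob_sigma_px=2.0),),
    )
    return make_phantom(spec, id="small34"), spec


@pytest.fixture()
def small_config():
    return AnalysisConfig(
        band=RadialBand(44.0, 76.0), n_theta=720, n_r=33, candidate_range=(20, 40)
    )


def ring_spec(n, size=128, radius=44.0, sigma=1.5, **kw):
    return PhantomSpec(
        image_size_px=size,
        shells=(ShellSpec(radius_px=radius, order_n=n, blob_sigma_px=sigma),),
        **kw,
    )
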