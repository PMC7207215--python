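import numpy as np
import pytest

from cropsuit.climate_io import MonthlyClimatology
from cropsuit.crop_params import CropParameters, load_crop_parameters
from cropsuit.synthetic import SyntheticClimateSpec


@pytest.fixture(scope="session")
def registry():
    return load_crop_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def simple_crop():
    """A 3-month crop with easy round-number thresholds."""
    return CropParameters(
        crop_name="testcrop",
        ktmp=0.0,
        t_abs_min=10.0,
        t_opt_min=20.0,
        t_opt_max=30.0,
        t_abs_max=40.0,
        r_abs_min=100.0,
        r_opt_min=300.0,
        r_opt_max=600.0,
        r_abs_max=1000.0,
        season_length=3,
    )


@pytest.fixture
def coarse_spec():
    """A fast 2-degree synthetic climate grid."""
    return SyntheticClimateSpec(spacing=2.0, seed=11)


def make_uniform_climatology(
    tmin=20.0, tmean=25.0, prec=150.0, n_lat=4, n_lon=5, period=(1971, 2000)
):
    """Spatially and seasonally uniform climatology for closed-form checks."""
    lats = np.linspace(3.0, 19.0, n_lat)
    lons = np.linspace(-18.0, 18.0, n_lon)
    shape = (n_lat, n_lon, 12)
    return MonthlyClimatology(
        lats=lats,
        lons=lons,
        tmin=np.full(shape, float(tmin)),
        tmean=np.full(shape, float(tmean)),
        prec=np.full(shape, float(prec)),
        mask=np.ones((n_lat, n_lon), dtype=bool),
        member_id="u01",
        period=period,
    )


@pytest.fixture
def uniform_clim():
    return make_uniform_climatology()
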