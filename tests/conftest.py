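import numpy as np
import pytest

from mesophot import (BasinSpec, GeoGrid, GridTransform, OpticalParams, delineate,
                      isolume_depth, kdpar_from_kd490, light_fields, make_basin,
                      make_ramp_fixture)

RAMP_KD = 0.1
RAMP_PAR = 40.0
RAMP_SLOPE = 2.5  # m per km


@pytest.fixture(scope="session")
def ramp():
    """Constant-optics, linear-ramp bathymetry with its analytic strip oracle."""
    kd, par, depth = make_ramp_fixture(RAMP_KD, RAMP_PAR, RAMP_SLOPE)
    kdpar, ez, pct = light_fields(kd, par, depth)
    zone = delineate(depth, ez)
    zstar = isolume_depth(RAMP_PAR, kdpar_from_kd490(RAMP_KD), zone.e_min)
    return {"kd490": kd, "par0": par, "depth": depth, "kdpar": kdpar,
            "ez": ez, "percent": pct, "zone": zone, "zstar": zstar,
            "slope": RAMP_SLOPE}


@pytest.fixture(scope="session")
def basin():
    """The default synthetic basin with gradients, land, and a coastal gap."""
    spec = BasinSpec(seed=11)
    kd, par, depth, land = make_basin(spec)
    kdpar, ez, pct = light_fields(kd, par, depth)
    zone = delineate(depth, ez)
    return {"spec": spec, "kd490": kd, "par0": par, "depth": depth,
            "land": land, "kdpar": kdpar, "ez": ez, "percent": pct, "zone": zone}


@pytest.fixture
def small_grid():
    rng = np.random.default_rng(42)
    v = rng.uniform(0.05, 0.3, (12, 16))
    v[2, 3] = np.nan
    return GeoGrid(v, GridTransform(10.0, 44.0, 0.25, 0.25), role="kd490")
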