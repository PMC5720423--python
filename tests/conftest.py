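import numpy as np
import pytest

import brachyresponse as br


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def water():
    return br.get_material("water")


@pytest.fixture(scope="session")
def detector_materials():
    return {name: br.get_material(name)
            for name in ("LiF", "Li2B4O7", "Al2O3", "diamond",
                         "silicon", "air")}


@pytest.fixture(scope="session")
def i125_water_tally():
    """Workhorse run: bare I-125 line source in the 20 cm water phantom,
    fluence scored at sixteen transverse distances.  Shared by the
    response, distance-independence and mean-energy checks."""
    cfg = br.load_preset("i125_water", n_histories=6_000_000, seed=20100728)
    return br.run_transport(cfg)


@pytest.fixture(scope="session")
def yb169_water_tally():
    """Bare Yb-169 line source in water, moderate statistics."""
    cfg = br.load_preset("yb169_water", n_histories=1_500_000, seed=19690413)
    return br.run_transport(cfg)


@pytest.fixture(scope="session")
def i125_response_tables(i125_water_tally, water, detector_materials):
    k_wat = br.kerma_from_tally(i125_water_tally, water)
    return {name: br.response_correction(
        br.kerma_from_tally(i125_water_tally, det), k_wat, det, water)
        for name, det in detector_materials.items()}


@pytest.fixture(scope="session")
def yb169_response_tables(yb169_water_tally, water, detector_materials):
    k_wat = br.kerma_from_tally(yb169_water_tally, water)
    return {name: br.response_correction(
        br.kerma_from_tally(yb169_water_tally, det), k_wat, det, water)
        for name, det in detector_materials.items()}
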