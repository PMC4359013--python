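import pytest

import linrelax as lr


@pytest.fixture(scope="session")
def acq():
    return lr.default_acquisition()


@pytest.fixture(scope="session")
def linked_phantom():
    """Brain phantom whose true R1 is generated by the linear model."""
    return lr.make_phantom(lr.linked_brain_spec(seed=3, grid_shape=(24, 24, 24)))


@pytest.fixture(scope="session")
def noiseless_series(linked_phantom, acq):
    return lr.simulate_mpm(linked_phantom, acq, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_qmaps(noiseless_series, linked_phantom):
    pdw, t1w, mtw = noiseless_series
    return lr.compute_quantitative_maps(pdw, t1w, mtw,
                                        b1_rel=linked_phantom.b1_rel)
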