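import pytest

import cestrecon as cr


@pytest.fixture(scope="session")
def pulse():
    return cr.SaturationPulse()


@pytest.fixture(scope="session")
def scanner():
    return cr.ScannerConfig()


@pytest.fixture(scope="session")
def bounds():
    return cr.default_bounds()


@pytest.fixture(scope="session")
def mid_tissue(bounds):
    return cr.midpoint_tissue(bounds)


def degenerate_bounds():
    """Bounds collapsed to their midpoints (LB == UB everywhere)."""
    b = cr.default_bounds()
    lo, hi = b.as_arrays()
    mid = 0.5 * (lo + hi)
    d = b.to_dict()
    d["water"] = {"t1": [mid[0], mid[0]], "t2": [mid[1], mid[1]]}
    from cestrecon.pools import SOLUTE_ROLES

    for j, role in enumerate(SOLUTE_ROLES):
        vals = mid[2 + 3 * j : 5 + 3 * j]
        d["solutes"][role.value] = {
            "fs": [vals[0], vals[0]],
            "ksw": [vals[1], vals[1]],
            "t2": [vals[2], vals[2]],
        }
    return cr.ParameterBounds.from_dict(d)


@pytest.fixture(scope="session")
def dataset5k():
    """Shared mid-sized simulated dataset (5,000 paired spectra)."""
    return cr.generate_dataset(5000, seed=123)


@pytest.fixture(scope="session")
def trained_small(dataset5k):
    """A TCN-LSTM trained briefly on the shared dataset; good enough for
    image-pipeline and consistency checks."""
    tcfg = cr.TrainingConfig(epochs=8, seed=123)
    model = cr.build_model(cr.ModelConfig(architecture="tcn_lstm"), seed=123)
    return cr.train(model, dataset5k, tcfg)
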