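import warnings

import pytest

from topoclan import synth
from topoclan.topology import ShortTMHelixWarning


@pytest.fixture(autouse=True)
def _quiet_short_tm():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortTMHelixWarning)
        yield


@pytest.fixture(scope="session")
def reentrant_family():
    """A 10H-2RH-Nout family with RH-blind predictions (the hard case)."""
    blueprint, annotation = synth.make_blueprint(10, "RH", "Nout")
    spec = synth.FamilySpec(
        blueprint=blueprint,
        annotation=annotation,
        n_sequences=12,
        seed=3,
        error_model=synth.PredictionErrorModel(p_miss_noncanonical=1.0),
    )
    return synth.generate_family(spec)


@pytest.fixture(scope="session")
def broken_family():
    """A 12H-2BH-Nin family with clean predictions and loop indels."""
    blueprint, annotation = synth.make_blueprint(12, "BH", "Nin")
    spec = synth.FamilySpec(
        blueprint=blueprint,
        annotation=annotation,
        n_sequences=10,
        seed=7,
        indel_rate=0.1,
    )
    return synth.generate_family(spec)
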