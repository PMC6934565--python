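from pathlib import Path

import numpy as np
import pytest

import ubidyn as u
from ubidyn.synth import ToyEnsembleSpec, gen_toy_ensemble

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference():
    return u.reference_peaklist()


@pytest.fixture(scope="session")
def uniform_dmax(reference):
    return u.ResidueSeries(
        values={k: (0.2, 0.0) for k in reference}, unit="ppm", metadata="dmax"
    )


@pytest.fixture(scope="session")
def toy_two_state():
    """Two-substate bead dimer with ground-truth labels and contacts."""
    return gen_toy_ensemble(
        ToyEnsembleSpec(
            beads_per_domain=20,
            n_substates=2,
            frames_per_substate=8,
            jitter_sigma=0.2,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def ub_like():
    """Packaged synthetic ubiquitin-like single-model backbone."""
    from ubidyn import io as uio

    return uio.read_ensemble(DATA / "synthetic_ub_like.pdb")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
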