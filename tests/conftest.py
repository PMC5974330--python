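from __future__ import annotations

import numpy as np
import pytest

from herbauth import simulate
from herbauth._dp import warm_up
from herbauth.its2_hmm import build_flank_hmms


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    warm_up()


@pytest.fixture(scope="session")
def flank_hmms():
    """Calibrated 5.8S-tail / 28S-head models from the packaged seeds."""
    return build_flank_hmms(seed=0)


@pytest.fixture(scope="session")
def refset3():
    """Three synthetic species at 5% divergence with private flank variants."""
    return simulate.make_reference_set(n_species=3, divergence=5.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
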