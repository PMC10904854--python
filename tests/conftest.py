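import sys
from pathlib import Path

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracles

import tileswitch as tw

CORE_MYC = "MVTELLGGDMVNQSFICDPDDETFIKNIIIQDCMWSGFSAAAKLVSEKLA"
TRRAP_PEPTIDE = "GVNSVSSSIKRGLSVDSAQEVKRFRTATGAISAVFGRSQSLPGADSLLAK"


@pytest.fixture(scope="session")
def cmyc():
    return tw.cmyc_sequence()


@pytest.fixture(scope="session")
def core_seq():
    return tw.ProteinSequence("coreMYC", CORE_MYC, numbering_offset=101)


@pytest.fixture(scope="session")
def compact_ens():
    """Collapsed 50-bead ensemble (shared across tests for speed)."""
    return tw.sample_chain(tw.compact_model(), 150, seed=2024)


@pytest.fixture(scope="session")
def extended_ens():
    """Extended 50-bead ensemble (shared across tests for speed)."""
    return tw.sample_chain(tw.extended_model(), 150, seed=2025)


@pytest.fixture(scope="session")
def toy():
    """Toy two-chain complex with stored brute-force oracle energies."""
    return tw.toy_complex(seed=3, n_frames=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
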