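import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hat_annotator.motifs import parse_motif
from hat_annotator.synthetic import synthetic_signature_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20180904)


@pytest.fixture(scope="session")
def anchor():
    """The degenerate 5-nt anchor used for TIR detection."""
    return parse_motif("(T/C)A(A/G)NG")


@pytest.fixture(scope="session")
def ac_spec():
    """Signature spec for the synthetic AC-numbered reference transposase."""
    return synthetic_signature_spec("AC")


@pytest.fixture(scope="session")
def hermes_spec():
    return synthetic_signature_spec("Hermes")
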