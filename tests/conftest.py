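import numpy as np
import pytest

from turnprint.fingerprint import InterfaceSplit
from turnprint.synth import make_multimer_stack, make_turn_peptide

AB_SPLIT = InterfaceSplit(frozenset("A"), frozenset("B"))


@pytest.fixture(scope="session")
def sharp_unit():
    """Single chain 25-31, sharp 25-29 turn, exposed key lysine, free C-term."""
    return make_turn_peptide(6.5, n_res=7, seed=1, span_between=(25, 29))


@pytest.fixture(scope="session")
def positive_trimer(sharp_unit):
    """Three well-separated sharp turns: a positive aggregate by construction."""
    return make_multimer_stack(sharp_unit, 3, 25.0, seed=2)


@pytest.fixture(scope="session")
def negative_fibril():
    """Nine 4.8 Å-spaced layers, wide turn, key lysine bridged to the chain's
    C-terminal carbonyl: negative by construction."""
    unit = make_turn_peptide(11.5, n_res=5, seed=4, key_dir="cterm")
    return make_multimer_stack(unit, 9, 4.8, seed=5)


@pytest.fixture
def rigid_transform():
    def _make(seed: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        Q, R = np.linalg.qr(A)
        Q = Q @ np.diag(np.sign(np.diag(R)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        return Q, rng.uniform(-20, 20, size=3)

    return _make
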