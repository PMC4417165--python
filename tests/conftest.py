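import numpy as np
import pytest

from mmdna import build_duplex, fiber_b_table, sequence_for


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def at_control():
    """Canonical A:T control duplex in the f2 environment."""
    return sequence_for("f2", "A", "T")


@pytest.fixture
def fiber_structure(at_control):
    """Straight fiber-like 13-mer build (rise 3.38 A, twist 36 deg)."""
    return build_duplex(at_control, fiber_b_table(13))


def random_table(rng, n_pairs=13, trans=3.0, rot=60.0,
                 rise_range=(2.0, 4.5)):
    """Random helical-parameter table within the stated draw box."""
    tab = fiber_b_table(n_pairs)
    tab.intra[:, :3] = rng.uniform(-trans, trans, (n_pairs, 3))
    tab.intra[:, 3:] = rng.uniform(-rot, rot, (n_pairs, 3))
    tab.inter[:, :2] = rng.uniform(-trans, trans, (n_pairs - 1, 2))
    tab.inter[:, 2] = rng.uniform(*rise_range, n_pairs - 1)
    tab.inter[:, 3:] = rng.uniform(-rot, rot, (n_pairs - 1, 3))
    return tab


# geometries (intra-pair parameters at the lesion) that realise specific
# hydrogen-bond topologies, established on the idealized base frames
GT_WOBBLE_INTRA = np.array([-2.0, -0.5, 0.0, 0.0, 0.0, 0.0])
GG_SCHEME_W_INTRA = np.array([0.25, 0.5, 0.0, 0.0, 0.0, 70.0])
GG_SCHEME_C_INTRA = np.array([-0.25, 0.5, 0.0, 0.0, 0.0, 70.0])
OPENED_INTRA = np.array([0.0, 3.5, 0.0, 0.0, 0.0, 0.0])
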