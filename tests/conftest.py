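import numpy as np
import pytest

from framefold.geometry import frames_from_structure
from framefold.losses import residue_templates
from framefold.oracle import make_reference


@pytest.fixture(scope="session")
def hairpin():
    """16-nt hairpin: 6-bp stem + 4-nt loop, with frames and templates."""
    beads, ss, full, sequence = make_reference("hairpin", stem=6, loop=4)
    return {
        "beads": beads,
        "ss": ss,
        "full": full,
        "sequence": sequence,
        "frames": frames_from_structure(beads, sequence),
        "local": residue_templates(sequence),
    }


@pytest.fixture(scope="session")
def duplex():
    """16-nt self-complementary duplex (8 pairs)."""
    beads, ss, full, sequence = make_reference("duplex", stem=8)
    return {
        "beads": beads,
        "ss": ss,
        "full": full,
        "sequence": sequence,
        "frames": frames_from_structure(beads, sequence),
        "local": residue_templates(sequence),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
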