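import numpy as np
import pytest

import stedspine as ss


@pytest.fixture
def sted():
    return ss.sted_preset()


@pytest.fixture
def twophoton():
    return ss.twophoton_preset()


@pytest.fixture
def small_scene():
    """A reproducible ~60-spine scene on 20 um of dendrite."""
    return ss.generate_scene(3.0, 20.0, seed=42)


def make_spine(x=1.0, azimuth=np.pi / 2, length=1.0, neck=0.15, head=0.36,
               spine_id="s0", born=0):
    return ss.Spine(
        spine_id=spine_id, x_pos=x, azimuth=azimuth, length=length,
        neck_diameter=neck, head_diameter_max=head, born_session=born,
    )


@pytest.fixture
def spine_factory():
    return make_spine
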