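import numpy as np
import pytest

from scratchdetect.dataset import FrameLabelTrack, build_dataset
from scratchdetect.synthvideo import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_synth_cfg():
    """Small, fast arena: 160x160 px, 10 s."""
    return SynthConfig(frame_px=(160, 160), n_frames=600, blob_axes=(22.0, 15.0),
                       appendage_radius=6.0, scratch_amp_px=13.0, groom_amp_px=9.0,
                       locomote_speed_px=2.0, seed=7)


def make_segset(labels, n_frames=None, px=8, seed=0, video_id="v0"):
    """SegmentSet with given frame labels over random tiny motion images."""
    labels = np.asarray(labels, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    motion = (rng.random((len(labels) - 1, px, px)) < 0.1).astype(np.uint8)
    return build_dataset([(motion, FrameLabelTrack(labels, video_id=video_id))])


@pytest.fixture
def segset_factory():
    return make_segset
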