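import numpy as np
import pytest

from engramkit import EpochSet, PoseTrack, TraceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(per_frame_step_cm, frame_rate=15.0, n_parts=10, jitter=0.0, rng=None):
    """Pose track whose centroid moves by the given step (cm) into each frame.

    Step i is the displacement from frame i-1 to frame i; the first entry is
    ignored (frame 0 has no predecessor).
    """
    steps = np.asarray(per_frame_step_cm, dtype=float)
    n = steps.size
    ang = 2 * np.pi * np.arange(n_parts) / n_parts
    offsets = 2.0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    centroid = np.zeros((n, 2))
    centroid[:, 0] = np.cumsum(np.concatenate([[0.0], steps[1:]]))
    pos = centroid[:, None, :] + offsets[None, :, :]
    if jitter and rng is not None:
        pos = pos + rng.normal(0, jitter, size=pos.shape)
    return PoseTrack(pos, frame_rate)


def trace_from_binned(binned, samples_per_bin=8):
    """TraceMatrix whose 1-s binned means equal ``binned`` exactly."""
    binned = np.atleast_2d(np.asarray(binned, dtype=float))
    values = np.repeat(binned, samples_per_bin, axis=1)
    return TraceMatrix(values, sample_rate=float(samples_per_bin))


@pytest.fixture
def fc_epochs():
    return EpochSet([("shock", 120, 130), ("shock", 180, 190),
                     ("shock", 240, 250), ("shock", 300, 310)])
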