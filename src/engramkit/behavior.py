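"""Pose-based freezing classification.

Freezing — the immobility response that indexes conditioned fear — is scored
from body-part tracking in two ways:

* the *online* (closed-loop) rule: a frame is freezing when at least
  ``min_immobile_parts`` of the tracked body parts move slower than
  0.5 cm/s.  The freezing-tag criterion uses 7 of 10 parts, the
  no-freezing-tag criterion 6 of 10, so that tagging errs on the side of
  purity for each condition;
* the *post-hoc* rule: a windowed count of frames whose centroid speed and
  head-direction change both fall under thresholds, with a minimum bout
  duration.  The original tool exposes five parameters (velocity threshold
  0.3 cm/s, angle threshold 12 deg, window width 32 frames, count threshold
  10 frames, minimum duration 0.5 s); the windowed-count contract
  implemented here is this package's own re-interpretation honoring all
  five literally, not a port.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .epochs import EpochSet, from_bool_array

#: default immobility threshold of the closed-loop system, cm/s
ONLINE_IMMOBILITY_CMS = 0.5
#: "freezing if >= 7 of 10 parts immobile" — freezing-tag criterion
FREEZING_TAG_MIN_PARTS = 7
#: "freezing if >= 6 of 10 parts immobile" — no-freezing-tag criterion
NO_FREEZING_TAG_MIN_PARTS = 6

DEFAULT_BODY_PARTS = (
    "nose", "neck", "ear_left", "ear_right", "side_left",
    "side_right", "middle_back", "hindleg_left", "hindleg_right", "tail_base",
)


@dataclass
class PoseTrack:
    """Frame x body-part x (x, y) positions in cm."""

    positions: np.ndarray          # (n_frames, n_parts, 2)
    frame_rate: float
    body_parts: Sequence[str] = DEFAULT_BODY_PARTS

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must be (n_frames, n_parts, 2)")
        if self.positions.shape[1] != len(self.body_parts):
            raise ValueError("body_parts length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class SpeedMatrix:
    """Per-frame, per-part speeds in cm/s; the first frame is defined as 0."""

    speeds: np.ndarray             # (n_frames, n_parts)
    frame_rate: float


@dataclass
class FreezingLabels:
    """Per-frame freezing labels plus the equivalent bout intervals.

    Bouts are the maximal runs of True frames converted to half-open second
    intervals (frame ``f`` covers ``[f/rate, (f+1)/rate)``), so the two
    representations are exactly interconvertible.
    """

    per_frame: np.ndarray          # bool, (n_frames,)
    frame_rate: float
    bouts: EpochSet = field(init=False)

    def __post_init__(self):
        self.per_frame = np.asarray(self.per_frame, dtype=bool)
        self.bouts = from_bool_array(self.per_frame, self.frame_rate, "freezing")

    @classmethod
    def from_bouts(cls, bouts: EpochSet, frame_rate: float, n_frames: int) -> "FreezingLabels":
        return cls(bouts.mask(frame_rate, n_frames), frame_rate)

    @property
    def n_frames(self) -> int:
        return self.per_frame.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def complement_bouts(self) -> EpochSet:
        return self.bouts.complement(0.0, self.duration_s, label="no-freezing")


def compute_speeds(track: PoseTrack) -> SpeedMatrix:
    """Per-part speed: displacement since the previous frame times frame rate."""
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames to compute speeds")
    disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=2)
    speeds = np.vstack([np.zeros((1, disp.shape[1])), disp * track.frame_rate])
    return SpeedMatrix(speeds=speeds, frame_rate=track.frame_rate)


def classify_freezing_online(
    speeds: SpeedMatrix,
    immobility_threshold: float = ONLINE_IMMOBILITY_CMS,
    min_immobile_parts: int = FREEZING_TAG_MIN_PARTS,
) -> FreezingLabels:
    """Closed-loop rule: freezing iff >= ``min_immobile_parts`` parts are immobile."""
    n_parts = speeds.speeds.shape[1]
    if not 1 <= min_immobile_parts <= n_parts:
        raise ValueError(f"min_immobile_parts must be in [1, {n_parts}]")
    immobile = speeds.speeds < immobility_threshold
    frozen = immobile.sum(axis=1) >= min_immobile_parts
    return FreezingLabels(frozen, speeds.frame_rate)


@dataclass
class PosthocParams:
    """The five parameters of the windowed post-hoc freezing classifier."""

    velocity_threshold: float = 0.3   # cm/s, centroid speed
    angle_threshold: float = 12.0     # deg/frame, head-direction change
    window_width: int = 32            # frames, centered window
    count_threshold: int = 10         # frames under both thresholds in window
    min_duration: float = 0.5         # s, minimum bout length

    def __post_init__(self):
        vals = (self.velocity_threshold, self.angle_threshold,
                self.window_width, self.count_threshold, self.min_duration)
        if any(v <= 0 for v in vals):
            raise ValueError("all post-hoc parameters must be positive")
        if self.count_threshold > self.window_width:
            raise ValueError("count_threshold cannot exceed window_width")


def _head_angle_change_deg(track: PoseTrack, nose: str, neck: str) -> np.ndarray:
    """Absolute per-frame change of the nose-neck vector angle, degrees.

    The first frame is 0; a zero-length vector keeps the previous angle.
    """
    parts = list(track.body_parts)
    v = track.positions[:, parts.index(nose), :] - track.positions[:, parts.index(neck), :]
    ang = np.arctan2(v[:, 1], v[:, 0])
    degenerate = np.hypot(v[:, 0], v[:, 1]) == 0
    if degenerate.any():           # carry last defined angle forward
        for f in range(track.n_frames):
            if degenerate[f]:
                ang[f] = ang[f - 1] if f > 0 else 0.0
    d = np.diff(ang)
    d = np.abs((d + np.pi) % (2 * np.pi) - np.pi)    # wrap to [-pi, pi]
    return np.degrees(np.concatenate([[0.0], d]))


def classify_freezing_posthoc(
    track: PoseTrack,
    params: PosthocParams | None = None,
    nose: str = "nose",
    neck: str = "neck",
) -> FreezingLabels:
    """Windowed post-hoc rule on centroid speed and head-direction change.

    A frame is a candidate iff it satisfies both thresholds (centroid speed
    under ``velocity_threshold`` and head-direction change under
    ``angle_threshold``) *and* at least ``count_threshold`` frames within
    its centered ``window_width``-frame window (truncated at the track
    edges) do too — the windowed count validates a frame against its
    neighborhood so isolated sub-threshold frames inside motion are not
    called freezing.  Candidate runs shorter than ``min_duration`` are
    discarded, so a 0.4-s still interval flanked by motion yields no bout.
    """
    params = params or PosthocParams()
    if track.n_frames < params.window_width:
        raise ValueError("track shorter than the classifier window")
    centroid = track.positions.mean(axis=1)
    disp = np.linalg.norm(np.diff(centroid, axis=0), axis=1)
    centroid_speed = np.concatenate([[0.0], disp * track.frame_rate])
    dangle = _head_angle_change_deg(track, nose, neck)

    ok = (centroid_speed < params.velocity_threshold) & (dangle < params.angle_threshold)
    half = params.window_width // 2
    csum = np.concatenate([[0], np.cumsum(ok)])
    n = track.n_frames
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (params.window_width - half), 0, n)
    counts = csum[hi] - csum[lo]
    candidate = ok & (counts >= params.count_threshold)

    min_frames = params.min_duration * track.frame_rate - 1e-9
    keep = np.zeros(n, dtype=bool)
    f = 0
    while f < n:
        if candidate[f]:
            g = f
            while g < n and candidate[g]:
                g += 1
            if g - f >= min_frames:
                keep[f:g] = True
            f = g
        else:
            f += 1
    return FreezingLabels(keep, track.frame_rate)


@dataclass
class FreezingReport:
    """Per-epoch freezing percentages and the light ON-OFF delta."""

    per_epoch: List[tuple]         # (label, start, end, pct)
    delta: float | None            # mean %ON - mean %OFF, None if labels absent


def freezing_metrics(
    labels: FreezingLabels,
    epochs: EpochSet,
    on_label: str = "ON",
    off_label: str = "OFF",
) -> FreezingReport:
    """Percent time frozen per epoch, and Dfreezing = mean %ON - mean %OFF."""
    rows = []
    for label, s, e in epochs:
        if e <= s:
            raise ValueError(f"zero-length epoch ({label}: {s}, {e})")
        pct = 100.0 * labels.bouts.overlap_duration(s, e) / (e - s)
        rows.append((label, s, e, pct))
    on = [r[3] for r in rows if r[0] == on_label]
    off = [r[3] for r in rows if r[0] == off_label]
    delta = (float(np.mean(on)) - float(np.mean(off))) if on and off else None
    return FreezingReport(per_epoch=rows, delta=delta)
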