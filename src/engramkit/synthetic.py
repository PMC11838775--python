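"""Synthetic sessions with known ground truth.

Emulates what the downstream statistics consume from a miniscope + behavior
experiment: a pose track whose body-part speeds encode freezing bouts, a
cells x samples fluorescence matrix with period-tuned planted ensembles,
field-of-view positions, and a cross-session registration map with
drop-out.

The generator's defaults are the study conditions: sessions follow the
printed protocol timelines (FC: 7 min with 2-s shocks at minutes 2-5);
90 cells per session (the reported per-session average); freezing is a
two-state Markov dwell process (exponential bout/inter-bout durations,
defaults 5 s / 10 s, i.e. one-third time frozen, typical of post-shock
contextual fear); background calcium events are Poisson at 0.02 events/s
and planted cells fire at ``gain_in_period`` x baseline inside their
condition epochs (default gain 10 — no effect sizes are reported for real
tagged cells, so the gain is a free parameter; 10 gives unambiguous
in-period tuning at these epoch lengths); each event is convolved with a
0.5-s single-exponential calcium kernel (fast-indicator-like) and Gaussian
noise is added; registration keeps each cell independently with
probability 0.7.

Only speed statistics of the pose track matter; the 10 body parts are a
rigid ring around a centroid random walk, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .behavior import DEFAULT_BODY_PARTS, FreezingLabels, PoseTrack
from .cross_session import RegistrationMap
from .ensembles import CellPositions, FC_GROUPS
from .epochs import EpochSet
from .events import TraceMatrix
from . import tagging

BACKGROUND = "background"


@dataclass
class SessionSpec:
    """Physical layout of one synthetic session."""

    duration_s: float = 420.0
    frame_rate_behavior: float = 15.0
    sample_rate_trace: float = 20.0
    n_cells: int = 90
    shock_onsets_s: Sequence[float] = (120.0, 180.0, 240.0, 300.0)
    shock_duration_s: float = 2.0
    context_label: str = "ctxA"
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        onsets = list(self.shock_onsets_s)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("shock onsets must be strictly increasing")
        if any(t + self.shock_duration_s > self.duration_s for t in onsets):
            raise ValueError("shock extends past session end")

    @classmethod
    def from_timeline(cls, timeline: tagging.SessionTimeline, **kwargs) -> "SessionSpec":
        return cls(duration_s=timeline.duration_s,
                   shock_onsets_s=tuple(timeline.shock_onsets()),
                   context_label=timeline.protocol_label, **kwargs)

    def timeline(self) -> tagging.SessionTimeline:
        shocks = EpochSet(("shock", t, t + self.shock_duration_s) for t in self.shock_onsets_s)
        return tagging.SessionTimeline(self.duration_s, shocks, self.context_label)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic session."""

    planted_membership: Dict[int, str] = field(default_factory=dict)  # cell -> group
    gain_in_period: float = 10.0
    baseline_event_rate: float = 0.02          # events/s
    registration_keep_prob: float = 0.7
    freezing_mean_bout_s: float = 5.0
    freezing_mean_interbout_s: float = 10.0
    kernel_tau_s: float = 0.5
    event_amplitude: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self):
        if not 0 <= self.registration_keep_prob <= 1:
            raise ValueError("registration_keep_prob must be a probability")
        if self.gain_in_period < 1:
            raise ValueError("gain_in_period must be >= 1")
        if self.freezing_mean_bout_s < 0 or self.freezing_mean_interbout_s <= 0:
            raise ValueError("dwell parameters must be positive (bout mean may be 0)")
        if self.kernel_tau_s <= 0:
            raise ValueError("kernel decay constant must be positive")

    def groups(self) -> Dict[str, set]:
        out: Dict[str, set] = {}
        for cell, g in self.planted_membership.items():
            if g != BACKGROUND:
                out.setdefault(g, set()).add(cell)
        return out


def plant_membership(n_cells: int, groups: Sequence[str] = FC_GROUPS,
                     group_size: int = 16,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> Dict[int, str]:
    """Disjoint planted groups of ``group_size`` cells each; rest background."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    if group_size * len(groups) > n_cells:
        raise ValueError("planted groups exceed the population")
    order = rng.permutation(n_cells)
    out = {int(c): BACKGROUND for c in range(n_cells)}
    for gi, g in enumerate(groups):
        for c in order[gi * group_size:(gi + 1) * group_size]:
            out[int(c)] = g
    return out


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _dwell_bouts(duration: float, mean_bout: float, mean_inter: float,
                 rng: np.random.Generator) -> List[Tuple[float, float]]:
    """Alternating exponential dwell process; returns freezing intervals."""
    if mean_bout == 0:
        return []
    p_frozen = mean_bout / (mean_bout + mean_inter)
    frozen = bool(rng.random() < p_frozen)     # stationary initial state
    t, bouts = 0.0, []
    while t < duration:
        dwell = rng.exponential(mean_bout if frozen else mean_inter)
        end = min(t + dwell, duration)
        if frozen and end > t:
            bouts.append((t, end))
        t, frozen = end, not frozen
    return bouts


def generate_behavior(
    spec: SessionSpec,
    truth: GroundTruth,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Tuple[PoseTrack, FreezingLabels]:
    """Pose track plus the generating freezing labels.

    Bouts are drawn in continuous time, bouts shorter than one frame
    dropped, then rasterized to frames (midpoint rule).  The displacement
    into each frame is small (< 0.5 cm/s for every part) when that frame
    is frozen and large (> 0.5 cm/s for every part) otherwise, so the
    labels are recoverable frame-for-frame from the speeds (except frame
    0, whose speed is 0 by definition).
    """
    rng = rng if rng is not None else np.random.default_rng(seed if seed is not None else spec.seed)
    rate = spec.frame_rate_behavior
    n_frames = int(round(spec.duration_s * rate))
    bouts = [(s, e) for s, e in _dwell_bouts(spec.duration_s, truth.freezing_mean_bout_s,
                                             truth.freezing_mean_interbout_s, rng)
             if (e - s) >= 1.0 / rate]
    per_frame = EpochSet(("freezing", s, e) for s, e in bouts).mask(rate, n_frames)
    labels = FreezingLabels(per_frame, rate)

    n_parts = len(DEFAULT_BODY_PARTS)
    ang = 2 * np.pi * np.arange(n_parts) / n_parts
    offsets = 1.5 * np.stack([np.cos(ang), np.sin(ang)], axis=1)   # cm ring

    # centroid random walk: step into frame f depends on frame f's state
    step_mag = np.where(per_frame, 0.003, 0.3)                     # cm/frame
    headings = np.cumsum(rng.normal(0, 0.3, size=n_frames))
    steps = step_mag[:, None] * np.stack([np.cos(headings), np.sin(headings)], axis=1)
    steps[0] = 0.0
    centroid = np.array([12.0, 12.0]) + np.cumsum(steps, axis=0)

    # jitter kept small even when moving so bout-entry frames (previous
    # frame's jitter still in the displacement) stay under 0.5 cm/s
    jitter_mag = np.where(per_frame, 0.002, 0.01)[:, None, None]
    jitter = rng.normal(0, 1.0, size=(n_frames, n_parts, 2))
    jitter *= jitter_mag / np.maximum(np.linalg.norm(jitter, axis=2, keepdims=True), 1e-12)
    positions = centroid[:, None, :] + offsets[None, :, :] + jitter
    return PoseTrack(positions, rate, DEFAULT_BODY_PARTS), labels


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _sample_times_in(intervals: EpochSet, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` uniform times within the union of ``intervals``."""
    merged = list(intervals.merged())
    if not merged:
        return np.empty(0)
    lens = np.array([e - s for _, s, e in merged])
    picks = rng.choice(len(merged), size=n, p=lens / lens.sum())
    u = rng.random(n)
    starts = np.array([merged[i][1] for i in picks])
    return starts + u * lens[picks]


def generate_traces(
    spec: SessionSpec,
    truth: GroundTruth,
    epochs: EpochSet,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Tuple[TraceMatrix, Dict[int, np.ndarray]]:
    """Fluorescence traces with planted period-tuned cells.

    ``epochs`` carries one label per planted condition; a planted cell
    fires Poisson events at ``gain_in_period x baseline`` inside its
    condition's epochs and at baseline outside.  Events are convolved with
    an exponential-decay kernel; Gaussian noise is added last.  Returns
    the trace matrix and the ground-truth event times per cell.
    """
    rng = rng if rng is not None else np.random.default_rng(seed if seed is not None else spec.seed)
    present = set(epochs.labels)
    for g in set(truth.planted_membership.values()) - {BACKGROUND}:
        if g not in present or epochs.select(g).total_duration() == 0:
            raise ValueError(f"planted group {g!r} has no epochs: group untestable")

    sr = spec.sample_rate_trace
    n_samples = int(round(spec.duration_s * sr))
    t_grid = np.arange(n_samples) / sr
    lam = truth.baseline_event_rate
    tau, amp = truth.kernel_tau_s, truth.event_amplitude
    tail = int(np.ceil(10 * tau * sr))

    values = np.zeros((spec.n_cells, n_samples))
    true_events: Dict[int, np.ndarray] = {}
    for c in range(spec.n_cells):
        g = truth.planted_membership.get(c, BACKGROUND)
        if g == BACKGROUND:
            in_set = EpochSet()
        else:
            in_set = epochs.select(g).merged()
        d_in = in_set.total_duration()
        out_set = in_set.complement(0.0, spec.duration_s, "out") if d_in else \
            EpochSet([("out", 0.0, spec.duration_s)])
        d_out = out_set.total_duration()
        n_in = rng.poisson(truth.gain_in_period * lam * d_in) if d_in else 0
        n_out = rng.poisson(lam * d_out) if d_out else 0
        times = np.sort(np.concatenate([
            _sample_times_in(in_set, n_in, rng) if n_in else np.empty(0),
            _sample_times_in(out_set, n_out, rng) if n_out else np.empty(0),
        ]))
        true_events[c] = times
        for te in times:
            i0 = int(np.ceil(te * sr - 1e-12))
            i1 = min(i0 + tail, n_samples)
            if i0 < n_samples:
                values[c, i0:i1] += amp * np.exp(-(t_grid[i0:i1] - te) / tau)
    if truth.noise_sd > 0:
        values += rng.normal(0, truth.noise_sd, size=values.shape)
    return TraceMatrix(values, sr, list(range(spec.n_cells))), true_events


# ---------------------------------------------------------------------------
# registration and positions
# ---------------------------------------------------------------------------

def generate_registration(
    n_cells_a: int,
    keep_prob: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    keep_prob_by_group: Dict[str, float] | None = None,
    membership: Dict[int, str] | None = None,
    shuffle: bool = True,
) -> RegistrationMap:
    """Cross-session tracking with uniform (or per-group) drop-out.

    Each session-A cell is kept independently with ``keep_prob`` (or the
    group-specific probability when given); kept cells get fresh,
    optionally shuffled, session-B indices.
    """
    if not 0 <= keep_prob <= 1:
        raise ValueError("keep_prob must be a probability")
    rng = rng if rng is not None else np.random.default_rng(seed)
    probs = np.full(n_cells_a, keep_prob)
    if keep_prob_by_group:
        if membership is None:
            raise ValueError("per-group keep probabilities need a membership map")
        for c in range(n_cells_a):
            g = membership.get(c, BACKGROUND)
            probs[c] = keep_prob_by_group.get(g, keep_prob)
    kept = np.flatnonzero(rng.random(n_cells_a) < probs)
    b_ids = rng.permutation(len(kept)) if shuffle else np.arange(len(kept))
    return RegistrationMap(list(zip(kept.tolist(), b_ids.tolist())))


def generate_positions(n_cells: int, seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       fov_um: Tuple[float, float] = (400.0, 400.0)) -> CellPositions:
    """Uniform cell positions in a rectangular field of view (microns)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    xy = rng.random((n_cells, 2)) * np.asarray(fov_um)
    return CellPositions(list(range(n_cells)), xy)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

PRESETS = {"fc": "FC", "recall": "RECALL", "ctxB": "ctxB", "ctxC": "ctxC"}


@dataclass
class SessionBundle:
    """Everything one synthetic session produces, plus its ground truth."""

    preset: str
    spec: SessionSpec
    truth: GroundTruth
    timeline: tagging.SessionTimeline
    track: PoseTrack
    labels: FreezingLabels
    condition_epochs: Dict[str, EpochSet]
    traces: TraceMatrix
    true_events: Dict[int, np.ndarray]
    positions: CellPositions
    seed: int


def condition_epochs_for(preset: str, timeline: tagging.SessionTimeline,
                         labels: FreezingLabels) -> Dict[str, EpochSet]:
    """Per-condition planting/detection epochs for a preset.

    FC sessions use the tagging-scheduler light epochs of the four
    acquisition conditions; recall sessions use the freezing bouts and
    their complement (detection for recall groups runs on whole periods,
    not a 40-s budget).  Neutral contexts have no conditions.
    """
    if preset == "fc":
        out = {}
        for cond in FC_GROUPS:
            plan = tagging.schedule(cond, timeline, labels=labels)
            out[cond] = EpochSet((cond, s, e) for _, s, e in plan.light_epochs)
        return out
    if preset == "recall":
        frz = EpochSet(("freezing", s, e) for _, s, e in labels.bouts)
        no_frz = EpochSet(("no-freezing", s, e) for _, s, e in labels.complement_bouts())
        return {"freezing": frz, "no-freezing": no_frz}
    return {}


_PRESET_GROUPS = {"fc": FC_GROUPS, "recall": ("freezing", "no-freezing")}


def generate_session(
    preset: str = "fc",
    seed: int = 0,
    truth: GroundTruth | None = None,
    spec: SessionSpec | None = None,
    group_size: int = 16,
) -> SessionBundle:
    """One fully formed synthetic session for a named protocol preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; known: {tuple(PRESETS)}")
    timeline = tagging.build_timeline(PRESETS[preset])
    if spec is None:
        spec = SessionSpec.from_timeline(timeline, seed=seed)
    rng = np.random.default_rng(seed)
    if truth is None:
        groups = _PRESET_GROUPS.get(preset, ())
        membership = plant_membership(spec.n_cells, groups, group_size, rng=rng) \
            if groups else {}
        truth = GroundTruth(planted_membership=membership)
    track, labels = generate_behavior(spec, truth, rng=rng)
    cond = condition_epochs_for(preset, timeline, labels)
    all_epochs = EpochSet([iv for eps in cond.values() for iv in eps])
    traces, true_events = generate_traces(spec, truth, all_epochs, rng=rng)
    positions = generate_positions(spec.n_cells, rng=rng)
    return SessionBundle(preset, spec, truth, timeline, track, labels,
                         cond, traces, true_events, positions, seed)


@dataclass
class Experiment:
    """An FC session, a recall session of the same animal, and their map."""

    fc: SessionBundle
    recall: SessionBundle
    registration: RegistrationMap
    seed: int


def generate_experiment(seed: int = 0, truth: GroundTruth | None = None,
                        group_size: int = 16) -> Experiment:
    """Paired FC + recall sessions sharing planted cells through registration.

    Freezing-/no-freezing-planted FC cells stay tuned to (non-)freezing
    bouts at recall; shock- and pre-shock-planted cells revert to
    background there, since their driving condition is absent.
    """
    ss = np.random.SeedSequence(seed)
    s_fc, s_reg, s_rec = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3))
    fc = generate_session("fc", seed=s_fc, truth=truth, group_size=group_size)
    reg = generate_registration(fc.spec.n_cells, fc.truth.registration_keep_prob,
                                seed=s_reg)
    a2b = reg.a_to_b()
    n_recall = fc.spec.n_cells
    mem_recall = {b: BACKGROUND for b in range(n_recall)}
    for a, b in reg.pairs:
        g = fc.truth.planted_membership.get(a, BACKGROUND)
        if g in ("freezing", "no-freezing"):
            mem_recall[b] = g
    truth_recall = GroundTruth(
        planted_membership=mem_recall,
        gain_in_period=fc.truth.gain_in_period,
        baseline_event_rate=fc.truth.baseline_event_rate,
        registration_keep_prob=fc.truth.registration_keep_prob,
        freezing_mean_bout_s=fc.truth.freezing_mean_bout_s,
        freezing_mean_interbout_s=fc.truth.freezing_mean_interbout_s,
        kernel_tau_s=fc.truth.kernel_tau_s,
        event_amplitude=fc.truth.event_amplitude,
        noise_sd=fc.truth.noise_sd,
    )
    rec_timeline = tagging.build_timeline("RECALL")
    rec_spec = SessionSpec.from_timeline(rec_timeline, n_cells=n_recall, seed=s_rec)
    recall = generate_session("recall", seed=s_rec, truth=truth_recall, spec=rec_spec)
    return Experiment(fc=fc, recall=recall, registration=reg, seed=seed)
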