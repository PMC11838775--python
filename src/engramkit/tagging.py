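"""Session timelines and tagging-epoch scheduling.

The closed-loop tagging system delivers blue light during condition-specific
windows of a behavioral session; a cell is tagged when light coincides with
its calcium activity.  This module reconstructs, for each tagging condition,
the light-delivery epochs the experiment would have produced:

===============  ==============================================================
condition        light epochs
===============  ==============================================================
pre-shock        the two minutes preceding the first shock
shock            10 s during-and-after each shock (2-s shock + 8 s), 4 x 10 s
freezing         freezing bouts after the 3rd shock's offset, up to 40 s
no-freezing      non-freezing time after the 2nd shock's offset, up to 40 s
recall-frz       freezing bouts of the recall session, up to 40 s
recall-no-frz    non-freezing time of the recall session, up to 40 s
sweeping         the four caller-supplied 10-s dot sweeps, verbatim
imm-shock        the entire 40-s immediate-shock session
grouped-shock    2:00-2:40 of the grouped-shock session
===============  ==============================================================

"After the Nth shock" means after the shock's *offset* (onset + 2 s): light
during the shock itself belongs to the shock condition.  Budgeted conditions
accumulate eligible time in order and truncate the last epoch so that the
total equals exactly min(budget, eligible time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .behavior import FreezingLabels
from .epochs import EpochSet

SHOCK_DURATION_S = 2.0
SHOCK_LIGHT_S = 10.0
LIGHT_BUDGET_S = 40.0
PRE_SHOCK_WINDOW_S = 120.0

PROTOCOLS = ("FC", "RECALL", "ctxB", "ctxC", "sweeping", "immediate_shock", "grouped_shock")
CONDITIONS = ("pre-shock", "shock", "freezing", "no-freezing",
              "recall-frz", "recall-no-frz", "sweeping", "imm-shock", "grouped-shock")

#: protocol -> (session duration s, shock onsets s)
_TIMELINES = {
    "FC": (420.0, (120.0, 180.0, 240.0, 300.0)),
    "RECALL": (480.0, ()),
    "ctxB": (420.0, ()),
    "ctxC": (480.0, ()),
    "sweeping": (480.0, ()),
    "immediate_shock": (40.0, (2.0, 8.0, 14.0, 20.0)),
    "grouped_shock": (300.0, (120.0, 126.0, 132.0, 138.0)),
}


@dataclass
class SessionTimeline:
    duration_s: float
    shocks: EpochSet
    protocol_label: str

    def __post_init__(self):
        prev_end = 0.0
        for _, s, e in self.shocks:
            if s < 0 or e > self.duration_s:
                raise ValueError("shock epoch outside session")
            if s < prev_end:
                raise ValueError("overlapping shock epochs")
            prev_end = e

    def shock_onsets(self):
        return self.shocks.starts

    def shock_offsets(self):
        return self.shocks.ends


@dataclass
class TaggingPlan:
    """Light-delivery epochs for one tagging condition.

    ``total_light_s`` is the scheduler's accumulated total; for budgeted
    conditions it equals min(budget, eligible time) exactly, by
    construction, rather than a re-summation of interval lengths.
    """

    condition: str
    light_epochs: EpochSet
    budget_s: Optional[float]      # None when the condition carries no budget
    eligibility_start_s: float
    shortfall: bool = False        # eligible time did not fill the budget
    total_light_s: float = 0.0

    def __post_init__(self):
        if not self.total_light_s:
            self.total_light_s = self.light_epochs.total_duration()


def build_timeline(protocol_label: str) -> SessionTimeline:
    """Timeline of one of the named behavioral protocols (printed shock times)."""
    if protocol_label not in _TIMELINES:
        raise ValueError(f"unknown protocol {protocol_label!r}; known: {PROTOCOLS}")
    duration, onsets = _TIMELINES[protocol_label]
    shocks = EpochSet(("shock", t, t + SHOCK_DURATION_S) for t in onsets)
    return SessionTimeline(duration_s=duration, shocks=shocks, protocol_label=protocol_label)


def _accumulate(eligible: EpochSet, budget: float, label: str) -> tuple[EpochSet, float, bool]:
    """First ``budget`` seconds of ``eligible`` time, last epoch truncated.

    When the budget is reached the final take is ``budget - acc``, so the
    accumulated total equals the budget exactly in floating point.
    """
    out, acc = [], 0.0
    for _, s, e in eligible.merged():
        if acc >= budget:
            break
        if e - s < budget - acc:
            take = e - s
            acc += take
        else:
            take = budget - acc
            acc = budget
        out.append((label, s, s + take))
    return EpochSet(out), acc, acc < budget


def schedule(
    condition: str,
    timeline: SessionTimeline,
    labels: FreezingLabels | None = None,
    budget_s: float = LIGHT_BUDGET_S,
    sweep_epochs: EpochSet | None = None,
) -> TaggingPlan:
    """Light-delivery plan for ``condition`` on ``timeline``.

    ``labels`` is required for the freezing-dependent conditions.  For
    no-freezing plans, pass labels classified with the 6-of-10-part
    criterion so that light only falls on frames with fewer than 6 immobile
    parts, as the closed-loop protocol did.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; known: {CONDITIONS}")
    T = timeline.duration_s
    onsets = timeline.shock_onsets()
    offsets = timeline.shock_offsets()

    if condition in ("freezing", "no-freezing", "recall-frz", "recall-no-frz"):
        if labels is None:
            raise ValueError(f"condition {condition!r} requires freezing labels")

    if condition == "pre-shock":
        if len(onsets) == 0:
            raise ValueError("pre-shock condition needs at least one shock")
        t1 = float(onsets[0])
        epochs = EpochSet([("light", max(0.0, t1 - PRE_SHOCK_WINDOW_S), t1)])
        return TaggingPlan(condition, epochs, None, max(0.0, t1 - PRE_SHOCK_WINDOW_S))

    if condition == "shock":
        epochs = EpochSet(("light", t, min(t + SHOCK_LIGHT_S, T)) for t in onsets)
        return TaggingPlan(condition, epochs, None, float(onsets[0]) if len(onsets) else 0.0)

    if condition == "sweeping":
        if sweep_epochs is None:
            raise ValueError("sweeping condition requires sweep_epochs")
        epochs = EpochSet(("light", s, e) for _, s, e in sweep_epochs)
        return TaggingPlan(condition, epochs, None, 0.0)

    if condition == "imm-shock":
        return TaggingPlan(condition, EpochSet([("light", 0.0, T)]), None, 0.0)

    if condition == "grouped-shock":
        start = float(onsets[0]) if len(onsets) else 120.0
        return TaggingPlan(condition, EpochSet([("light", start, start + 40.0)]), None, start)

    if condition == "freezing":
        if len(offsets) < 3:
            raise ValueError("freezing condition needs at least three shocks")
        start = float(offsets[2])
        eligible = labels.bouts.clip(start, T)
    elif condition == "no-freezing":
        if len(offsets) < 2:
            raise ValueError("no-freezing condition needs at least two shocks")
        start = float(offsets[1])
        eligible = labels.complement_bouts().clip(start, T)
    elif condition == "recall-frz":
        start = 0.0
        eligible = labels.bouts.clip(0.0, T)
    else:  # recall-no-frz
        start = 0.0
        eligible = labels.complement_bouts().clip(0.0, T)

    epochs, total, shortfall = _accumulate(eligible, budget_s, "light")
    return TaggingPlan(condition, epochs, budget_s, start, shortfall, total)
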