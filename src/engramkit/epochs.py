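"""Labeled half-open time intervals.

Every stage of the pipeline — shock timelines, light-delivery plans,
freezing bouts, condition epochs for ensemble detection — is expressed as a
set of labeled ``[start, end)`` intervals in seconds from session start.
Frames and 1-s bins are mapped onto epochs by the *midpoint rule*: frame
``f`` at rate ``r`` covers ``[f/r, (f+1)/r)`` and belongs to an epoch iff
its midpoint does.  For full-second epochs and 1-s bins this coincides with
containment.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator, Sequence, Tuple

import numpy as np

Interval = Tuple[str, float, float]


class EpochSet:
    """An ordered collection of labeled half-open intervals ``[start, end)``.

    Intervals are kept sorted by start time.  Overlaps between intervals of
    different labels are allowed (e.g. a shock epoch inside a light epoch);
    most derived quantities (durations, masks) operate on the merged union.
    """

    __slots__ = ("_labels", "_starts", "_ends")

    def __init__(self, intervals: Iterable[Interval] = ()):
        rows = sorted(((str(l), float(s), float(e)) for l, s, e in intervals),
                      key=lambda r: (r[1], r[2]))
        for label, s, e in rows:
            if not (math.isfinite(s) and math.isfinite(e)):
                raise ValueError(f"non-finite epoch bounds ({label}: {s}, {e})")
            if e < s:
                raise ValueError(f"epoch end before start ({label}: {s}, {e})")
        self._labels = tuple(r[0] for r in rows)
        self._starts = np.array([r[1] for r in rows], dtype=float)
        self._ends = np.array([r[2] for r in rows], dtype=float)

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[Interval]:
        return iter(zip(self._labels, self._starts, self._ends))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (self._labels == other._labels
                and np.array_equal(self._starts, other._starts)
                and np.array_equal(self._ends, other._ends))

    def __repr__(self) -> str:
        inner = ", ".join(f"{l}[{s:g},{e:g})" for l, s, e in self)
        return f"EpochSet({inner})"

    @property
    def labels(self) -> Tuple[str, ...]:
        return self._labels

    @property
    def starts(self) -> np.ndarray:
        return self._starts.copy()

    @property
    def ends(self) -> np.ndarray:
        return self._ends.copy()

    # -- selection and algebra ----------------------------------------------------

    def select(self, label: str) -> "EpochSet":
        """Sub-set of intervals carrying ``label``."""
        return EpochSet((l, s, e) for l, s, e in self if l == label)

    def merged(self, label: str | None = None) -> "EpochSet":
        """Union of all intervals as maximal disjoint intervals.

        Adjacent intervals (end == next start) are fused.  Labels are
        replaced by ``label`` (default: label of the first fused member).
        """
        out = []
        for l, s, e in self:
            if s == e:
                continue
            if out and s <= out[-1][2]:
                out[-1][2] = max(out[-1][2], e)
            else:
                out.append([label if label is not None else l, s, e])
        return EpochSet((l, s, e) for l, s, e in out)

    def intersect(self, other: "EpochSet", label: str | None = None) -> "EpochSet":
        """Pairwise intersection with the merged form of ``other``.

        Labels of ``self`` are kept unless ``label`` overrides them.
        """
        om = other.merged()
        out = []
        for l, s, e in self:
            for _, os_, oe in om:
                lo, hi = max(s, os_), min(e, oe)
                if hi > lo:
                    out.append((label if label is not None else l, lo, hi))
        return EpochSet(out)

    def clip(self, t0: float, t1: float) -> "EpochSet":
        return self.intersect(EpochSet([("window", t0, t1)]))

    def complement(self, t0: float, t1: float, label: str = "complement") -> "EpochSet":
        """Gaps of the merged union within ``[t0, t1)``."""
        out = []
        cursor = t0
        for _, s, e in self.merged():
            if e <= t0 or s >= t1:
                continue
            if s > cursor:
                out.append((label, cursor, min(s, t1)))
            cursor = max(cursor, e)
        if cursor < t1:
            out.append((label, cursor, t1))
        return EpochSet(out)

    def union(self, other: "EpochSet") -> "EpochSet":
        return EpochSet(list(self) + list(other))

    # -- durations and rasterization ---------------------------------------------

    def total_duration(self) -> float:
        """Length of the merged union in seconds (overlaps counted once)."""
        return float(sum(e - s for _, s, e in self.merged()))

    def span_durations(self) -> np.ndarray:
        """Per-interval lengths, in stored order (overlaps not deduplicated)."""
        return self._ends - self._starts

    def overlap_duration(self, start: float, end: float) -> float:
        """Length of the merged union falling inside ``[start, end)``."""
        return self.clip(start, end).total_duration()

    def mask(self, rate: float, n: int) -> np.ndarray:
        """Boolean membership of ``n`` frames/bins at ``rate`` Hz (midpoint rule)."""
        mid = (np.arange(n) + 0.5) / float(rate)
        out = np.zeros(n, dtype=bool)
        for _, s, e in self.merged():
            out |= (mid >= s) & (mid < e)
        return out

    def bin_mask(self, n_bins: int, bin_width: float = 1.0) -> np.ndarray:
        """Membership of ``n_bins`` contiguous bins of ``bin_width`` seconds."""
        return self.mask(1.0 / bin_width, n_bins)


def from_bool_array(per_frame: Sequence[bool], rate: float, label: str) -> EpochSet:
    """Maximal runs of True frames as half-open intervals in seconds."""
    arr = np.asarray(per_frame, dtype=bool)
    if arr.size == 0:
        return EpochSet()
    d = np.diff(arr.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if arr[0]:
        starts = [0] + starts
    if arr[-1]:
        ends = ends + [arr.size]
    return EpochSet((label, s / rate, e / rate) for s, e in zip(starts, ends))
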