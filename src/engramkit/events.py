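"""Calcium-event extraction from fluorescence traces.

Traces are averaged into non-overlapping 1-s bins, each cell's binned
series is z-scored (its own mean, population SD), values below 2 SD are
zeroed, and calcium "events" are the strict local maxima of the surviving
values.  The result is a binary cells x 1-s-bins event raster: 0 for a
second without events, 1 for a second with at least one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

Z_CUT_SD = 2.0


@dataclass
class TraceMatrix:
    """Cells x samples fluorescence with its sampling rate."""

    values: np.ndarray             # (n_cells, n_samples)
    sample_rate: float             # Hz
    cell_ids: Sequence[int] | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.values.shape[1] < 60:
            raise ValueError("traces must span at least 60 samples")
        if self.cell_ids is None:
            self.cell_ids = list(range(self.values.shape[0]))
        self.cell_ids = list(self.cell_ids)
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class EventRaster:
    """Binary cells x 1-s-bin event array."""

    events: np.ndarray             # (n_cells, n_bins), values in {0, 1}
    cell_ids: Sequence[int]
    bin_width: float = 1.0

    def __post_init__(self):
        self.events = np.atleast_2d(np.asarray(self.events))
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event raster must be binary")
        self.events = self.events.astype(np.uint8)
        self.cell_ids = list(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.events.shape[0]

    @property
    def n_bins(self) -> int:
        return self.events.shape[1]


@dataclass
class BinnedZ:
    """Thresholded z-scored binned traces; zero-variance cells are flagged."""

    values: np.ndarray             # (n_cells, n_bins), 0 where z < 2
    cell_ids: Sequence[int]
    flagged: List[int] = field(default_factory=list)   # zero-variance cell ids


def bin_trace(trace: TraceMatrix, bin_width: float = 1.0) -> np.ndarray:
    """Average each cell into non-overlapping ``bin_width``-second windows.

    The trailing partial window is dropped.
    """
    spb = int(round(trace.sample_rate * bin_width))
    if spb < 1:
        raise ValueError("sample_rate below one sample per bin")
    n_bins = trace.n_samples // spb
    if n_bins < 1:
        raise ValueError("trace shorter than one bin")
    v = trace.values[:, : n_bins * spb]
    return v.reshape(trace.n_cells, n_bins, spb).mean(axis=2)


def zscore_cut(binned: np.ndarray, cell_ids: Sequence[int] | None = None,
               z_cut: float = Z_CUT_SD) -> BinnedZ:
    """Z-score each row (own mean, population SD) and zero values below ``z_cut``.

    Rows with zero variance cannot be z-scored; they come back all-zero and
    flagged rather than silently dropped.
    """
    binned = np.atleast_2d(np.asarray(binned, dtype=float))
    if cell_ids is None:
        cell_ids = list(range(binned.shape[0]))
    mu = binned.mean(axis=1, keepdims=True)
    sd = binned.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (binned - mu) / sd_safe
    z[z < z_cut] = 0.0
    z[flat] = 0.0
    return BinnedZ(values=z, cell_ids=list(cell_ids),
                   flagged=[cid for cid, f in zip(cell_ids, flat) if f])


def bin_and_zscore(trace: TraceMatrix, z_cut: float = Z_CUT_SD) -> BinnedZ:
    """Bin in 1-s windows, z-score per cell, zero activity below ``z_cut`` SD."""
    return zscore_cut(bin_trace(trace), trace.cell_ids, z_cut)


def detect_events(z: BinnedZ) -> EventRaster:
    """Mark bins holding a strict local maximum of the surviving z values.

    A bin is an event iff its value is positive and strictly greater than
    both neighbors (boundary bins: the single neighbor).  Plateaus of tied
    values yield no event under strict inequality.
    """
    v = z.values
    n = v.shape[1]
    ev = np.zeros_like(v, dtype=np.uint8)
    if n == 1:
        ev[:, 0] = v[:, 0] > 0
    else:
        left = np.concatenate([v[:, :1] * 0 - np.inf, v[:, :-1]], axis=1)
        right = np.concatenate([v[:, 1:], v[:, -1:] * 0 - np.inf], axis=1)
        ev[(v > 0) & (v > left) & (v > right)] = 1
    return EventRaster(events=ev, cell_ids=z.cell_ids)


def extract_events(trace: TraceMatrix, z_cut: float = Z_CUT_SD) -> EventRaster:
    """Full pipeline: bin, z-score with the 2-SD cut, detect event peaks."""
    return detect_events(bin_and_zscore(trace, z_cut))


def event_rate(raster: EventRaster) -> np.ndarray:
    """Per-cell average events per second (mean of each binary row)."""
    if raster.n_bins == 0:
        raise ValueError("empty raster")
    return raster.events.mean(axis=1) / raster.bin_width
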