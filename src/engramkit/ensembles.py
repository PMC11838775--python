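"""Ensemble (cell-group) detection.

Two detection routes mirror the tagging emulation:

* *activity ranking*: average each cell's raw trace over the condition
  epochs (the putative tagging period); cells whose in-epoch mean exceeds
  the across-cell mean plus one population SD belong to the group.
* *statistical*: per cell, the ratio of mean binned activity inside vs
  outside the condition epochs is compared to the same ratio under
  ``n_shifts`` random circular shifts of the cell's binned series; the
  cell is a member iff its real ratio strictly exceeds the nearest-rank
  95th percentile of that null.

Both operate per condition, so a cell can belong to several groups.
Group topography is summarized by asymmetric mean nearest-neighbor
distances between group positions in the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

import numpy as np
from scipy.spatial.distance import cdist

from ._stats import nearest_rank_percentile
from .behavior import FreezingLabels
from .epochs import EpochSet
from .events import TraceMatrix, bin_trace

FC_GROUPS = ("pre-shock", "shock", "freezing", "no-freezing")
RECALL_GROUPS = ("frz-recall", "no-frz-recall")


@dataclass
class CellPositions:
    """Cell centroid positions (microns) in the miniscope field of view."""

    cell_ids: Sequence[int]
    xy: np.ndarray                 # (n_cells, 2)

    def __post_init__(self):
        self.cell_ids = list(self.cell_ids)
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.cell_ids), 2)
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite positions")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    def of(self, ids: Sequence[int]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.cell_ids)}
        return self.xy[[index[c] for c in ids]]


@dataclass
class GroupDetection:
    """Outcome of one group detection (one condition, one method)."""

    members: Set[int]
    method: str                    # "rank" | "statistical"
    threshold: float | None = None           # rank: mean + n_sd * SD cut
    statistics: Dict[int, float] = field(default_factory=dict)
    null_p95: Dict[int, float] = field(default_factory=dict)
    flagged: List[int] = field(default_factory=list)


def in_epoch_mean(trace: TraceMatrix, epochs: EpochSet) -> np.ndarray:
    """Per-cell mean of the raw trace over epoch-covered samples."""
    mask = epochs.mask(trace.sample_rate, trace.n_samples)
    if not mask.any():
        raise ValueError("epochs cover no samples")
    return trace.values[:, mask].mean(axis=1)


def detect_rank(trace: TraceMatrix, epochs: EpochSet, n_sd: float = 1.0) -> GroupDetection:
    """Activity-ranking detection: in-epoch mean > mean + ``n_sd`` population SD.

    The threshold is taken over the across-cell distribution of in-epoch
    means; the inequality is strict, so a flat distribution (SD 0) yields
    an empty group.
    """
    means = in_epoch_mean(trace, epochs)
    thr = float(means.mean() + n_sd * means.std(ddof=0))
    members = {cid for cid, m in zip(trace.cell_ids, means) if m > thr}
    return GroupDetection(members=members, method="rank", threshold=thr,
                          statistics=dict(zip(trace.cell_ids, means.tolist())))


def _in_out_ratio(in_sum: float, k: int, total: float, n: int) -> float:
    """Mean-in over mean-out; +inf when out-activity is non-positive but in is."""
    out_mean = (total - in_sum) / (n - k)
    in_mean = in_sum / k
    if out_mean <= 0:
        return np.inf if in_mean > 0 else np.nan
    return in_mean / out_mean


def detect_statistical(
    trace: TraceMatrix,
    epochs: EpochSet,
    n_shifts: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bin_width: float = 1.0,
) -> GroupDetection:
    """Circular-shift detection on the binned (pre-threshold) series.

    Null replicates whose shifted out-of-epoch activity is non-positive
    (undefined ratio) are resampled; all-zero cells are flagged
    non-members.  Offsets are uniform integers in [1, n_bins - 1].
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    binned = bin_trace(trace, bin_width)
    n = binned.shape[1]
    in_mask = epochs.bin_mask(n, bin_width)
    k = int(in_mask.sum())
    if k == 0 or k == n:
        raise ValueError("need both in-epoch and out-of-epoch bins")
    in_idx = np.flatnonzero(in_mask)

    members: Set[int] = set()
    stats: Dict[int, float] = {}
    p95s: Dict[int, float] = {}
    flagged: List[int] = []
    for row, cid in zip(binned, trace.cell_ids):
        if not np.any(row):
            flagged.append(cid)
            stats[cid] = np.nan
            continue
        total = float(row.sum())
        real = _in_out_ratio(float(row[in_idx].sum()), k, total, n)
        null = np.empty(n_shifts)
        filled = 0
        attempts = 0
        while filled < n_shifts:
            m = n_shifts - filled
            offs = rng.integers(1, n, size=m)
            in_sums = row[(in_idx[None, :] - offs[:, None]) % n].sum(axis=1)
            vals = (in_sums / k) / ((total - in_sums) / (n - k))
            ok = (total - in_sums) > 0
            good = vals[ok]
            null[filled:filled + good.size] = good
            filled += good.size
            attempts += 1
            if attempts > 50 and filled == 0:
                # out-activity non-positive for every shift: degenerate cell
                flagged.append(cid)
                break
        else:
            q95 = nearest_rank_percentile(null, 95.0)
            stats[cid] = real
            p95s[cid] = q95
            if np.isfinite(real) and real > q95:
                members.add(cid)
            elif np.isinf(real) and real > 0:
                members.add(cid)
            continue
        stats[cid] = real
    return GroupDetection(members=members, method="statistical",
                          statistics=stats, null_p95=p95s, flagged=flagged)


def detect_groups(
    trace: TraceMatrix,
    condition_epochs: Dict[str, EpochSet],
    method: str = "rank",
    **kwargs,
) -> Dict[str, GroupDetection]:
    """Run one detection method for every condition in ``condition_epochs``."""
    detect = {"rank": detect_rank, "statistical": detect_statistical}[method]
    return {g: detect(trace, eps, **kwargs) for g, eps in condition_epochs.items()}


def recall_groups(
    trace_recall: TraceMatrix,
    freezing_labels: FreezingLabels,
    method: str = "rank",
    **kwargs,
) -> Dict[str, GroupDetection]:
    """Frz-recall / no-frz-recall groups from recall-session freezing bouts."""
    frz = freezing_labels.bouts
    if len(frz) == 0:
        raise ValueError("no freezing bouts: frz-recall group undefined")
    no_frz = freezing_labels.complement_bouts()
    if len(no_frz) == 0:
        raise ValueError("no non-freezing time: no-frz-recall group undefined")
    return detect_groups(trace_recall, {"frz-recall": frz, "no-frz-recall": no_frz},
                         method=method, **kwargs)


def nearest_group_distance(
    positions: CellPositions,
    members_x: Set[int],
    members_y: Set[int],
) -> float:
    """Mean over X of the distance to the closest Y cell (asymmetric).

    When a cell belongs to both groups its self-distance is excluded.
    """
    if not members_x or not members_y:
        raise ValueError("both groups must be nonempty")
    xs = sorted(members_x)
    ys = sorted(members_y)
    d = cdist(positions.of(xs), positions.of(ys))
    for i, cx in enumerate(xs):
        for j, cy in enumerate(ys):
            if cx == cy:
                d[i, j] = np.inf
    mins = d.min(axis=1)
    if not np.all(np.isfinite(mins)):
        raise ValueError("a cell's only neighbor is itself")
    return float(mins.mean())
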