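"""Cross-session reactivation metrics.

Groups detected during fear conditioning (FC) are carried into other
sessions through a cell-registration map, and their re-engagement is
quantified:

* *relative reactivation*: (fraction of a group's cells tracked into
  recall) / (fraction of all FC cells tracked).  Chance is 1: e.g. with
  100 FC cells of which 70 are tracked, a 10-cell group with 5 tracked
  scores (5/10)/(70/100) = 50%/70% = 0.71.
* per-group recall event rates, split into freezing-bout and
  non-freezing bins, with the in/out ratio flagged (not dropped) when the
  out-rate is zero;
* group composition: the percentage of each FC group's tracked cells that
  are members of the recall freezing ensemble.

The "others" group — cells detected in both sessions belonging to none of
the four FC groups — is computed for parity in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .behavior import FreezingLabels
from .events import EventRaster

OTHERS = "others"


@dataclass
class RegistrationMap:
    """Injective correspondence between cell ids of two sessions."""

    pairs: Sequence[Tuple[int, int]]

    def __post_init__(self):
        self.pairs = [(int(a), int(b)) for a, b in self.pairs]
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("registration map must be injective on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_ids(self) -> Set[int]:
        return {a for a, _ in self.pairs}

    @property
    def b_ids(self) -> Set[int]:
        return {b for _, b in self.pairs}

    def a_to_b(self) -> Dict[int, int]:
        return dict(self.pairs)


@dataclass
class ReactivationRow:
    """Per-group reactivation metrics; None marks undefined quantities."""

    group: str
    group_size: int
    tracked: int
    relative: Optional[float] = None
    rate: Optional[float] = None               # events/s over the session
    rate_in_freezing: Optional[float] = None
    rate_out_freezing: Optional[float] = None
    in_out_ratio: Optional[float] = None
    ratio_undefined: bool = False              # out-rate was zero
    pct_frz_recall: Optional[float] = None
    animal: Optional[str] = None


def others_group(reg: RegistrationMap, membership: Dict[str, Set[int]]) -> Set[int]:
    """Tracked FC cells that belong to none of the named groups."""
    in_any: Set[int] = set().union(*membership.values()) if membership else set()
    return reg.a_ids - in_any


def relative_reactivation(
    reg: RegistrationMap,
    group: Set[int],
    n_cells_fc: int,
) -> float:
    """Tracked fraction of ``group`` relative to the overall tracked fraction."""
    if n_cells_fc <= 0:
        raise ValueError("n_cells_fc must be positive")
    if not group:
        raise ValueError("empty group")
    overall = len(reg) / n_cells_fc
    if overall == 0:
        raise ValueError("no cells tracked overall")
    return (len(group & reg.a_ids) / len(group)) / overall


def recall_activity(
    reg: RegistrationMap,
    membership: Dict[str, Set[int]],
    raster_recall: EventRaster,
    labels_recall: FreezingLabels,
    n_cells_fc: int | None = None,
    animal: str | None = None,
    include_others: bool = True,
) -> List[ReactivationRow]:
    """Per-group recall event rates inside/outside freezing bouts.

    Rates are means over tracked members of per-cell rates; the group-level
    in/out ratio divides the two mean rates and is flagged undefined when
    the out-rate is zero.  Groups with zero tracked members yield a row of
    absent-value markers.
    """
    a2b = reg.a_to_b()
    row_of = {cid: i for i, cid in enumerate(raster_recall.cell_ids)}
    in_mask = labels_recall.bouts.bin_mask(raster_recall.n_bins, raster_recall.bin_width)
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())

    groups = dict(membership)
    if include_others:
        groups[OTHERS] = others_group(reg, membership)

    rows: List[ReactivationRow] = []
    for gname, gcells in groups.items():
        tracked_b = [a2b[c] for c in gcells if c in a2b and a2b[c] in row_of]
        row = ReactivationRow(group=gname, group_size=len(gcells),
                              tracked=len(tracked_b), animal=animal)
        if gcells:
            n_fc = n_cells_fc if n_cells_fc is not None else len(membership_universe(reg, membership))
            row.relative = relative_reactivation(reg, gcells, n_fc)
        if tracked_b:
            ev = raster_recall.events[[row_of[b] for b in tracked_b]]
            row.rate = float(ev.mean()) / raster_recall.bin_width
            if n_in:
                row.rate_in_freezing = float(ev[:, in_mask].mean()) / raster_recall.bin_width
            if n_out:
                row.rate_out_freezing = float(ev[:, ~in_mask].mean()) / raster_recall.bin_width
            if row.rate_in_freezing is not None and row.rate_out_freezing is not None:
                if row.rate_out_freezing > 0:
                    row.in_out_ratio = row.rate_in_freezing / row.rate_out_freezing
                else:
                    row.ratio_undefined = True
        rows.append(row)
    return rows


def membership_universe(reg: RegistrationMap, membership: Dict[str, Set[int]]) -> Set[int]:
    """All FC cell ids known to the report: group members plus tracked cells."""
    out: Set[int] = set(reg.a_ids)
    for cells in membership.values():
        out |= cells
    return out


def recall_group_composition(
    reg: RegistrationMap,
    membership_fc: Dict[str, Set[int]],
    frz_recall_members: Set[int],
) -> Dict[str, Optional[float]]:
    """Percentage of each FC group's tracked cells in the frz-recall group.

    ``frz_recall_members`` are recall-session cell ids.  Groups with zero
    tracked members map to None.
    """
    a2b = reg.a_to_b()
    out: Dict[str, Optional[float]] = {}
    for gname, gcells in membership_fc.items():
        tracked = [a2b[c] for c in gcells if c in a2b]
        if not tracked:
            out[gname] = None
        else:
            hit = sum(1 for b in tracked if b in frz_recall_members)
            out[gname] = 100.0 * hit / len(tracked)
    return out
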