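"""Pairwise event-raster correlations and their circular-shift null.

Pearson correlations are computed between every unordered pair of binary
event arrays (1-s bins).  The null model circularly shifts each cell's
event array by an independent uniform offset and recomputes the pair
correlations; shifting preserves every cell's event count exactly while
destroying pairwise timing, so the null controls for firing rates and
sample size.

A group slice (e.g. freezing-freezing intra-correlations) is declared
significantly correlated when its observed mean r strictly exceeds the
nearest-rank 95th percentile of the per-replicate mean r over the same
pair set (one-sided, alpha = 0.05 by default).  The test statistic is this
package's own definition.

Implementation note: because a circular shift only changes the pairwise
cross term, null correlations are evaluated through each pair's full
circular cross-correlation (computed once by FFT and rounded back to the
exact integer counts), then indexed at the replicate's relative offset.
``materialize_replicate`` reconstructs the explicitly shifted raster so the
fast path can be cross-checked against direct correlation of the shifted
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._stats import nearest_rank_percentile
from .events import EventRaster

UNDERPOWERED_REPLICATES = 20


@dataclass
class CorrelationTable:
    """Observed pair correlations plus the excluded-cell list."""

    pairs: pd.DataFrame            # cell_i, cell_j, r, group_i, group_j
    excluded: List[Tuple[int, str]]
    membership: Dict[str, Set[int]] = field(default_factory=dict)
    session: str = ""

    def pair_mask(self, group_a: str, group_b: str) -> np.ndarray:
        """Unordered slice: pairs with one cell in each group (both, if equal)."""
        in_a_i = self.pairs.cell_i.isin(self.membership.get(group_a, set()))
        in_a_j = self.pairs.cell_j.isin(self.membership.get(group_a, set()))
        in_b_i = self.pairs.cell_i.isin(self.membership.get(group_b, set()))
        in_b_j = self.pairs.cell_j.isin(self.membership.get(group_b, set()))
        return ((in_a_i & in_b_j) | (in_a_j & in_b_i)).to_numpy()


@dataclass
class NullCorrelations:
    """Per-replicate pair correlations under independent circular shifts."""

    r: np.ndarray                  # (n_replicates, n_pairs)
    pair_index: pd.DataFrame       # cell_i, cell_j aligned with columns of r
    offsets: np.ndarray            # (n_replicates, n_cells) shift per cell
    cell_order: List[int]          # cell ids aligned with offset columns
    n_replicates: int
    seed: Optional[int]


def _group_labels(cid: int, membership: Dict[str, Set[int]]) -> str:
    gs = sorted(g for g, cells in membership.items() if cid in cells)
    return "|".join(gs)


def pairwise_correlations(
    raster: EventRaster,
    membership: Dict[str, Set[int]] | None = None,
    session: str = "",
) -> CorrelationTable:
    """Pearson r for every unordered pair of cells with nonzero variance.

    Zero-variance cells appear in the excluded list with a reason rather
    than being silently dropped.
    """
    membership = membership or {}
    ev = raster.events.astype(float)
    var = ev.var(axis=1)
    keep = var > 0
    excluded = [(cid, "zero variance") for cid, k in zip(raster.cell_ids, keep) if not k]
    ids = [cid for cid, k in zip(raster.cell_ids, keep) if k]
    if len(ids) < 2:
        raise ValueError("need at least two cells with nonzero variance")
    corr = np.corrcoef(ev[keep])
    iu, ju = np.triu_indices(len(ids), k=1)
    rows = pd.DataFrame({
        "cell_i": [ids[i] for i in iu],
        "cell_j": [ids[j] for j in ju],
        "r": corr[iu, ju],
        "group_i": [_group_labels(ids[i], membership) for i in iu],
        "group_j": [_group_labels(ids[j], membership) for j in ju],
    })
    return CorrelationTable(pairs=rows, excluded=excluded,
                            membership=membership, session=session)


def null_correlations(
    raster: EventRaster,
    table: CorrelationTable,
    n_replicates: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullCorrelations:
    """Circular-shift null for the pair set of ``table``.

    Every included cell is shifted by an independent uniform offset in
    [1, n_bins - 1] per replicate; r is recomputed for every pair.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ids = sorted(set(table.pairs.cell_i) | set(table.pairs.cell_j))
    row_of = {cid: i for i, cid in enumerate(raster.cell_ids)}
    x = raster.events[[row_of[c] for c in ids]].astype(float)
    n_cells, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 bins")
    offsets = rng.integers(1, n, size=(n_replicates, n_cells))

    s1 = x.sum(axis=1)
    s2 = (x * x).sum(axis=1)
    denom_cell = n * s2 - s1 * s1           # shift-invariant per cell

    fx = np.fft.rfft(x, axis=1)
    col = {cid: i for i, cid in enumerate(ids)}
    pi = table.pairs.cell_i.map(col).to_numpy()
    pj = table.pairs.cell_j.map(col).to_numpy()
    # full circular cross-correlation per pair: c[d] = sum_u x_i[u] x_j[(u+d) % n]
    cross = np.fft.irfft(np.conj(fx[pi]) * fx[pj], n=n, axis=1)
    cross = np.rint(cross)                  # event counts are integers

    d = (offsets[:, pi] - offsets[:, pj]) % n           # (reps, pairs)
    c = cross[np.arange(len(pi))[None, :], d]
    num = n * c - s1[pi] * s1[pj]
    den = np.sqrt(denom_cell[pi] * denom_cell[pj])
    r = num / den
    return NullCorrelations(r=r, pair_index=table.pairs[["cell_i", "cell_j"]].copy(),
                            offsets=offsets, cell_order=ids,
                            n_replicates=n_replicates, seed=seed)


def materialize_replicate(
    raster: EventRaster,
    null: NullCorrelations,
    replicate: int,
) -> EventRaster:
    """The explicitly shifted raster of one null replicate (for cross-checks)."""
    row_of = {cid: i for i, cid in enumerate(raster.cell_ids)}
    x = raster.events[[row_of[c] for c in null.cell_order]]
    shifted = np.empty_like(x)
    for i, off in enumerate(null.offsets[replicate]):
        shifted[i] = np.roll(x[i], off)
    return EventRaster(events=shifted, cell_ids=null.cell_order,
                       bin_width=raster.bin_width)


@dataclass
class GroupNullComparison:
    group_pair: Tuple[str, str]
    n_pairs: int
    observed_mean: float
    null_means: np.ndarray
    p95: float
    significant: bool
    underpowered: bool
    observed_r: np.ndarray         # sorted, for cumulative-distribution export
    null_r: np.ndarray             # pooled over replicates, sorted


def compare_group_to_null(
    table: CorrelationTable,
    null: NullCorrelations,
    group_pair: Tuple[str, str],
    alpha: float = 0.05,
) -> GroupNullComparison:
    """One-sided test of a group slice's mean r against the shift null."""
    mask = table.pair_mask(*group_pair)
    if not mask.any():
        raise ValueError(f"no pairs in slice {group_pair}")
    obs_r = np.sort(table.pairs.r.to_numpy()[mask])
    observed = float(obs_r.mean())
    null_means = null.r[:, mask].mean(axis=1)
    p95 = nearest_rank_percentile(null_means, 100.0 * (1 - alpha))
    underpowered = null.n_replicates < UNDERPOWERED_REPLICATES
    return GroupNullComparison(
        group_pair=group_pair, n_pairs=int(mask.sum()),
        observed_mean=observed, null_means=null_means, p95=p95,
        significant=bool(observed > p95), underpowered=underpowered,
        observed_r=obs_r, null_r=np.sort(null.r[:, mask].ravel()),
    )
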