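"""Small shared statistical helpers."""

from __future__ import annotations

import math

import numpy as np


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * m)-th smallest of m values."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("percentile of empty sample")
    k = max(1, math.ceil(q / 100.0 * v.size))
    return float(v[k - 1])
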