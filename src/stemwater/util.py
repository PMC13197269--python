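"""Shared numeric conventions: the package-wide percentile and gap policy."""

from __future__ import annotations

import numpy as np

__all__ = ["percentile", "DAY_COMPLETENESS"]

# Fraction of expected samples a calendar day must have to be retained.
DAY_COMPLETENESS = 0.8


def percentile(values, p: float) -> float:
    """Linear-interpolation percentile, the single convention used everywhere.

    Equivalent to ``numpy.percentile(..., method="linear")``: the p-th
    percentile interpolates between order statistics at rank
    ``(n − 1)·p/100``.  Raises on empty or all-NaN input rather than
    returning NaN silently.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("percentile of empty (or all-missing) input")
    if not 0 <= p <= 100:
        raise ValueError(f"percentile p must be in [0, 100], got {p}")
    return float(np.percentile(arr, p, method="linear"))
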