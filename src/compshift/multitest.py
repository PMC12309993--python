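"""Benjamini-Hochberg step-up adjustment with NA passthrough."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust"]


def bh_adjust(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values.

    Sorts the m finite p-values ascending, forms p_(i) * m / i, and
    enforces monotonicity by a reverse cumulative minimum, capped at 1.
    NaN entries are ignored for m and returned as NaN in place.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = ~np.isnan(p)
    pf = p[finite]
    if ((pf < 0) | (pf > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    restored = np.empty(m)
    restored[order] = adj
    out[finite] = restored
    return out
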