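"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np

__all__ = ["fdr_correct"]


def fdr_correct(p, family_size=None):
    """Benjamini–Hochberg step-up adjusted p-values.

    ``family_size`` makes the size of the test family explicit; it may
    exceed the number of p-values supplied, in which case the remaining
    family members are treated as nonsignificant (p = 1), which only
    affects the scaling ``m * p / rank``.  Valid under independence and
    positive dependence of the tests.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a nonempty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
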