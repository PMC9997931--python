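"""Benjamini-Hochberg and Benjamini-Yekutieli step-up adjustments.

Note that a second adjustment pass is not idempotent in general (the step-up
minimum has already been applied), so adjusted vectors should not be fed
back into :func:`adjust`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["adjust", "DEFAULT_PAIRING"]

#: Per-detector default FDR procedure: BY for the mean/variance GLM detector
#: (its Wald p-values need the more conservative correction), BH elsewhere.
DEFAULT_PAIRING = {
    "levene": "bh",
    "mdseq": "by",
    "robust": "bh",
    "gamlss": "bh",
}


def adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Step-up adjusted p-values.

    BH: ``q_(i) = min_{j>=i} p_(j) * n / j``.  BY multiplies by the harmonic
    sum ``1 + 1/2 + ... + 1/n``.  Values are capped at 1; NaNs propagate.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    if n == 0:
        return out
    method = method.lower()
    if method not in ("bh", "by"):
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    if method == "by":
        ranked *= np.sum(1.0 / np.arange(1, n + 1))
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(n)
    adj[order] = q
    out[ok] = adj
    return out
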