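"""Sign-validated consensus workflow for over-dispersed gene discovery.

DE genes are called with the covariate-capable detector, dispersion calls
are made among the remaining (non-DE) genes per detector, sensitive
detectors are validated against the robust detector's fold-change signs,
and the validated DD+ sets are unioned with provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dispersim.detectors.base import DetectorResult

__all__ = [
    "GeneCalls",
    "call_de_genes",
    "call_dd_among_non_de",
    "validate_signs",
    "union_dd_plus",
    "MIN_SAMPLES_PER_CONDITION",
]

logger = logging.getLogger(__name__)

#: Analysis mode refuses smaller datasets unless forced.
MIN_SAMPLES_PER_CONDITION = 30


@dataclass
class GeneCalls:
    """DE partition plus per-method DD calls restricted to non-DE genes."""

    de_up: set = field(default_factory=set)
    de_down: set = field(default_factory=set)
    non_de: set = field(default_factory=set)
    dd_up: dict[str, set] = field(default_factory=dict)
    dd_down: dict[str, set] = field(default_factory=dict)


def call_de_genes(
    result: DetectorResult, alpha: float = 0.05
) -> tuple[set, set, set]:
    """Partition genes into (DE+, DE-, non-DE) from adjusted mean p-values."""
    if result.q_mean is None:
        raise ValueError("result has no adjusted p-values; call .adjusted() first")
    ids = np.asarray(result.gene_ids)
    sig = result.q_mean < alpha
    up = set(ids[sig & (result.log2_mean_fc > 0)])
    down = set(ids[sig & (result.log2_mean_fc <= 0)])
    non_de = set(ids) - up - down
    return up, down, non_de


def call_dd_among_non_de(
    results: dict[str, DetectorResult],
    non_de: set,
    alpha: float = 0.05,
) -> tuple[dict[str, set], dict[str, set]]:
    """Per-method DD+ / DD- sets within the non-DE genes."""
    dd_up: dict[str, set] = {}
    dd_down: dict[str, set] = {}
    for name, res in results.items():
        if res.q_disp is None:
            raise ValueError(f"{name}: no adjusted p-values; call .adjusted() first")
        ids = np.asarray(res.gene_ids)
        in_scope = np.isin(ids, list(non_de))
        sig = (res.q_disp < alpha) & in_scope
        dd_up[name] = set(ids[sig & (res.log2_disp_fc > 0)])
        dd_down[name] = set(ids[sig & (res.log2_disp_fc <= 0)])
    return dd_up, dd_down


def validate_signs(
    dd_calls: set,
    sensitive_result: DetectorResult,
    robust_result: DetectorResult,
) -> set:
    """Keep calls whose fold-change sign agrees with the robust detector.

    A call is dropped when the robust estimate is exactly zero, the robust
    fit did not converge, or the gene is absent from the robust result.
    """
    sens = dict(zip(sensitive_result.gene_ids, sensitive_result.log2_disp_fc))
    rob_fc = dict(zip(robust_result.gene_ids, robust_result.log2_disp_fc))
    rob_ok = dict(zip(robust_result.gene_ids, robust_result.converged))
    kept = set()
    for g in dd_calls:
        if g not in rob_fc:
            logger.warning("gene %s absent from robust result; call dropped", g)
            continue
        if not rob_ok[g] or rob_fc[g] == 0.0:
            continue
        if np.sign(sens[g]) == np.sign(rob_fc[g]):
            kept.add(g)
    return kept


def union_dd_plus(dd_up_sets: dict[str, set]) -> pd.DataFrame:
    """Union of per-method DD+ sets with a per-gene supporting-method list."""
    support: dict[str, list[str]] = {}
    for method, genes in dd_up_sets.items():
        for g in genes:
            support.setdefault(g, []).append(method)
    rows = [
        {"gene_id": g, "n_methods": len(ms), "methods": "+".join(sorted(ms))}
        for g, ms in sorted(support.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_methods", "methods"])
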