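"""Levene's test for equality of variances on normalized log2 counts."""

from __future__ import annotations

import numpy as np
from scipy import stats

from dispersim.detectors.base import DetectorResult, GroupDesign, build_design
from dispersim.preprocess import NormalizationFactors, log_transform
from dispersim.simdata import CountDataset

__all__ = ["levene_dispersion_test", "levene_statistic"]


def levene_statistic(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """Mean-centered Levene W for two groups (vectorized over genes).

    ``x1``/``x2`` are genes x samples blocks.  W is referred to
    F(k-1, N-k) with k = 2.  Genes with zero within-group deviation in both
    groups get W = 0 and p = 1.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    N, k = n1 + n2, 2
    z1 = np.abs(x1 - x1.mean(axis=1, keepdims=True))
    z2 = np.abs(x2 - x2.mean(axis=1, keepdims=True))
    zbar1 = z1.mean(axis=1)
    zbar2 = z2.mean(axis=1)
    zbar = (n1 * zbar1 + n2 * zbar2) / N
    between = n1 * (zbar1 - zbar) ** 2 + n2 * (zbar2 - zbar) ** 2
    within = ((z1 - zbar1[:, None]) ** 2).sum(axis=1) + (
        (z2 - zbar2[:, None]) ** 2
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = (N - k) / (k - 1) * between / within
    W = np.where(within > 0, W, 0.0)
    p = stats.f.sf(W, k - 1, N - k)
    p = np.where(within > 0, p, 1.0)
    return W, p


def levene_dispersion_test(
    dataset: CountDataset,
    factors: NormalizationFactors,
    design: GroupDesign | None = None,
    pseudocount: float = 1.0,
) -> DetectorResult:
    """Per-gene Levene test on log2(normalized count + pseudocount).

    ``log2_disp_fc`` is the log2 ratio of group variances of the log counts
    (condition 2 over condition 1); the mean axis is a Welch t-test on the
    same matrix.
    """
    if design is None:
        design = build_design(dataset, factors, use_batch=False)
    logmat = log_transform(dataset, factors, pseudocount=pseudocount)
    g1, g2 = design.group_masks()
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each condition needs at least 2 samples")
    x1, x2 = logmat[:, g1], logmat[:, g2]
    W, p_disp = levene_statistic(x1, x2)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_disp_fc = np.log2(v2 / v1)
    log2_disp_fc = np.where(np.isfinite(log2_disp_fc), log2_disp_fc, 0.0)
    t_res = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    log2_mean_fc = x2.mean(axis=1) - x1.mean(axis=1)
    p_mean = np.where(np.isfinite(t_res.pvalue), t_res.pvalue, 1.0)
    return DetectorResult(
        gene_ids=list(dataset.gene_ids),
        method="levene",
        log2_mean_fc=log2_mean_fc,
        log2_disp_fc=log2_disp_fc,
        stat_mean=np.nan_to_num(t_res.statistic),
        stat_disp=W,
        p_mean=p_mean,
        p_disp=p_disp,
        converged=np.ones(dataset.n_genes, dtype=bool),
    )
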