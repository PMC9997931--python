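"""Count-matrix preprocessing: TMM scale factors, CPM filtering, log transform."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from dispersim.simdata import CountDataset

__all__ = [
    "NormalizationFactors",
    "tmm_factors",
    "cpm_matrix",
    "filter_low_expression",
    "log_transform",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample TMM scale factors and library sizes."""

    factors: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", np.asarray(self.factors, dtype=float))
        object.__setattr__(
            self, "library_sizes", np.asarray(self.library_sizes, dtype=float)
        )
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be strictly positive")

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.factors * self.library_sizes

    def to_tsv(self, path: str | Path, sample_ids=None) -> None:
        pd.DataFrame(
            {
                "sample_id": sample_ids
                if sample_ids is not None
                else np.arange(len(self.factors)),
                "factor": self.factors,
                "library_size": self.library_sizes,
                "effective_library_size": self.effective_library_sizes,
            }
        ).to_csv(path, sep="\t", index=False)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM log2 factor of one sample against the reference.

    Doubly trims the per-gene log-ratios (M) and average log intensities (A)
    and returns the precision-weighted mean M, with weights from the
    delta-method binomial variance of a log count ratio.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        logger.warning("sample shares no co-expressed genes with reference; factor 1")
        return 0.0
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    # degenerate case: all M identical (e.g. pure depth change)
    if np.max(np.abs(m - m[0])) < 1e-6:
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    dataset: CountDataset,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: Optional[int] = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scale factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose upper quartile of scaled
    counts is closest to the mean upper quartile across samples.
    """
    counts = dataset.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    if reference is None:
        uq = np.array(
            [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
        )
        reference = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, reference].astype(float)
    log_f = np.array(
        [
            _tmm_pair(counts[:, j].astype(float), ref, lib[j], lib[reference], trim_m, trim_a)
            if j != reference
            else 0.0
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0**log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(factors=factors, library_sizes=lib)


def cpm_matrix(dataset: CountDataset, factors: NormalizationFactors) -> np.ndarray:
    """Counts per million computed on effective library sizes."""
    eff = factors.effective_library_sizes
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")
    return dataset.counts / eff[None, :] * 1e6


def filter_low_expression(
    dataset: CountDataset,
    factors: NormalizationFactors,
    threshold: float = 1.0,
) -> tuple[CountDataset, np.ndarray]:
    """Keep genes whose mean CPM across all samples is >= ``threshold``.

    Returns the reduced dataset (gene order preserved) and the kept row
    indices into the input.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mean_cpm = cpm_matrix(dataset, factors).mean(axis=1)
    keep = np.flatnonzero(mean_cpm >= threshold)
    if keep.size == 0:
        raise ValueError("low-expression filter removed every gene")
    return dataset.subset_genes(keep), keep


def log_transform(
    dataset: CountDataset,
    factors: NormalizationFactors,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """log2(normalized count + pseudocount).

    Counts are scaled by ``mean(effective lib) / effective lib_j`` so that
    normalized values stay on the original count depth scale.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    eff = factors.effective_library_sizes
    norm = dataset.counts * (eff.mean() / eff)[None, :]
    return np.log2(norm + pseudocount)
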