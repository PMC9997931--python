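"""Shared detector data structures."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from dispersim.multiple_testing import DEFAULT_PAIRING, adjust
from dispersim.preprocess import NormalizationFactors
from dispersim.simdata import CountDataset

__all__ = ["GroupDesign", "DetectorResult", "build_design"]


@dataclass(frozen=True)
class GroupDesign:
    """Two-group design with optional batch covariates and per-sample offsets.

    ``condition`` is a 0/1 indicator (1 = second condition level); ``batch``
    is a one-hot matrix with the first level dropped; ``offset`` is the log
    effective library size.
    """

    condition: np.ndarray
    offset: np.ndarray
    batch: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", np.asarray(self.condition, dtype=float))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        levels = np.unique(self.condition)
        if not np.array_equal(levels, [0.0, 1.0]):
            raise ValueError("condition must be a 0/1 indicator with both levels")
        X = self.matrix(include_condition=True)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.condition.size

    def matrix(self, include_condition: bool = True) -> np.ndarray:
        cols = [np.ones(self.n_samples)]
        if include_condition:
            cols.append(self.condition)
        if self.batch is not None:
            cols.append(np.asarray(self.batch, dtype=float))
        return np.column_stack([np.atleast_2d(c.T).T for c in cols])

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        return self.condition == 0, self.condition == 1


def build_design(
    dataset: CountDataset, factors: NormalizationFactors, use_batch: bool = True
) -> GroupDesign:
    """Design from a dataset's condition/batch labels and TMM offsets."""
    levels = np.unique(dataset.condition)
    cond = (dataset.condition == levels[1]).astype(float)
    offset = np.log(factors.effective_library_sizes)
    batch = None
    if use_batch and dataset.batch is not None:
        b = pd.Series(dataset.batch).astype("category")
        dummies = pd.get_dummies(b, drop_first=True)
        if dummies.shape[1]:
            batch = dummies.to_numpy(dtype=float)
    return GroupDesign(condition=cond, offset=offset, batch=batch)


@dataclass
class DetectorResult:
    """Per-gene mean and dispersion effect estimates, statistics and p-values."""

    gene_ids: list[str]
    method: str
    log2_mean_fc: np.ndarray
    log2_disp_fc: np.ndarray
    stat_mean: np.ndarray
    stat_disp: np.ndarray
    p_mean: np.ndarray
    p_disp: np.ndarray
    converged: np.ndarray
    q_mean: np.ndarray = field(default=None)
    q_disp: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        for name in ("p_mean", "p_disp"):
            p = np.asarray(getattr(self, name), dtype=float)
            ok = ~np.isnan(p)
            if ok.any() and ((p[ok] < 0).any() or (p[ok] > 1).any()):
                raise ValueError(f"{name} outside [0, 1]")
            setattr(self, name, p)
        self.converged = np.asarray(self.converged, dtype=bool)
        # non-converged genes carry p = 1 by contract
        self.p_mean = np.where(self.converged, self.p_mean, 1.0)
        self.p_disp = np.where(self.converged, self.p_disp, 1.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def adjusted(self, method: Optional[str] = None) -> "DetectorResult":
        """Fill q_mean/q_disp using BH or BY (default: the per-detector pairing)."""
        if method is None:
            method = DEFAULT_PAIRING.get(self.method, "bh")
        self.q_mean = adjust(self.p_mean, method)
        self.q_disp = adjust(self.p_disp, method)
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "method": self.method,
                "log2_mean_fc": self.log2_mean_fc,
                "log2_disp_fc": self.log2_disp_fc,
                "stat_mean": self.stat_mean,
                "stat_disp": self.stat_disp,
                "p_mean": self.p_mean,
                "p_disp": self.p_disp,
                "q_mean": self.q_mean,
                "q_disp": self.q_disp,
                "converged": self.converged.astype(int),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
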