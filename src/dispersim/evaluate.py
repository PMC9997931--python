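"""Scoring of detector output against simulation truth.

FDR/TPR from the call table, AUC of the dispersion p-value ranking, UpSet
style exclusive intersections of true-positive sets, and sign-correctness
tabulations of estimated dispersion fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from dispersim.detectors.base import DetectorResult
from dispersim.simdata import SimTruth

__all__ = [
    "classify_calls",
    "confusion_rates",
    "roc_auc",
    "intersect_calls",
    "sign_error_analysis",
    "EvalSummary",
    "evaluate_detector",
]


@dataclass(frozen=True)
class EvalSummary:
    """One method x replicate evaluation row."""

    method: str
    fdr: float
    tpr: float
    auc: float
    n_calls: int
    n_sign_errors: int

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "fdr": self.fdr,
            "tpr": self.tpr,
            "auc": self.auc,
            "n_calls": self.n_calls,
            "n_sign_errors": self.n_sign_errors,
        }


def classify_calls(result: DetectorResult, alpha: float = 0.05) -> np.ndarray:
    """Boolean dispersion calls: adjusted p strictly below alpha."""
    if result.q_disp is None:
        raise ValueError("result has no adjusted p-values; call .adjusted() first")
    return np.asarray(result.q_disp) < alpha


def confusion_rates(calls: np.ndarray, truth_labels: np.ndarray) -> tuple[float, float]:
    """(FDR, TPR) of boolean calls against boolean truth labels.

    FDR is defined as 0 when there are no discoveries.
    """
    calls = np.asarray(calls, dtype=bool)
    truth_labels = np.asarray(truth_labels, dtype=bool)
    if calls.shape != truth_labels.shape:
        raise ValueError("calls and truth are misaligned")
    tp = int((calls & truth_labels).sum())
    fp = int((calls & ~truth_labels).sum())
    fn = int((~calls & truth_labels).sum())
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    return fdr, tpr


def roc_auc(p_values: np.ndarray, labels: np.ndarray) -> float:
    """AUC of ranking positives (labels True) by small p, via Mann-Whitney.

    Ties receive average ranks; NaNs (non-converged genes) rank worst.
    """
    p = np.asarray(p_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    score = -p  # larger score = more significant
    score = np.where(np.isnan(score), -np.inf, score)
    ranks = rankdata(score)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def intersect_calls(call_sets: Mapping[str, set]) -> pd.DataFrame:
    """Sizes of every non-empty exclusive region of the Venn partition.

    Each output row names the member methods (``+``-joined) and the number
    of genes belonging to exactly that combination of sets.
    """
    names = list(call_sets)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(set(call_sets[n]) for n in combo))
            for other in names:
                if other not in combo:
                    inside -= set(call_sets[other])
            if inside:
                rows.append({"methods": "+".join(combo), "degree": k, "size": len(inside)})
    return pd.DataFrame(rows, columns=["methods", "degree", "size"])


def sign_error_analysis(
    results: Mapping[str, DetectorResult],
    truth: SimTruth,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sign correctness of estimated dispersion fold changes among true positives.

    For each method: true-positive dispersion calls whose estimated
    ``log2_disp_fc`` sign differs from the simulated one, stratified by the
    true dispersion direction and by the true mean-change direction.
    Non-converged genes are excluded.
    """
    true_sign = np.sign(truth.log2_disp_fc)
    # an exactly unchanged mean counts as the non-decrease stratum
    mean_sign = np.where(truth.log2_mean_fc >= 0, 1, -1)
    rows = []
    for name, res in results.items():
        calls = classify_calls(res, alpha)
        tp = calls & truth.is_dd & res.converged
        est_sign = np.sign(res.log2_disp_fc)
        err = tp & (est_sign != true_sign)
        for disp_dir in (1, -1):
            for mean_dir in (1, -1):
                stratum = tp & (true_sign == disp_dir) & (mean_sign == mean_dir)
                n_tp = int(stratum.sum())
                n_err = int((err & stratum).sum())
                rows.append(
                    {
                        "method": name,
                        "true_disp_direction": disp_dir,
                        "true_mean_direction": mean_dir,
                        "n_true_positive": n_tp,
                        "n_sign_errors": n_err,
                        "pct_sign_errors": 100.0 * n_err / n_tp if n_tp else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def evaluate_detector(
    result: DetectorResult, truth: SimTruth, alpha: float = 0.05
) -> EvalSummary:
    """FDR/TPR/AUC summary of one adjusted detector result against truth."""
    if list(result.gene_ids) != list(truth.gene_ids):
        raise ValueError("result and truth gene ids are misaligned")
    calls = classify_calls(result, alpha)
    fdr, tpr = confusion_rates(calls, truth.is_dd)
    p = np.where(result.converged, result.p_disp, np.nan)
    auc = roc_auc(p, truth.is_dd)
    est_sign = np.sign(result.log2_disp_fc)
    tp = calls & truth.is_dd & result.converged
    n_sign_errors = int((tp & (est_sign != np.sign(truth.log2_disp_fc))).sum())
    return EvalSummary(
        method=result.method,
        fdr=fdr,
        tpr=tpr,
        auc=auc,
        n_calls=int(calls.sum()),
        n_sign_errors=n_sign_errors,
    )
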