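"""Two-condition negative-binomial RNA-seq count simulator.

Counts are drawn gene-by-gene from NB distributions parameterized by a mean
``mu`` and a dispersion ``phi`` such that ``Var = mu + phi * mu**2``.
Baseline (condition 1) parameter pairs come from a user table or a packaged
surrogate; condition 2 parameters are obtained by applying controlled
multiplicative fold changes to the mean and/or the dispersion, with the
fold-change structure balanced across differential-expression strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "ParameterPairTable",
    "SimTruth",
    "CountDataset",
    "load_parameter_pairs",
    "assign_truth",
    "simulate_counts",
    "inject_outliers",
    "simulate_dataset",
]

SCENARIO_UNCONSTRAINED = "unconstrained"
SCENARIO_MODERATED = "moderated"

#: Parameters of the packaged surrogate (mean, dispersion) joint distribution:
#: log-normal means and a decreasing hyperbolic mean-dispersion trend with
#: log-normal noise, loosely emulating bulk RNA-seq parameter estimates.
SURROGATE_PARAMS = {
    "mean_log_mu": 5.0,
    "mean_log_sigma": 1.2,
    "disp_asymptote": 0.15,
    "disp_slope": 3.0,
    "disp_log_sigma": 0.35,
    "mean_floor": 1.0,
}


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (unlike banker's round)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated two-condition dataset."""

    n_genes: int = 10_000
    n_per_condition: int = 50
    scenario: str = SCENARIO_UNCONSTRAINED
    fc_disp_min: float = 1.5
    fc_mean_min: float = 1.5
    fc_mean_max: float = 1.5
    exp_rate: float = 1.0
    frac_dd: float = 0.5
    frac_highly_de: float = 0.5
    outlier_fraction: float = 0.1
    outlier_multiplier_range: tuple[float, float] = (5.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be a positive integer")
        if self.scenario not in (SCENARIO_UNCONSTRAINED, SCENARIO_MODERATED):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("fc_disp_min", "fc_mean_min", "fc_mean_max"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be a fold change >= 1")
        if self.exp_rate <= 0:
            raise ValueError("exp_rate must be positive")
        for name in ("frac_dd", "frac_highly_de", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.outlier_multiplier_range
        if not (0 < lo <= hi):
            raise ValueError("outlier_multiplier_range must be a positive interval")

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["outlier_multiplier_range"] = list(self.outlier_multiplier_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "outlier_multiplier_range" in d:
            d["outlier_multiplier_range"] = tuple(d["outlier_multiplier_range"])
        return cls(**d)


@dataclass(frozen=True)
class ParameterPairTable:
    """Baseline (mean, dispersion) parameter pairs for condition 1."""

    means: np.ndarray
    dispersions: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        disps = np.asarray(self.dispersions, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "dispersions", disps)
        if means.size == 0:
            raise ValueError("parameter pair table is empty")
        if means.shape != disps.shape:
            raise ValueError("means and dispersions differ in length")
        for name, arr in (("mean", means), ("dispersion", disps)):
            bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
            if bad.size:
                raise ValueError(
                    f"non-positive or non-finite {name} at row {bad[0]}"
                )

    def __len__(self) -> int:
        return int(self.means.size)

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` pairs with replacement."""
        idx = rng.integers(0, len(self), size=n)
        return self.means[idx], self.dispersions[idx]


@dataclass
class SimTruth:
    """Per-gene ground truth of a simulated dataset."""

    gene_ids: list[str]
    baseline_mean: np.ndarray
    baseline_dispersion: np.ndarray
    mean_fc: np.ndarray  # effective multiplicative factor, mu2 = mean_fc * mu1
    disp_fc: np.ndarray  # effective multiplicative factor, phi2 = disp_fc * phi1
    disp_direction: np.ndarray  # +1 / -1 for DD genes, 0 otherwise
    disp_extra: np.ndarray  # exponential extra amount c for DD genes
    is_dd: np.ndarray
    is_highly_de: np.ndarray
    condition2_mean: np.ndarray
    condition2_dispersion: np.ndarray
    outlier_sample: np.ndarray = field(default=None)  # -1 where no outlier
    outlier_multiplier: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.outlier_sample is None:
            self.outlier_sample = np.full(n, -1, dtype=int)
        if self.outlier_multiplier is None:
            self.outlier_multiplier = np.full(n, np.nan)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def log2_disp_fc(self) -> np.ndarray:
        return np.log2(self.disp_fc)

    @property
    def log2_mean_fc(self) -> np.ndarray:
        return np.log2(self.mean_fc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "baseline_mean": self.baseline_mean,
                "baseline_dispersion": self.baseline_dispersion,
                "mean_fc": self.mean_fc,
                "disp_fc": self.disp_fc,
                "disp_direction": self.disp_direction,
                "disp_extra": self.disp_extra,
                "is_dd": self.is_dd.astype(int),
                "is_highly_de": self.is_highly_de.astype(int),
                "condition2_mean": self.condition2_mean,
                "condition2_dispersion": self.condition2_dispersion,
                "outlier_sample": self.outlier_sample,
                "outlier_multiplier": self.outlier_multiplier,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def subset(self, gene_ids: Sequence[str]) -> "SimTruth":
        """Row-subset aligned to ``gene_ids`` (order preserved)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return SimTruth(
            gene_ids=list(gene_ids),
            baseline_mean=self.baseline_mean[idx],
            baseline_dispersion=self.baseline_dispersion[idx],
            mean_fc=self.mean_fc[idx],
            disp_fc=self.disp_fc[idx],
            disp_direction=self.disp_direction[idx],
            disp_extra=self.disp_extra[idx],
            is_dd=self.is_dd[idx],
            is_highly_de=self.is_highly_de[idx],
            condition2_mean=self.condition2_mean[idx],
            condition2_dispersion=self.condition2_dispersion[idx],
            outlier_sample=self.outlier_sample[idx],
            outlier_multiplier=self.outlier_multiplier[idx],
        )


@dataclass
class CountDataset:
    """Integer count matrix with sample condition (and optional batch) labels."""

    counts: np.ndarray  # genes x samples, non-negative integers
    gene_ids: list[str]
    sample_ids: list[str]
    condition: np.ndarray  # per-sample label in {1, 2}
    batch: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.condition = np.asarray(self.condition)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match counts")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length does not match counts")
        if self.condition.shape[0] != self.counts.shape[1]:
            raise ValueError("condition length does not match counts")
        if len(np.unique(self.condition)) != 2:
            raise ValueError("condition must have exactly two levels")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks for the two condition levels, in sorted level order."""
        levels = np.unique(self.condition)
        return self.condition == levels[0], self.condition == levels[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    def sample_sheet(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_ids, "condition": self.condition}
        if self.batch is not None:
            d["batch"] = self.batch
        return pd.DataFrame(d)

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, samples_path: str | Path
    ) -> "CountDataset":
        mat = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        if "sample_id" not in sheet.columns or "condition" not in sheet.columns:
            raise ValueError("sample sheet needs 'sample_id' and 'condition' columns")
        unknown = set(sheet["sample_id"]) - set(mat.columns)
        if unknown:
            raise ValueError(f"unknown sample ids in sheet: {sorted(unknown)}")
        mat = mat[list(sheet["sample_id"])]
        batch = sheet["batch"].to_numpy() if "batch" in sheet.columns else None
        return cls(
            counts=mat.to_numpy(),
            gene_ids=list(mat.index.astype(str)),
            sample_ids=list(sheet["sample_id"].astype(str)),
            condition=sheet["condition"].to_numpy(),
            batch=batch,
        )

    def subset_genes(self, keep: np.ndarray) -> "CountDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountDataset(
            counts=self.counts[keep],
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            condition=self.condition.copy(),
            batch=None if self.batch is None else self.batch.copy(),
        )


def stage_rngs(seed: int, stages: Sequence[str]) -> dict[str, np.random.Generator]:
    """Derive one independent generator per named stage from a master seed.

    Children are spawned in the (sorted) alphabetical order of the stage
    names, so the stream assigned to a stage does not depend on call order.
    """
    names = sorted(stages)
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def load_parameter_pairs(source: str | Path = "surrogate") -> ParameterPairTable:
    """Load baseline (mean, dispersion) pairs from a TSV or the packaged surrogate.

    ``source`` may be a path to a two-column numeric table (whitespace- or
    tab-delimited, no header) or the builtin name ``"surrogate"``, which
    draws 10 000 pairs with log-normal means and dispersions following a
    decreasing mean-dispersion trend with log-normal noise.
    """
    if isinstance(source, str) and source == "surrogate":
        return surrogate_parameter_pairs()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"parameter pair table not found: {path}")
    try:
        table = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse parameter pair table {path}: {exc}")
    if table.shape[1] < 2:
        raise ValueError(
            f"parameter pair table {path} has fewer than 2 columns"
        )
    means = pd.to_numeric(table.iloc[:, 0], errors="coerce").to_numpy()
    disps = pd.to_numeric(table.iloc[:, 1], errors="coerce").to_numpy()
    for name, arr in (("mean", means), ("dispersion", disps)):
        bad = np.flatnonzero(~np.isfinite(arr) | (arr <= 0))
        if bad.size:
            raise ValueError(
                f"invalid {name} value at row {bad[0] + 1} of {path}"
            )
    return ParameterPairTable(means=means, dispersions=disps)


def surrogate_parameter_pairs(
    n: int = 10_000, seed: int = 20_230_309, **overrides: float
) -> ParameterPairTable:
    """Draw a surrogate joint distribution of bulk RNA-seq (mean, dispersion).

    Means are log-normal; dispersions follow ``asymptote + slope / mean``
    scaled by log-normal noise, giving the canonical decreasing trend of
    dispersion with expression strength.
    """
    p = dict(SURROGATE_PARAMS, **overrides)
    rng = np.random.default_rng(seed)
    means = np.maximum(
        rng.lognormal(p["mean_log_mu"], p["mean_log_sigma"], size=n),
        p["mean_floor"],
    )
    trend = p["disp_asymptote"] + p["disp_slope"] / means
    disps = trend * rng.lognormal(0.0, p["disp_log_sigma"], size=n)
    return ParameterPairTable(means=means, dispersions=disps)


def _balanced_split(indices: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Split an index block into (first, rest) with |first| = round-half-up."""
    k = round_half_up(frac * indices.size)
    return indices[:k], indices[k:]


def assign_truth(
    config: SimConfig,
    pairs: ParameterPairTable,
    rng: Optional[np.random.Generator] = None,
) -> SimTruth:
    """Assign baseline parameters, fold changes and DD/DE flags to every gene.

    DD genes receive a dispersion fold-change magnitude ``fc_disp_min + c``
    with ``c ~ Exponential(exp_rate)``, applied multiplicatively for half of
    them and reciprocally for the other half.  In the unconstrained scenario
    highly-DE genes receive an analogous mean fold change while lowly-DE
    genes get ``U(1, fc_mean_min)``; in the moderated scenario all genes get
    ``U(1, fc_mean_max)``.  DD flags are balanced exactly across DE strata
    and DD direction across DE direction (round-half-up per stratum,
    remainders landing in the DD+/DE+ cell).
    """
    if rng is None:
        rng = stage_rngs(config.seed, ["truth", "counts", "outliers"])["truth"]
    n = config.n_genes
    mu1, phi1 = pairs.sample(n, rng)
    perm = rng.permutation(n)

    is_dd = np.zeros(n, dtype=bool)
    is_highly_de = np.zeros(n, dtype=bool)
    disp_dir = np.zeros(n, dtype=int)
    mean_dir = np.ones(n, dtype=int)

    if config.scenario == SCENARIO_UNCONSTRAINED:
        high, low = _balanced_split(perm, config.frac_highly_de)
        is_highly_de[high] = True
        de_strata = [high, low]
    else:
        de_strata = [perm]

    for stratum in de_strata:
        up, down = _balanced_split(stratum, 0.5)
        mean_dir[down] = -1
        for cell in (up, down):
            dd, _ = _balanced_split(cell, config.frac_dd)
            is_dd[dd] = True
            plus, minus = _balanced_split(dd, 0.5)
            disp_dir[plus] = 1
            disp_dir[minus] = -1

    # dispersion fold changes
    disp_extra = np.zeros(n)
    disp_fc = np.ones(n)
    n_dd = int(is_dd.sum())
    if n_dd:
        c = rng.exponential(scale=1.0 / config.exp_rate, size=n_dd)
        disp_extra[is_dd] = c
        mag = config.fc_disp_min + c
        direction = disp_dir[is_dd].astype(float)
        disp_fc[is_dd] = np.where(direction > 0, mag, 1.0 / mag)

    # mean fold changes
    mean_fc = np.ones(n)
    if config.scenario == SCENARIO_UNCONSTRAINED:
        n_high = int(is_highly_de.sum())
        mag_high = config.fc_mean_min + rng.exponential(
            scale=1.0 / config.exp_rate, size=n_high
        )
        low_mask = ~is_highly_de
        mag_low = rng.uniform(1.0, config.fc_mean_min, size=int(low_mask.sum()))
        mag = np.empty(n)
        mag[is_highly_de] = mag_high
        mag[low_mask] = mag_low
    else:
        mag = rng.uniform(1.0, config.fc_mean_max, size=n)
    mean_fc = np.where(mean_dir > 0, mag, 1.0 / mag)

    return SimTruth(
        gene_ids=[f"gene_{i + 1}" for i in range(n)],
        baseline_mean=mu1,
        baseline_dispersion=phi1,
        mean_fc=mean_fc,
        disp_fc=disp_fc,
        disp_direction=disp_dir,
        disp_extra=disp_extra,
        is_dd=is_dd,
        is_highly_de=is_highly_de,
        condition2_mean=mu1 * mean_fc,
        condition2_dispersion=phi1 * disp_fc,
    )


def _nb_draw(
    mu: np.ndarray, phi: np.ndarray, size: tuple, rng: np.random.Generator
) -> np.ndarray:
    """Draw NB counts with mean ``mu`` and variance ``mu + phi * mu**2``."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), size)
    if not (np.isfinite(mu).all() and np.isfinite(phi).all()):
        bad = np.flatnonzero(
            ~(np.isfinite(mu).all(axis=-1) & np.isfinite(phi).all(axis=-1))
        )
        raise ValueError(f"non-finite NB parameters for gene index {bad[0]}")
    out = np.empty(size, dtype=np.int64)
    tiny = phi < 1e-7  # Poisson limit; avoids overflow in the size parameter
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    if big.any():
        r = 1.0 / phi[big]
        p = r / (r + mu[big])
        out[big] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    truth: SimTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> CountDataset:
    """Draw the count matrix implied by ``truth``: NB per cell, first
    ``n_per_condition`` samples in condition 1, the rest in condition 2."""
    if rng is None:
        rng = stage_rngs(config.seed, ["truth", "counts", "outliers"])["counts"]
    n = truth.n_genes
    m = config.n_per_condition
    shape = (n, m)
    y1 = _nb_draw(truth.baseline_mean[:, None], truth.baseline_dispersion[:, None], shape, rng)
    y2 = _nb_draw(
        truth.condition2_mean[:, None], truth.condition2_dispersion[:, None], shape, rng
    )
    counts = np.hstack([y1, y2])
    sample_ids = [f"s{j + 1}_c1" for j in range(m)] + [f"s{j + 1}_c2" for j in range(m)]
    condition = np.array([1] * m + [2] * m)
    return CountDataset(
        counts=counts,
        gene_ids=list(truth.gene_ids),
        sample_ids=sample_ids,
        condition=condition,
    )


def inject_outliers(
    dataset: CountDataset,
    truth: SimTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CountDataset, SimTruth]:
    """Multiply one count by a U(multiplier range) draw for a fraction of genes.

    Exactly ``round(outlier_fraction * n_genes)`` distinct genes are chosen
    uniformly; for each, one sample (uniform among samples with a positive
    count, so the outlier is visible) has its count multiplied and rounded.
    Positions and multipliers are recorded in the returned truth.
    """
    if rng is None:
        rng = stage_rngs(config.seed, ["truth", "counts", "outliers"])["outliers"]
    n = dataset.n_genes
    k = round_half_up(config.outlier_fraction * n)
    counts = dataset.counts.copy()
    out_sample = truth.outlier_sample.copy()
    out_mult = truth.outlier_multiplier.copy()
    if k:
        genes = rng.choice(n, size=k, replace=False)
        lo, hi = config.outlier_multiplier_range
        mults = rng.uniform(lo, hi, size=k)
        for g, mult in zip(genes, mults):
            row = counts[g]
            positive = np.flatnonzero(row > 0)
            candidates = positive if positive.size else np.arange(row.size)
            j = int(rng.choice(candidates))
            counts[g, j] = int(round(row[j] * mult))
            out_sample[g] = j
            out_mult[g] = mult
    new_truth = replace(truth, outlier_sample=out_sample, outlier_multiplier=out_mult)
    new_dataset = CountDataset(
        counts=counts,
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        condition=dataset.condition.copy(),
        batch=None if dataset.batch is None else dataset.batch.copy(),
    )
    return new_dataset, new_truth


def simulate_dataset(
    config: SimConfig, pairs: Optional[ParameterPairTable] = None
) -> tuple[CountDataset, SimTruth]:
    """Full pipeline: truth assignment, count sampling, outlier injection."""
    if pairs is None:
        pairs = load_parameter_pairs("surrogate")
    rngs = stage_rngs(config.seed, ["truth", "counts", "outliers"])
    truth = assign_truth(config, pairs, rngs["truth"])
    dataset = simulate_counts(truth, config, rngs["counts"])
    dataset, truth = inject_outliers(dataset, truth, config, rngs["outliers"])
    return dataset, truth
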