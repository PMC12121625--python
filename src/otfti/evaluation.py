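"""Accuracy metrics and resampling analyses for replicate free energy
tables: MAE/RMSE/R^2 against reference values, a label-permutation
significance test, batch resampling over replicate combinations,
truncated-gradient reanalysis and computational-savings accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GradientSeries
from .equilibration import detect_equilibration, subsample
from .estimators import LambdaSchedule, integrate

__all__ = [
    "ReplicateTable",
    "MetricDistribution",
    "error_metrics",
    "permutation_test",
    "batch_resample",
    "truncation_analysis",
    "savings",
]


@dataclass(frozen=True)
class ReplicateTable:
    """Replicate free energies per transformation with optional references.

    ``replicates`` maps a transformation label to its replicate values
    (kcal/mol); ``references`` maps labels to the experimental or
    long-run value the predictions are judged against.
    """

    replicates: Mapping[str, Sequence[float]]
    references: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for label, vals in self.replicates.items():
            if len(vals) < 1:
                raise ValueError(f"transformation {label!r} has no replicates")
        if self.references is not None:
            for label, ref in self.references.items():
                if not math.isfinite(ref):
                    raise ValueError(f"reference for {label!r} is not finite")

    @property
    def labels(self) -> list[str]:
        return list(self.replicates)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReplicateTable":
        """Build from a long-format frame with columns
        (transformation, replicate, value[, reference])."""
        reps = {str(k): g["value"].tolist() for k, g in df.groupby("transformation", sort=False)}
        refs = None
        if "reference" in df.columns:
            refs = {
                str(k): float(g["reference"].iloc[0])
                for k, g in df.groupby("transformation", sort=False)
            }
        return cls(replicates=reps, references=refs)


@dataclass(frozen=True)
class MetricDistribution:
    """Sampled metric distributions at one batch size."""

    batch_size: int
    mae: np.ndarray
    rmse: np.ndarray
    r2: np.ndarray
    exhaustive: bool

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in (("MAE", self.mae), ("RMSE", self.rmse), ("R2", self.r2)):
            finite = arr[np.isfinite(arr)]
            rows.append(
                {
                    "metric": name,
                    "mean": float(finite.mean()) if finite.size else math.nan,
                    "std_err": float(finite.std(ddof=1) / math.sqrt(finite.size))
                    if finite.size > 1
                    else math.nan,
                }
            )
        return pd.DataFrame(rows)


def error_metrics(predicted: Sequence[float], reference: Sequence[float]) -> tuple[float, float, float]:
    """(MAE, RMSE, R^2) of predictions against references.

    R^2 is the squared Pearson correlation; it is NaN when either
    vector has zero variance or fewer than two entries.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.size != r.size or p.size == 0:
        raise ValueError("predicted and reference must have equal nonzero length")
    err = p - r
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    if p.size < 2 or p.std() == 0 or r.std() == 0:
        r2 = math.nan
    else:
        r2 = float(np.corrcoef(p, r)[0, 1] ** 2)
    return mae, rmse, r2


def permutation_test(
    predicted: Sequence[float],
    reference: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fraction of label permutations whose MAE (and RMSE) fall below
    the observed values.

    The references are permuted ``n_perm`` times against the fixed
    predictions; a small returned fraction means the observed agreement
    beats nearly all permuted pairings.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.size != r.size or p.size < 3:
        raise ValueError("need at least 3 matched pairs for a permutation test")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    mae_obs, rmse_obs, _ = error_metrics(p, r)
    rng = np.random.default_rng(seed)
    perm = np.array([rng.permutation(r) for _ in range(n_perm)])
    err = p[None, :] - perm
    mae_null = np.abs(err).mean(axis=1)
    rmse_null = np.sqrt((err**2).mean(axis=1))
    return float((mae_null < mae_obs).mean()), float((rmse_null < rmse_obs).mean())


def batch_resample(
    table: ReplicateTable,
    batch_size: int,
    n_samples: int = 10_000,
    seed: int = 0,
) -> MetricDistribution:
    """Metric distributions over random replicate combinations.

    Per sample, ``batch_size`` replicates are drawn without replacement
    within each transformation (independently across transformations),
    averaged, and scored against the references. When every
    transformation has exactly ``batch_size`` replicates there is a
    single combination, enumerated deterministically.
    """
    if table.references is None:
        raise ValueError("batch_resample requires reference values")
    labels = table.labels
    reps = [np.asarray(table.replicates[lab], dtype=float) for lab in labels]
    refs = np.array([table.references[lab] for lab in labels])
    min_count = min(len(v) for v in reps)
    if not 1 <= batch_size <= min_count:
        raise ValueError(f"batch_size must lie in [1, {min_count}], got {batch_size}")

    n_combos = [math.comb(len(v), batch_size) for v in reps]
    total_combos = math.prod(n_combos)
    exhaustive = total_combos <= n_samples

    if exhaustive:
        per_label_means = [
            np.array([np.mean(v[list(c)]) for c in combinations(range(len(v)), batch_size)])
            for v in reps
        ]
        grids = np.meshgrid(*per_label_means, indexing="ij")
        preds = np.stack([g.ravel() for g in grids], axis=1)
    else:
        rng = np.random.default_rng(seed)
        preds = np.empty((n_samples, len(labels)))
        for j, v in enumerate(reps):
            draws = np.array([rng.choice(v, size=batch_size, replace=False) for _ in range(n_samples)])
            preds[:, j] = draws.mean(axis=1)

    mae = np.empty(preds.shape[0])
    rmse = np.empty(preds.shape[0])
    r2 = np.empty(preds.shape[0])
    for i, row in enumerate(preds):
        mae[i], rmse[i], r2[i] = error_metrics(row, refs)
    return MetricDistribution(batch_size=batch_size, mae=mae, rmse=rmse, r2=r2, exhaustive=exhaustive)


def truncation_analysis(
    replicate_windows: Mapping[str, Sequence[GradientSeries]],
    truncation_grid: Sequence[float],
    schedule: LambdaSchedule,
) -> pd.DataFrame:
    """Free energy versus gradient truncation time.

    For each truncation time T (ns), every window series of every
    replicate is truncated to its first T ns (series shorter than T
    contribute their full length), re-equilibrated, decorrelated and
    averaged, and the window means integrated into a per-replicate
    free energy; replicates aggregate to a mean and standard error.

    Returns a frame with columns (truncation_ns, dg_mean, dg_std_err,
    n_replicates).
    """
    grid = sorted(float(t) for t in truncation_grid)
    if not grid:
        raise ValueError("empty truncation grid")
    min_available = min(
        s.sampling_interval for series_list in replicate_windows.values() for s in series_list
    )
    if grid[0] < min_available:
        raise ValueError("truncation time precedes the first available sample")

    rows = []
    for t in grid:
        dgs = []
        for rep_label, series_list in replicate_windows.items():
            means = []
            for s in series_list:
                trunc = s.truncated(min(t, s.duration))
                eq = detect_equilibration(trunc)
                dec = subsample(trunc, eq)
                means.append(float(dec.values.mean()))
            dgs.append(integrate(schedule, np.asarray(means)).delta_g)
        dgs = np.asarray(dgs)
        rows.append(
            {
                "truncation_ns": t,
                "dg_mean": float(dgs.mean()),
                "dg_std_err": float(dgs.std(ddof=1) / math.sqrt(dgs.size)) if dgs.size > 1 else 0.0,
                "n_replicates": int(dgs.size),
            }
        )
    return pd.DataFrame(rows)


def savings(total_simulated: float, baseline: float) -> float:
    """Fraction of a fixed-allocation budget saved: 1 - total/baseline.

    Negative when the adaptive run exceeded the baseline budget. Any
    time-step cost multipliers (e.g. x2 for halved time steps) belong
    in the caller-supplied baseline.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 1.0 - total_simulated / baseline
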