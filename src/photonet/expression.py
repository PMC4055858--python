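"""Experiment selection and between-array normalisation of expression data.

Mutual-information inference needs the regulators to actually vary, so whole
experiments (groups of chips) are kept only when more than half of the TFs
of interest show expression diversity there — coefficient of variation above
0.1 on linear-scale intensities by default.  The retained chips are then
quantile-normalised across arrays so every sample shares the same intensity
distribution (the single-channel default of limma's normalizeBetweenArrays).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "ExperimentFilterReport",
    "coefficient_of_variation",
    "filter_experiments",
    "quantile_normalize",
]


@dataclass(frozen=True)
class ExperimentFilterReport:
    """Per-experiment outcome of the TF expression-diversity filter."""

    per_experiment: tuple[tuple[str, int, int, float, bool], ...]
    # (experiment_id, n_samples, n_tfs_passing_cv, fraction_passing, kept)

    def kept_experiments(self) -> list[str]:
        return [e for e, _, _, _, kept in self.per_experiment if kept]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_experiment,
            columns=["experiment_id", "n_samples", "n_tfs_passing_cv",
                     "fraction_passing", "kept"],
        )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean values")
    return float(v.std(ddof=1) / mean)


def filter_experiments(
    expr: ExpressionMatrix,
    tf_gene_ids: Sequence[str],
    cv_threshold: float = 0.1,
    fraction: float = 0.5,
    log2: bool = False,
) -> tuple[ExpressionMatrix, ExperimentFilterReport]:
    """Keep experiments where the fraction of TFs with CV > cv_threshold
    exceeds ``fraction``.

    CV is computed per experiment on linear intensities (``log2=True``
    switches to log2(1 + x) values).  Whole experiments are kept or dropped;
    sample sets are never split.
    """
    tf_gene_ids = list(tf_gene_ids)
    missing = [t for t in tf_gene_ids if t not in expr.data.index]
    if missing:
        raise KeyError(f"TF genes absent from expression matrix: {missing}")
    if not tf_gene_ids:
        raise ValueError("no TF genes given")

    rows = []
    kept_samples: list[str] = []
    for exp_id in expr.experiments:
        samples = expr.samples_of_experiment(exp_id)
        if len(samples) < 2:
            raise ValueError(f"experiment {exp_id!r} has fewer than 2 samples")
        block = expr.data.loc[tf_gene_ids, samples].to_numpy()
        if log2:
            block = np.log2(1.0 + block)
        means = block.mean(axis=1)
        sds = block.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cvs = np.where(means != 0, sds / means, 0.0)
        n_pass = int((cvs > cv_threshold).sum())
        frac = n_pass / len(tf_gene_ids)
        kept = frac > fraction
        rows.append((exp_id, len(samples), n_pass, frac, kept))
        if kept:
            kept_samples.extend(samples)
    report = ExperimentFilterReport(tuple(rows))
    if not kept_samples:
        filtered = ExpressionMatrix(expr.data.iloc[:, :0].copy(), {})
    else:
        filtered = expr.restrict_samples(kept_samples)
    return filtered, report


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common quantile profile (the mean of the
    per-sample sorted values).

    Within-sample rank order is preserved; tied values within a sample
    receive the mean of the quantile values they span.  Idempotent.
    """
    df = expr.data
    if df.shape[1] < 2:
        raise ValueError("quantile normalisation requires at least 2 samples")
    if df.isna().to_numpy().any():
        raise ValueError("missing values are not supported")
    vals = df.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)  # common quantile profile
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # ties: average the quantile values the tied block spans
        s = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    norm = pd.DataFrame(out, index=df.index, columns=df.columns)
    return ExpressionMatrix(norm, dict(expr.experiment_of_sample))
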