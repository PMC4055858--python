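"""ARACNE-style mutual-information inference between TFs and genes.

The default estimator is the kernel estimator of the ARACNE family: both
variables are rank-transformed to their empirical copula, mapped to normal
scores, and the joint and marginal densities are estimated with a
fixed-bandwidth Gaussian product kernel (h = c * sd * n^(-1/6), c = 1.06 by
default) evaluated leave-one-out at the data points.  The estimate

    MI = mean_i ln( f_xy(x_i, y_i) / (f_x(x_i) * f_y(y_i)) )

is symmetric, invariant under strictly monotone transforms of either
variable (only ranks enter), and clamped at zero.  A histogram ("bins")
estimator is provided as an independent fallback.

Significance far beyond permutation resolution (the working threshold is
p < 1e-7) is obtained by exponential tail extrapolation: the permutation
null of the rank-based estimator depends only on the sample count, its
upper-decile survival is fit as ln P(MI > m) = a - b*m, and p(mi) =
min(1, exp(a - b*mi)).  Edges passing the threshold may optionally be
pruned by ARACNE's data-processing-inequality (DPI) triangle rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import ExpressionMatrix

__all__ = [
    "MIEdge",
    "RankedTargets",
    "NullModel",
    "mutual_information",
    "fit_null",
    "infer_edges",
    "dpi_prune",
    "DEFAULT_P_THRESHOLD",
    "DEFAULT_DPI_TOLERANCE",
]

DEFAULT_P_THRESHOLD = 1e-7
DEFAULT_DPI_TOLERANCE = 0.15
DEFAULT_BANDWIDTH_SCALE = 1.06


@dataclass(frozen=True)
class MIEdge:
    tf_id: str
    gene_id: str
    mi: float  # nats
    p: float


@dataclass(frozen=True)
class RankedTargets:
    """All genes ranked by descending MI with one TF (ties: ascending id)."""

    tf_id: str
    targets: tuple[str, ...]
    mi_values: tuple[float, ...]


@dataclass(frozen=True)
class NullModel:
    """Exponential tail fit of the permutation null: ln P(MI > m) = a - b*m."""

    n_samples: int
    intercept: float  # a
    slope: float      # b > 0
    n_permutations: int
    seed: int

    def p_value(self, mi):
        """min(1, exp(a - b*mi)); a zero (or clamped) MI estimate carries no
        evidence, so p(mi <= 0) = 1."""
        mi = np.asarray(mi, dtype=float)
        p = np.minimum(1.0, np.exp(self.intercept - self.slope * mi))
        p = np.where(mi <= 0, 1.0, p)
        return float(p) if p.ndim == 0 else p


def _normal_scores(x: np.ndarray) -> np.ndarray:
    n = x.size
    return norm.ppf(rankdata(x) / (n + 1))


def _kernel_matrix(z: np.ndarray, h: float) -> np.ndarray:
    d = z[:, None] - z[None, :]
    K = np.exp(-0.5 * (d / h) ** 2)
    np.fill_diagonal(K, 0.0)  # leave-one-out
    return K


def _mi_kernel(x: np.ndarray, y: np.ndarray, bandwidth_scale: float) -> float:
    n = x.size
    zx = _normal_scores(x)
    zy = _normal_scores(y)
    h = bandwidth_scale * zx.std(ddof=1) * n ** (-1.0 / 6.0)
    Kx = _kernel_matrix(zx, h)
    Ky = _kernel_matrix(zy, h)
    sx = Kx.sum(axis=1)
    sy = Ky.sum(axis=1)
    sxy = (Kx * Ky).sum(axis=1)
    est = float(np.mean(np.log((n - 1) * sxy / (sx * sy))))
    return max(est, 0.0)


def _mi_bins(x: np.ndarray, y: np.ndarray, bins: int | None) -> float:
    n = x.size
    if bins is None:
        bins = max(2, int(round(n ** (1.0 / 3.0))))
    # equal-frequency bins on ranks keep marginals uniform
    qx = np.minimum((rankdata(x, method="ordinal") - 1) * bins // n, bins - 1)
    qy = np.minimum((rankdata(y, method="ordinal") - 1) * bins // n, bins - 1)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (qx, qy), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    return max(float(np.nansum(terms)), 0.0)


def mutual_information(
    x: Sequence[float],
    y: Sequence[float],
    estimator: str = "kernel",
    bandwidth_scale: float = DEFAULT_BANDWIDTH_SCALE,
    bins: int | None = None,
) -> float:
    """Mutual information (nats) between two equal-length samples.

    A constant input carries no information: the estimate is defined as 0
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: mutual information defined as 0")
        return 0.0
    if estimator == "kernel":
        return _mi_kernel(x, y, bandwidth_scale)
    if estimator == "bins":
        return _mi_bins(x, y, bins)
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# Permutation null and tail extrapolation

_NULL_CACHE: dict[tuple[int, int, int, float], NullModel] = {}


def _null_mis(n: int, n_permutations: int, seed: int, bandwidth_scale: float) -> np.ndarray:
    """Null MI draws for tie-free data of size n.

    The estimator sees only ranks, so under permutation both margins are the
    fixed normal-score grid and each draw is determined by a random pairing
    of grid points; the kernel matrix of the grid is computed once.
    """
    g = norm.ppf(np.arange(1, n + 1) / (n + 1))
    h = bandwidth_scale * g.std(ddof=1) * n ** (-1.0 / 6.0)
    K = _kernel_matrix(g, h)
    s = K.sum(axis=1)
    logmarg = np.log(s)
    mean_logmarg = logmarg.mean()

    rng = np.random.default_rng(seed)
    mis = np.empty(n_permutations)
    block = max(1, min(64, n_permutations))
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        KP = K[perms[:, :, None], perms[:, None, :]]
        sxy = (KP * K[None, :, :]).sum(axis=2)
        mis[done : done + b] = (
            np.log((n - 1) * sxy).mean(axis=1) - mean_logmarg - logmarg[perms].mean(axis=1)
        )
        done += b
    return mis


def fit_null(
    expr_subset: ExpressionMatrix | int,
    n_permutations: int = 100_000,
    seed: int = 0,
    bandwidth_scale: float = DEFAULT_BANDWIDTH_SCALE,
) -> NullModel:
    """Calibrate the MI null by permutation and fit its exponential tail.

    Because the kernel estimator is rank-based, the permutation null for
    tie-free data is a function of the sample count alone; ``expr_subset``
    supplies that count (an integer is accepted directly).  The upper decile
    of the permuted MI values is fit by least squares as ln survival vs MI,
    and p-values are extrapolated as p(mi) = min(1, exp(a - b*mi)).
    """
    if isinstance(expr_subset, ExpressionMatrix):
        n = len(expr_subset.sample_ids)
    else:
        n = int(expr_subset)
    if n < 8:
        raise ValueError("need at least 8 samples to calibrate the null")
    if n_permutations < 100:
        raise ValueError("too few permutations for a tail fit")
    key = (n, n_permutations, seed, bandwidth_scale)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]

    mis = _null_mis(n, n_permutations, seed, bandwidth_scale)
    srt = np.sort(mis)
    if srt[0] == srt[-1]:
        raise ValueError("degenerate permutation null: all MI values identical")
    k0 = int(0.9 * n_permutations)
    tail = srt[k0:-1]  # drop the most extreme point (empirical survival 0)
    surv = 1.0 - (np.arange(k0, n_permutations - 1) + 1) / n_permutations
    A = np.vstack([np.ones_like(tail), tail]).T
    coef, *_ = np.linalg.lstsq(A, np.log(surv), rcond=None)
    a, b = float(coef[0]), float(-coef[1])
    if not b > 0:
        raise ValueError("tail fit produced non-positive decay rate")
    model = NullModel(n_samples=n, intercept=a, slope=b,
                      n_permutations=n_permutations, seed=seed)
    _NULL_CACHE[key] = model
    return model


# ---------------------------------------------------------------------------
# Edge inference and DPI


def infer_edges(
    expr: ExpressionMatrix,
    tf_gene_ids: Sequence[str],
    null: NullModel,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    bandwidth_scale: float = DEFAULT_BANDWIDTH_SCALE,
) -> tuple[list[MIEdge], dict[str, RankedTargets]]:
    """MI of every TF against every other gene.

    Returns the significant edges (p < p_threshold, self-pairs excluded) and,
    for each TF, the full descending-MI ranking over all other genes (the
    complete ranking is what the downstream coherence analysis consumes).
    """
    tf_gene_ids = list(tf_gene_ids)
    missing = [t for t in tf_gene_ids if t not in expr.data.index]
    if missing:
        raise KeyError(f"TF genes absent from expression matrix: {missing}")
    if len(expr.sample_ids) != null.n_samples:
        raise ValueError(
            f"null calibrated for n={null.n_samples} but matrix has "
            f"{len(expr.sample_ids)} samples"
        )
    genes = expr.gene_ids
    vals = expr.data.to_numpy()
    idx = {g: i for i, g in enumerate(genes)}

    edges: list[MIEdge] = []
    rankings: dict[str, RankedTargets] = {}
    for tf in tf_gene_ids:
        x = vals[idx[tf]]
        mi_of: dict[str, float] = {}
        for g in genes:
            if g == tf:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mi_of[g] = mutual_information(x, vals[idx[g]],
                                              bandwidth_scale=bandwidth_scale)
        order = sorted(mi_of, key=lambda g: (-mi_of[g], g))
        rankings[tf] = RankedTargets(
            tf_id=tf,
            targets=tuple(order),
            mi_values=tuple(mi_of[g] for g in order),
        )
        ps = null.p_value([mi_of[g] for g in order])
        for g, p in zip(order, ps):
            if p < p_threshold:
                edges.append(MIEdge(tf_id=tf, gene_id=g, mi=mi_of[g], p=float(p)))
    return edges, rankings


def dpi_prune(edges: Sequence[MIEdge], tolerance: float = DEFAULT_DPI_TOLERANCE) -> list[MIEdge]:
    """ARACNE's data-processing-inequality pruning.

    In every fully connected triple the weakest edge is presumed indirect
    and removed when its MI falls below (1 - tolerance) times the smaller of
    the other two.  All removal decisions are taken on the input graph
    simultaneously (no cascade).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    mi_of: dict[frozenset[str], float] = {}
    neighbors: dict[str, set[str]] = {}
    for e in edges:
        pair = frozenset((e.tf_id, e.gene_id))
        mi_of[pair] = e.mi
        neighbors.setdefault(e.tf_id, set()).add(e.gene_id)
        neighbors.setdefault(e.gene_id, set()).add(e.tf_id)

    doomed: set[frozenset[str]] = set()
    nodes = sorted(neighbors)
    for a in nodes:
        for b in neighbors[a]:
            if b <= a:
                continue
            for c in neighbors[a] & neighbors[b]:
                if c <= b:
                    continue
                trio = [
                    (mi_of[frozenset((a, b))], frozenset((a, b))),
                    (mi_of[frozenset((a, c))], frozenset((a, c))),
                    (mi_of[frozenset((b, c))], frozenset((b, c))),
                ]
                trio.sort(key=lambda t: t[0])
                weakest_mi, weakest = trio[0]
                if weakest_mi < (1.0 - tolerance) * trio[1][0]:
                    doomed.add(weakest)
    return [e for e in edges if frozenset((e.tf_id, e.gene_id)) not in doomed]
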