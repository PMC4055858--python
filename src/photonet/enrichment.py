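"""Cutoff-scanning Fisher enrichment for calling photosynthesis-associated TFs.

For one TF, the per-gene affinity scores are thresholded at a series of
cutoffs (default 0.5 to 5.0 in steps of 0.1); at each cutoff the genes
scoring strictly above it form the candidate target set, and a one-sided
Fisher exact test (hypergeometric upper tail) asks whether that set is
enriched in the photosynthesis gene set relative to the background.  The
minimal p-value across the scan is the TF's score; TFs with min p < 0.001
are called photosynthesis regulators.

Taking the raw minimum over 46 correlated tests inflates the type-I rate
(bounded above by 46x the per-test level); a Benjamini-Hochberg adjusted
column across TFs is emitted as supplementary output but is not used for
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "CutoffScanResult",
    "default_cutoffs",
    "fisher_enrichment_p",
    "cutoff_scan",
    "select_photosynthesis_tfs",
    "enrichment_table",
]

DEFAULT_ALPHA = 0.001


def default_cutoffs(lo: float = 0.5, hi: float = 5.0, step: float = 0.1) -> np.ndarray:
    """The affinity-score cutoff series: 0.5, 0.6, ..., 5.0 (46 values)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


@dataclass(frozen=True)
class CutoffScanResult:
    """Enrichment scan of one TF: per-cutoff 2x2 counts and p-values, the
    minimal p and the target set realised at the best cutoff."""

    tf_id: str
    per_cutoff: tuple[tuple[float, int, int, float], ...]  # (cutoff, k, K, p)
    min_p: float
    best_cutoff: float
    target_set_at_best: frozenset[str]


def fisher_enrichment_p(k, K: int, m: int, N: int):
    """One-sided enrichment p-value: P(X >= k) for X ~ Hypergeom(N, m, K).

    k = candidate targets inside the photoset (an int or an integer array),
    K = candidate targets total, m = photoset size, N = background size.
    Returns 1.0 when k = 0 (no hits cannot be enrichment).
    """
    ks = np.asarray(k)
    if not (0 <= K <= N and 0 <= m <= N):
        raise ValueError(f"inconsistent counts K={K}, m={m}, N={N}")
    if np.any(ks < 0) or np.any(ks > min(K, m)):
        raise ValueError(f"inconsistent counts k={k}, K={K}, m={m}, N={N}")
    p = np.where(ks == 0, 1.0, hypergeom.sf(ks - 1, N, m, K))
    return float(p) if np.ndim(k) == 0 else p


def cutoff_scan(
    tf_scores: Mapping[str, float] | pd.Series,
    photoset: Iterable[str],
    background_genes: Iterable[str],
    cutoffs: Sequence[float] | None = None,
    tf_id: str = "",
) -> CutoffScanResult:
    """Scan affinity cutoffs for one TF and keep the minimal enrichment p.

    At each cutoff the target set is {g : score(g) > cutoff} (strictly
    above); ties in p across cutoffs resolve to the smallest cutoff.  Genes
    with missing (NaN) scores never pass a cutoff.
    """
    scores = pd.Series(tf_scores, dtype=float)
    background = list(dict.fromkeys(background_genes))
    if not background:
        raise ValueError("empty background gene set")
    photoset = set(photoset)
    if not photoset <= set(background):
        raise ValueError("photoset must be a subset of the background genes")
    missing = [g for g in background if g not in scores.index]
    if missing:
        raise ValueError(f"background genes without scores: {missing[:5]}...")
    cuts = default_cutoffs() if cutoffs is None else np.asarray(sorted(cutoffs), dtype=float)
    if cuts.size == 0:
        raise ValueError("cutoffs must be non-empty")

    vals = scores[background].to_numpy()
    photo_mask = np.fromiter((g in photoset for g in background), bool, len(background))
    N, m = len(background), len(photoset)

    above = vals[:, None] > cuts[None, :]        # genes x cutoffs
    above &= ~np.isnan(vals)[:, None]
    Ks = above.sum(axis=0)
    ks = (above & photo_mask[:, None]).sum(axis=0)
    # vectorised upper tail; sf(-1) = 1 covers k = 0
    ps = hypergeom.sf(ks - 1, N, m, Ks)
    ps = np.where(ks == 0, 1.0, ps)

    best = int(np.argmin(ps))  # first minimum = smallest cutoff
    target_set = frozenset(np.array(background)[above[:, best]])
    per_cutoff = tuple(
        (float(c), int(k), int(K), float(p)) for c, k, K, p in zip(cuts, ks, Ks, ps)
    )
    return CutoffScanResult(
        tf_id=tf_id,
        per_cutoff=per_cutoff,
        min_p=float(ps[best]),
        best_cutoff=float(cuts[best]),
        target_set_at_best=target_set,
    )


def select_photosynthesis_tfs(
    results: Iterable[CutoffScanResult], alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """TFs whose minimal scan p-value is below alpha, ordered by min p then id."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    hits = [r for r in results if r.min_p < alpha]
    hits.sort(key=lambda r: (r.min_p, r.tf_id))
    return [r.tf_id for r in hits]


def enrichment_table(results: Sequence[CutoffScanResult]) -> pd.DataFrame:
    """Summary across TFs with a supplementary BH-adjusted min-p column."""
    rows = []
    for r in results:
        c, k, K, _ = next(pc for pc in r.per_cutoff if pc[0] == r.best_cutoff)
        rows.append(
            {"tf_id": r.tf_id, "min_p": r.min_p, "best_cutoff": r.best_cutoff,
             "k_at_best": k, "K_at_best": K}
        )
    df = pd.DataFrame(rows).sort_values(["min_p", "tf_id"]).reset_index(drop=True)
    p = df["min_p"].to_numpy()
    n = len(p)
    if n:
        ranked = p * n / (np.arange(n) + 1)
        df["bh_q"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    return df
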