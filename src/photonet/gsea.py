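"""GSEA-style coherence between promoter-affinity target sets and MI rankings.

For each TF the promoter evidence yields a discrete target set and the
expression evidence a genome-wide ranking by mutual information.  The
enrichment score (ES) walks down the ranking, incrementing on set members
(weighted by |mi|^weight_p, normalised over the set) and decrementing by
1/(N - N_h) on non-members; ES is the running sum's signed maximum
deviation.  Significance is assessed by gene-set permutation: random sets
of the same size drawn from the ranked universe, with the nominal p taken
against the same-signed portion of the null and +1 smoothing so p never
reaches zero (results below resolution are reported as "<floor").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mi import RankedTargets

__all__ = [
    "CoherenceResult",
    "enrichment_score",
    "gsea_nominal_p",
    "merge_target_sets_by_ortholog",
    "coherence_table",
]


@dataclass(frozen=True)
class CoherenceResult:
    tf_id: str                   # Arabidopsis gene id of the (merged) TF
    labels: tuple[str, ...]      # source TF names mapping to this gene
    set_size: int                # "Num": set members present in the ranking
    es: float
    nom_p: float
    n_permutations: int
    seed: int
    at_floor: bool               # no same-signed null ES was as extreme

    @property
    def p_display(self) -> str:
        if self.at_floor:
            return f"<{self.nom_p:.6g}"
        return f"{self.nom_p:.6g}"


def _hit_weights(mi_values: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> np.ndarray:
    w = np.abs(mi_values) ** weight_p if weight_p != 0 else np.ones_like(mi_values)
    w = np.where(hit_mask, w, 0.0)
    total = w.sum()
    if total == 0:
        # all hit scores are zero: fall back to unweighted increments
        w = hit_mask.astype(float)
        total = w.sum()
    return w / total


def enrichment_score(
    ranked: RankedTargets,
    gene_set: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Running-sum enrichment of a gene set within a descending-MI ranking.

    Returns the signed maximum deviation and the full running sum.
    """
    genes = ranked.targets
    mi = np.asarray(ranked.mi_values, dtype=float)
    gene_set = set(gene_set)
    hit = np.fromiter((g in gene_set for g in genes), bool, len(genes))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == len(genes):
        raise ValueError("gene set covers the entire ranked list")
    steps = _hit_weights(mi, hit, weight_p) - (~hit) / (len(genes) - nh)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _null_es(
    ranked: RankedTargets,
    set_size: int,
    weight_p: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of random same-size gene sets (gene-set permutation null)."""
    N = len(ranked.targets)
    mi = np.asarray(ranked.mi_values, dtype=float)
    w_all = np.abs(mi) ** weight_p if weight_p != 0 else np.ones(N)
    es = np.empty(n_permutations)
    block = max(1, min(256, n_permutations))
    done = 0
    miss_dec = 1.0 / (N - set_size)
    while done < n_permutations:
        b = min(block, n_permutations - done)
        # b random subsets of given size, without replacement
        idx = np.argsort(rng.random((b, N)), axis=1)[:, :set_size]
        hit = np.zeros((b, N), dtype=bool)
        np.put_along_axis(hit, idx, True, axis=1)
        w = np.where(hit, w_all[None, :], 0.0)
        totals = w.sum(axis=1)
        zero = totals == 0
        if zero.any():
            w[zero] = hit[zero].astype(float)
            totals[zero] = set_size
        steps = w / totals[:, None] - (~hit) * miss_dec
        running = np.cumsum(steps, axis=1)
        pick = np.argmax(np.abs(running), axis=1)
        es[done : done + b] = running[np.arange(b), pick]
        done += b
    return es


def gsea_nominal_p(
    ranked: RankedTargets,
    gene_set: Iterable[str],
    weight_p: float = 1.0,
    n_permutations: int = 999,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> CoherenceResult:
    """Observed ES plus its gene-set-permutation nominal p-value.

    The p-value is one-sided against null ES of the same sign as the
    observed value, with +1 smoothing; when no null value is as extreme the
    result sits at the resolution floor and is flagged for "<p" display.
    """
    if n_permutations < 99:
        raise ValueError("too few permutations for a nominal p-value")
    gene_set = set(gene_set)
    present = gene_set & set(ranked.targets)
    es, _ = enrichment_score(ranked, present, weight_p)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked, len(present), weight_p, n_permutations, rng)
    if es >= 0:
        same = null[null >= 0]
        extreme = int((same >= es).sum())
    else:
        same = null[null < 0]
        extreme = int((same <= es).sum())
    nom_p = (1 + extreme) / (1 + same.size)
    return CoherenceResult(
        tf_id=ranked.tf_id,
        labels=tuple(labels) if labels is not None else (ranked.tf_id,),
        set_size=len(present),
        es=es,
        nom_p=float(nom_p),
        n_permutations=n_permutations,
        seed=seed,
        at_floor=extreme == 0,
    )


def merge_target_sets_by_ortholog(
    target_sets: Mapping[str, Iterable[str]],
    ortholog_map,
) -> dict[str, tuple[tuple[str, ...], frozenset[str]]]:
    """Group source-TF target sets by their Arabidopsis ortholog gene.

    TFs sharing an ortholog are merged into one entry carrying the union of
    their target sets and the sorted tuple of source labels.
    """
    merged: dict[str, tuple[list[str], set[str]]] = {}
    for tf_id in sorted(target_sets):
        gene = ortholog_map[tf_id]
        labels, union = merged.setdefault(gene, ([], set()))
        labels.append(tf_id)
        union.update(target_sets[tf_id])
    return {
        gene: (tuple(labels), frozenset(union))
        for gene, (labels, union) in sorted(merged.items())
    }


def coherence_table(results: Sequence[CoherenceResult]) -> pd.DataFrame:
    """One row per distinct TF ortholog: labels, gene id, Num, ES, NOM p."""
    if not results:
        raise ValueError("no coherence results")
    rows = [
        {
            "tf": ",".join(r.labels),
            "homolog": r.tf_id,
            "num": r.set_size,
            "es": r.es,
            "nom_p": r.nom_p,
            "nom_p_display": r.p_display,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values("homolog").reset_index(drop=True)
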