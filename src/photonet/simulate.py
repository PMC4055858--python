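"""Synthetic inputs with planted ground truth.

The generator emulates the study's three data sources so every stage of the
pipeline — and the end-to-end intersection — can be tested against a known
answer: PWMs of controlled information content, promoter sequences with
consensus (or PWM-sampled) binding sites written at recorded positions, and
expression matrices in which each true TF-target pair carries a planted
latent correlation.  True edges therefore have BOTH a promoter site and an
expression dependence, so the two evidence streams are individually and
jointly recoverable.

Expression is generated on a latent Gaussian scale and mapped to positive
intensities by exponentiation with a small log-scale, which keeps the
coefficient of variation meaningful on linear intensities for the
experiment filter.  When a photoset gene is targeted by two TFs, those TFs
are given a common latent factor so that each edge can still realise its
nominal correlation (two independent parents cap the per-parent correlation
at 1/sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .io import (
    COMPONENTS,
    ExpressionMatrix,
    GeneSetAnnotation,
    OrthologMap,
    PromoterRecord,
    PWM,
    write_expression_tsv,
    write_gene_annotation,
    write_ortholog_map,
    write_promoter_fasta,
    write_transfac_pwm,
)

import pandas as pd

__all__ = [
    "GroundTruth",
    "FixtureConfig",
    "Bundle",
    "generate_pwm",
    "pwm_consensus",
    "plan_sites",
    "generate_promoters",
    "generate_expression",
    "make_end_to_end_fixture",
    "write_bundle",
    "evaluate_recovery",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: which TF regulates which gene, where the binding
    sites were written, and the latent correlation of every true edge."""

    true_edges: frozenset[tuple[str, str]]
    planted_sites: dict[tuple[str, str], tuple[tuple[int, str], ...]]
    correlation_of_edge: dict[tuple[str, str], float]
    seed: int
    tf_groups: tuple[tuple[str, ...], ...] = ()  # TFs sharing a latent factor

    def __post_init__(self) -> None:
        extra = set(self.correlation_of_edge) - set(self.true_edges)
        if extra:
            raise ValueError(f"correlated edges that are not true edges: {sorted(extra)[:3]}")


def _column_entropy(p_major: float) -> float:
    """Shannon entropy (bits) of (p, q, q, q) with q = (1-p)/3."""
    q = (1.0 - p_major) / 3.0
    h = 0.0
    for p in (p_major, q, q, q):
        if p > 0:
            h -= p * math.log2(p)
    return h


def generate_pwm(
    width: int,
    information_content: float = 1.5,
    seed: int = 0,
    scale: float = 20.0,
    tf_id: str = "SYN",
) -> PWM:
    """A synthetic PWM whose columns each carry the requested information
    content (bits, in (0, 2]); the dominant base of each column is random.

    Columns are of the form (p, q, q, q) with p solved so that
    2 - H(column) equals the target exactly; counts are frequencies scaled
    by ``scale``.
    """
    if width < 4:
        raise ValueError("width must be at least 4")
    if not (0 < information_content <= 2):
        raise ValueError("information content must be in (0, 2] bits")
    target_h = 2.0 - information_content
    if target_h == 0:
        p_major = 1.0
    else:
        p_major = brentq(lambda p: _column_entropy(p) - target_h, 0.2500001, 1 - 1e-12)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(width):
        col = np.full(4, (1.0 - p_major) / 3.0)
        col[rng.integers(4)] = p_major
        rows.append(col * scale)
    return PWM(tf_id, np.array(rows))


def pwm_consensus(pwm: PWM) -> str:
    """Per-position argmax base (ties: alphabetically first)."""
    return "".join(_BASES[i] for i in np.argmax(pwm.matrix, axis=1))


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def plan_sites(
    edges_of_gene: Mapping[str, Sequence[str]],
    widths: Mapping[str, int],
    length: int,
    sites_per_edge: int,
    rng: np.random.Generator,
    gap: int = 2,
) -> dict[tuple[str, str], tuple[tuple[int, str], ...]]:
    """Draw non-overlapping (position, strand) slots for every planted site.

    ``edges_of_gene`` maps each gene to the TFs that bind it.  Raises if the
    requested sites cannot be placed without overlap.
    """
    planted: dict[tuple[str, str], tuple[tuple[int, str], ...]] = {}
    for gene, tfs in edges_of_gene.items():
        occupied: list[tuple[int, int]] = []
        for tf in tfs:
            w = widths[tf]
            sites = []
            for _ in range(sites_per_edge):
                for _attempt in range(1000):
                    pos = int(rng.integers(0, length - w + 1))
                    if all(pos + w + gap <= a or b + gap <= pos for a, b in occupied):
                        occupied.append((pos, pos + w))
                        strand = "+" if rng.random() < 0.5 else "-"
                        sites.append((pos, strand))
                        break
                else:
                    raise ValueError(
                        f"cannot place {sites_per_edge} non-overlapping sites for "
                        f"gene {gene!r} (promoter too crowded)"
                    )
            planted[(tf, gene)] = tuple(sites)
    return planted


def generate_promoters(
    gene_ids: Sequence[str],
    pwms: Mapping[str, PWM] | None = None,
    planted: Mapping[tuple[str, str], Sequence[tuple[int, str]]] | None = None,
    length: int = 1500,
    gc: float = 0.36,
    sample_sites: bool = False,
    seed: int = 0,
    region: tuple[int, int] = (1000, 500),
) -> list[PromoterRecord]:
    """I.i.d. background sequences at the stated GC content with planted
    binding sites written in at recorded (position, strand) slots.

    Sites are the PWM consensus by default; ``sample_sites=True`` draws each
    base from the PWM column frequencies instead.  Overlapping planted sites
    within one gene are an error.
    """
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    planted = dict(planted or {})
    pwms = dict(pwms or {})
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    sites_of_gene: dict[str, list[tuple[int, str, str]]] = {}
    for (tf, gene), slots in planted.items():
        pwm = pwms[tf]
        freqs = pwm.matrix / pwm.matrix.sum(axis=1, keepdims=True)
        for pos, strand in slots:
            if not (0 <= pos and pos + pwm.width <= length):
                raise ValueError(f"site at {pos} for {tf!r} does not fit in length {length}")
            if sample_sites:
                site = "".join(
                    _BASES[rng.choice(4, p=freqs[i])] for i in range(pwm.width)
                )
            else:
                site = pwm_consensus(pwm)
            if strand == "-":
                site = _reverse_complement(site)
            sites_of_gene.setdefault(gene, []).append((pos, site, tf))

    records = []
    up, down = region
    if up + down != length:
        region_pair = None
    else:
        region_pair = region
    for gene in gene_ids:
        seq = rng.choice(4, size=length, p=probs)
        chars = np.array(list("ACGT"))[seq]
        intervals: list[tuple[int, int]] = []
        for pos, site, tf in sites_of_gene.get(gene, []):
            end = pos + len(site)
            if any(pos < b and a < end for a, b in intervals):
                raise ValueError(f"overlapping planted sites in gene {gene!r}")
            intervals.append((pos, end))
            chars[pos:end] = list(site)
        records.append(PromoterRecord(gene, "".join(chars), region_pair))
    return records


def generate_expression(
    ground_truth: GroundTruth,
    gene_ids: Sequence[str],
    tf_gene_of: Mapping[str, str] | None = None,
    n_samples: int = 300,
    n_experiments: int = 6,
    noise_sd: float = 1.0,
    seed: int = 0,
    intensity_scale: float = 100.0,
    log_sd: float = 0.4,
    flat_tf_experiments: Sequence[str] = (),
) -> ExpressionMatrix:
    """Expression with the planted TF-target dependence.

    TF rows are latent standard normals (TFs within a ground-truth group
    share a common factor); each true target is a linear mix of its parent
    TFs achieving the edge's nominal correlation, other genes are
    independent noise.  All latent values are mapped to intensities
    ``intensity_scale * exp(log_sd * z)`` and samples are partitioned into
    equally sized experiments.  ``flat_tf_experiments`` lists experiment
    labels in which every TF row is made constant (no expression
    diversity), for exercising the experiment filter.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    tf_gene_of = dict(tf_gene_of or {})
    rng = np.random.default_rng(seed)

    tfs = sorted({tf for tf, _ in ground_truth.true_edges})
    for tf in tfs:
        tf_gene_of.setdefault(tf, tf)
    # latent TF values, with group factors where requested
    z_tf: dict[str, np.ndarray] = {}
    grouped = {tf for grp in ground_truth.tf_groups for tf in grp}
    for grp in ground_truth.tf_groups:
        rhos = [ground_truth.correlation_of_edge.get(e, 0.0)
                for e in ground_truth.true_edges if e[0] in grp]
        rho_max = max((abs(r) for r in rhos), default=0.0)
        r = max(0.0, 2 * rho_max * rho_max - 1.0)
        f = rng.standard_normal(n_samples)
        for tf in grp:
            z_tf[tf] = math.sqrt(r) * f + math.sqrt(1 - r) * rng.standard_normal(n_samples)
    for tf in tfs:
        if tf not in grouped:
            z_tf[tf] = rng.standard_normal(n_samples)

    parents_of: dict[str, list[str]] = {}
    for tf, gene in sorted(ground_truth.true_edges):
        parents_of.setdefault(gene, []).append(tf)

    latent: dict[str, np.ndarray] = {}
    for gene in gene_ids:
        parents = parents_of.get(gene)
        if not parents:
            latent[gene] = rng.standard_normal(n_samples)
        elif len(parents) == 1:
            tf = parents[0]
            rho = ground_truth.correlation_of_edge.get((tf, gene), 0.0)
            eps = rng.standard_normal(n_samples)
            latent[gene] = rho * z_tf[tf] + math.sqrt(1 - rho * rho) * noise_sd * eps
        else:
            if len(parents) > 2:
                raise ValueError(f"gene {gene!r} has more than 2 parent TFs")
            t1, t2 = parents
            rho = ground_truth.correlation_of_edge.get((t1, gene), 0.0)
            r_nom = max(0.0, 2 * rho * rho - 1.0)
            u = (z_tf[t1] + z_tf[t2]) / math.sqrt(2 * (1 + r_nom))
            w = min(1.0, rho * math.sqrt(2.0 / (1 + r_nom)))
            s = math.sqrt(max(0.0, 1 - w * w))
            latent[gene] = w * u + s * noise_sd * rng.standard_normal(n_samples)

    all_rows = list(gene_ids) + [tf_gene_of[tf] for tf in tfs
                                 if tf_gene_of[tf] not in gene_ids]
    sample_ids = [f"S{i+1:04d}" for i in range(n_samples)]
    bounds = np.linspace(0, n_samples, n_experiments + 1).astype(int)
    experiment_of_sample = {}
    for e in range(n_experiments):
        for i in range(bounds[e], bounds[e + 1]):
            experiment_of_sample[sample_ids[i]] = f"E{e+1:02d}"

    mat = np.empty((len(all_rows), n_samples))
    tf_rows = {tf_gene_of[tf] for tf in tfs}
    for i, row_gene in enumerate(all_rows):
        src = None
        for tf in tfs:
            if tf_gene_of[tf] == row_gene:
                src = z_tf[tf]
                break
        if src is None:
            src = latent.get(row_gene)
        if src is None:
            src = rng.standard_normal(n_samples)
        mat[i] = intensity_scale * np.exp(log_sd * src)
    if flat_tf_experiments:
        flat = set(flat_tf_experiments)
        cols = [j for j, s in enumerate(sample_ids) if experiment_of_sample[s] in flat]
        for i, row_gene in enumerate(all_rows):
            if row_gene in tf_rows:
                mat[np.ix_([i], cols)] = intensity_scale
    df = pd.DataFrame(mat, index=all_rows, columns=sample_ids)
    return ExpressionMatrix(df, experiment_of_sample)


# ---------------------------------------------------------------------------
# End-to-end fixture


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic benchmark."""

    n_tfs: int = 10
    n_genes: int = 200
    n_photoset: int = 30
    targets_per_tf: int = 4
    fraction_in_photoset: float = 1.0
    rho: float = 0.9
    n_samples: int = 300
    n_experiments: int = 6
    pwm_width: int = 10
    information_content: float = 1.5
    sites_per_edge: int = 3
    promoter_length: int = 1500
    gc: float = 0.36
    sample_sites: bool = False
    plant_sites: bool = True
    noise_sd: float = 1.0
    log_sd: float = 0.4
    flat_tf_experiments: tuple[str, ...] = ()


@dataclass
class Bundle:
    """A consistent set of pipeline inputs plus the planted truth."""

    pwms: list[PWM]
    promoters: list[PromoterRecord]
    expression: ExpressionMatrix
    annotation: GeneSetAnnotation
    ortholog_map: OrthologMap
    ground_truth: GroundTruth
    config: FixtureConfig


def _allocate_targets(
    cfg: FixtureConfig, tf_ids: list[str], photoset: list[str], others: list[str],
    rng: np.random.Generator,
) -> tuple[set[tuple[str, str]], tuple[tuple[str, ...], ...]]:
    """Assign each TF its target genes.

    Photoset targets come first; when the photoset is too small for disjoint
    allocation, TFs are paired and each pair shares some photoset genes (a
    shared gene counts as a target of both).  Non-photoset targets are
    always disjoint.
    """
    n_in = int(round(cfg.fraction_in_photoset * cfg.targets_per_tf))
    n_out = cfg.targets_per_tf - n_in
    slots = cfg.n_tfs * n_in
    edges: set[tuple[str, str]] = set()
    groups: list[tuple[str, ...]] = []
    photo_pool = list(photoset)
    rng.shuffle(photo_pool)

    if slots <= len(photo_pool):
        it = iter(photo_pool)
        for tf in tf_ids:
            for _ in range(n_in):
                edges.add((tf, next(it)))
    else:
        n_shared_total = slots - len(photo_pool)
        if cfg.n_tfs % 2:
            raise ValueError(
                "photoset too small for disjoint targets and TF count is odd; "
                "cannot pair TFs for sharing"
            )
        n_pairs = cfg.n_tfs // 2
        base, rem = divmod(n_shared_total, n_pairs)
        it = iter(photo_pool)
        for p in range(n_pairs):
            t1, t2 = tf_ids[2 * p], tf_ids[2 * p + 1]
            shared = base + (1 if p < rem else 0)
            if shared > n_in:
                raise ValueError("photoset too small even with pairwise sharing")
            if shared > 0:
                groups.append((t1, t2))
            for _ in range(shared):
                g = next(it)
                edges.add((t1, g))
                edges.add((t2, g))
            for tf in (t1, t2):
                for _ in range(n_in - shared):
                    edges.add((tf, next(it)))

    other_pool = list(others)
    rng.shuffle(other_pool)
    if cfg.n_tfs * n_out > len(other_pool):
        raise ValueError("not enough non-photoset genes for out-of-set targets")
    it = iter(other_pool)
    for tf in tf_ids:
        for _ in range(n_out):
            edges.add((tf, next(it)))
    return edges, tuple(groups)


def make_end_to_end_fixture(config: FixtureConfig | None = None, seed: int = 0) -> Bundle:
    """Generate a consistent bundle where every true edge has both a planted
    promoter site and a planted expression correlation."""
    cfg = config or FixtureConfig()
    if cfg.n_tfs <= 0:
        raise ValueError("n_tfs must be positive")
    if cfg.n_photoset > cfg.n_genes:
        raise ValueError("photoset larger than gene universe")
    if cfg.targets_per_tf > cfg.n_genes:
        raise ValueError("more targets per TF than genes")
    rng = np.random.default_rng(seed)

    tf_ids = [f"TF{i+1:02d}" for i in range(cfg.n_tfs)]
    gene_ids = [f"G{i+1:04d}" for i in range(cfg.n_genes)]
    photoset = sorted(rng.choice(cfg.n_genes, size=cfg.n_photoset, replace=False))
    photoset = [gene_ids[i] for i in photoset]
    others = [g for g in gene_ids if g not in set(photoset)]

    edges, groups = _allocate_targets(cfg, tf_ids, photoset, others, rng)
    correlation = {e: cfg.rho for e in edges} if cfg.rho != 0 else {}

    pwms = [
        generate_pwm(cfg.pwm_width, cfg.information_content,
                     seed=int(rng.integers(2**31)), tf_id=tf)
        for tf in tf_ids
    ]
    pwm_of = {p.tf_id: p for p in pwms}

    if cfg.plant_sites:
        edges_of_gene: dict[str, list[str]] = {}
        for tf, gene in sorted(edges):
            edges_of_gene.setdefault(gene, []).append(tf)
        planted = plan_sites(
            edges_of_gene, {tf: pwm_of[tf].width for tf in tf_ids},
            cfg.promoter_length, cfg.sites_per_edge, rng,
        )
    else:
        planted = {}

    truth = GroundTruth(
        true_edges=frozenset(edges),
        planted_sites=planted,
        correlation_of_edge=correlation,
        seed=seed,
        tf_groups=groups,
    )

    promoters = generate_promoters(
        gene_ids, pwm_of, planted, length=cfg.promoter_length, gc=cfg.gc,
        sample_sites=cfg.sample_sites, seed=int(rng.integers(2**31)),
        region=(1000, cfg.promoter_length - 1000) if cfg.promoter_length > 1000 else (0, cfg.promoter_length),
    )

    ortholog = OrthologMap({tf: f"AT{tf}" for tf in tf_ids})
    expression = generate_expression(
        truth,
        gene_ids,
        tf_gene_of={tf: ortholog[tf] for tf in tf_ids},
        n_samples=cfg.n_samples,
        n_experiments=cfg.n_experiments,
        noise_sd=cfg.noise_sd,
        seed=int(rng.integers(2**31)),
        log_sd=cfg.log_sd,
        flat_tf_experiments=cfg.flat_tf_experiments,
    )

    comp_of = {g: COMPONENTS[i % len(COMPONENTS)] for i, g in enumerate(sorted(photoset))}
    annotation = GeneSetAnnotation(frozenset(photoset), comp_of)
    return Bundle(pwms, promoters, expression, annotation, ortholog, truth, cfg)


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture in exactly the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "promoters": out / "promoters.fasta",
        "pwms": out / "pwms.transfac",
        "expression": out / "expression.tsv",
        "experiments": out / "experiments.tsv",
        "annotation": out / "photoset.tsv",
        "orthologs": out / "orthologs.tsv",
    }
    write_promoter_fasta(bundle.promoters, paths["promoters"])
    write_transfac_pwm(bundle.pwms, paths["pwms"])
    write_expression_tsv(bundle.expression, paths["expression"], paths["experiments"])
    write_gene_annotation(bundle.annotation, paths["annotation"])
    write_ortholog_map(bundle.ortholog_map, paths["orthologs"])
    return paths


def evaluate_recovery(network, ground_truth: GroundTruth, ortholog_map: OrthologMap) -> tuple[float, float]:
    """(precision, recall) of a final network against the planted edges.

    Network TF nodes are ortholog gene ids; planted edges use source TF ids.
    """
    true_pairs = {
        (ortholog_map[tf], gene) for tf, gene in ground_truth.true_edges
    }
    found = network.edge_pairs()
    if not found:
        return (1.0 if not true_pairs else 0.0), (1.0 if not true_pairs else 0.0)
    tp = len(found & true_pairs)
    precision = tp / len(found)
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall
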