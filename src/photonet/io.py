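"""Readers and writers for the external file formats used by the pipeline.

Everything downstream consumes the lightweight container types defined here:
promoter sequences (FASTA), TF position weight matrices (TRANSFAC-style
matrix blocks), expression matrices with experiment labels (TSV), gene-set /
component annotations (TSV), TF-to-ortholog maps (TSV) and regulatory
networks (TSV or SIF).  Every reader/writer pair is a lossless round trip on
its own output, and all tabular output is deterministically sorted so runs
are diffable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "COMPONENTS",
    "PromoterRecord",
    "PWM",
    "ExpressionMatrix",
    "GeneSetAnnotation",
    "OrthologMap",
    "read_promoter_fasta",
    "write_promoter_fasta",
    "read_transfac_pwm",
    "write_transfac_pwm",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_ortholog_map",
    "write_ortholog_map",
    "write_network",
    "read_network",
]

#: Functional components of the photosynthetic machinery: Calvin cycle,
#: photosystems II and I, light-harvesting complex, photosynthetic electron
#: transport, cytochrome b6/f, F-type ATPase and C4-related genes.
COMPONENTS = ("CC", "PSII", "PSI", "LHC", "PET", "Cytb6/f", "FTA", "C4")

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence around a gene's transcription start site.

    ``region`` is the (upstream, downstream) extent in bp relative to the
    TSS; the default promoter definition is -1000..+500.  Minus-strand genes
    are assumed pre-reverse-complemented in the input FASTA.
    """

    gene_id: str
    sequence: str
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"promoter {self.gene_id!r}: invalid bases {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if self.region is not None:
            up, down = self.region
            if up + down != len(seq):
                raise FormatError(
                    f"promoter {self.gene_id!r}: sequence length {len(seq)} "
                    f"!= region extent {up}+{down}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix of one TF: W rows x 4 columns (A, C, G, T).

    Entries are non-negative counts or frequencies; every row must have at
    least one strictly positive entry.
    """

    tf_id: str
    matrix: np.ndarray
    source_species: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise FormatError(f"PWM {self.tf_id!r}: matrix must be W x 4 with W >= 1")
        if np.any(m < 0):
            raise FormatError(f"PWM {self.tf_id!r}: negative entries")
        if np.any(m.sum(axis=1) <= 0):
            raise FormatError(f"PWM {self.tf_id!r}: all-zero row")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix with an experiment label per sample."""

    data: pd.DataFrame  # index = gene_ids, columns = sample_ids
    experiment_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        missing = [s for s in self.data.columns if s not in self.experiment_of_sample]
        if missing:
            raise FormatError(f"samples without experiment label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def experiments(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(self.experiment_of_sample[s], None)
        return list(seen)

    def samples_of_experiment(self, experiment: str) -> list[str]:
        return [s for s in self.data.columns if self.experiment_of_sample[s] == experiment]

    def restrict_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data[list(samples)].copy(),
            {s: self.experiment_of_sample[s] for s in samples},
        )


@dataclass(frozen=True)
class GeneSetAnnotation:
    """The photosynthesis gene set and its component label per gene."""

    photoset: frozenset[str]
    component_of_gene: dict[str, str]

    def __post_init__(self) -> None:
        extra = set(self.component_of_gene) - set(self.photoset)
        if extra:
            raise FormatError(f"annotated genes outside photoset: {sorted(extra)}")
        bad = set(self.component_of_gene.values()) - set(COMPONENTS)
        if bad:
            raise FormatError(f"unknown components {sorted(bad)}; allowed: {COMPONENTS}")


@dataclass(frozen=True)
class OrthologMap:
    """Map from source-species TF identifier to its Arabidopsis ortholog gene."""

    pairs: dict[str, str]

    def __getitem__(self, tf_id: str) -> str:
        try:
            return self.pairs[tf_id]
        except KeyError:
            raise KeyError(f"TF {tf_id!r} has no ortholog mapping") from None

    def __contains__(self, tf_id: str) -> bool:
        return tf_id in self.pairs


# ---------------------------------------------------------------------------
# FASTA


def read_promoter_fasta(path: str | Path, region: tuple[int, int] | None = None) -> list[PromoterRecord]:
    """Read promoter sequences; the first whitespace token of each header is
    the gene id.  Lowercase bases are uppercased; duplicate ids are an error.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
                break
        else:
            return []
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            gene_id = rec.id
            if gene_id in seen:
                raise FormatError(f"{path}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            records.append(PromoterRecord(gene_id, str(rec.seq), region))
    return records


def write_promoter_fasta(records: Iterable[PromoterRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TRANSFAC matrices


def read_transfac_pwm(path: str | Path) -> list[PWM]:
    """Parse TRANSFAC-style matrix blocks.

    A block carries the matrix identifier on an ``ID`` (or ``NA``) line,
    per-position rows of four numeric fields (an optional leading position
    index and trailing consensus letter are tolerated), and ends with ``//``.
    """
    path = Path(path)
    pwms: list[PWM] = []
    tf_id: str | None = None
    species: str | None = None
    rows: list[list[float]] = []
    in_block = False

    def flush(lineno: int) -> None:
        nonlocal tf_id, species, rows
        if tf_id is None:
            raise FormatError(f"{path}:{lineno}: matrix block without ID/NA line")
        if not rows:
            raise FormatError(f"{path}:{lineno}: matrix {tf_id!r} has no count rows")
        pwms.append(PWM(tf_id, np.array(rows, dtype=float), species))
        tf_id, species, rows = None, None, []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("//"):
                flush(lineno)
                in_block = False
                continue
            in_block = True
            tag = line[:2]
            if tag in ("ID", "AC") and tf_id is None:
                tf_id = line[2:].strip()
                continue
            if tag == "NA":
                val = line[2:].strip()
                if tf_id is None:
                    tf_id = val
                continue
            if tag == "BF":
                species = line[2:].strip()
                continue
            fields = line.split()
            if tag in ("PO", "P0"):
                continue
            if fields and _is_int(fields[0]):
                # per-position row: leading position index, 4 counts, optional
                # trailing consensus letter
                body = fields[1:]
                if body and not _is_number(body[-1]):
                    body = body[:-1]
                if len(body) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected 4 numeric count fields, got {len(body)}"
                    )
                try:
                    vals = [float(v) for v in body]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric count: {exc}") from None
                if any(v < 0 for v in vals):
                    raise FormatError(f"{path}:{lineno}: negative count")
                rows.append(vals)
            # other annotation tags ignored
    if in_block:
        raise FormatError(f"{path}:{lineno}: matrix block not terminated by '//'")
    return pwms


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_transfac_pwm(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.tf_id}\n")
            if pwm.source_species:
                fh.write(f"BF {pwm.source_species}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.matrix, 1):
                fh.write(f"{i:02d} " + " ".join(repr(float(v)) for v in row) + "\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression_tsv(path: str | Path, experiment_map_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene
    ids) plus a two-column sample -> experiment map."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from None
    if df.isna().to_numpy().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise FormatError(
            f"{path}: missing/non-numeric cell at gene {df.index[rows[0]]!r}, "
            f"sample {df.columns[cols[0]]!r}"
        )
    df.index.name = None
    emap = _read_two_column(experiment_map_path, "sample_id", "experiment")
    return ExpressionMatrix(df, emap)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path, experiment_map_path: str | Path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    with open(experiment_map_path, "w") as fh:
        fh.write("sample_id\texperiment\n")
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.experiment_of_sample[s]}\n")


def _read_two_column(path: str | Path, key_name: str, value_name: str) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if lineno == 1 and fields[0] == key_name:
                continue  # optional header
            if fields[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate key {fields[0]!r}")
            out[fields[0]] = fields[1]
    return out


# ---------------------------------------------------------------------------
# Annotation / ortholog map


def read_gene_annotation(path: str | Path) -> GeneSetAnnotation:
    """Two-column TSV gene_id <tab> component; the photoset is the set of all
    listed genes."""
    mapping = _read_two_column(path, "gene_id", "component")
    return GeneSetAnnotation(frozenset(mapping), dict(mapping))


def write_gene_annotation(annotation: GeneSetAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcomponent\n")
        for g in sorted(annotation.photoset):
            fh.write(f"{g}\t{annotation.component_of_gene[g]}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    return OrthologMap(_read_two_column(path, "tf_id", "ortholog_gene_id"))


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tortholog_gene_id\n")
        for tf in sorted(omap.pairs):
            fh.write(f"{tf}\t{omap.pairs[tf]}\n")


# ---------------------------------------------------------------------------
# Network TSV / SIF


def write_network(network, path: str | Path, dialect: str = "tsv") -> None:
    """Write a regulatory network; ``tsv`` carries both evidence values,
    ``sif`` is the graph-viewer interchange form.  Edges are written in
    lexicographic (tf_id, target_id) order."""
    edges = sorted(network.edges, key=lambda e: (e.tf_id, e.gene_id))
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("tf_id\ttarget_id\taffinity\tmi\n")
            for e in edges:
                fh.write(f"{e.tf_id}\t{e.gene_id}\t{e.affinity!r}\t{e.mi!r}\n")
    elif dialect == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.tf_id} regulates {e.gene_id}\n")
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path: str | Path, annotation: GeneSetAnnotation | None = None):
    """Read the TSV network dialect back into a RegulatoryNetwork."""
    from .topology import Edge, RegulatoryNetwork

    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["tf_id", "target_id", "affinity", "mi"]:
            raise FormatError(f"{path}: unexpected network header {header}")
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            edges.append(Edge(fields[0], fields[1], float(fields[2]), float(fields[3])))
    comp = dict(annotation.component_of_gene) if annotation is not None else {}
    return RegulatoryNetwork(edges=edges, component_of_gene=comp)
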