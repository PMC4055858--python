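"""Run configuration: every threshold of the workflow in one place.

The config file is plain text, one ``key = value`` pair per line (``#``
comments allowed).  Field names match :class:`RunConfig`; unknown keys are
an error so typos do not silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # input files
    promoters: str = "promoters.fasta"
    pwms: str = "pwms.transfac"
    expression: str = "expression.tsv"
    experiments: str = "experiments.tsv"
    annotation: str = "photoset.tsv"
    orthologs: str = "orthologs.tsv"
    out_dir: str = "photonet_out"

    # promoter-affinity model
    lam: float = 0.7
    pseudocount: float = 1.0
    top_n: int = 1000

    # enrichment scan
    cutoff_min: float = 0.5
    cutoff_max: float = 5.0
    cutoff_step: float = 0.1
    alpha: float = 0.001

    # expression preparation
    cv_threshold: float = 0.1
    cv_fraction: float = 0.5
    cv_log2: bool = False

    # mutual-information network
    p_threshold: float = 1e-7
    bandwidth_scale: float = 1.06
    n_permutations: int = 100_000
    dpi: bool = True
    dpi_tolerance: float = 0.15

    # coherence analysis
    gsea_permutations: int = 999
    gsea_weight: float = 1.0

    seed: int = 17


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    known = {f.name: f for f in fields(RunConfig)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        typ = known[key].type
        if typ in ("bool", bool):
            values[key] = val.lower() in ("1", "true", "yes", "on")
        elif typ in ("int", int):
            values[key] = int(val)
        elif typ in ("float", float):
            values[key] = float(val)
        else:
            values[key] = val
    return RunConfig(**values)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            fh.write(f"{key} = {val}\n")
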