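"""Shared fixtures.

The heavy session fixtures run the full pipeline on the default synthetic
study conditions (10 TFs, 200 genes, photoset 30, rho = 0.9, planted
consensus sites, 300 chips) over 10 seeds, plus 10 negative-control runs
with no planted signal; several tests consume the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import photonet as pn

E2E_SEEDS = list(range(1, 11))
E2E_PERMUTATIONS = 20_000
PIPELINE_SEED = 17


@pytest.fixture(scope="session")
def default_bundle():
    return pn.make_end_to_end_fixture(seed=1)


def _run_one(seed: int, **cfg_kwargs):
    bundle = pn.make_end_to_end_fixture(
        pn.FixtureConfig(**cfg_kwargs) if cfg_kwargs else None, seed=seed
    )
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        result = pn.run_from_bundle(
            bundle, tmp, n_permutations=E2E_PERMUTATIONS, seed=PIPELINE_SEED
        )
    return bundle, result


@pytest.fixture(scope="session")
def e2e_runs():
    """Ten full pipeline runs on the planted-signal study conditions."""
    runs = []
    for seed in E2E_SEEDS:
        bundle, result = _run_one(seed)
        precision, recall = pn.evaluate_recovery(
            result.network, bundle.ground_truth, bundle.ortholog_map
        )
        true_pairs = {
            (bundle.ortholog_map[tf], g) for tf, g in bundle.ground_truth.true_edges
        }
        mi_pairs = {(e.tf_id, e.gene_id) for e in result.mi_edges}
        mi_tp = len(mi_pairs & true_pairs)
        runs.append(
            {
                "seed": seed,
                "bundle": bundle,
                "result": result,
                "precision": precision,
                "recall": recall,
                "n_selected": len(result.selected_tfs),
                "mi_precision": mi_tp / len(mi_pairs) if mi_pairs else 0.0,
                "mi_recall": mi_tp / len(true_pairs) if true_pairs else 0.0,
            }
        )
    return runs


@pytest.fixture(scope="session")
def negative_control_runs():
    """Ten runs with no planted promoter sites and no planted correlation."""
    runs = []
    for seed in E2E_SEEDS:
        _, result = _run_one(seed, plant_sites=False, rho=0.0)
        runs.append({"seed": seed, "n_selected": len(result.selected_tfs)})
    return runs
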