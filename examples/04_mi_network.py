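"""Infer TF-target edges from expression by mutual information.

Calibrates the permutation null of the rank-based kernel MI estimator,
extrapolates its exponential tail to reach the p < 1e-7 working threshold,
and prunes indirect edges with the data-processing-inequality rule.
"""

import numpy as np
import pandas as pd

import photonet as pn

rng = np.random.default_rng(3)
n = 300
tf = rng.standard_normal(n)
target = 0.9 * tf + np.sqrt(1 - 0.81) * rng.standard_normal(n)
noise = rng.standard_normal((18, n))
mat = np.vstack([tf, target, noise])
genes = ["TF01", "G001"] + [f"G{i:03d}" for i in range(2, 20)]
samples = [f"s{i}" for i in range(n)]
expr = pn.ExpressionMatrix(
    pd.DataFrame(np.exp(0.4 * mat) * 100, index=genes, columns=samples),
    {s: "E01" for s in samples},
)

null = pn.fit_null(expr, n_permutations=20_000, seed=0)
print(f"null tail fit: ln P(MI > m) = {null.intercept:.2f} - {null.slope:.1f} m")
print(f"MI needed for p < 1e-7: {(null.intercept + np.log(1e7)) / null.slope:.3f} nats")

edges, rankings = pn.infer_edges(expr, ["TF01"], null, p_threshold=1e-7)
edges = pn.dpi_prune(edges, tolerance=0.15)
for e in edges:
    print(f"edge {e.tf_id} -> {e.gene_id}: MI = {e.mi:.3f} nats, p = {e.p:.2e}")
# Only the planted pair survives: its MI (~0.7 nats, close to the Gaussian
# value -0.5 ln(1-0.81) = 0.83) sits far beyond the extrapolated null tail,
# while the noise genes' MI stays near zero.
print(f"top of TF01 ranking: {rankings['TF01'].targets[:3]}")
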