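"""Score a TF's binding motif against promoters with the occupancy model.

Builds a synthetic 10-bp motif, plants three consensus copies into one
promoter out of fifty, and shows that the expected-occupancy score N picks
that promoter out, and that the top-candidate ranking is insensitive to the
energy scale lambda.
"""

import numpy as np

import photonet as pn

pwm = pn.generate_pwm(width=10, information_content=1.5, seed=1, tf_id="TF01")
genes = [f"G{i:03d}" for i in range(50)]
promoters = pn.generate_promoters(
    genes, {"TF01": pwm},
    planted={("TF01", "G000"): [(100, "+"), (400, "-"), (900, "+")]},
    length=1500, seed=2,
)

model = pn.build_energy_model(pwm, lam=0.7)
scores = {p.gene_id: pn.affinity_score(model, p) for p in promoters}
top = sorted(scores, key=lambda g: -scores[g])[:3]
print(f"motif consensus: {model.consensus}, R0 = {model.r0:.3f}")
print("top promoters by occupancy N:")
for g in top:
    print(f"  {g}: N = {scores[g]:.4f}")
# G000 carries the planted sites, so its N (~1.6, roughly 3 sites x the
# consensus binding probability) dwarfs the ~1e-3 background of the rest.

sweep = pn.lambda_sweep(pwm, promoters, lambdas=(0.5, 0.7, 0.9), n=10)
print("\ntop-10 overlap against the lambda = 0.7 ranking:")
print(sweep.to_string(index=False))
# An overlap of 1.0 means the candidate list is unchanged: the ranking is
# robust to the mismatch-energy scale.
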