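"""Check that promoter-evidence target sets agree with the MI ranking.

For one TF, the promoter stream proposes a discrete target set and the
expression stream a genome-wide MI ranking; the enrichment score measures
whether the set concentrates at the top of the ranking, with a gene-set
permutation p-value.
"""

import numpy as np

import photonet as pn
from photonet.mi import RankedTargets

rng = np.random.default_rng(5)
genes = tuple(f"G{i:03d}" for i in range(100))
mi = np.sort(rng.exponential(0.05, 100))[::-1]
mi[:5] += 0.5  # five genes with genuinely high MI at the top
ranking = RankedTargets("ATTF01", genes, tuple(mi))

coherent_set = set(genes[:5]) | set(genes[40:45])    # half the set at the top
random_set = set(rng.choice(genes, 10, replace=False))

for name, gene_set in [("coherent", coherent_set), ("random", random_set)]:
    res = pn.gsea_nominal_p(ranking, gene_set, weight_p=1, n_permutations=999, seed=1)
    print(f"{name} target set: Num = {res.set_size}, ES = {res.es:.3f}, "
          f"NOM p = {res.p_display}")
# The coherent set's ES approaches 1 (its members carry most of the MI
# weight near rank 1) and its permutation p sits at the reporting floor;
# the random set's ES is small and its p is unremarkable.
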