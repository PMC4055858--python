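# Methods

## Promoter-occupancy scoring

A PWM (counts or frequencies, columns A,C,G,T) is regularised with a
pseudocount (default 1.0, spread by the background composition, default
uniform) and converted to a mismatch-energy matrix: at each position the
argmax base (ties broken A<C<G<T) defines the consensus and carries zero
energy; every other base pays `ln(w_max/w_b)/λ`. λ (default 0.7) scales
mismatch energies in thermal units; β ≡ 1 throughout. A width-W site binds
with probability `p = R0·e^(−E)/(1+R0·e^(−E))`, and the promoter score N
sums p over all L−W+1 windows of the forward strand **and** of the reverse
complement. Both strands are scored because many of the relevant motifs
(the G-box CACGTG bound by the bZIP family) are palindromic or
near-palindromic; the both-strand sum also makes N invariant under
reverse-complementing the promoter. N therefore lies in [0, 2(L−W+1)].

R0 folds together the TF concentration and the consensus equilibrium
constant, neither observable here; the default is the published TRAP width
calibration `ln R0 = 0.584·W − 5.66`, overridable per TF. Two useful
identities are enforced by construction and covered by tests: a uniform
PWM at R0 = 1 gives N = L−W+1 exactly, and adding a constant c to the
energy of any single motif position is exactly compensated by multiplying
R0 by e^c (gauge freedom of the Fermi function). `N` bases are charged the
background-expected energy of their position rather than invalidating the
window, keeping N comparable across promoters with occasional ambiguous
bases.

Promoters are the −1000..+500 region around the TSS (1500 bp); minus-strand
genes are assumed pre-reverse-complemented in the input FASTA.

## Cutoff-scanning enrichment

For each TF the per-gene scores are thresholded at cutoffs 0.5 to 5.0 in
steps of 0.1 (46 values, strict `score > cutoff`); at each cutoff the
candidate set is tested for photosynthesis-set enrichment with the
one-sided hypergeometric upper tail (k = 0 defined as p = 1), and the
minimum p across cutoffs is the TF's statistic, called at p < 0.001. The
background is the full promoter universe. Taking a raw minimum over 46
nested, correlated tests inflates the type-I rate — bounded above by the
Bonferroni envelope 46 × 0.001 and measured at ≈0.01 under a simulated
null in the acceptance checks — so a Benjamini–Hochberg column across TFs
is emitted as supplementary output; selection itself uses the raw minimum,
which is the procedure under study. The target set reported for each TF is
the set realised at the p-minimising cutoff (ties resolve to the smallest
cutoff); the same set feeds the coherence analysis and the final
intersection, the only internally consistent choice.

## Expression preparation

Mutual information needs the regulators to vary, so whole experiments
(chip groups) are kept only when more than half of the TFs of interest
have coefficient of variation (sample sd / mean, n−1 denominator) above
0.1 within that experiment, computed on linear intensities (a log2 option
exists). Kept chips are quantile-normalised: every sample is mapped onto
the mean of the per-sample sorted intensity vectors, ties within a sample
receiving the mean of the quantile values they span. This is the
single-channel default behaviour of limma's between-array normalisation,
is idempotent, and preserves within-sample rank order — which is all the
rank-based MI estimator downstream can see.

## Mutual information and significance

The estimator rank-transforms both variables to their empirical copula,
maps the ranks to normal scores (Φ⁻¹(r/(n+1))), and estimates joint and
marginal densities with a fixed-bandwidth Gaussian product kernel,
h = 1.06·sd·n^(−1/6), evaluated leave-one-out at the data points:
`MI = mean ln( f̂_xy / (f̂_x·f̂_y) )`, clamped at zero. The estimator is
exactly symmetric and exactly invariant under strictly monotone transforms
of either variable. On the bivariate-Gaussian benchmark (ρ = 0.9,
n = 10⁴, closed form −½ln(1−ρ²) ≈ 0.830) the estimate lands within a few
hundredths of a nat; under independence at n = 5000 the absolute estimate
stays below 0.02. An equal-frequency histogram estimator (`bins`) is
provided as an independent fallback for cross-checks.

The working significance threshold, p < 10⁻⁷, is far beyond raw
permutation resolution. Because the estimator is rank-based, its
permutation null for tie-free data depends only on the sample count: both
margins are the fixed normal-score grid and a permutation is a random
pairing of grid points. The null is therefore computed once per sample
count (kernel matrix precomputed on the grid; default 10⁵ permutations,
cached) and its upper decile fit by least squares as
`ln P(MI > m) = a − b·m`; p-values are `min(1, e^(a−b·mi))`, with
p(mi ≤ 0) ≡ 1. The exponential-tail extrapolation is an approximation in
the ARACNE tradition; its fitted survival reproduces the empirical 99th
percentile within a factor of two, and at n = 300 the extrapolated 10⁻⁷
point sits near 0.07 nats — an order of magnitude below the MI of a
planted ρ = 0.9 pair — so edge calls are insensitive to moderate fit
error. DPI pruning (on by default, tolerance 0.15) removes, in every fully
connected triple, the weakest edge when its MI falls below (1−tolerance)
times the smaller of the other two, all decisions taken simultaneously on
the input graph. Edges are inferred TF-versus-all-genes (TF–TF edges
included so DPI has triangles); gene–gene edges are out of scope.

## Coherence analysis

For each called TF (TFs sharing an Arabidopsis ortholog merged, with the
union of their target sets), the promoter-derived target set is tested for
concentration at the top of the TF's full MI ranking with the standard
weighted running sum: hits add `|mi|^p` (normalised over the set, p = 1 by
default; p = 0 is the classic unweighted statistic), misses subtract
1/(N−N_hits), and the enrichment score is the signed maximum deviation.
Significance uses gene-set permutation — random same-size sets from the
ranked universe — since a preranked list admits no phenotype permutation.
The nominal p is computed against the same-signed portion of the null with
+1 smoothing, so it is uniform under the null (verified by a KS check in
the acceptance suite) and never exactly zero; results below resolution are
reported as "<floor", matching the "<0.001" convention of permutation
GSEA output.

## Network intersection and topology

The final network keeps the pair (TF, gene) iff the gene is in the TF's
best-cutoff target set and the pair carries a significant MI edge; edges
record both evidence values, and the intersection invariant is asserted on
every build. Topology is computed on the undirected projection of the
largest connected component (the convention of the graph-analysis tools
used in this field): diameter and mean shortest path by BFS over all
reachable ordered pairs, mean neighbours = mean degree, clustering by
neighbour-pair counting (degree < 2 → 0). The degree distribution is
fitted two ways: least squares on (ln degree, ln count) over positive
counts, and the continuous maximum-likelihood exponent with k_min = 1.
The two disagree systematically on raw samples from heavy-tailed graphs —
count regression flattens when tail bins hold single nodes — which is why
both are reported and no goodness-of-fit claim is made; they coincide
exactly on an exactly power-law histogram. The TF-component bipartite
collapse links a TF to a pathway component (CC, PSII, PSI, LHC, PET,
Cytb6/f, FTA, C4) when it targets at least one of the component's genes,
weighted by the number of such genes; unannotated targets go to
"unassigned" with a warning.

## Synthetic study conditions

The generator emulates the study's three inputs with recoverable ground
truth. Defaults, chosen once as realistic for this system:

- **PWMs**: width 10 (G-box-family motifs are ~10 bp), information content
  1.5 bits/column (columns of form (p, q, q, q) with p solved exactly for
  the target content, dominant base random).
- **Promoters**: 1500 bp, i.i.d. background at GC 0.36 (Arabidopsis
  promoter regions are AT-rich), 3 planted consensus copies per true edge
  at random non-overlapping positions and strands (tandem G-box copies are
  common in light-regulated promoters). Three copies put a planted gene's
  occupancy near 1.6 — inside the 0.5–5.0 cutoff window — against a
  background of ~10⁻³ with occasional chance consensus hits (~0.5).
- **Regulatory structure**: 10 TFs × 4 targets, all inside the 30-gene
  photoset, so the best-cutoff table is k = K = 4 of m = 30 in N = 200 and
  the enrichment call is deterministic (p ≈ 4×10⁻⁴ < 10⁻³). Forty target
  slots exceed the photoset, so TFs are paired (like bZIP heterodimer
  partners) and each pair shares some targets; paired TFs receive a common
  latent factor so a shared target still realises the nominal per-edge
  correlation — two *independent* parents would cap it at 1/√2.
- **Expression**: latent standard-normal TF profiles; each target is a
  linear mix of its parent(s) achieving ρ = 0.9; 300 chips in 6
  experiments; intensities = 100·e^(0.4·z), a log-normal map that keeps
  the linear-scale CV ≈ 0.41 so informative experiments pass the 0.1
  filter. The log-normal map attenuates Pearson correlation only slightly
  (0.9 → ≈0.89) and does not affect the rank-based MI at all.

What the generator does **not** emulate: probe-level microarray noise,
saturation, batch effects, indirect regulatory chains, combinatorial
(AND/OR) regulation, and chromatin context of binding sites. Passing the
recovery tests therefore shows the pipeline's statistical machinery is
correct and calibrated, not that real TRANSFAC/GEO inputs would yield the
same accuracy.

## Problem sizes and numerical choices

The test and acceptance runs scale the expensive calibrations to sizes
that keep a full run within a few minutes on one CPU while leaving wide
statistical margins: 2×10⁴ permutations for the MI null (the fitted tail
is stable from ~10⁴; the library default remains 10⁵), 10 generator seeds
for the recovery medians, 2000–5000 simulated TFs for the cutoff-scan null
rate, 999 (tests: 199) gene-set permutations for coherence p-values.
Floating-point ties: consensus and ranking ties break alphabetically /
by ascending gene id; cutoff ties resolve to the smallest cutoff; all
tabular output is deterministically sorted, and identical config + seed
reproduce every output byte for byte (the run manifest records seeds,
digests and timings).

Known limitations: the exponential tail extrapolation is unvalidated
beyond the permutation range it is fitted on; the min-p cutoff scan is
deliberately uncorrected (fidelity to the procedure under study); DPI with
tolerance 0 can remove true edges in tightly co-regulated triples; and the
power-law regression estimate inherits the raw-histogram bias discussed
above.
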