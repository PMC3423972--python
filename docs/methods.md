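# Methods

## Model and procedure

The object of analysis is a compound × gene matrix **P** of fitness-defect
p-values: entry `P[c, g]` is the significance of compound *c*'s growth
interaction with the deletion strain of gene *g*. Profiles are clustered as
rows (compounds); genes are never clustered.

**Prioritization.** Given a signature compound *s*, a set of clustering
trials T (each a similarity measure paired with a linkage rule), and a
subcluster policy, the consensus frequency of compound *c* is

    f(c) = |{t in T* : c in S_t(s)}| / |T*|

where S_t(s) is the signature's subcluster in trial *t* and T* is the set
of trials that completed (a trial whose distance matrix contains an
uninformative pair — NaN — is skipped and removed from the denominator;
a failed trial carries no evidence either way). Compounds are ranked by
descending f, ties broken by identifier. f(s) = 1 identically.

**Similarity measures** (over the genes present in *both* profiles —
pairwise-complete deletion): Pearson correlation distance 1 − r, the
uncentered (cosine-like) analogue 1 − Σxy/√(Σx²Σy²), their absolute
variants 1 − |·|, Spearman distance 1 − r_s with average (mid-rank) ties,
Euclidean √Σ(x−y)² and city-block Σ|x−y|. The metric sums are not rescaled
by the shared-gene count by default (matching the Cluster-3.0 behavior
family); `scale_by_shared=True` divides them by the count for users who
want length-invariance under missingness. A correlation that is undefined
(constant profile, or fewer than two shared genes) is assigned the
measure's maximum distance (2, or 1 for absolute variants) with a logged
warning — "no evidence of similarity" is the conservative reading.

**Linkages.** Greedy agglomeration, recording the merge dissimilarity as
height: single = min over cross pairs, complete = max, average = UPGMA
(unweighted mean over cross pairs; "average linkage" unqualified means
UPGMA). Centroid linkage computes the coordinate-wise mean profile of each
cluster (mean over present entries per gene) and evaluates the trial's own
measure between centroids — Cluster-3.0 semantics, which is what makes
centroid linkage meaningful under correlation measures; the Lance–Williams
centroid update is valid only for squared-Euclidean geometry and is not
used. Consequence: centroid heights may invert; inversions are logged and
kept. Ties at the minimal distance are broken deterministically by the
lexicographically least (smaller, larger) pair of cluster representatives,
each cluster represented by its smallest original row index; this makes
trees reproducible across platforms and row orderings.

**Subcluster policies.** `min_size:M` walks up the tree from the signature
leaf to the smallest ancestor with ≥ M leaves (default M = max(2,
⌈0.05·n⌉)); `cut_k:K` cuts the tree into K blocks by undoing the last K−1
merges and takes the signature's block. The ancestor walk is the default
because it directly formalizes "the compounds nearest the signature in the
tree" independent of total tree depth. Note its one sharp edge: the
ancestor size can jump well past M in a single merge, so with weak signal
the window often contains far more than M compounds.

**Phenotype statistics.** The 2×2 exact test conditions on both margins
and sums hypergeometric probabilities of all tables as-or-less-probable
than the observed one (relative tolerance 1e-7 on the comparison, so exact
ties survive float round-off; mid-p is not used). On the ectopic-vessel
incidence table (6/8 vs 0/9) this yields p = 0.00226, i.e. 0.0023 at the
printed precision — the identification of the test as the exact conditional
test rests on reproducing that value, since the original analysis does not
name it. Tumor volume is width²·length/2 (width the shorter caliper axis;
reversed inputs are swapped with a note). Wound closure is
(area₀ − area_t)/area₀, reported negative if the gap grew. Dose conversion:
mg/kg = mass/body-mass; µmol/kg = mg/kg ÷ molar mass × 1000, and under the
1 kg ≈ 1 L density assumption µmol/kg is reported as the µM-equivalent
body concentration. The thiabendazole molar mass constant is 201.25 g/mol
(C10H7N3S). Vessel area is the fraction of pixels strictly above the
intensity threshold ("above" = strict inequality).

## Synthetic screens

The generator emulates a chemogenomic p-value matrix: background entries
i.i.d. Uniform(0,1); entries at (module compound, module gene) positions
i.i.d. Beta(α, 1) — a one-parameter p-value family that is the uniform
null at α = 1 and concentrates near zero as α → 0 (mean α/(α+1)); cells
are then masked missing completely at random. Defaults: 20 compounds, 100
genes, a 4-compound × 20-gene module, α = 0.05, no missingness, the first
module compound as signature. These defaults are a modeling choice: the
original data's significance fraction and dependence structure are not
characterized anywhere usable, so the generator aims for a clearly planted
but not trivial module at a desk-scale matrix size.

What the generator does **not** emulate: correlated noise between strains,
batch effects, dose–response structure, informative missingness, or the
heavy compound redundancy of real libraries. Passing recovery tests
therefore show the machinery is correct and the consensus logic behaves as
designed — not that real screens separate this cleanly.

## Numerical choices

- All randomness flows from explicit integer seeds (`numpy`
  `default_rng`); identical parameters give bit-identical matrices, trees
  and output files.
- Correlations are clipped to [−1, 1] and correlation distances to their
  theoretical range to absorb float round-off.
- TSV values are written with 12 significant digits; round-trips preserve
  values to 1 part in 1e11 and masks exactly.
- `.gtr` scores are 1 − height/h_max, mapping merge heights onto a [0, 1]
  similarity scale (descending down the file when heights are monotone);
  the original tool family does not pin this normalization down, and this
  choice matches what TreeView expects to render.
- Complete-data distance computation uses vectorised BLAS paths; masked
  data falls back to an explicit per-pair loop. Both are tested against a
  direct-formula oracle at 1e-12.

## Validation design

Clustering is verified against a from-scratch O(n³) re-scan oracle (all
inter-cluster distances recomputed from member lists at every step) across
all 28 measure × linkage combinations on random matrices with 10%
missingness, to 1e-9 on heights and exact topology; single/complete/average
heights are additionally cross-checked against an independent
library implementation on complete data. The exact test is verified against
exhaustive integer-arithmetic enumeration for every table with total ≤ 40
and cross-checked against an independent implementation.

Method-level validation uses two synthetic regimes:

- **Recovery** (α = 0.05): the three planted partners should occupy the top
  three consensus ranks. With a tight subcluster window (`min_size:4`) this
  holds in every synthetic screen exercised in the test suite. With the wide
  `min_size:8` window and all 28 trials on raw p-values it holds in only
  roughly half of the screens (`planted_module_recovery_pct`), for two
  compounding reasons measured in `results/acceptance.json`: (i) uncentered
  correlation on raw p-values is dominated by the large non-significant
  entries (module signal lives in values near 0, which cosine similarity
  of positive vectors barely weights), so the 8 uncentered-family trials
  are effectively noise; (ii) the wide window admits ~4 background
  compounds per informative trial, giving the best background compounds
  near-tie frequencies (background mean f ≈ 0.65 vs planted ≈ 0.93). The
  −log10 transform (`transform="neglog10"`) largely repairs (i) and is the
  recommended mode when uncentered measures are in the trial set; it is
  never applied silently because it changes which compounds look similar.
- **Null** (α = 1): planted labels are exchangeable with background; a
  label-permutation test on the planted-minus-background mean frequency
  gap, pooled over 100 independent screens, stays far from rejection
  (p ≈ 0.37 at the 0.01 level).

## Problem sizes

Default validation sizes — 20×100 screens, 10×30 oracle matrices, 20
recovery and 100 null seeds, 999 permutations — were chosen so the full
suite and the acceptance script each complete in well under a coffee break
on one core while keeping every Monte-Carlo standard error far below the
margins being asserted.

## Known limitations

- Which subset of measure × linkage combinations constituted the original
  nineteen trials is not recorded anywhere; the default here is all 28,
  and any chosen subset can be reproduced via the exclusion list.
- Whether the original subcluster came from an algorithmic cut or visual
  tree inspection is unknown; both offered policies are explicit
  formalizations, recorded in run metadata.
- Whether the original analysis pairwise-deleted or zero-filled missing
  entries is unstated; pairwise-complete deletion is the default here.
- Column (gene) trees and `.atr` output are not emitted; only compound
  clustering affects prioritization.
- No significance is attached to consensus frequencies (no bootstrap or
  stability resampling); the frequency is a descriptive prioritization
  score.
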