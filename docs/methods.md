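# Methods

This note records the statistical conventions, model assumptions and design
choices behind `haptonet`, at the level of detail a user needs to interpret
its outputs or reproduce them with another toolkit.

## Synthetic data model

The generator emulates a paired-layer marine amplicon survey: `n_stations`
stations (default 14), each sampled at the surface and at the subsurface
chlorophyll maximum (SCM), for 2 × `n_stations` samples. Environmental
covariates are drawn uniformly within per-habitat ranges patterned on
summer Arctic hydrography (SCM depth 15–62 m, temperature −1.58 to
2.96 °C, salinity 30.7–32.4, PO₄ 0.71–2.01 µM, NO₂+NO₃ 0.7–8.22 µM, SiO₂
2.55–23.74 µM); NH₄ is set missing for roughly two-thirds of SCM stations
to mimic below-detection values, and missingness is always explicit (NA),
never encoded as zero.

Counts follow a log-normal/multinomial (softmax) model. For sample *s* and
ZOTU *j*:

    eta[s, j] = base[j]
              + habitat_effect * 1[j in differential set of habitat(s)]
              + scm_dominance  * 1[j in dominance set, habitat(s) = SCM]
              + temperature_effect * z_temp[s] * loading[j]
              + noise_sd[habitat(s)] * noise[s, j]

with `base ~ N(0, base_sd²)` (a log-normal rank-abundance curve),
`loading ~ N(0, 1)` fixed per ZOTU, and `noise` standard normal except
inside declared correlation blocks, where members share a latent factor
with weight √ρ so the within-block latent correlation is exactly ρ and
cross-block correlation is 0. Counts are a multinomial draw of size
`Uniform(depth_range)` (default 35,677–121,493 reads, the depth range of
the emulated survey) from `softmax(eta[s])`. One integer seed drives
everything; identical (design, seed) is bit-reproducible.

The `paper_like` preset freezes the study conditions used by the
end-to-end tests and the acceptance script: 600 ZOTUs, `base_sd` 1.5,
habitat shift 2.0 on 60 surface- and 40 SCM-designated ZOTUs, temperature
effect 1.0, SCM latent dispersion 2.0 (vs 1.0 at the surface), a strong
surface block (the 60 surface-designated ZOTUs, ρ = 0.85) and a weak SCM
block (ρ = 0.30). Two mechanisms were chosen deliberately:

* **Higher SCM dispersion, not explicit dominance, drives the alpha
  contrast.** Doubling the latent noise scale concentrates each SCM
  sample's reads on fewer taxa, which lowers observed richness, Shannon
  and PD at equal depth — the way a bloom-dominated SCM community looks —
  while leaving the habitat-enrichment classification stable. (A knob for
  explicit bloom dominance, `scm_dominance`, exists but defaults off.)
* **Co-occurrence asymmetry comes from block strength.** The surface
  differential set shares a strong latent factor, so its subnetwork is
  dense and attack-robust; SCM taxa co-vary only weakly, so their
  subnetwork is sparse. This is the structure the paper-level contrast
  (denser, more stable surface network) requires, planted explicitly.

What the generator does **not** emulate: sequence-level artifacts (PCR
bias, chimeras), overdispersion beyond the log-normal, phylogenetic signal
in abundances (the random tree is independent of the latent model), and
spatial autocorrelation between stations. Passing tests therefore
demonstrate that the analysis recovers planted statistical structure, not
that it is robust to those real-data complications.

Trees are random rooted binary topologies built by sequential joins with
i.i.d. exponential branch lengths (mean 0.1); any rooted tree suffices for
PD/UniFrac because both are defined purely by branch lengths and leaf
memberships.

## Diversity

* **Rarefaction** subsamples each sample without replacement (multivariate
  hypergeometric) to a common depth, default the minimum sample total, in
  one seeded draw (no repeat-averaging); all-zero ZOTU columns are kept so
  ids stay aligned.
* **Shannon** is reported in nats (`base` rescales); **richness** counts
  ZOTUs with count > 0; **Faith's PD** sums branch lengths of the minimal
  rooted subtree spanning the present leaves, *including the stem to the
  root* — the convention matters for oracle comparisons and matches
  scikit-bio's `faith_pd`.
* **Group comparisons** default to the unpaired two-sided Mann–Whitney
  rank-sum test (exact when both groups have n ≤ 8 without ties, normal
  approximation with tie correction otherwise); a station-paired Wilcoxon
  signed-rank variant is available because paired layers pair naturally,
  but which variant an individual survey used is rarely stated, so
  unpaired is the default.
* **Alpha–environment screening** uses Spearman correlations with
  pairwise deletion of missing covariates; pairs with fewer than 4
  complete observations are flagged `not-computed` rather than reported
  as 0.

## Beta diversity and ordination

* **Bray–Curtis**: Σ|x−y| / Σ(x+y) on counts; identical to the
  relative-abundance form when totals are equal (i.e. after rarefaction).
* **Weighted UniFrac**: raw form Σ_b l_b |p_A(b) − p_B(b)| over branches,
  where p_X(b) is the fraction of sample X's reads descending branch b.
  The normalized form (divide by Σ_b l_b (p_A(b)+p_B(b))) is available;
  raw is the default and the choice is surfaced in the API because the
  two variants are not interchangeable.
* **PCoA** is classical scaling: double-center −½ J D² J, eigendecompose,
  keep positive eigenvalues (tolerance 1e−10 relative), scale
  eigenvectors by √λ, flip each axis so its first nonzero loading is
  positive. Negative eigenvalues are dropped without Lingoes/Cailliez
  correction; their absolute mass is reported so the user can judge
  non-Euclideanness.
* **ANOSIM** ranks all n(n−1)/2 distances (average ranks on ties);
  R = (mean between-rank − mean within-rank) / (n(n−1)/4). The p-value is
  the seeded label-permutation estimate (1 + #{R_perm ≥ R_obs}) /
  (1 + N_perm), which cannot return 0; default 999 permutations, so the
  smallest attainable p is 0.001. An exact-enumeration mode exists for
  small n and is what the enumeration tests compare against.

## Environmental drivers

* Predictor distances are |z_i − z_j| on each covariate z-scored over its
  non-missing samples (ddof = 1); geographic distance is the haversine on
  a 6371-km sphere. Constant covariates are flagged and excluded.
* **Mantel** is the classical Pearson correlation of the two unfolded
  lower triangles, permuting one matrix's rows/columns jointly, one-sided
  for positive association (the common ecology-package default); r² is
  reported alongside r. Pairs with a missing covariate member are dropped
  from both vectors.
* **LMG decomposition**: ordinary least squares (with intercept) of the
  unfolded community dissimilarities on all predictor distances; the
  share of predictor k is the average over predictor orderings of the R²
  gain when k enters. Orderings are enumerated exhaustively up to 8
  predictors (exact; subset R² values are cached, 2^p fits) and sampled
  with a fixed seed beyond that. Shares always sum to the full-model R²
  (checked to 1e−10). The response defaults to Bray–Curtis; rank-deficient
  designs raise an error naming the most collinear predictor pair. NH₄ is
  excluded from the default driver list because it is largely missing.
* **Taxon screening** aggregates relative abundances at a chosen
  taxonomy-rank depth by summation, then Spearman ρ/p per (taxon,
  covariate) with pairwise deletion and optional BH q-values across the
  whole matrix; constant series are `not-computed`, not ρ = 0.

## Co-occurrence network

Stage order: filter → Spearman → BH → threshold → enrichment/modules/
metrics. Conventions:

* **Filter**: a ZOTU is deleted only if *both* its pooled relative
  abundance < 0.01% *and* its prevalence < 25% of samples — the deletion
  rule is a conjunction; failing one condition keeps the taxon.
* **Correlation**: pairwise Spearman on relative abundances (rank-based,
  so equivalent under per-sample rescaling, but the network stage
  consumes the rarefied table for consistency); two-sided p via the
  t-approximation; zero-variance taxa yield `not-computed` pairs.
* **FDR**: Benjamini–Hochberg step-up over the upper triangle; the
  *adjusted* q is compared to the 0.01 level.
* **Edges**: q < 0.01 and ρ ≥ 0.6 — positive correlations only by
  default, since the threshold is a one-sided "ρ ≥ 0.6" rule; an
  absolute-value policy (|ρ| ≥ 0.6) is available by flag for studies that
  keep negative associations. Isolated nodes are dropped.
* **Enrichment**: per-ZOTU two-sided rank-sum on relative abundances
  between habitats, BH across ZOTUs, class = habitat with the larger mean
  relative abundance when q < 0.05. (Surveys rarely document this step;
  rank-sum + BH at 0.05 is this package's explicit choice.)
* **Modules**: Louvain on the unweighted simple graph (networkx
  implementation), seeded; labels are renumbered by decreasing module
  size; modularity Q is reported.
* **Node metrics**: degree; shortest-path betweenness normalized by
  (N−1)(N−2)/2; closeness per connected component, (n_c−1)/Σd scaled by
  (n_c−1)/(N−1) (Wasserman–Faust). These conventions are pinned here
  because GUI network tools document theirs poorly.
* **Network metrics**: density 2E/N(N−1); mean local clustering with
  degree-<2 nodes contributing 0; diameter and average path length over
  reachable pairs only, with largest-component values reported separately.

## Robustness

Natural connectivity λ̄ = ln[(1/N) Σ e^{λᵢ}] over adjacency eigenvalues,
computed with a log-sum-exp shift. Attack curves remove nodes in an order
fixed from the intact graph (descending degree or betweenness, ties broken
by node id — "predetermined order"; a dynamic-recompute variant is out of
scope), or in seeded random shuffles (default 100 repetitions, mean ± sd
reported). Isolated nodes remain counted in N until removed, because λ̄ is
defined over the node set and dropping isolates would discontinuously
inflate it. Default step 1 node and maximum removal fraction 0.8; the
pipeline auto-coarsens the step to ≈50 curve points on large subnetworks.
Curve comparison interpolates both curves to the union grid and reports
the fraction of grid points where one dominates plus the trapezoidal AUC
difference.

## Pipeline

`run_pipeline` executes simulate/load → rarefy → alpha → beta → drivers →
network → robustness. Every stochastic stage derives its seed as
`crc32(f"{global_seed}:{stage}") XOR global_seed mod 2³¹`, so any stage
re-run from persisted intermediates reproduces the full-run output. The
bundle carries a provenance block (config hash, per-stage seeds) and four
qualitative pattern flags summarizing the habitat contrast (surface alpha
higher with p < 0.05 on all three metrics; ANOSIM R > 0 with p < 0.05;
surface subnetwork denser and higher-degree than SCM; surface attack curve
above the SCM curve on ≥ 90% of the common grid).

## Problem sizes and known limitations

The shipped study conditions (28 samples, 600 ZOTUs, read depths 35,677–
121,493, 999 permutations, 50–100 random-attack repetitions) run the full
pipeline in well under a minute on a laptop-class core; calibration and
recovery tests use 60–200 replicate datasets at 50–60 ZOTUs. Because the
alpha-contrast flag demands p < 0.05 on all three metrics simultaneously
with n = 14 per group, individual seeds can miss it (the Shannon test is
the noisiest) even though the direction is always planted; the seeded
example and tests use conditions where all four flags hold. Mantel and
ANOSIM p-values are permutation estimates and inherit Monte-Carlo noise at
the 1/(N+1) scale. The LMG decomposition assumes the unfolded-dissimilarity
regression is meaningful despite non-independent pairs; its p-values are
not reported for exactly that reason — only variance shares.
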