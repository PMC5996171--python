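# Methods

This note documents the statistical procedures `rhizonet` implements,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions a
maintainer would want to know about.

## 1. Feature-table curation

A per-kingdom feature table (taxa × samples, non-negative integer
counts, semicolon-delimited ranked lineages, sample metadata with
niche ∈ {bulk, rhizosphere, root}) passes through, in order:

1. **Lineage exclusion** — case-insensitive substring match on the full
   lineage; the pattern `Unassigned` additionally matches empty
   lineages. Typical patterns: `Chloroplast`/`Mitochondria` for 16S,
   `Archaeplastida`/`Plantae`/`Unassigned` for 18S. Exclusion runs
   *before* the bleed-through filter so plant-derived reads do not
   inflate the grand total; the order is configurable.
2. **Bleed-through filter** — taxa holding strictly fewer than 0.1% of
   the grand total (computed before removal) are dropped; this
   compensates for index hopping between sequencing runs. "Fewer than"
   is a strict `<`.
3. **Rarefaction** — multivariate-hypergeometric subsampling without
   replacement to a common depth; samples under the depth are dropped
   and listed rather than raising, since discarding the shallowest
   libraries is the normal practice. `auto-min` uses the smallest
   remaining library per kingdom — the two kingdoms are rarefied to
   independent depths because they are separate sequencing runs.
4. **Taxonomic collapse** — taxa sharing the lineage prefix down to the
   requested rank are summed. Taxa unresolved at that rank are kept,
   grouped under their deepest resolved name suffixed `_unresolved`;
   informal clade names (e.g. bacterial "Ellin6513") therefore survive
   collapsing as their own groups. Name collisions across different
   prefixes fall back to the full prefix as identifier.
5. **Network prefilter** (on relative abundances) — drop taxa present in
   fewer than 5% of samples; drop taxa whose relative abundance stays
   below 1% in every sample ("below 1% everywhere" is the only reading
   under which a realistic sparse table retains taxa); optionally drop
   taxa at or below an absolute read floor (strict `>`).

After the prefilter the column sums fall below one. The
`RelativeAbundanceTable` records this (`complete=False`); when the two
kingdom tables are concatenated for pair testing the proportions are
rescaled by 1/2, which is rank-preserving per taxon and cancels exactly
in the ReBoot renormalization.

## 2. Diversity

- **Chao1** uses the bias-corrected form
  `S_obs + F1(F1−1)/(2(F2+1))`, defined when no doubletons exist.
- **Shannon** uses log base 2 by default (configurable); **Simpson
  evenness** is the inverse Simpson index divided by observed richness.
- **Weighted UniFrac** is the normalized variant
  `Σ l_b |A_b − B_b| / Σ l_b (A_b + B_b)` over branches `b`, computed by
  a single postorder accumulation of descendant proportions. Branches
  without lengths default to 1.0 (with a warning). Tests verify it
  against an independent branch-enumeration oracle and against
  scikit-bio's implementation.
- **PCoA** is classical MDS via double-centering; negative eigenvalues
  are clipped to zero and their mass reported.
- **PERMANOVA** is single-factor: `SS_total = Σ_{i<j} d²_ij / n`,
  within-group terms analogously per group, pseudo-F with (a−1, n−a)
  degrees of freedom, and `p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1)` so
  the estimate can never be zero (999 permutations resolve p ≥ 0.001).
  `n_perm="exact"` enumerates all label permutations; tests compare this
  against exhaustive enumeration on 6 samples and against scikit-bio's
  pseudo-F. Multi-factor and strata designs are out of scope.
- **Differential abundance** is a per-taxon two-sided Welch t-test on
  proportions after an optional read floor, with Benjamini-Hochberg
  step-up FDR (via statsmodels). Zero-variance taxa get p = 1 and a
  flag rather than an exception.

## 3. Checkerboard co-occurrence with ReBoot significance

**Binning.** Each profile is discretized into `B = ceil(log2 n + 1)`
(Sturges) equal-frequency bins of its own ranks; ties receive the bin of
their average rank, so any monotone transformation of a profile yields
identical bins. Constant profiles are flagged degenerate (score 0,
p = 1).

**Score.** Over all `n(n−1)/2` sample pairs, strictly concordant bin
orderings count +1, strict discordances ("checkerboards") −1, ties 0;
the sum is normalized to [−1, 1]. This is a Kendall-τa-style statistic
on the binned profiles. Internally it is evaluated as a quadratic form
over the joint bin contingency table — algebraically identical to pair
enumeration (tests verify equality on all small inputs) but vectorizable
across thousands of permutation replicates.

**Significance.** For the tested pair within its full table:

- *null*: permute the two rows independently across samples,
  renormalize every sample column to sum one, re-bin, re-score —
  `n_iter` times. The renormalization re-injects compositional coupling
  into the null, so closure-induced association does not count as
  signal.
- *bootstrap*: resample samples with replacement, re-score — `n_iter`
  times.
- `z = (mean_boot − mean_null)/sd_null`, two-sided normal tail.

The bootstrap mean stabilizes the observed score against sample noise;
the permutation null supplies both the location and the scale of the
reference distribution. A pooled-variance form
(`sqrt(var_boot + var_null)` in the denominator) was evaluated first and
rejected: on 600 independent pairs (n = 40, n_iter = 500) its type-I
error was 0.012 at α = 0.05 and 0/600 at α = 0.01 — markedly
conservative, because under independence the bootstrap and permutation
variances both approximate the sampling variance of the score, deflating
z by ≈ √2. The `sd_null` form measures 0.060–0.072 at α = 0.05 and
0.017 at α = 0.01, i.e. approximately calibrated with a mild liberal
bias that the Bonferroni margin absorbs. `n_iter` affects only the
moment estimates, not a p-value floor, so strong edges can reach
p ≪ 1/n_iter.

**Sweep.** All unordered pairs at one taxonomic level are tested once;
cutoffs {0.01, 0.001, 0.0001, Bonferroni} only filter the shared
p-values, so edge sets are nested by construction. The Bonferroni family
is the set of pairs tested at that level after prefiltering
(α = 0.05/m); families are per-level, not pooled across levels.

**Kingdom classes.** Taxa from the 16S table are bacteria, 18S-table
taxa eukaryotes; each edge is bacteria-bacteria, eukaryote-eukaryote, or
inter-kingdom, and summaries report nearest-integer percentages per
class and per sign within class.

## 4. Hub detection

Per network (one level × one cutoff): degree ignores signs; betweenness
is computed on the unweighted topology and normalized by
`(N−1)(N−2)/2`; closeness is *harmonic* closeness normalized by `N−1`.
Harmonic closeness deviates from the per-component classical convention
of common GUI tools deliberately: these networks are disconnected, where
classical closeness is undefined; the choice is switchable in the module
surface. For each metric a normal distribution is fitted (sample
mean/SD) to the network's own node population — edge-incident nodes
only, since an edge-list import defines the population — and values
strictly above `mean + z_{0.9}·SD` (z ≈ 1.2816, upper 10% tail) are
outliers. Zero-variance populations yield no outliers.

Two-tier consensus: a node is a **level hub** when it is an outlier on
*all three* metrics in at least 2 of the 4 cutoff networks of that
level, and a **consensus hub** when it is a level hub at ≥ 2 of the 3
taxonomic levels. Because node identifiers differ between levels (a
genus and the family containing it), cross-level identity is resolved
through the shared lineage prefix down to the order rank; without
lineages the rule degrades to name identity. Thresholds are never pooled
across networks.

## 5. Synthetic community generator

Per sample, per kingdom, each taxon's latent log-abundance is

```
log a_ts = base_t + niche_effect_t(niche_s) + noise_sd · (Λ z_s + sqrt(1 − ||λ_t||²) ε_ts)
```

with standard-normal latent factors `z` shared according to the planted
structure, and counts drawn `Multinomial(depth_s, softmax(log a))` —
compositional by construction. Sequencing depths are log-normal with
per-kingdom means anchored to realistic rarefaction depths (7,136 reads
for 16S, 1,922 for 18S; σ = 0.3 on the log scale). The two kingdoms are
independent compositions that share latent factors only through planted
inter-kingdom structures, mirroring separate library preparations.

Planted structure and the reasoning behind the defaults:

- **Pairwise edges** (3 positive, 2 negative) use loading 0.99, i.e.
  latent correlation ≈ 0.98. This is deliberately near-deterministic:
  after compositional closure, multinomial sampling, and rank-binning,
  the *realized* NC-scores land around 0.6–0.7 — the "high-strength"
  regime of real co-occurrence surveys — and detection at a Bonferroni
  threshold of ~1.7·10⁻⁵ from 30 samples is possible but not trivial.
- **Both planted negative edges are inter-kingdom.** Within a single
  composition the ReBoot null deliberately absorbs closure-induced
  negativity, so an intra-kingdom planted co-exclusion is partially
  confounded with the null by design; planting co-exclusions across the
  two independent compositions makes them a clean test of true negative
  dependence. (Negative inter-kingdom associations are a documented
  feature of real bulk-soil/root networks.)
- **Hub**: one bacterial taxon loading 1.0 on a factor shared with 8
  neighbors (4 bacterial, 4 eukaryotic) at loading 0.80 with alternating
  signs. Gaussian transitivity forces neighbor-neighbor correlation =
  0.8² = 0.64, so the hub's edges (corr 0.80) separate from the induced
  neighbor clique (corr 0.64) mainly through the stricter cutoff
  networks — which is precisely the regime the two-tier rule is designed
  for. Alternating neighbor signs keep the module's contribution to the
  column sums balanced; an all-positive module swings whole-sample
  totals and measurably corrupts the ranks of *unrelated* taxa.
- **Planted taxa get a +1 log-unit baseline boost** and singleton
  families/orders in the synthesized taxonomy. Real hub taxa are
  abundant, prevalent groups, and collapsing must not merge a planted
  taxon with background noise, or the planted truth becomes undefined at
  the family/order levels. Background OTUs share 15 families nested in
  8 orders per kingdom, so collapsing is non-trivial where it should be.
- **Species sorting**: 30% of taxa receive niche effects
  ~N(0, 0.4²) on the log scale (bulk as reference). At the fixture's 30
  samples this yields weighted-UniFrac PERMANOVA R² ≈ 0.10–0.13 with
  inconsistent significance — a *mild* gradient. Stronger sorting (SD
  0.8 on half the taxa, R² ≈ 0.27) was evaluated and rejected because
  niche-driven background covariation competes with the planted signal
  and drags Bonferroni edge sensitivity from ~0.89 to ~0.60. The
  generator therefore prioritizes identifiable planted structure; users
  studying sorting itself should raise `niche_effect_sd` knowingly.

What the generator does **not** emulate: sequencing error, chimeras and
OTU-picking artifacts (generation starts at the count table), taxon-
specific amplification bias, overdispersion beyond the log-normal
factor structure, phylogenetic signal in abundances (trees are random
and independent of the covariance structure), and temporal or spatial
autocorrelation between samples. Passing recovery tests therefore shows
the inference chain is correct and well calibrated on compositional
count data with known dependence — not that real soil communities meet
the model's assumptions.

## 6. Recovery accounting

Recovery tests score (i) *edge sensitivity*: planted pairs recovered at
the genus-level Bonferroni cutoff with the correct sign; (ii) *false
edges*: Bonferroni edges between taxa sharing **no** latent factor —
neighbor-neighbor pairs inside the hub module share a factor and are
genuinely dependent, so they are not false; (iii) *hub recovery*: the
planted hub appears in a consensus entity; (iv) *background false
hubs*: consensus entities containing no planted taxon. Hub-module
neighbors called as co-hubs are reported but not counted as false — by
construction they carry genuinely elevated connectivity, and penalizing
their detection would penalize correct inference. At the frozen
defaults (20 replicate seeds, n_iter = 200): edge sensitivity ≈ 0.86–
0.89, hub recovery ≈ 0.85, background false hubs ≈ 0. Replicate batches
at other base seeds scatter by a few points (binomial noise plus
correlated factor draws within a community).

## 7. Problem sizes and numerical choices

The canonical fixture is 2 × 40 taxa × 30 samples (3 niches × 2
habitats × 5 replicates); sweeps test ~3,000 genus-level pairs per
scope. Tests use n_iter = 120–500 and recovery uses n_iter = 200:
since n_iter only sets moment-estimation precision, these sizes leave
the z-statistics essentially unchanged while keeping a full 20-replicate
recovery run in minutes on one core. Other numerical decisions:

- Permutation/bootstrap seeds derive from one master seed via a child
  seed per pair drawn in canonical pair order; all stochastic stages of
  the pipeline similarly derive labeled child seeds from the run seed,
  making report bundles byte-reproducible (manifests contain no
  timestamps, floats are written with `%.10g`).
- Degenerate inputs never raise mid-pipeline: constant profiles score 0
  with p = 1, zero-variance outlier populations yield no outliers,
  empty edge sets build valid empty networks, all-zero samples are
  flagged and carried.
- PCoA clips negative eigenvalues; PERMANOVA treats `SS_within = 0`
  (perfect separation) as infinite pseudo-F.
- The NC kernel caches the `B² × B²` sign kernel per bin count.

## 8. Known limitations

- The ReBoot p-value is mildly liberal (≈ 0.06–0.07 at nominal 0.05 on
  independent compositional pairs); raw-p cutoffs at 0.01 inherit this,
  while Bonferroni-scale decisions are effectively unaffected.
- The normal outlier fit on very small networks (< ~10 nodes) is noisy;
  degree distributions are discrete and the 10% tail can flag
  low-degree nodes in near-empty networks. The two-tier consensus
  suppresses most of this, but sparse-cutoff networks remain the main
  source of spurious hub calls.
- Hub/neighbor separation is bounded by Gaussian transitivity
  (neighbor-neighbor correlation equals the squared neighbor loading);
  a generator with non-Gaussian dependence could decouple these.
- Single-factor PERMANOVA only; no strata, no interactions.
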