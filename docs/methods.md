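# Methods

This note documents the statistical procedures implemented in `dmftbiome`,
the assumptions behind the synthetic cohort generator, and the design
decisions taken where the methodology was genuinely open.

## The analysis model

### DMFT categorization and filtering

DMFT scores are binned as healthy = 0, low = 1–3, medium = 4–6,
high = 7–13, extremely high ≥ 14. The ≥14 boundary is the only contiguous
partition of the non-negative integers consistent with a high bin ending at
13; `categorize_dmft` is total and deterministic, and `SampleMetadata`
re-derives the category from the score on construction so the two can never
disagree. The depth filter retains samples with **at least** 3,000 reads
(inclusive); it acts on samples, never on taxa, and is idempotent. Counts
stay integers end to end — relative abundances are computed inside each
downstream operation and never stored.

### Diversity

Shannon entropy is reported in nats (the log base is a convention; nats
make H(uniform k) = ln k). Rarefaction subsamples without replacement via
the multivariate hypergeometric distribution, seeded. Bray–Curtis and
Jensen–Shannon act on relative abundances; JSD is returned as the
divergence (ln 2 for disjoint supports) with an optional square-root metric
form. UniFrac comes from scikit-bio behind the module surface; the wrapper
validates leaf coverage itself (listing missing taxa) and accepts
multifurcating roots, which are mathematically unproblematic for UniFrac.
Weighted UniFrac defaults to the normalized variant so all stock distances
live on [0, 1].

PCoA is classical metric scaling: Gower double-centering of −½D², a
symmetric eigendecomposition, and coordinates only for strictly positive
eigenvalues. Negative eigenvalues (Bray–Curtis and JSD are semi-metrics)
are reported but truncated at zero for TVE — the simplest defensible
choice; no Lingoes/Cailliez correction is applied. TVE(k) =
Σ_{i≤k} max(λ_i,0) / Σ_i max(λ_i,0) is monotone in k and defaults to k = 5.

PERMANOVA is the one-way decomposition SS_total = Σ_{i<j} d²_ij/n,
SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g, with pseudo-F =
(SS_between/(g−1))/(SS_within/(n−g)) and a label-permutation p-value with
the +1 correction (p never reaches 0). It is implemented in-package — the
formula is short and the permutation loop needed to be cheap enough for
1,000-dataset calibration runs — and is cross-checked in the tests against
both an exhaustive-enumeration oracle and scikit-bio's implementation.
Under exchangeable data with 199 permutations the achievable p-values are
exactly uniform on {1/200, …, 1}, so the α = 0.05 rejection rate is
calibrated by construction; the test suite verifies 0.035–0.065 over 1,000
simulations.

### Pan / core / accessory

Presence means count > 0 (no detection floor). The core threshold is
inclusive: a taxon present in exactly 85% of a category's samples is core.
The partition invariant accessory = pan \ core is enforced in the type
itself. The DMFT core intersects the per-category cores, with prevalence
computed within category. Richness proportions assign each pan genus to
exactly one group with precedence core > accessory > disease-associated >
normal-flora > unclassified; the precedence is a package choice that makes
the four reported fractions well-defined on disjoint groups. The curated
genus lists are editable newline-delimited files shipped with the package
(`dmftbiome/data/`); results should always be reported alongside the list
version used, and the partition output records its source string.

### Co-occurrence networks and the entropy statistic

Spearman ρ and p (large-sample t approximation; a seeded permutation
option exists for very small groups) are computed on genus relative
abundances; constant genera are flagged and excluded rather than given a
spurious ρ. p-values are BH-adjusted across all tested pairs. Pruning
keeps |ρ| strictly > 0.5; FDR significance (α = 0.05) is an **edge
attribute**, not a pruning criterion, because significance is presentation
("coloring"), not topology. Correlation is symmetric, so the graph is
undirected. Communities come from greedy modularity maximization on |ρ|
weights (chosen for determinism and small-graph auditability; the
algorithm is otherwise interchangeable), with sorted, deterministic
output. The entropy statistic is the fraction of retained edges that are
significant; a denominator option computes it over all tested pairs
instead, since either convention is defensible. It is reported raw — the
caller decides that a high significant fraction means low entropy.

### Influence (leave-one-genus-out ΔTVE)

Baseline: TVE of the weighted-UniFrac PCoA. For each candidate genus the
column is dropped, the tree sheared, and everything recomputed from
scratch — no incremental updates, correctness over speed at this scale.
Drops are independent, never cumulative, so candidate order cannot change
any delta (asserted in tests). The delta is signed (perturbed − baseline);
consumers usually rank by magnitude. An all-zero genus cannot move any
sample's branch proportions, so its delta is exactly 0. If a drop empties
a sample, that sample is excluded from the perturbed ordination with a
warning. Candidates come from either mean relative abundance or network
degree (both truncate at 50), selected by config. For aggregated tables
the phylogeny is collapsed to one representative leaf per rank label — an
approximation appropriate for the synthetic cohort (one leaf per genus)
and serviceable for real data, where a dedicated rank-level tree can be
supplied instead.

### Quasi-Poisson biomass models

The outcome is each sample's total count (a biomass proxy; the outcome
definition is selectable in principle and deliberately narrow in this
version). The mean model is Poisson with log link fitted by IRLS
(statsmodels); quasi-Poisson inference multiplies the Poisson standard
errors by √φ with φ = Pearson χ²/(n−p) and refers Wald statistics to
t(n−p), matching R's `glm(family = quasipoisson)` summary. φ is reported
even when ≈ 1. Covariates are sex, HIV status, periodontal status, and
the relative abundances of an explicit list of families (one family must
always be left out — the fractions sum to one). Within a category,
covariates that are constant or exactly collinear (easy at n ≈ 11 with
binary covariates) are dropped with a warning and reported as NaN in the
aligned comparison table. No multiplicity correction is applied across
the table by default; a BH option exists.

## The synthetic cohort generator

The generator emulates a cross-sectional severity-staged cohort, not
sequencing physics. Per sample:

    depth   ~ round(LogNormal(μ + x'β, σ))          library size
    log α   = log α_base + strength · (Λ f),  f ~ N(0, I)
    p       ~ Dirichlet(α restricted to present taxa)
    counts  ~ Multinomial(depth, p)

Defaults (chosen once, as the cohort conditions the pipeline targets):
11/32/21/16/8 participants per category; 160 genera with a 60-genus core;
α_base = 0.5 per core genus and 0.08 per accessory genus (so accessory
prevalence is low); μ = 9.2, σ = 0.9 — median depth ≈ 10⁴ with roughly a
tenth of samples under the 3,000-read filter; 4 latent factors at strength
1.0, each loading half-normal weights on a random quarter of the taxa;
HIV-positive 67%, female 57%, periodontitis 42%, salivary flow
N(0.9, 0.5) ml/min truncated at 0.05; DMFT scores uniform on each
category's integer range (extremely-high capped at 20, as observed scores
rarely exceed that).

Category-specific accessory genera are disjoint random slices of the
non-core taxa (15% each) whose concentrations are zeroed outside their
home category — this is what gives the unweighted-UniFrac PERMANOVA its
between-category signal. When `core_prevalence_target = 1.0`, any core
genus drawn at zero in a sample is repaired to count 1 by moving one read
from the sample's most abundant taxon, guaranteeing full prevalence while
preserving the exact depth; for targets < 1 the per-sample core
concentrations are thinned by Bernoulli(target), giving approximate
prevalence. Shared latent factors shift log-concentrations jointly and
therefore induce positive rank correlation; strength 0 gives
(compositionally) independent taxa, and the significant-association
fraction is empirically non-decreasing in the strength. An optional
explicit loading matrix supports designed experiments such as "one genus
carries the only latent signal". Everything planted is recorded in a
`SyntheticTruth` object for recovery tests.

What the generator does **not** emulate: sequencing error, chimeras,
taxonomic misassignment, zero-inflation beyond what
Dirichlet-multinomial sampling produces, phylogenetic signal in the
random tree (branch lengths are i.i.d. exponential), and real
compositional correlation structure such as mutual-exclusion patterns.
Passing recovery tests therefore demonstrates algorithmic correctness
under the stated generative model, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

- Eigenvalues below max(λ)·1e−12 are treated as zero in PCoA; TVE errors
  if no eigenvalue is positive.
- PERMANOVA errors when a group equals the whole sample set or n < 4.
- Spearman requires ≥ 4 samples; constant genera yield NaN, a warning,
  and no edges.
- An edgeless graph has an undefined entropy statistic (error), since the
  denominator is the retained edges; calibration code treats "no edges
  retained" as "nothing spurious found".
- Ties in degree ranking and candidate selection break lexicographically,
  making every ranking deterministic.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed gives a byte-identical pipeline summary.

## Problem sizes used in the validation suite

The test and acceptance suites run at desk scale, chosen as the smallest
sizes at which each statistical claim is sharp: oracle-equivalence
fixtures use ≤ 10 samples; PERMANOVA calibration uses 1,000 simulated
20-sample datasets at 199 permutations; the entropy null uses 50
replicate cohorts of 100 genera × 40 samples; GLM recovery uses n = 2,000
observations; influence recovery uses 20 replicate 12-genus cohorts. The
pipeline itself defaults to the full 88-sample cohort with 9,999
permutations.

## Known limitations

- The per-rank phylogeny used after aggregation is a representative-leaf
  collapse, not a reconstructed rank-level tree.
- The biomass model's outcome (total counts) conflates library size with
  biomass unless the library preparation is quantitative; a depth offset
  is the natural extension.
- Plain Spearman correlation on relative abundances is not
  compositionality-aware; SparCC-style estimators are out of scope by
  design.
- CAP/db-RDA ordination and heat-tree visualization are out of scope; the
  quantitative claims are covered by PCoA + PERMANOVA.
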