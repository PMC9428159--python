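# Methods

This note documents the models and procedures implemented in `denitnet`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Chamber fluxes and cumulative emission

N₂O flux from a static chamber closure is

    f = ρ · (V/A) · (ΔC/Δt) · 273/(273 + T)

with `f` in μg m⁻² h⁻¹, `ρ` the N₂O density at STP (default
1.964 kg m⁻³ = 44.013 g mol⁻¹ / 22.414 l mol⁻¹; configurable), `V/A` the
chamber headspace height in m (default geometry 38 cm × 35 cm footprint ×
36.5 cm height, so V/A = 0.365 m), `ΔC/Δt` the concentration rise in
μl l⁻¹ h⁻¹, and `T` the chamber air temperature in °C. The slope is an
ordinary least-squares fit over all closure points (default sampling at
0/10/20 min); OLS is the standard chamber protocol and degrades gracefully
to the two-point difference quotient. A numerically constant series is a
perfect zero-slope fit (r² = 1). Negative fluxes (soil N₂O uptake) are
retained, not truncated.

Seasonal cumulative emission integrates per-date fluxes by the trapezoid

    M = Σ (F_{N+1} + F_N) · 0.5 · (T_{N+1} − T_N) · 24 · 10⁻²

with `F` in mg m⁻² h⁻¹, `T` in days since the first sampling, and `M` in
kg ha⁻¹. The unit boundary is deliberate: per-date fluxes live on the
μg m⁻² h⁻¹ scale and an explicit ×10⁻³ converter (`flux_ug_to_mg`) bridges
to the mg scale so the printed ×10⁻² constant stays bit-exact. Integration
is per plot first, then averaged across replicates; trapezoid additivity
(splitting an interval at a linearly interpolated interior point changes
nothing) is a tested invariant.

## Alpha diversity and composition

Shannon uses the natural log by default (the R convention; the base is an
argument) via scikit-bio. Chao1 is the bias-corrected estimator
`S_obs + F₁(F₁−1)/(2(F₂+1))`, which stays finite when no doubletons are
observed; the classical form is available by flag, and non-integer counts
are rejected because the estimator is undefined on relative abundances.
Genus composition pools unlabeled OTUs as `unclassified` and genera below a
mean-relative-abundance threshold into `Others`. Community composition is
summarized by the first principal coordinate of classical (metric) PCoA on
Bray–Curtis dissimilarities of relative abundances; negative eigenvalues
are dropped with a warning (no Lingoes/Cailliez correction), and the
axis sign — arbitrary in PCoA — is fixed deterministically, either against
a supplied covariate or by making the largest-magnitude score positive.

Treatment comparison is one-way ANOVA plus all-pairs Tukey HSD on the
studentized range (statsmodels), summarized as a compact letter display by
the insert-and-absorb construction: start from one set holding all
treatments and split it at every significant pair, so treatments share a
letter exactly when they are not significantly different. Letters are
ordered by descending treatment mean with design order breaking ties. The
degenerate zero-within-variance case is handled directly (p → 0 for
differing means, p = 1 for equal ones) rather than through the studentized
range. Correlation matrices report Pearson r with two-sided p from
`t = r√((n−2)/(1−r²))`, pairwise-complete with per-cell n; zero-variance
variables yield missing cells, never 0. No multiple-testing correction is
applied by default (matching the `*`/`**` raw-significance convention);
Benjamini–Hochberg is an option.

## Co-occurrence networks

One network per functional gene across all samples. The stages:

1. **Prevalence filter.** Default `strict` keeps OTUs with nonzero counts
   in every replicate of every treatment (the conservative reading of
   "occurred in all replicates of each treatment");
   `any-treatment` implements the looser reading (complete in at least one
   treatment).
2. **Candidate edges.** Pearson correlation between all OTU pairs on
   per-sample relative abundances (the compositional convention; raw-count
   mode available). Candidates need |r| > 0.7 and parametric p < 0.05.
3. **Resampling validation** (1,000 iterations by default). Permutation p
   shuffles one member's sample order, with the add-one estimator
   `(1 + #{|r_perm| ≥ |r_obs|})/(n_iter + 1)` so p is never 0. Bootstrap
   support resamples samples with replacement and counts the fraction of
   replicates with the observed sign and |r*| > 0.9 × 0.7 — the 10%
   relaxation avoids penalizing edges sitting exactly at the threshold.
   An edge is validated iff it passes the candidate screen, p_perm ≤ 0.05
   and support ≥ 0.95. Validation prunes edges (it does not merely
   annotate them); all constants are exposed.
4. **Topology** on the unweighted, undirected validated graph: node/edge
   counts, average degree 2E/N, average clustering, average shortest path
   over the largest connected component, per-node closeness, and "network
   centrality" implemented and labeled as Freeman degree centralization
   `Σ(d_max − d_i)/((N−1)(N−2))`.
5. **Modules.** Modularity maximization: exhaustive search over all set
   partitions for graphs of ≤ 8 nodes (the provable optimum is cheap
   there), seeded Louvain above. Modules are relabeled I, II, III, … by
   descending internal edge count, ties broken by node count then by the
   lexicographically smallest member; isolated nodes become trailing
   singleton modules.
6. **Keystones.** Nodes at or above both the degree and the closeness
   quantile (default 0.9 each) within their own network, using `≥` so ties
   at the cutoff pass (every node of a regular graph passes the degree
   screen). Networks with fewer than 10 nodes warn that the thresholds are
   degenerate.

The null behavior of the full chain is tested: on communities of
independent OTUs the fraction of pairs surviving validation stays well
below the nominal α = 0.05 (the |r| > 0.7 screen at n = 15 is already far
stricter than α, and validation only prunes further).

## Module eigengenes and trait correlations

A module eigengene is the first principal component of the samples ×
member-OTUs matrix of standardized relative abundances (the WGCNA
definition), reported with `variance_explained = λ₁/Σλ`. Scores are
standardized to mean 0 and unit (population) variance; the sign is fixed
by requiring a positive mean member loading, making eigengenes invariant
to member ordering. Zero-variance members are dropped with a warning. The
module–trait matrix correlates eigengenes and community summaries
(abundance = qPCR copy numbers when supplied, otherwise summed counts;
diversity = Chao1; composition = PCoA PC1) against soil traits, PDA and
cumulative N₂O, starring p < 0.05 (`*`) and p < 0.01 (`**`). PDA and N₂O
are treated as per-sample values.

## Predictor importance

A bagged ensemble of regression trees (500 trees; 1/3 of features per
split and minimum leaf size 5, the classic regression random-forest
defaults) with the bootstrap bookkeeping done in this package, so
out-of-bag (OOB) permutation importance is exact: per tree, the increase
in OOB MSE after permuting one predictor's OOB values, averaged over
trees, floored at zero, and normalized to percentages summing to 100.
Significance per predictor comes from a response-permutation null — the
ensemble is refit on permuted responses (default 100 permutations,
rfPermute's convention) and `p = (1 + #{null ≥ observed})/(R + 1)`. With
R = 50 the smallest attainable p is 1/51 ≈ 0.0196, so the nominal 5% level
effectively tests rank ≤ 2 among the null refits; the null
false-positive rate is correspondingly slightly conservative (≈ 4%).

## The synthetic-data generator

The generator emulates the study design downstream of sequencing and gas
chromatography; it is the ground-truth source for every recovery test.

- **Design**: 5 treatments (CK, MF, MOF, OFP, MSP) × 3 replicates = 15
  samples by default. Generators accept more replicates because
  correlation power at n = 15 is marginal and recovery tests need
  headroom.
- **Soil covariates**: per-sample draws from truncated normal
  distributions with the built-in per-treatment means/SDs (pH, TN, SOC,
  NO₃⁻–N, NH₄⁺–N, AP, DON, SWC), truncated to physical ranges (pH in
  (0, 14], concentrations ≥ 0, SWC in [0, 100]). Traits are drawn
  independently within a sample; cross-trait correlation arises only
  through shared treatment means (the simplest defensible null — e.g. the
  strong negative pH–NO₃⁻–N coupling across treatments emerges this way).
  PDA and cumulative N₂O were published only as percent changes against
  the unfertilized control, so the built-in table carries synthetic CK
  baselines (50 ng N₂O-N g⁻¹ h⁻¹; 0.85 kg ha⁻¹) scaled by the published
  ratios, with a synthetic 10% CV.
- **OTU tables**: each module has a latent factor — the standardized
  per-sample values of a driver trait times a ±1 sign, or an independent
  standard normal when no driver is named (needed for planted-partition
  tests, since treatment structure correlates most trait pairs). Regular
  members load √ρ on the factor (pairwise latent correlation ρ =
  `within_module_correlation`); keystone members instead track the
  standardized mean profile of a fraction (≥ ½, default all) of the
  regular members, which lifts their correlation with those members to
  ≈ √(ρ + (1−ρ)/m) > ρ — elevated connectivity by construction, since a
  pure one-factor model cannot put keystone–member correlations above the
  member–member level. Log-abundances are `μ_i + s·signal` with per-OTU
  baselines μ_i ~ N(0, 1) (a log-normal abundance distribution) and
  biological scale s = 0.5; columns are closed by a softmax and counts
  drawn multinomially to a fixed depth (default 10⁴). Column sums
  therefore equal the configured depth exactly. Closure matters: a module
  that makes up a large share of the community has its shared signal
  absorbed by the normalization, so realistic tables need a background
  pool of independent OTUs; recovery tests use 20–80 background OTUs.
  Published tables do not state sequencing depth or totals, so depth and
  OTU counts are configurable defaults, not claims. Genus labels are drawn
  from per-gene pools of the dominant genera.
- **Chamber series**: the flux equation is inverted for the concentration
  slope; concentrations rise linearly from an ambient 0.33 μl l⁻¹ baseline
  with optional Gaussian noise. At zero noise the round trip through
  `compute_flux` is exact — the generator/analysis pair is mutually
  inverse by construction. A whole simulated season uses ten 15-day
  sampling dates with a mid-summer Gaussian peak shaped so the control's
  cumulative emission matches its configured baseline, scaled per
  treatment by the cumulative-N₂O ratios.

**What passing tests do and do not show.** The generator plants linear,
log-normal co-abundance structure with multinomial counting noise. Real
communities add overdispersion, zero inflation, phylogenetic structure and
nonlinear environmental responses; recovery of planted modules and
keystones here demonstrates the pipeline's correctness, not that field
networks identify true ecological interactions.

## Problem sizes and fixed test conditions

Recovery checks run at sizes chosen to make the expected effects
detectable with margin while staying quick:

- Null edge validation: 50 communities × 30 independent OTUs, n = 15,
  1,000 resampling iterations.
- Module recovery: 3 planted modules (12/9/7 OTUs; the largest driven by
  +NO₃⁻–N) + 20 background OTUs, ρ = 0.95, n = 15.
- Keystone recovery: 3 modules of 9 (8 regular + 1 keystone tracking the
  module mean, strength 1.0), ρ = 0.65, 80 background OTUs, 12 replicates
  per treatment (n = 60), depth 3×10⁴, scored on the candidate-edge
  network over 20 seeds. These follow Fisher-z power calculations: at
  n = 60 the keystone–member correlation (≈ 0.78 observed) clears the 0.7
  edge threshold ≈ 90% of the time while member pairs (≈ 0.58 observed)
  rarely do.
- Importance: n = 15 samples × 6 predictors, 100–200 trees, 50 response
  permutations.

## Known limitations

- Pearson-on-relative-abundance networks inherit compositional bias;
  SparCC/SPIEC-EASI-style methods are out of scope by design.
- Louvain above 8 nodes is a heuristic; the exact-search guarantee holds
  only for tiny graphs.
- The compact letter display is exact for the significance pattern given,
  but letter assignments (not membership) depend on the descending-mean
  ordering convention.
- No gap-filling between chamber sampling dates beyond the linear
  interpolation the trapezoid implies; no nonlinear (HMR-type) chamber
  fits.
- Which centralization index "network centrality" denotes is ambiguous in
  common usage; Freeman degree centralization is implemented and labeled.
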