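# Methods

This note documents the statistical model behind `commstruct`, the
conventions and numerical choices that affect its outputs, what the
synthetic-data generator does and does not emulate, and the design
decisions taken where the analysis could reasonably be set up in more than
one way.

## Null-model structure indices

For an assemblage of k species with a pool distance matrix d (patristic or
Gower), the observed metric is MPD (mean over all k(k−1)/2 unordered
pairs) or MNND (mean nearest-neighbour distance). The null model shuffles
taxon labels across the pool's distance matrix; because MPD and MNND
depend only on which pool positions the members occupy, this is
implemented as a uniform redraw of k labels from the pool without
replacement (the equivalence is asserted exhaustively in the test suite on
a 4-species pool). The default is 5000 null draws.

Conventions, stated because SES values are sensitive to them:

- **Null SD** is the sample standard deviation (ddof = 1) of the null
  draws.
- **NRI = −SES(MPD), NTI = −SES(MNND)**: positive index = clustering.
- **Permutation p (clustering tail)**:
  p = (#{null < obs} + 0.5·#{null = obs} + 1) / (n_null + 1), mid-rank for
  ties and add-one so p is never 0. The numerator is capped at n_null so
  the complementary (overdispersion) tail is also never 0; p therefore
  lies in [1/(n_null+1), n_null/(n_null+1)].
- **Classification**: clustered if p < 0.025, overdispersed if p > 0.975
  (strict inequalities), otherwise random.
- **Degenerate nulls** (null SD = 0, e.g. an assemblage equal to its pool,
  or a pool whose distances are all equal) leave SES undefined; the site
  is classified random and a warning is logged rather than raising.
- **Reproducibility**: each site × pool × metric combination consumes its
  own `numpy` SeedSequence substream derived from the run seed and the
  site index, so results do not depend on evaluation order.

Sites with richness < 2 are flagged and excluded from SES computation (MPD
is undefined there) but retained for richness models.

### Pools

The continental pool is the union of all species; each biome pool is the
union of that biome's site lists (range maps are not assumed available).
Biomes with fewer than `min_sites_per_biome` (default 3) localities get no
pool: with one or two sites the "biome pool" degenerates toward the site
lists themselves. Biome-level assemblages (each biome's species union) are
always tested against the continental pool.

Per-biome proportions of clustered/overdispersed/random sites are reported
with Wilson 95% binomial intervals — a method had to be chosen, and Wilson
behaves sensibly at the small per-biome counts involved. For biome-level
index uncertainty the 2.5/97.5% quantiles of the null distribution of the
index are the natural analogue and can be derived from the stored null
mean/SD only under normality; we deliberately report the permutation p
instead of a CI there.

## Distances

**Patristic** distances are computed in one postorder sweep (pairs merge
at their MRCA: d = depth_i + depth_j − 2·depth(mrca)); this is exactly the
tip-to-tip path length and is invariant to pruning, which the tests assert
against dendropy's MRCA-based matrix.

**Gower** distances average the available trait contributions per pair:
|Δ body size| / range, and a 0/1 lifestyle mismatch. Three choices matter:

- The body-size **range is fixed to the species pool** supplied to the
  null model (continental or biome) and held constant across null draws.
  Normalising per-assemblage would break exchangeability between observed
  and null values; fixing the range per pool is the only choice that keeps
  the null valid. The alternative (one global range for all pools) is
  available by passing `ranges=` explicitly.
- **Intermediate lifestyles** (e.g. terrestrial/arboreal) are full
  categories at distance 1 from both parent states. A partial-credit
  coding (distance 0.5 to each parent state) is exposed as
  `partial_intermediate=True` but off by default.
- **Missing lifestyle** is handled by trait-wise deletion: the pair's
  distance is the body-size term alone. Dropping such species entirely is
  a sensitivity analysis, not the default.

## Climate models

Predictors are Bio1 (mean annual temperature), Bio4 (temperature
seasonality, log), Bio12 (annual precipitation), Bio14 (precipitation of
the driest month, log(x+1)), Bio15 (precipitation seasonality, √), then
z-standardised; responses are z-standardised too, so reported coefficients
are standardised in both variables (a convention that had to be fixed; it
makes coefficients comparable across responses). The collinearity screen
is greedy in input order at |r| > 0.75: a variable is dropped the moment
it clashes with an already-retained one.

"Stepwise regression by AICc" is implemented as an exhaustive all-subsets
search — with 5 predictors that is 32 models, which is what the classic
`dredge` semantics enumerate anyway, and it removes path-dependence.
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting **all** estimated
parameters: coefficients, intercept, error variance, and λ for SAR fits
(software packages differ here; this choice is stated so AICc values are
comparable). Akaike weights over the 2^p models give per-predictor
importance (sum of weights of models containing the predictor).

Spatial weights are k-nearest-neighbour (k ∈ {2, 6, 10}, great-circle
distance, ties broken by site order) or a binary 1500-km distance band,
row-standardised. A site with no neighbour keeps a zero row and simply
drops out of the autocorrelation term (logged), rather than erroring.

Moran's I = (n/S0)·(zᵀWz)/(zᵀz) on centred residuals, permutation p with
(r+1)/(n_perm+1), default 999 permutations, **greater tail**: the decision
rule only acts on the presence of positive autocorrelation (a two-sided
option exists).

The SAR error model y = Xβ + u, u = λWu + ε is fitted by profile maximum
likelihood: log|I − λW| is evaluated from the (possibly complex)
eigenvalues of W computed once, the profile is scanned on a 199-point grid
over (−0.999, 0.999) and refined by bounded Brent search to 1e−6; β is the
GLS solution at the optimum. Nagelkerke pseudo-R² =
1 − exp((2/n)(ℓ₀ − ℓ₁)) uses the **intercept-only non-spatial** model as
ℓ₀ (the baseline is not uniquely defined in the literature; this choice is
recorded in the fit metadata). The SAR (k = 6 weights) is reported instead
of the best OLS iff it wins on AICc or the OLS residuals' Moran p < 0.05;
AICc ties go to OLS (parsimony). All four weight schemes are fitted and
archived for sensitivity.

## Post hoc biome comparisons

Fligner–Killeen (α = 0.05 — the gate level had to be chosen) decides
between Tukey HSD (pooled variance, studentised range) and Games–Howell
(Welch SE, Welch–Satterthwaite df, studentised-range p via
`scipy.stats.studentized_range`). Biomes with fewer than 3 sites are
excluded before testing. The Games–Howell implementation is cross-checked
against pingouin in the test suite.

## Synthetic worlds

The generator emulates the structure of a continental squamate survey:

- **Scale**: 904 species, 92 sites, six biomes with 2/21/7/1/30/31 sites,
  ordered humid → arid (TMBF, FGS, TGSS, MGS, MFWS, DXS).
- **Tree**: Yule, rate 1 per lineage per unit time (time units are
  arbitrary; only relative branch lengths matter to the indices).
- **Traits**: body size by Brownian motion (σ² = 0.2 per unit time from a
  root of 1.3 log₁₀ g, giving a realistic ~1 log₁₀-unit spread across
  tips); lifestyle by a symmetric 10-state Mk process (per-state flow
  0.05, slow enough to retain phylogenetic signal); 20/904 lifestyles
  masked as missing.
- **Climate**: a latent aridity axis a ∈ [0,1] assigns biomes as
  contiguous bands and drives the five bioclim variables. Bio12 is linear
  in (1 − a) and is deliberately the cleanest aridity proxy; the other
  four mix a with an independent latent driver (≈0.45/0.55) plus 5%
  multiplicative noise, so the generated set behaves like a
  post-collinearity-screen variable set (pairwise |r| ≈ 0.3–0.7).
  Latitude tracks aridity, making the climate gradient spatial, which is
  what gives the SAR/Moran machinery something to detect.
- **Richness**: negative binomial (mean 40, size 5) truncated to ≥ 2 —
  the order of magnitude of real squamate locality lists.
- **Assembly rules**: neutral (uniform draw); filtering (weights
  exp(−(z−μ_s)²/2σ_f²) on body size, σ_f = 0.35, site optimum μ_s larger
  in humid sites); limiting similarity (greedy max–min Gower — chosen over
  probabilistic repulsion for determinism given a seed; it is a stylised
  competition model, not a mechanistic claim); and mixed (filtering in
  arid biomes; in humid biomes limiting similarity restricted to one
  large clade, ~40% of species, so humid sites are phylogenetically
  clustered while functionally overdispersed — the SDH layout).

What the generator does **not** emulate: dispersal limitation and
historical biogeography, abundance structure, sampling effort gradients,
spatially aggregated site placement within biomes, and trait–environment
feedbacks beyond the single filter trait. Passing calibration on these
worlds therefore shows the statistics are correct and the pipeline recovers
planted processes — not that real assemblages satisfy the generative
assumptions.

## Problem sizes used in calibration runs

The acceptance script and test suite size their simulations to single-CPU
scales chosen once: exact-enumeration oracles on 10-species pools
(assemblages ≤ 4); type-I calibration with 500 neutral sites at 1000 null
draws; process recovery over 50 replicate worlds per rule at 200 species /
20 sites / 300 null draws (the separation between rules is many SES units,
so replicate count, not world size, carries the information); the SDH
signature at the full default scale (904/92) with 1000 null draws; SAR
recovery on a 20×20 lattice. The same directional checks at reduced n
appear in the unit tests.

## Known limitations

- The label-shuffle null is the only null model; independent/trial-swap
  nulls that preserve occupancy frequencies are out of scope.
- MPD/MNND are presence/absence only; no abundance weighting.
- The SAR implementation is dense-matrix and comfortable to ~2000 sites;
  beyond that a sparse log-determinant would be needed.
- Biome pools are unions of observed lists, so rare species enter a biome
  pool only if sampled; with very few sites per biome the biome-pool SES
  is conservative by construction.
- Country-scale "localities" violate the point-coordinate assumption of
  the spatial weights; the subset machinery exists precisely to drop them
  in sensitivity runs.
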