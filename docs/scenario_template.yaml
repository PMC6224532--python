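# Scenario template for `commstruct simulate --scenario <file> --out <dir>`.
# Every key is optional; omitted keys use the defaults shown.

n_species: 904          # tips in the simulated phylogeny
n_sites: 92             # localities
# Biome plan, ordered humid -> arid; site counts must sum to n_sites.
biome_plan:
  - [TMBF, 31]          # tropical moist broadleaf forests
  - [FGS, 1]            # flooded grasslands & savannahs
  - [TGSS, 30]          # tropical grasslands, savannahs & shrublands
  - [MGS, 7]            # montane grasslands & shrublands
  - [MFWS, 2]           # mediterranean forests, woodlands & scrubs
  - [DXS, 21]           # deserts & xeric shrublands

yule_rate: 1.0          # birth rate per lineage per unit time
sigma2_bm: 0.2          # Brownian rate of log10 body mass per unit time
mk_rate: 0.05           # per-state flow rate of the 10-state lifestyle Mk
missing_lifestyle_frac: 0.0221   # fraction of species with unknown lifestyle

# neutral | filtering | limiting_similarity | mixed
assembly: neutral
sigma_f: 0.35           # filter width on log10 mass (filtering/mixed)
clade_fraction: 0.4     # clade size for humid pools (mixed only)

richness_mean: 40.0     # per-site richness: truncated negative binomial
richness_disp: 5.0
climate_noise: 0.05     # relative noise on bioclim values

seed: 0
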