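# Methods

`adaptscape` builds a simulated adaptation landscape for wheat: a marker
panel with population structure, a quantitative-genetic basis for the
physiological parameters of a daily growth surrogate, a synthetic target
population of environments (TPE), and the statistical toolkit used to
analyse the resulting multi-environment trial (MET) — G×E decomposition,
environment typing, time-resolved association scans, and multi-environment
genomic prediction. This note records the models, their assumptions, the
defaults, and the design choices that were genuinely open.

## Marker panel and population structure

Markers are simulated under the Balding–Nichols model: each SNP draws an
ancestral frequency from Uniform(0.05, 0.95) and a per-SNP differentiation
parameter F from a scaled Beta(1.2, 3.5); each of the (default five)
subpopulations then draws its own frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) and genotypes are binomial dosages. The
`fst_level` knob ("low"/"moderate"/"high", or a numeric multiplier) scales
the F draw; at "moderate" the realized per-SNP Weir–Cockerham Fst spans 0 to
roughly 0.8. SNPs with minor-allele frequency below 0.02 are discarded (the
simulator oversamples ~1.8× to compensate). The default panel is 199
genotypes × 3,035 SNPs on 21 chromosomes.

Nine *designated loci* act as flowering-gene proxies. They are chosen as the
SNPs whose realized Fst is nearest to nine fixed targets spanning 0.11–0.72
with median 0.50 — moderate-to-large differentiation, so the phenology
parameters seated on them are partially confounded with population
structure, a deliberate feature of the study design that this panel
emulates.

Kinship is `A = XX′/n_m` with X the column-standardized dosage matrix.
Standardization uses mean 2p and sd √(2p(1−p)) by default; an
`scale="empirical"` option standardizes by the observed sd, in which case
trace(A) = n exactly and the off-diagonal mean is −1/(n−1). Structure is
read from the significant eigenvalues of A by the Tracy–Widom test
(Patterson-style effective-sample estimation; critical values 0.9793 /
2.0234 / 3.2724 at α = 0.05 / 0.01 / 0.001), followed by Ward clustering of
the significant PCs into (n_significant + 1) groups. Per-SNP Fst is the
Weir–Cockerham θ estimator with negative estimates clamped to 0.

## Genetic architecture of the model parameters

Twelve physiological parameters (phenology sensitivities, resource capture
and use efficiencies, partitioning and grain-sink traits) each have a
literature-based population range and are controlled by 300 additive QTLs.

*Magnitudes.* Absolute QTL effects follow gamma marginals. When empirical
GWAS effect tables are supplied, each environment column is fitted by
maximum likelihood and the element-wise median of shape and rate across
environments is used. Without empirical input the default marginal is
Gamma(shape 1.2, rate 25): a leptokurtic spectrum of many small and few
large effects. A Gaussian copula couples the absolute effects of three
targeted parameter pairs — transpiration efficiency × radiation-use
efficiency (target r = −0.40), grains-per-gram-stem × maximum grain size
(−0.50), maximum grain size × grain-filling rate (+0.45) — with copula
correlation |target r|; all other parameters are sampled independently.

*Signs.* Each parameter's effects get independent random signs (50/50),
except the targeted pairs: 60% of QTLs (chosen at random per pair) receive
coupled signs — identical for a positive target, opposite for a negative
one. Maximum grain size sits in two pairs and acts as the anchor: its signs
are drawn once and each partner is coupled to it.

*Positions.* The 300 QTLs are seated on uniformly sampled SNPs; the nine
designated loci are always included, and the photoperiod- and
vernalization-sensitivity columns are permuted so their nine largest
magnitudes sit on those loci.

*Genotypic values and acceptance.* Parameter values are
`y_i^p = μ^p + Σ_q x_iq α_q^p` with x ∈ {−1, 0, 1} and μ^p the range
midpoint, then affinely rescaled per column so min/max hit the published
range. An architecture is accepted only if every untargeted pair has
realized |r| ≤ 0.4 and every targeted pair is within ±0.2 of its target;
otherwise signs and positions are redrawn (the copula draw is kept), up to
200 retries. At panel scale acceptance typically arrives within ~10–20
retries; panels below ~50 genotypes rarely satisfy the audit (66 noisy
pairwise correlations), so an `on_fail="best"` mode returns the
least-violating attempt flagged unaccepted — used by the pipeline for smoke
runs, never for analysis-scale results.

## Synthetic environments

Four site archetypes represent contrasting wheat-belt growing areas
(latitude, annual/seasonal rainfall and pattern, mean temperature and
radiation, soil plant-available water capacity, sowing water, nitrogen
management). The TPE is the cross of archetypes and seasons (default 4 × 31
= 124 trials); the soil is reset at sowing each season, so years are
independent environment samples.

Weather is a Richardson-type daily generator. Rain occurrence is a
first-order Markov chain with month-varying probabilities shaped by the
site's rainfall pattern (summer-dominant, winter-dominant, even); monthly
totals are rescaled so the May–November window matches the seasonal target
and the calendar year the annual target. Wet-day amounts are gamma
(shape 3) with the month's implied mean, so totals match the targets in
expectation; occurrence probabilities are deliberately high and amounts
correspondingly small, which keeps seasonal totals tight enough that the
winter-dominant site is winter-dominant in ≈98% of simulated years — the
generator trades realistic dry-spell clustering for stable seasonal
contrasts between sites. Temperature and radiation are seasonal sinusoids
centered on the archetype means (southern-hemisphere phase, diurnal range
12 °C with seasonal modulation) with AR(1) residuals. Daylength is the
standard spherical-astronomy formula at sun altitude −0.83°.

What the generator does **not** emulate: inter-annual climate modes (ENSO),
trends, heat and frost extremes beyond the sinusoid tails, spatial
correlation between sites, and realistic dry-spell length distributions.
Conclusions from passing tests therefore concern the machinery — not
site-specific climatology.

## The daily growth surrogate

A deliberately minimal daily wheat model carries the causal semantics of
the cropping-systems models used for this kind of study, with every one of
the 12 parameters on an active pathway. All constants below are surrogate
choices collected in `CropsimConstants`.

- **Phenology.** Daily thermal time tt = max(0, (tmin+tmax)/2). Before
  floral initiation the effective increment is tt × min(photoperiod factor,
  vernalization factor); the photoperiod factor is
  clamp(1 − 0.002·photop_sens·(20 − daylength)², 0, 1); vernal days accrue
  on days with mean temperature in [0, 15) °C and the vernalization factor
  is clamp(vdays / (16·vern_sens), 0, 1). Floral initiation requires both
  the thermal target (`tt_floral_initiation`) and *completed* vernalization
  (a hard gate — winter habit). Stage offsets: emergence 120 °Cd, floral
  initiation → heading 350, heading → flowering 120, flowering → maturity
  650; Zadoks-like codes 2.1/3.1/5.5/6.5 are attached for reporting.
- **Water.** Single soil bucket of capacity PAWC; supply = 0.08 ×
  extractable water above a floor shifted by (ll_modifier − 1)·PAWC;
  demand = potential growth × VPD / (1000 × transp_eff_cf) with VPD = 0.75 ×
  (svp(tmax) − svp(tmin)) (Tetens); transpiration = min(supply, demand,
  PAW); stress = min(1, supply/demand) (zero-demand days report the ratio
  cap of 10 and a stress multiplier of 1). Bucket overflow is explicit
  runoff, so water is conserved exactly.
- **Growth and canopy.** Potential growth = y_rue × radiation ×
  (1 − exp(−y_extinct_coef × LAI)); actual growth = potential × stress.
  Pre-flowering, a y_frac_leaf share becomes leaf mass driving LAI at a
  constant specific leaf area of 0.020 m² g⁻¹; from floral initiation
  (node turnover at stem elongation) to maturity, LAI decays at
  fr_lf_sen_rate per day, doubled under stress < 0.5. Emergence endows
  LAI 0.05 and 2 g m⁻² of seed reserve (excluded from stem biomass).
- **Grain.** At flowering, grain number = grains_per_gram_stem × stem
  biomass (stem = (1 − y_frac_leaf) of accumulated growth). The daily
  filling sink is grain number × potential_grain_filling_rate × min(1,
  tt/26) × stress, halted entirely below stress 0.15 ("haying off");
  filling is further capped by assimilate (daily growth plus a
  retranslocation pool of 20% of stem mass), by max_grain_size per grain,
  and by a harvest-index ceiling of 0.62. Yield = grain number × final
  grain weight; crops that never set grain are flagged failed with yield 0,
  not raised.

The temperature and stress scaling of the filling sink and the
floral-initiation onset of senescence are what keep the grain-sink and
canopy-turnover parameters causally live: without them, supply-limited
growth cancels the canopy out of the water-limited growth identity and the
sink never binds in any regime. Demand's 1000 factor is the g↔kg unit
bridge making demand come out in mm for growth in g m⁻².

The surrogate is *not* a re-implementation of any published crop model and
is not calibrated against one; only orderings, conservation laws, and the
presence of causal pathways are asserted about it.

## Environment typing and covariables

A reference genotype holding every parameter at its range midpoint is run
in each trial; its flowering date anchors a thermal-time grid. The stress
index min(1, supply/demand) is averaged in 100 °Cd windows from emergence
to 450 °Cd after flowering (window 0 covers the flowering day), trials are
clustered by Ward linkage on the window columns complete in every trial,
and the k = 4 clusters are renamed ET1…ET4 in order of increasing mean
stress, so ET1 is always "no drought".

Environmental covariables are computed per trial over four periods bounded
by the reference phenology — P1 sowing → floral initiation, P2 → flowering,
P3 → flowering + 300 °Cd, P4 → maturity: mean temperature above 0, radiation
sum and mean (both are emitted because the two conventions coexist in
practice; the sum is the canonical one), their ratio, mean stress index,
frost-day count (tmin ≤ 0), cold sum (|Σ tmin| below −4 °C), and the
maximum and mean daylength. Empty periods yield missing values, which the
downstream standardization imputes at the covariable mean.

## G×E analyses

- **AMMI.** Main effects are row/column means of the complete genotype ×
  environment table; the interaction is the SVD of the double-centered
  residual with symmetric score scaling (each side carries √singular
  value). No imputation: missing cells fail.
- **Variance components.** Three models: genotype/location/year (random G,
  G×L, G×Y, G×L×Y, with G×L×Y absorbing the residual stratum),
  ET-nested (G, G×ET, residual G×E), and two-way (G, G×E). In all three the
  fixed part is saturated in trials, so REML reduces exactly to maximizing
  the Wishart likelihood of the genotype-centered trial × trial covariance
  with n_geno − 1 degrees of freedom; the structured covariance (one
  variance per random term, box-constrained at 0) is maximized by L-BFGS-B
  with the analytic gradient, and standard errors come from the observed
  information. On balanced layouts this equals the classical ANOVA
  closed forms (tested to 1e−6). Share tables round to integer percent.
- **Daily G×E and autocorrelation.** The two-way model per day over a
  days × genotypes × environments biomass cube; lagged (5/10/15 d) Pearson
  autocorrelation of biomass across genotypes per environment.
- **Association scans.** Single-locus mixed model with a polygenic
  background whose kinship excludes the tested SNP's chromosome
  (leave one chromosome out). The genetic/residual variance ratio is
  profiled once per phenotype and kinship (the P3D shortcut), then each SNP
  is tested by GLS; effects are reported raw and as a percentage of the
  phenotype mean, with Bonferroni flags at α = 0.05 across SNPs.

## Genomic prediction

Deterministic surrogate phenotypes are degraded with independent per-trial
noise of variance σ²_g(1/H² − 1), targeting H² = 0.5 for yield and 0.7 for
the parameter phenotypes. Training sets are stratified draws of `per_et`
trials per ET (default 4 × 4 = 16; 20 splits, configurable to 30); the
remaining trials are validation.

- **ETmean** fits genotype effects per ET with covariance Σ_G ⊗ Σ_E (Σ_G
  the genomic kinship; Σ_E an unstructured 4×4 across ETs) as a two-stage
  plug-in: per-ET genotype means, method-of-moments Σ_E with the within-ET
  error variance of the mean subtracted from the diagonal (projected to the
  nearest positive-definite matrix when needed), then multivariate GBLUP.
  A validation trial is predicted by its ET's mean plus the genotype's
  ET-specific genomic effect. The plug-in replaces a one-stage unstructured
  mixed model, which is unstable at this scale.
- **MeanPC / IndivPC** regress yield on cross-products of the four leading
  genotypic-kinship PCs and three environmental-kinship PCs, with trial
  main effects — one slope on the averaged product vector, or one slope per
  product. The environmental kinship is the trial × trial Euclidean
  distance matrix on standardized covariables: unlike a centered
  cross-product matrix it has a dominant constant-sign eigenvector, which
  gives the averaged product a stable genotype-ranking pathway across
  trials (with a centered kinship the MeanPC validation accuracy is ~0 by
  construction). Unobserved validation trials take the mean training-trial
  effect of their ET as the environmental anchor — a modeling choice, since
  an unobserved trial has no estimable main effect.
- **FReg** is factorial regression on products of (noisy) physiological
  parameters and environmental covariables, grown by forward selection:
  each round the most significant candidate enters with its square, the
  square is dropped if not itself significant (F-tests, α = 0.01), and
  selection stops when nothing passes or at 10 terms. Terms are named
  `parameter.covariable_period`.

Accuracy is the per-validation-trial Pearson correlation between
predictions and the *noise-free* genotypic values, aggregated across splits
on Fisher's z scale (z = arctanh r, back-transformed with tanh; r clipped
at ±0.9999) with a normal-theory 95% interval.

## Reproducibility and problem sizes

Every operation takes a single integer seed (or a NumPy SeedSequence);
the pipeline derives all stage seeds from one master seed, and identical
configs give identical manifests. The test suite exercises the full
pipeline at a reduced scale chosen to keep the suite fast while leaving all
qualitative structure intact — an 80-genotype × 600-SNP panel across 4
sites × 10 years — and the calibration checks run the architecture
procedure at the full 199 × 3,035 panel scale. The acceptance script uses
10 master seeds for the architecture correlations and a 2-site × 3-year
199-genotype MET with 50 noise seeds for the heritability calibration.

## Known limitations

- The growth surrogate is a caricature: no nitrogen dynamics, no frost or
  heat kill, one soil layer, fixed stage offsets. Its MET statistics have
  realistic *structure* (large G×E dominated by location and water regime,
  ET classifications aligned with site aridity), not site-accurate values.
- The weather generator's occurrence/amount trade-off (many small wet
  days) understates dry-spell persistence.
- MeanPC/IndivPC accuracies depend on the eigenstructure of the
  environmental kinship; with few training trials per ET the averaged-PC
  model is near its breakeven point.
- The architecture acceptance rules presuppose a panel of ~100+ genotypes;
  smaller panels must use the best-attempt fallback and carry the
  unaccepted flag.
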