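# Methods

This note documents the models behind each `flaxpop` module, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data calibrations do and do not demonstrate.

## Sequence diversity and neutrality tests

Statistics operate on haplotype alignments over {A, C, G, T, -, N} after
*complete deletion*: any column containing a gap or N in any sequence is
removed.  This is the simplest defensible convention for short amplicon
alignments; it discards information when missingness is heavy, but makes
every statistic a function of a fully observed matrix.

* Segregating sites S are columns with ≥2 observed residues; the mutation
  count η is taken equal to S (infinite-sites convention — multi-hit
  columns are rare at the sub-kilobase scale these tests target).
* π is the mean number of pairwise differences; θ̂_W = S/a₁ with
  a₁ = Σ_{i<n} 1/i.
* Tajima's D uses the standard variance coefficients; at n = 2 the
  variance vanishes together with the numerator (π = S = θ̂_W), and D is
  reported as the degenerate 0 rather than undefined.
* Fu & Li's D* and F* use the no-outgroup ("starred") forms with the
  corrected coefficient expressions adopted by mainstream software;
  singletons are residues observed exactly once at a polymorphic site.
  When an outgroup sequence is available, `fu_li_outgroup` polarizes
  singletons against it and computes D and F proper.  The starred variants
  are the default because amplicon panels often lack a usable outgroup.
* R₂ follows its definition: R₂ = √((1/n)Σᵢ(Uᵢ − k/2)²)/S with Uᵢ the
  singletons carried by sequence i and k = π.
* Any statistic is NaN (never 0) when S = 0; a zero would silently bias
  summaries over loci.
* Significance beyond sign comes from a fixed-S coalescent null
  (`neutrality_pvalues`): genealogies at the observed n, exactly S
  mutations placed multinomially by branch length, two-sided empirical
  p-values.  Conditioning on S avoids having to estimate θ.

Allele (haplotype) collapsing treats N as a wildcard.  Because
"identical outside N" is not transitive, assignment is greedy in input
order against a per-group consensus whose N positions are filled as
members resolve them; groups are reported largest-first.  This matches
the practical goal (count distinct alleles under partial sequence
ambiguity) at the cost of a formally order-dependent edge case when two
groups are bridgeable only through an all-N region.

The two-locus statistic r is computed exactly as defined from observed
haplotype-combination proportions; its numerator equals the classical D,
and it is NaN with an explanatory message when either locus is
monomorphic.

## Selection from dated allele frequencies

The estimator assumes a single biallelic locus under constant viability
selection in a partially selfing annual.  Genotype frequencies are
reconstructed each generation from the allele frequency p and Wright's F:

    D_AA = p² + Fpq,  H = 2pq(1 − F),  R = q² + Fpq,

with fitnesses {1, 1, 1−s} when the focal allele is dominant and
{1, 1−s, 1−s} when recessive, and

    p′ = (w_AA·D_AA + ½·w_Aa·H) / w̄ .

Given two dated observations, G = round(Δyears / generation_time)
(generation time 1 year by default — flax is annual), ŝ is the unique
root of forward(p_start, s, G) = p_stop, found by bisection on
s ∈ (−0.5, 0.5); the forward map is monotone in s, realistic estimates
(~10⁻³) lie far inside the bracket, and the bisection terminates at an
interval below 10⁻¹² in s.  The selection differential k relates to s by
s = 1 − 1/(1 − k) (an involution, so k̂ = 1 − 1/(1 − ŝ)).

Sampling error: both endpoint frequencies are drawn from Beta(x+1, n−x+1)
— the binomial posterior under a uniform prior, chosen because the data
model is stated as a binomial process with no prior information — and s is
re-estimated per draw; the reported bounds are empirical quantiles.
Draws whose (p_start, p_stop) pair is unreachable within the bracket are
skipped and counted; bounds are flagged unreliable above 50% infeasible.
Phenotype-frequency data are converted to allele frequencies through the
genotype model (carriers for a dominant trait, homozygotes for a
recessive one) before estimation.

Identifiability: when the trajectory saturates numerically at 0 or 1 the
two observations no longer determine s.  The round-trip validation
therefore anchors the *stop* frequency at 0.5 and solves for the matching
start per (s, F, G) cell by geometric bisection (start frequencies as low
as ~10⁻¹⁶ arise at the strongest-selection, longest-time cells); the
estimator then recovers planted s to ~10⁻¹² across
s ∈ {0.001…0.02} × F ∈ {0, 0.5, 0.9, 0.95} × G ∈ {50, 500, 2000} and both
dominance modes.

Coverage of the Beta bounds was validated on Wright-Fisher data
(N = 10,000, 100 generations, outcrossing 3–5% as reported for flax,
true s = 0.01, 40 sampled alleles per date, 1000 draws per interval, 200
replicates): 92–96% of nominal-95% intervals cover the truth.  N was set
high enough that drift noise stays below the binomial sampling noise the
Beta bounds model; with small populations the intervals under-cover
because they propagate sampling error only, not drift — a real limitation
when applying the method to small demes.

## F_ST and the outlier scan

`fst_locus` implements the Weir & Cockerham (1984) two-population
variance-component estimator directly on allele counts, with the
within-individual heterozygosity term set to zero (appropriate for pooled
allele counts from highly selfing material, where heterozygotes are
rare).  The *uncorrected* variant is the infinite-sample limit
θ = s²/(s² + p̄q̄ − s²/2); it is non-negative by construction, which suits
the chi-square null model below.  The *corrected* variant keeps the
finite-sample terms and is the better point estimate.

The outlier scan drops loci with pooled expected heterozygosity
He = 2p̄q̄ < 0.10 (low-He loci carry little frequency information and
destabilize the null fit; the threshold is a flag), trims the lowest and
highest 5% of uncorrected F_ST, and fits F_ST·df/μ ~ χ²_df by maximum
likelihood over (df, μ).  Two likelihood treatments of the trimmed tails
are provided:

* **censored** (default): the trimmed tails enter as censored counts
  (values known only to lie beyond the trim quantiles).  This anchors the
  fitted tail mass to the observed trim fractions, so right-tail p-values
  stay calibrated at working significance levels even where the
  chi-square family fits the extreme tail imperfectly — on
  Balding-Nichols nulls (5000 loci, F = 0.05, 100 alleles per
  population) the p < 0.05 fraction is ≈ 0.04 and the p-value KS distance
  from uniform < 0.03.
* **truncated**: classical conditioning on the core range.  On the same
  nulls this is conservative (p < 0.05 fraction ≈ 0.025) because the
  Balding-Nichols beta tails are lighter than chi-square.

Per-locus right-tail p-values are converted to Benjamini-Hochberg
q-values (the standard FDR choice where only a q-value is reported);
outliers are flagged at q < 0.05.  With two populations the fitted df is
≈ 1, so the null's right tail is heavy and single-locus detection at
q < 0.05 over thousands of loci requires F_ST ≳ 0.9: the power scenario
plants near-fixed frequency differences (0.975 vs 0.025), the magnitude
of the strongest local-adaptation outliers this scan exists to catch, and
recovers ≥ 7/10 (typically 10/10).  Moderately elevated divergence
(e.g. tripled drift) is *not* detectable at these settings — an honest
statement about per-locus outlier scans between two demes.

## 2D allele-frequency-spectrum probability maps

Each locus is a point (f_N, f_S); its diagonal position is
m = (f_N + f_S)/2 and its signed perpendicular distance
d = (f_N − f_S)/√2 (the 1/√2 makes the coordinate Euclidean; any monotone
rescaling yields identical p-values).  m ∈ [0, 1] is cut into 10 bins by
default; per bin the mean and standard deviation of d are estimated, and
(μ_d, σ_d) are interpolated linearly between bin centers with constant
extrapolation beyond the outer centers.  Empty or single-point bins are
interpolated from neighbours and flagged.  The probability of a query
point is the two-sided Gaussian tail 2·(1 − Φ(|d − μ_d(m)|/σ_d(m))),
capped at 1; σ_d = 0 yields NaN, and a panel with f_N = f_S everywhere is
rejected as degenerate.  Self-querying a 5000-locus Balding-Nichols null
gives near-uniform p-values (KS < 0.02).  Frequencies are polarized by
the global minor allele over the pooled sample (configurable upstream);
`heatmap_grid` serializes the map on a regular grid for plotting.

## Latitudinal clines

`logistic_cline` fits P(presence) against latitude by a binomial GLM
(IRLS) and reports the Wald p-value for the slope — the conventional
single-number test where a regression p-value is quoted.  Complete
separation (including all-0/all-1 outcomes and a perfect latitude
threshold) is detected up front and raises an error advising a penalized
fit rather than returning divergent estimates.  The fitted curve is
exported at 0.1° steps.

## Gene-flow tests

∂f subsets collect loci whose wild-north frequency exceeds the wild-south
frequency by more than 0.5/0.4/0.3 (strict, north higher); subsets nest.
Informativeness for assignment follows Rosenberg's I_n with 0·ln 0 = 0
and the unweighted mean frequency across K populations; it is computed on
the two wild populations by default (K configurable).  Note the selection
effect: a subset *chosen* by ∂f on the same populations used for I_a is
mechanically enriched for informative loci, which is exactly the contrast
the subset-vs-total ratio (I_a∂f / I_at) expresses.

The resampling test compares the subset's mean uncorrected F_ST between
cultivated north and south with the same statistic on random equal-size
subsets drawn uniformly without replacement from all retained loci
(100,000 by default, reducible); p = (1 + #{null ≥ obs})/(R + 1), so
p ≥ 1/(R+1).  He-matched resampling is not applied by default (the null
is all loci), a documented choice.

f₃(target; A, B) is the mean over loci of (p_T − p_A)(p_T − p_B), with the
target sampling-bias term p_T(1−p_T)/(n_T − 1) subtracted when requested;
the z-score uses a delete-one-locus jackknife (no genome coordinates are
assumed, so no block jackknife).  The shared-elevation fraction counts
strict f_cultN > f_cultS over subset loci; ties are excluded from the
denominator and an all-tie subset is undefined.

## Photoperiod growth model

The growth simulator is a deliberately minimal, fully deterministic daily
mechanism that reproduces the qualitative architecture/latitude
predictions of TFL1-like floral repression:

* day length L(φ, day) uses the cosine declination approximation
  δ = −23.44°·cos(2π(day+10)/365) and L = (24/π)·arccos(−tanφ·tanδ),
  clamped to [0, 24] (polar cases warn); no refraction correction, which
  keeps midsummer values within ~0.3 h of astronomical tables in the
  mid-latitudes of interest (18.49 h at 60° N on day 172);
* while vegetative, nodes accrue at `node_rate` (0.5/day) and a florigen
  signal accrues at `ft_gain`·max(0, L − threshold) with a 14 h default
  threshold;
* floral transition occurs the first day the signal strictly exceeds the
  TFL1 set-point T; afterwards flowers accrue at `flower_rate` on days
  with L > threshold until the season ends (days 105–280 by default,
  mid-April to early October);
* stem height = vegetative nodes × internode length (10 mm).

Consequences (all asserted in tests): height is nondecreasing in T at
fixed latitude; lowering the threshold never prevents flowering; at 60° N
the above-threshold window opens earlier and closes later than at 35° N,
so large-T forms flower longer and produce more flowers in the north,
while at the equator a 14 h threshold is never met and the plant stays
vegetative all season.  Axillary branching, assimilate budgets and any
stochasticity are out of scope; the per-day rates are parameters with
documented defaults, not fitted constants.

## Synthetic-data generators

All generators take a seed (or a numpy Generator) and are reproducible;
scenario generators return their ground truth alongside the data.

* `neutral_coalescent_alignment`: Kingman coalescent (exponential
  inter-coalescent times at rate k(k−1)/2, time in units of 2N), mutations
  Poisson(θ/2 × branch length) under infinite sites, columns written as
  ancestral A / derived T in random site order.  Validated against
  E[S] = θ·a₁ (within 2% over 2000 replicates at n = 20, θ = 5) and mean
  Tajima's D within (−0.15, 0.15).  A mutation-free genealogy is emitted
  as a single monomorphic column so the container stays valid.
* `wright_fisher_selfing`: per generation, genotype construction from
  (p, F), viability selection identical to the deterministic model,
  multinomial resampling of N individuals, and the selfing recursion
  F′ = (1−t)(1+F)/2 with F started at its equilibrium (1−t)/(1+t) unless
  overridden.  Tracking F dynamically (rather than fixing it) lets tests
  cover non-equilibrium starts; the mean trajectory converges to the
  fixed-F recursion as N grows (asserted at N = 10⁴).
* `balding_nichols_panel`: ancestral p ~ U(0.05, 0.95), per-population
  p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F), binomial counts at the stated
  allele sample sizes (100/population by default).  Chosen as the drift
  null because it is standard and closed-form.
* `geneflow_scenario`: wild north/south by Balding-Nichols (F = 0.05);
  both cultivated populations founded from the wild south through a
  50-founder bottleneck; 20 generations of drift at N = 500 during which
  the cultivated north receives wild-north migrants at rate m per
  generation; optional spiked loci get a deterministic +0.4 (clipped)
  boost in wild north (pre-founding) and cultivated north (at the end) —
  transparent analogues of a northern-adapted allele.  Sample sizes
  default to 56/56/62/62 alleles, the scale of a modest accession panel.
  With m = 0.1 the ∂f > 0.4 subset shows a resampling p at the floor and
  a shared-elevation fraction near 1; with m = 0 the fraction sits near
  0.5.
* `selfing_t2_segregation`: selfed progeny of a parent hemizygous at L
  unlinked transgene loci; per locus the allele count is Binomial(2, ½)
  (¼ : ½ : ¼), a carrier holds ≥1 allele anywhere, and the analytic
  carrier : non-carrier ratio is (4^L − 1):1 — 15:1 at L = 2.

What the calibrations show — and do not.  Passing tests demonstrate that
the estimators are internally correct and calibrated *under the generating
models*: free recombination between loci, no linkage, no ascertainment
bias, binomial sampling, island-free Balding-Nichols drift, and a
single-locus selection model without drift in the deterministic limit.
Real RAD panels add linked loci, allele-calling error, uneven coverage
and complex demography; none of those are emulated, so calibration here
is necessary but not sufficient evidence for real-data behaviour.

## Problem sizes

The shipped validation suites use 2000 coalescent replicates (n = 20,
θ = 5), 5000-locus panels for the outlier and spectrum calibrations,
3000-locus gene-flow scenarios with 10⁴ resamples, 200 coverage
replicates at 1000 Beta draws, and the full 120-cell selection round-trip
grid — sizes at which every Monte-Carlo band asserted in the tests is
comfortably wider than its standard error, chosen as the package's
standard validation conditions.
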