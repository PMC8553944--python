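# Methods

`rangeshift` implements three analysis arms commonly combined in studies of
poleward range extension in marine fishes — SNP-based population
connectivity, dietary DNA-metabarcoding curation with community statistics,
and thermal-threshold isotherm projection from multi-model SST ensembles —
together with synthetic-data generators that provide recoverable ground
truth for every stage. This note records the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic tests do
and do not establish about real data.

## Genotype simulation

Two generative modes produce biallelic SNP matrices (dosage coding 0/1/2,
−1 missing) over a set of sampling sites.

**Balding–Nichols mode** (`target_fst=F`): ancestral minor-allele
frequencies are Uniform(0.05, 0.95); each population draws its frequency
from Beta(p(1−F)/F, (1−p)(1−F)/F). The among-population variance of the
per-locus frequency is F·p(1−p), so the Weir–Cockerham multilocus estimator
is analytically unbiased for F — this is the parameter-recovery oracle.
Recovery holds to ±0.005 at 2 × 50 × 2000 (pops × individuals × loci)
across F ∈ {0.01, 0.05, 0.10, 0.20}.

**Migration mode** (`migration_matrix`): all demes start at the ancestral
frequency and evolve for 100 non-overlapping generations (configurable);
each generation applies deterministic migration (entry [i, j] is the
fraction of deme j replaced by emigrants from deme i) followed by binomial
drift of 2N gene copies, N = 250 by default. These values give per-pair
differentiation of a few percent after 100 generations — the weakly
structured regime typical of high-gene-flow marine fishes — while leaving
enough drift for directional signal.

Genotypes are Hardy–Weinberg draws from population frequencies; missingness
is independent per call; per-locus coverage is log-normal clipped to
`coverage_range`, the simplest model that exercises the coverage filters.
One global seed feeds labelled child generators (CRC-derived), so adding
draws in one stage never perturbs another and all outputs are
bit-reproducible.

## SNP quality control

The cascade order is fixed: per-locus filters → monomorphic/individual
removal (iterated to a fixed point) → HWE/LD pruning → outlier scan. Every
stage appends a `FilterReport`, so the four-stage locus-count sequence is
auditable on any input. Per-locus filters run sequentially (call rate ≥
0.95, mean coverage in [20, 200]×, observed heterozygosity ≤ 0.75, folded
MAF ≥ 0.05); bounds are read as strict removal criteria, so a locus exactly
at a bound survives. Coverage bounds apply to mean locus depth, not
per-call depth.

The HWE test is the classic exact conditional test (Levene/Haldane, mid-p
off), Bonferroni-corrected within each population across its testable loci;
a locus is removed when significant in ≥ 2 populations. LD uses the
composite genotypic r² (squared Pearson correlation of dosages,
pairwise-complete), χ² = n·r² on 1 df, Bonferroni across pairs within
population, plus an r² ≥ 0.8 floor; of a pruned pair the member with the
lower call rate goes (ties: lower MAF, then the lexicographically later
id). Populations under 5 genotyped individuals are excluded from voting and
logged.

**Outlier scan.** Per-locus F_st is computed twice: the standard
finite-sample Weir–Cockerham form for reporting, and an uncorrected form
(components without the small-sample adjustments) for the null fit, where
the sampling inflation is absorbed into the inferred degrees of freedom.
Loci with pooled expected heterozygosity < 0.1 are excluded. A scaled
chi-square — x ~ (F̄/df)·χ²(df), truncated to the central 90% window after a
5% two-sided trim — is fitted by Nelder–Mead maximum likelihood on
(log df, log F̄), moment-initialized; the fit recovers a known df within
10% on direct chi-square simulations. Right-tail p-values are converted to
q-values by Benjamini–Hochberg and loci with q below the FDR become
outliers. Power to detect a 5-fold variance inflation is intrinsically
limited by the chi-square df ≈ (number of demes − 1): at 7 demes the
planted loci's own sampling spread caps detection near 50% regardless of
sample size, so the power validation uses a 20-deme island metapopulation
(≈ 87% detection), while null calibration is also checked at a 7-site
design (flagged fraction ≪ 5%).

## Differentiation, diversity, and isolation by distance

Pairwise F_st is the multilocus Weir–Cockerham estimator as a ratio of
summed variance components (Σa / Σ(a+b+c)), not a mean of per-locus ratios.
Confidence intervals bootstrap loci; the p-value is the bootstrap
probability of an estimate ≤ 0 (10,000 replicates by default) and is
adjusted across pairs with the Benjamini–Yekutieli FDR. Pairs sharing fewer
than two informative loci are flagged unreliable. A presentation-only
`shift_nonnegative` adds a recorded constant so the smallest pairwise value
is zero; it is never fed back into inference.

G_st is Nei (1973): H_S the unweighted mean of within-population expected
heterozygosities, H_T from the mean frequencies, multilocus as the ratio of
across-locus averages. Jost's D applies the n/(n−1) population-number
scaling. Both get locus-bootstrap intervals (1,000 replicates by default).

Diversity per site reports mean observed/expected heterozygosity and
allelic richness rarefied by the exact hypergeometric formula to the
smallest per-locus allele count across sites — deterministic and bounded in
[1, 2] for biallelic loci — with intervals from bootstrapping individuals
within sites.

The Mantel test linearizes differentiation as F_st/(1−F_st), correlates
off-diagonal entries with a supplied distance matrix (one matrix per depth
layer; ocean distances are consumed, never computed), and permutes site
labels of the distance matrix. The test is one-sided against the
isolation-by-distance alternative (r > 0), the convention of the standard
community-ecology implementations; the permutation null is exactly
calibrated (rejection 0.051 at α = 0.05 over 2,000 independent nulls).
Entries at F_st = 1 linearize to infinity and are excluded with a warning.

## Directional relative migration

For each ordered pair of demes a hypothetical pooled population is the
equal-weight mean of the pair's allele frequencies. Within a pair the mean
member-pool heterozygosity gap (the G_st numerator) is algebraically
symmetric — per locus it equals q²/8 for both members, q the frequency
difference — so the entire directional signal lives in the denominators:
immigration raises the receiver's diversity, which lowers the G_st-type
statistic of the *receiver* against the pool (larger H_T) but lowers the
Jost-D statistic of the *source* (larger 1−H_S). The G_st/Nm bases
therefore transform the receiver-pool statistic and the D basis the
source-pool statistic; the two readings provably order every pair
identically, and all three recover planted 10× asymmetric emigration in
20/20 forward simulations. Rates use the island-model transform
((1/G)−1)/4 for G_st/Nm and (1−D)/D for D, truncated at zero, then the
whole directed matrix is divided by its maximum. The orientation
(receiver-closer-to-pool under immigration) was fixed by forward
simulation before any downstream testing.

Asymmetry per unordered pair bootstraps individuals within demes (10,000
replicates by default), recomputes the normalized directed matrix, and
flags the pair when the percentile interval of m[i→j] − m[j→i] excludes
zero. The null false-positive rate is below α + 2 SE in symmetric island
models; detecting a 10× emigration asymmetry with ≥ 80% probability needs
on the order of 4,000 loci (power ≈ 65% at 1,000), consistent with the
several-thousand-locus panels such studies retain.

## OTU simulation and curation

The generator draws each sample's reads from a Dirichlet-multinomial
(log-normal base weights, concentration 150, depths 35–60k) with exact
bookkeeping of planted structure: indicator OTUs present only and
abundantly in their group combination; parent–daughter error pairs where
the daughter is a fixed 5–20% fraction of its parent in every sample where
the parent holds ≥ 20 reads (errors arise from abundant templates, which
also keeps co-occurrence intact under later subsampling); decoy pairs that
are similar by identity but occupy disjoint sample halves; contaminants
with ≥ 2 reads in every control; and low-read OTUs totalling < 10 reads.

Curation order is fixed and logged: rarefaction to 30,000 reads per
biological sample (single hypergeometric draw per seed, without
replacement; shallower samples dropped with a warning; controls pass
unchanged) → co-occurrence curation → control-OTU removal (≥ 2 reads in
any control; controls then dropped) → minimum-total filter (≥ 10 reads).
The co-occurrence curation walks OTUs by decreasing total abundance and
merges an OTU into a retained higher-ranked OTU when match-list identity ≥
84%, the parent occurs in ≥ 95% of the daughter's samples, and the
parent/daughter ratio over shared samples is ≥ 1 (minimum-ratio rule);
these are the published defaults of the post-clustering curation method and
are exposed in configuration. Decisions use pre-merge abundances, so the
outcome does not depend on merge order within a rank; ties in ranking are
broken stably. A 1,337-OTU reference community with 602 planted daughters
and 17 contaminants curates to 735 and then 718 OTUs exactly, for any
rarefaction seed tried.

## Community statistics

Bray–Curtis dissimilarities are computed on per-sample relative abundances
(rarefied-relative by default; raw counts optional). nMDS wraps the
non-metric MDS of scikit-learn (Kruskal stress-1, monotone regression, 50
random restarts, seeded); planar configurations reach stress < 10⁻³.

PERMANOVA is the one-way pseudo-F from the Gower-centred matrix,
SS_among = Σ_g (1'_g G 1_g)/n_g, R² = SS_among/SS_total, with free
permutation of sample labels (vectorized; 100,000 by default). It is exact
by exchangeability: type-I error 0.048–0.053 at α = 0.05 over thousands of
Dirichlet-multinomial nulls, and the statistic matches scikit-bio's to
1e-9.

PERMDISP embeds samples by principal coordinates, keeping negative
eigenvalues as imaginary axes whose squared distances subtract, computes
each sample's distance to its group centre (spatial median via Weiszfeld by
default, centroid optional; the statistic matches vegan's betadisper to
1e-7), and permutes those distances among groups. Validity is
sample-size-dependent in both this and the reference implementation: at ~5
samples/group the median variant is conservative (~0.03) and the centroid
variant liberal (~0.08); both are calibrated at 25 samples/group (0.0465
and 0.054). Dispersion conclusions from very small groups should be read
accordingly.

IndVal uses the group-size-corrected statistic: specificity from group mean
abundances (A_C = Σ_{g∈C} x̄_g / Σ_h x̄_h), fidelity as the occurrence
fraction within the combination, IndVal = √(A·B) over all non-empty group
combinations. The p-value permutes group labels and compares the best
combination's statistic against its permutation distribution;
Benjamini–Hochberg across OTUs. OTUs absent everywhere report 0 with a
flag. Planted perfect indicators score exactly 1.0 and their combinations
are recovered.

## Climate projection

Fields are monthly (time, lat, lon) arrays in °C. Two climatological
metrics over a year window: the annual mean, and the minimum monthly mean
(MiMM) — the coldest calendar month of the across-years monthly
climatology, a proxy for the winter thermal floor; MiMM ≤ annual mean
cell-wise by construction. Cells need ≥ 80% of window months (configurable)
else they are masked.

Delta-change projection: corrected(window) = observed climatology +
(model(window) − model(base window)), per metric, base 2008–2017. A static
model bias cancels exactly (verified to 1e-10 on float64 fields), and over
the base window the corrected field equals the observed climatology.
Models are bilinearly regridded onto the observed grid when needed.
Ensembles average member anomalies cell-wise (ensemble mean first, contour
extraction second; the alternative order is available), with min–max
member spread retained.

Isotherm latitudes are extracted per longitude column as the poleward-most
linearly interpolated crossing of the threshold (17 °C on MiMM for
overwintering, 20 °C on the annual mean for spawning, in the motivating
application); multiple crossings resolve poleward and are logged, columns
that never cross are NaN and flagged. Decades are calendar decades; the
decadal mean contour comes from the decadal-mean ensemble field and the
range spans the yearly ensemble-mean contours within the decade (member
spread optional). On synthetic ensembles (11 pseudo-models with biases
−1.5…+1.5 °C, 1900–2100 monthly, 1° grid, 0.45 °C/°lat gradient, trend 0.4
°C/decade) the projected 2090s displacement matches the closed form
ΔT/gradient to ~0.004°, far inside one grid step.

Heatwave anomalies subtract the baseline-window seasonal climatology
(1980–2015, JFM by default) from the event season, identically for SST and
current components. Note the baseline contains the event year, so a
planted pulse of amplitude A is recovered as A·(1 − 1/n_years).

## Synthetic data: what it does and does not show

The generators are stand-ins: the motivating study provides no generative
model for any of its data, so every distributional choice here
(Balding–Nichols structure, log-normal abundances, Dirichlet-multinomial
sampling, linear trends with additive bias and Gaussian noise) is the
simplest standard form that exercises the corresponding inference. Passing
tests establish correctness of the implementations and calibration of
their error rates under these models — not robustness to real-data
features such as null alleles, batch effects in coverage, PCR/primer bias,
taxon-correlated read counts, ENSO-scale climate variability, or coastline
masking. Problem sizes in the test suite (2,000-locus panels, 20-deme
power designs, 24-sample communities, 5-column longitude strips) were
chosen to estimate each property accurately while keeping the full suite
around a minute of compute; all scale up linearly through configuration.

## Known limitations

- The HWE/LD tests approximate the behaviour of the original filtering
  toolchain; counts on any given dataset may differ legitimately since the
  original tests are unstated.
- The directional-migration formulas are the published construction as
  interpreted here (pool as equal-weight frequency mean; basis-specific
  orientation as derived above); other implementations may differ in
  variant details.
- `normalize_depth` is a single rarefaction draw per seed; averaging over
  draws is available but not default.
- PERMDISP inherits the small-group bias of the standard procedure.
- Isotherm extraction is per-longitude-column (1-D crossings), matching a
  latitude-of-isotherm presentation; it does not trace closed 2-D contours.
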