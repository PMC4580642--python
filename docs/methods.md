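# Methods

This note records the models implemented in `epigwa`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that a user extending the package
should know about. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are homozygous biallelic calls of a fully inbred panel, coded
−1 for the major-allele homozygote and +1 for the minor-allele
homozygote (0 is the missing sentinel; heterozygotes are rejected by
default, or masked under the `"missing"` policy). The coding is
re-normalized at load so that the frequency of +1 is ≤ 0.5 per SNP; a
tie at exactly 0.5 is broken toward the alphabetically earlier allele
label (or the current column orientation when labels are absent), which
makes write→read round-trips stable across all three dialects (PLINK
bed/bim/fam, VCF, delimited matrix). SNPs with more than 5% missing
calls are dropped at load with a logged count — the source studies for
this kind of panel do not discuss missingness, and the threshold only
exists so that downstream stages may assume essentially complete data.
Coordinates are 1-based; the canonical SNP id is
`<chromosome>_<position>`.

## Phenotype standardization

Seedling records carry (accession, set, replicate, root length,
optional hypocotyl length). The prep pipeline is, in order:

1. **Hypocotyl filter** — seedlings with hypocotyl < 5 mm are removed
   (likely delayed germination; day-7 root length would be biased low).
   Records without a hypocotyl measurement are kept.
2. **Control-based set correction** — every value is shifted by the
   difference between the shared control accession's mean in its
   set × replicate cell and the control's global mean. The correction
   leaves the global control mean unchanged and is idempotent. A
   set-level-only variant is available via `by_replicate=False`.
3. **Replicate residualization** — within each set, values become
   residuals from a replicate-means model, re-centered on the set grand
   mean so the trait stays in mm (effect sizes downstream are reported
   in mm; raw residuals would lose location).
4. **Per-accession summary** — mean, unbiased (n−1) variance, count.

Filtering precedes the control correction; the order matters only
marginally (the filter removes a per-mille fraction of rows) and is
logged.

## Kinships and variance components

The additive kinship is `G = ZZ'/m`, where each polymorphic SNP column
is centered by its panel mean and scaled by its population standard
deviation (divisor n). This is the most common GWA convention and makes
diagonals ≈ 1; monomorphic SNPs are skipped with a logged count. The
additive-by-additive kinship is the Hadamard square `G∘G`, which is PSD
by the Schur product theorem.

The mixed model `y = μ + a + b + e` with `a ~ N(0, G σ²_a)` and
`b ~ N(0, G∘G σ²_aa)` is fitted by REML rather than the hierarchical
likelihood of the software that popularized this decomposition: the
target quantities are identical and REML's convergence behaviour is
better understood. Because G and G∘G do not commute, there is no joint
eigen-rotation; the restricted likelihood is evaluated directly via
Cholesky factorizations of `V = σ²_a G + σ²_aa G∘G + σ²_e I`, with the
analytic gradient `∂(−2ℓ_R)/∂σ²_i = tr(P V_i) − y'P V_i P y`, and
minimized by L-BFGS-B under non-negativity bounds from three
deterministic starts. Estimates below `1e-6 · var(y)` are reported as
exactly 0 (boundary solutions). Heritabilities are ratios on the
accession-level trait: `h² = σ²_a/σ²_P`, `H² = (σ²_a+σ²_aa)/σ²_P` with
`σ²_P = σ²_a+σ²_aa+σ²_e` from the fit.

Standard errors are delete-one-accession jackknife (the accession is
the analysis unit); deletions are warm-started from the full-data
estimates with a coarser optimizer tolerance (`ftol` 1e-6), which is
negligible against the between-deletion spread being estimated. Wald
tests are one-sided for variance ratios (testing > 0):
`p = ½·χ²₁-tail((est/se)²)` for positive estimates. The classical
broad-sense heritability is also provided from one-way ANOVA on
accession, using the mean-square method with the average group size
`n₀ = (N − Σn_i²/N)/(a−1)`; the actual F-test p-value is reported, never
a "p = 0" display artifact.

**Identifiability caveat.** Separating σ²_aa from σ²_e requires `G∘G`
to be far from the identity. A Cramér–Rao computation at
(σ²_a, σ²_aa, σ²_e) = (0, 2, 1), n = 200 shows the best achievable
z-statistic for H² = 2/3 is ~1.7 under weakly structured panels
(divergence F ≈ 0.3 between a few subpopulations) and ~4.7 under
family-structured panels (20 subpopulations at F = 0.8, i.e. groups of
closely related lines). Real inbred collections contain many closely
related accessions, and published Wald statistics of this magnitude for
epistatic variance components imply kinships of the informative kind;
the variance-component experiments in the test suite and acceptance
script therefore use the strongly related panel. Power claims do not
transfer to panels whose kinship is near-identity — no estimator can
beat the bound above.

## Additive scans

*Score scan.* Phenotype and SNP dosages are residualized on the
intercept plus the top `n_axes` eigenvectors of the kinship (default 3,
the most common choice for this panel size; configurable). Each SNP's
statistic is squared correlation × residual df `(n − n_axes − 1)`,
referred to χ²₁. The genome-wide call uses Bonferroni α/m.

*HEM ridge scan.* Stage 1 fits SNP-BLUP (`y = μ + Zu + e`,
`u ~ N(0, σ²_u I)`) with the common shrinkage chosen by REML on the
eigendecomposition of `ZZ'`. Stage 2 re-weights each SNP's prior
variance by `û_j²/(1 − h_jj)` with effect leverage
`h_jj = λ z_j'(λZZ'+I)⁻¹z_j` and re-solves the ridge system through the
n × n Woodbury form, so large stage-1 effects escape shrinkage. The 5%
genome-wide threshold is the 95th percentile of the maximum absolute
stage-2 effect over seeded phenotype permutations (default 1000); the
permutation p of the observed maximum is reported alongside, since a
threshold stated as a p-value is ambiguous for an effect-scale
statistic. The genotype eigenstructure is computed once and reused
across permutations. The threshold is label-invariant in distribution
(not draw-by-draw: permutations are drawn as index permutations).

## Two-locus scan

For −1/+1 dosages, `A² = B² = (AB)² = 1`, `A·AB = B`, `B·AB = A`, so the
normal equations of `Y ~ b0 + b1·A + b2·B + b3·AB + e` depend on the
data only through n, the column sums of A, B, AB and four phenotype
cross-products. The scan therefore reduces to two m × m matrix products
(`G'G` and `G'diag(y)G`, blocked to bound memory) plus batched 4 × 4
solves — ~2×10⁵ pairs fit in well under a second at n = 93. Filters, in
order: MAF strictly > 0.25; smallest two-locus class ≥ 4 (the *smallest*
class, not necessarily the double-minor one — it is the power-limiting
cell); collinear pairs (A ≡ ±B) skipped and counted. The interaction
t-test uses n − 4 df; pairs with p ≤ 1e-8 are retained, and the visit
counts reconcile exactly
(`total = skipped_class + skipped_collinear + visited`). `b3` is
reported in both the −1/+1 coding and the 0/1 coding (factor 4), since
the interaction contrast's parameterization differs between
conventions.

Survivors are refitted with the same four fixed terms plus a random
accession effect `N(0, G σ²_g)` — a one-kinship model, so the standard
eigen-rotation applies, with the variance ratio by 1-D REML and a Wald
t on b3 (n − 4 df, matching the pre-scan's reference under a degenerate
kinship). The genome-wide threshold treats the genome as
`genome_length/ld_block` independent blocks (125 Mb / 10 kb = 12,500)
and uses α/n_blocks² = 3.2×10⁻¹⁰; the unordered-pair count
n_blocks(n_blocks−1)/2 ≈ 78.1 million and its threshold variant are
reported alongside, because the two conventions differ by a factor ~2
and both appear in practice.

Pairs detected through tightly linked SNPs are merged by union-find on
the relation "both ends match with r² ≥ 0.8 in either orientation"
(transitive closure); each group's representative is its smallest
mixed-model p. Per-pair R² is from the four-term model; the joint R²
puts all unique pairs' A, B, AB columns in one model (aliased columns
handled by the least-squares projection); CIs are percentile bootstrap
over accessions, 1000 replicates by default, seeded.

## G-P map decomposition

For an estimated 2 × 2 class-mean map with observed joint class
frequencies, the additive variance v_a is the variance of the weighted
least-squares projection of the class means onto {1, x_A, x_B} under
those frequencies — the classical average-effect definition, which
handles LD between the loci automatically — and v_aa = v_g − v_a
exactly (orthogonality of the weighted residual). The decomposition is
computed under observed joint frequencies, not an independence
approximation; for independent loci at the construction frequency of a
cancellation map, v_a = 0 to 1e-10. Only non-empty classes enter; with
fewer than three non-empty classes the projection is undetermined and
v_a is flagged undefined (a model-based fill-in is deliberately not the
default). The cancellation index v_a/v_g is 0 under complete
cancellation and 1 for a purely additive map.

The cancellation construction itself: means
(b, b−d, b−d, b + d(1−2q)/q) for the four classes at shared minor
frequency q solve the zero-marginal identity
`(1−q)(g(+1,−1)−g(−1,−1)) + q(g(+1,+1)−g(−1,+1)) = 0` exactly, so both
loci have zero average allele-substitution effect at frequency q. The
same map at other frequencies has v_a > 0 — the cancellation is a
property of the map *and* the frequencies jointly.

## Small-sample false-positive statistic

A pair's double-recessive pseudo-marker is the indicator of the
double-minor homozygote. Given the (structure-adjusted) phenotype, the
null distribution of the carrier/non-carrier mean difference depends
only on the carrier count k, so the genome-wide false-positive
probability of an observed effect is determined by the carrier-count
histogram {k: M_k} over all scanned pairs:
`FPR = 1 − Π_k (1 − p_k)^{M_k}`, assuming pseudo-marker independence
(conservative under LD). p_k is the fraction of size-k carrier subsets
whose absolute mean difference matches or exceeds the observed one —
exhaustive over all C(n, k) subsets when that count is ≤ 2×10⁵,
otherwise seeded Monte-Carlo with an add-one correction. The observed
effect is the carrier/non-carrier mean difference on the phenotype
residualized on the top kinship eigenvectors (the same adjustment as
the additive scan); the model-coefficient alternative and the
no-adjustment variant are both reachable through the function
arguments.

**Limitation.** The add-one correction floors Monte-Carlo p_k at
`1/(mc_draws+1)` (1e-5 at the default), so for a very strong effect
scanned against ≳10⁵ pseudo-markers the aggregated FPR saturates near 1
— the report is conservative by construction, never anti-conservative.
Resolving genome-scale FPRs for such effects requires analytic tail
evaluation beyond the permutation-equivalent definition implemented
here; the exact-enumeration branch is unaffected.

## Apparent-epistasis risk

A significant pair may tag one unobserved causal variant: any variant
in high r² with the pair's pseudo-marker can masquerade as epistasis.
Against a large re-sequenced reference panel, subsamples of the GWA
panel's size (default 93) are drawn repeatedly (default 50 replicates)
with exactly `round(maf_pm · n_sample)` pseudo-marker carriers
(stratified uniform sampling), and the squared Pearson correlation
between the pseudo-marker and every variant is profiled. Reported:
grand-mean r² ± replicate spread, mean per-replicate maximum ± spread,
and the exceedance risk P(r²_max > 0.8) from a Gaussian fit to the
replicate maxima — the raw exceedance fraction of 50 replicates cannot
resolve probabilities below 0.02, while the Gaussian tail can, and both
are reported. The pair's own loci (± 1 bp) are excluded from the scan
by default, plus any supplied list of genotyped markers; variants
monomorphic within a subsample are skipped for that replicate and
counted. Under an independent panel the grand-mean r² equals the
permutation expectation `1/(n_sample − 1)` ≈ 0.011 at n = 93.

## Synthetic data: what is and is not emulated

*Panel.* Balding–Nichols divergence with haploid-equivalent (inbred)
sampling: ancestral frequency per SNP uniform on (0.05, 0.5), each
subpopulation's frequency Beta-distributed around it with divergence F,
each accession drawing its homozygote from its subpopulation frequency.
Defaults: 93 accessions, 3 subpopulations, F = 0.3 — strong regional
structure with a single interpretable parameter. Not emulated:
recombination maps, LD decay along chromosomes (SNPs are exchangeable
within subpopulation), selection, coalescent genealogies. Tests passing
on this generator show correctness of the *analysis*, not robustness to
fine-scale LD, which real panels have and this generator deliberately
does not.

*Planted pairs.* The two loci of a planted architecture are generated
independent of each other and of the panel (the interesting real pairs
are inter- or long-range intra-chromosomal), holding their target
minor-class count exactly (`round(q·n)` carriers placed at random):
detected pairs in a real scan have their observed frequencies by
construction, and Bernoulli sampling would drop a q = 0.3 locus below
the strict MAF > 0.25 filter in a quarter of runs. The residual noise
is Gaussian at the accession level; `residual_sd_for_r2` converts a
target pair-R² into a noise scale via the map's population genetic
variance. The recovery experiments plant the pair at accession-level
R² = 0.35, the interaction strength implied by genome-wide-significant
detection at n = 93 (t ≈ 6.9 for p ≈ 1.5×10⁻¹⁰); at R² = 0.15 the
interaction t is ~4.0, below the noise floor of ~2×10⁵ simultaneous
tests, and no scan could rank such a pair first.

*Seedlings.* 4 sets of 23 accessions plus the shared control accession
in every set, 3 replicates, 70 seedlings per accession and replicate;
record = accession mean + set shift (sd 0.5 mm) + replicate shift
(sd 0.3 mm) + seedling noise (sd 1.732 mm). Accession means are drawn
at 12 ± 1 mm and standardized so the panel's realized dispersion is
exactly 1 mm — the panel is a fixed set of lines whose between-line
variance is a property of the panel — making the accession-level
broad-sense heritability 1/(1+3) = 0.25 by construction. A small
fraction of seedlings (rate 0.0016) receive hypocotyls below 5 mm to
exercise the filter. Not emulated: non-germination, spatial plate
effects, non-Gaussian measurement error.

*Reference panel.* 728 accessions, independent variants at uniform
frequencies; optionally one planted variant whose sample r² with a
given pseudo-marker reaches a target within ±0.05 (greedy single-entry
flips from an exact copy). Real reference panels have genome-wide LD
structure; the independent panel isolates the null behaviour of the
r² profile.

## Numerical choices and degenerate inputs

- Kinship validation: symmetry to 1e-10 (relative), PSD to −1e-8 × the
  largest eigenvalue.
- REML: σ²_e bounded below at 1e-8 · var(y) to keep V positive
  definite; zero-variance phenotypes short-circuit to all-zero
  components with p = 1.
- Pair scan: exact-fit pairs (zero residual) get p = 0 via the t-test's
  infinite statistic; negative rounding residue in RSS is clipped at 0.
- `gaussian_tail_risk` with zero spread returns 0/1 by the sign of
  (threshold − mean), 0.5 at an exact tie.
- Single-row replicates residualize to the set mean (residual 0) with a
  logged warning.
- All generators and all resampling stages (permutations, bootstraps,
  Monte-Carlo tails, subsamples) consume `numpy.random.default_rng`
  streams derived from explicit seeds; reruns are byte-identical.

## Problem sizes used by the shipped experiments

The test suite and acceptance script run the scans on 93-accession
panels with ~1200 SNPs (~500–700 after the MAF filter; ~1.6×10⁵ pairs),
the variance-component experiments at n = 200 with 20 jackknifed runs,
the null LD profile on a 728 × 10,000 reference panel with 50
replicates, and the seedling design at its full 20,160 rows. These
sizes make every stage's statistical claim measurable in minutes on one
CPU while keeping the per-stage estimators identical to what a
full-size panel would use.
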