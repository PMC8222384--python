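# Methods

## Data model and coordinate conventions

Input is one Bismark-coverage-style table per sample: chromosome,
1-based position, strand, context (CpG / CHG / CHH), methylated and
unmethylated read counts. CHG and CHH are collapsed to a single "CpH"
context at read time, and all analyses run separately per context.
Interval inputs (CpG islands, exons, introns, enhancers,
super-enhancers) are BED, 0-based half-open; a cytosine at 1-based
position *p* overlaps [s, e) iff s < p ≤ e. Symmetric CpGs on opposite
strands are kept as distinct sites — no destranding or strand merging
is applied, since the effect of merging on the counteraction logic is
not obvious and keeping sites distinct is the conservative choice.

## Per-cytosine test

After coverage filtering (total ≥ 10 reads, inclusive; per-sample
upper cap at that sample's 99.9th coverage percentile, computed over
the sample's own retained records) and the unite rule (site covered in
≥ 3 samples of every compared group; missing entries are absent, not
zero), each site is tested with a binomial logistic regression of
methylation proportion on group membership, sample counts as trials,
and a 1-df likelihood-ratio chi-squared test of the group term.

Because the model has a single binary covariate, its MLE is available
in closed form — the fitted proportion of every sample is its group's
pooled methylated fraction — so the statistic is computed vectorised
as a deviance difference:

G = 2·[ ℓ(p̂₁, p̂₂) − ℓ(p̂₀) ],  p = P(χ²₁ ≥ G),

with p̂ the pooled fractions per group and overall. This is
numerically identical to fitting the GLM per site (verified against
statsmodels in the tests) and reduces exactly to the classical 2×2
G-test for one-sample-per-group designs. The methylation difference is
reported in percentage points as 100·(p̂₂ − p̂₁), group2 minus group1.
No overdispersion correction is applied in the per-site test (a
deliberate match to the standard count-based caller's default);
between-sample dispersion enters only in region calling.

## Multiple testing: SLIM q-values

The null proportion π₀ is estimated with a sliding-linear-model
scheme: the p-value survival curve S(λ) = frac(p > λ) is evaluated on
a λ grid (0.01–0.95, 100 points); ten overlapping windows of the grid
are each fitted by ordinary least squares; the window with the
smallest mean squared residual — i.e. the most linear stretch, which
under a two-component mixture is the region where the alternative
density has vanished — supplies the slope, and π₀ = −slope clipped to
(0, 1]. q-values are π₀ times Benjamini–Hochberg, clipped to [0, 1];
with π₀ = 1 the two methods coincide exactly, and BH is selectable as
a fallback. The original publication's bootstrap-based window
selection is simplified to this goodness-of-fit selection; with fewer
than 100 tests π₀ is fixed at 1 (BH), since a mixture cannot be
estimated reliably there. Under uniform nulls (10⁴ draws) the
estimator stays within [0.97, 1.0].

Significance uses strict inequalities at both thresholds: q < 0.001
and |Δ| > 25 percentage points. Direction (hyper/hypo) is the sign of
Δ at significant sites.

## Region calling

Per site and group, the beta-binomial mean is the pooled fraction and
the intra-class correlation ρ is a method-of-moments estimate from the
coverage-weighted dispersion of sample-level proportions; the Wald
statistic tests the mean difference with variance inflated by
1 + (n−1)ρ. Qualifying sites (Wald p < 0.01 and |Δ| > 25) within
1000 bp of each other are merged; regions need ≥ 3 cytosines and
|mean Δ| > 25; the region p combines member z-scores (Stouffer) and is
BH-adjusted with a 0.05 threshold. No kernel smoothing is applied —
the merging-distance and site-level screen stand in for it, and the
simplification is noted in the output metadata by construction (the
region caller has no smoothing parameters to echo).

## Counteraction

The aging comparison is aged-STD vs young-STD; the enrichment
comparison is aged-ENR vs aged-STD. On the intersection of the two
united site universes every site receives exactly one class:

- **counteracted** — significant in both comparisons, opposite signs;
- **same_direction** — significant in both, same sign;
- **age_only** / **enr_only** — significant in one;
- **unaffected** — significant in neither.

Counteraction deliberately requires significance in *both*
comparisons; a sub-threshold opposite trend stays age_only. Sites
present in only one unite are classified from the available evidence
and flagged `partial`; they are excluded from the shared-universe
summary counts. Overlap significance is the one-sided upper-tail
hypergeometric probability of the both-significant overlap given the
two set sizes and the universe.

Restoration re-runs the per-site test young-STD vs aged-ENR restricted
to counteracted sites and reports the fraction *not* significant. The
random-sampling control draws the enrichment-set size uniformly
without replacement from the universe and measures the overlap
fraction with the age-affected set; the draw is realised through the
exactly equivalent hypergeometric overlap distribution, which is why
its mean matches |age_dm|/|universe| by construction. The empirical p
uses the add-one convention, (#{resamples ≥ observed}+1)/(n+1). The
split-half control partitions aged-STD at random into disjoint
discovery and comparison subsets of three, recomputes both result sets
independently, and reports the hypergeometric overlap p.

## Annotation and enrichment

Shores are the 2 kb flanks of every CpG island minus any island
overlap, clipped at position 0; promoters span TSS ± 1 kb (2 kb + 1
position); intergenic is the complement of gene bodies
(exons ∪ introns) and promoters. Feature classes are tested
independently — a site may belong to several — matching per-feature
reporting rather than a precedence hierarchy. Enrichment of a
differentially methylated set within its covered background is a
logistic regression of the site's dm indicator on feature membership
(statsmodels GLM); the log2 odds ratio is the coefficient over ln 2,
with a one-sided normal p (direction carried by the sign) and FDR
across classes. For the single binary covariate the MLE equals the
2×2 cross-product ratio, which serves as the independent oracle in
the tests; zero-margin tables are flagged and reported as ±∞ with a
Haldane-corrected (+0.5) estimate alongside.

Sites map to the gene with the nearest TSS; exact ties prefer the
gene for which the site lies upstream on the gene's strand, then
lexicographic gene id, and are flagged. Genes with ≥ 4 annotated dm
cytosines (CpG and CpH counted together, the inclusive "at least
four" rule) are differentially methylated genes; a flag-free helper
(`gene_direction`) assigns a gene-level direction by majority of its
dm cytosines with exact ties labelled "mixed", for direction-aware
gene overlaps. Gene-set over-representation is the upper-tail
hypergeometric p with q = |query ∩ set|, m = |background ∩ set|,
n = |background \ set|, k = |query|, FDR across sets.

## Motif scanning

PWMs are per-position base probabilities (columns sum to 1); scores
are log-odds against a uniform background after a 10⁻³ pseudocount. A
window is a hit when its best score over all offsets and both strands,
rescaled linearly from [min_possible, max_possible] to [0, 1], reaches
the match threshold (default 0.90 — the convention of standard motif
tools for a "90% match score"). Unknown bases contribute the column
minimum, so degenerate windows cannot reach a high threshold. Window
half-width defaults to 25 bp around the cytosine. Motif enrichment is
the same upper-tail hypergeometric test with dm/background hit
counts, FDR across motifs; a stratified breakdown tests whether
motif-hit counteracted cytosines are enriched for the
hypomethylated-with-aging stratum.

## Synthetic data generator

The generator emulates a four-group RRBS aging study on two synthetic
chromosomes:

- **Design:** group sizes 5 (young-STD), 5 (young-ENR), 7 (aged-STD),
  7 (aged-ENR) by default — the study's sample sizes.
- **Coverage:** negative binomial, mean 30, dispersion 5 — RRBS depth
  is strongly overdispersed, and a Poisson/uniform model would
  understate the filtering steps.
- **Baselines:** CpG levels from a bimodal Beta mixture (0.9 weight
  Beta(8,2) high, 0.1 weight Beta(2,8) low), CpH levels Beta(1,50).
  The source data report no distributions; these are modelling choices
  recorded in the config and chosen to reproduce the characteristic
  bimodal CpG / near-zero CpH marginal pattern.
- **Aging effects:** a configurable fraction of sites (default 0.05)
  shifts by ± the effect size (default 0.35) in aged-STD; 78% of CpG
  effects are hypomethylating and 74% of CpH effects
  hypermethylating, mirroring the reported directional asymmetry.
  Direction assignment honours headroom — methylation is lost
  preferentially where it exists and gained where there is room —
  because a shift that clamps at the [0.01, 0.99] bounds is both
  biologically implausible and undetectable; residual clamps are
  counted and reported.
- **Counteraction:** a configurable fraction of age-affected sites
  (default 0.32) has the aged-ENR level equal to the baseline (full
  restoration); all other age-affected sites carry the aged-STD level
  in aged-ENR too. Both young groups sit at the baseline.
- **Placement:** features are tiled deterministically (one gene per
  8 kb with an exon–intron–exon body, islands over alternating TSSs,
  enhancers in the intergenic gaps, every tenth enhancer widened to a
  super-enhancer); aging effects can be concentrated into enhancers at
  a configurable factor, and motif consensus sequences are embedded in
  the windows of counteracted hypomethylated CpGs at a configurable
  multiple of a 3% background rate. The shipped PWM is a sharp
  synthetic CpG-centred matrix (`Mecp2_synthetic`), not a biological
  motif: its 0.991 per-column sharpness means only exact consensus
  matches pass the 0.90 threshold, keeping chance hits near 10⁻³ so
  planted rate ratios are interpretable.
- **Counts:** methylated reads are Binomial(coverage, level) per
  sample; everything is driven by one seed and emitted fixtures are
  byte-identical under it.

What the generator does *not* emulate: read-level bisulfite
conversion error, fragment-end artifacts, SNP contamination,
CpG-density-dependent coverage clustering, and biological
between-sample variance beyond binomial sampling (no per-sample
random effects). Passing the recovery tests therefore demonstrates
the correctness of the analysis logic and its calibration under the
modelled noise, not performance on real RRBS libraries, where
overdispersion between replicates will reduce per-site power.

Default problem sizes used in the automated checks — 2 × 10⁴ CpGs
for calibration runs, smaller fixtures for integration tests — are
desk-scale choices; a real RRBS experiment covers an order of
magnitude more cytosines, and the thresholds' behaviour is expected
to transfer since all tests are per-site.

## Numerical choices and degenerate inputs

- Strict inequalities at both significance thresholds; q exactly at
  threshold or |Δ| exactly 25 is not significant.
- Empty inputs propagate as empty outputs (coverage filter, region
  caller below 3 sites, empty counteracted set → restoration NA).
- xlogy handles zero counts in the deviance; the G statistic is
  floored at 0 against round-off.
- The per-site Wald z is set to 0 where the standard error vanishes
  (both groups at 0% or 100% with no dispersion).
- Hypergeometric tails come from scipy's `hypergeom.sf(q−1, …)`,
  matching the upper-tail `phyper(q−1, …, lower.tail = FALSE)` form;
  exhaustive enumeration backs it in tests for small universes.
- The percentage summary rounds to two decimals, the precision used in
  the reported accounting.

## Known limitations

- The per-site test ignores between-replicate overdispersion; q-values
  on real data are anti-conservative to the degree replicates exceed
  binomial noise. The region caller's beta-binomial Wald statistic is
  the overdispersion-aware path.
- SLIM's window selection is goodness-of-fit based, not bootstrap
  based; with strong signal concentrated near p = 0 the estimator is
  mildly conservative (π₀ biased towards 1).
- The split-half control fixes subset size at 3 to respect the unite
  rule; with 7 aged-STD samples one sample is left unused per split.
- Nearest-TSS annotation considers only genes on the same chromosome;
  sites on a chromosome without genes stay unmapped.
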